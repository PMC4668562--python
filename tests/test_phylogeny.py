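import random

import dendropy
import numpy as np
import pytest

from ltrscape.families import Family
from ltrscape.motifs import lineage_references
from ltrscape.phylogeny import (
    DistanceMatrix,
    assign_lineage,
    nj_tree,
    pairwise_distances,
)
from ltrscape.synthetic import _random_seq, mutate


def test_identical_sequences_zero_matrix():
    rng = np.random.default_rng(0)
    s = _random_seq(rng, 200)
    dm = pairwise_distances({"a": s, "b": s, "c": s})
    assert np.allclose(dm.matrix, 0)


def test_pairwise_jc_closed_form():
    rng = np.random.default_rng(1)
    a = _random_seq(rng, 200)
    b = list(a)
    for i in range(0, 200, 20):  # 10 changes over 200 sites
        b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
    dm = pairwise_distances({"a": a, "b": "".join(b), "c": a})
    assert dm.matrix[0, 1] == pytest.approx(0.0517, abs=5e-4)


def test_saturated_pair_capped():
    dm = pairwise_distances({"a": "A" * 150, "b": "C" * 150, "c": "A" * 150})
    assert dm.matrix[0, 1] == 3.0
    assert ("a", "b") in dm.capped_pairs


def test_too_few_or_short():
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError):
        pairwise_distances({"a": _random_seq(rng, 200), "b": _random_seq(rng, 200)})
    with pytest.raises(ValueError):
        pairwise_distances({"a": "ACGT" * 10, "b": "ACGT" * 10, "c": "ACGT" * 10})


def test_nj_three_taxa_closed_form():
    dm = DistanceMatrix(["A", "B", "C"],
                        np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]]))
    tree = dendropy.Tree.get(data=nj_tree(dm), schema="newick")
    lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx(0.05)
    assert lengths["B"] == pytest.approx(0.15)
    assert lengths["C"] == pytest.approx(0.25)


def test_nj_two_taxa_errors():
    dm = DistanceMatrix(["A", "B"], np.array([[0, 0.1], [0.1, 0]]))
    with pytest.raises(ValueError):
        nj_tree(dm)


def test_nj_asymmetric_matrix_errors():
    m = np.array([[0, 0.1, 0.2], [0.3, 0, 0.1], [0.2, 0.1, 0]])
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["A", "B", "C"], m))


def _random_additive_case(trial, rng):
    n = int(rng.integers(6, 11))
    taxa = [f"t{i}" for i in range(n)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=ns, rng=random.Random(trial))
    for e in tree.preorder_edge_iter():
        if e.head_node is not tree.seed_node:
            e.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                m[i, j] = pdm.distance(ns[i], ns[j])
    return tree, ns, taxa, m


def test_nj_recovers_additive_trees():
    """Topology and branch lengths recovered exactly from additive input."""
    rng = np.random.default_rng(3)
    for trial in range(30):
        true_tree, ns, taxa, m = _random_additive_case(trial, rng)
        est = dendropy.Tree.get(data=nj_tree(DistanceMatrix(taxa, m)),
                                schema="newick", taxon_namespace=ns)
        for t in (true_tree, est):
            t.is_rooted = False
            t.deroot()
            t.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(true_tree, est) == 0
        pdm2 = est.phylogenetic_distance_matrix()
        n = len(taxa)
        for i in range(n):
            for j in range(i + 1, n):
                assert abs(pdm2.distance(ns[i], ns[j]) - m[i, j]) < 1e-9


def test_newick_roundtrip():
    dm = DistanceMatrix(["A", "B", "C", "D"],
                        np.array([[0, 0.3, 0.5, 0.6],
                                  [0.3, 0, 0.6, 0.7],
                                  [0.5, 0.6, 0, 0.3],
                                  [0.6, 0.7, 0.3, 0]]))
    nwk = nj_tree(dm)
    t1 = dendropy.Tree.get(data=nwk, schema="newick")
    nwk2 = t1.as_string(schema="newick").strip()
    t2 = dendropy.Tree.get(data=nwk2, schema="newick",
                           taxon_namespace=t1.taxon_namespace)
    for t in (t1, t2):
        t.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


def test_nj_with_outgroup_roots_tree():
    dm = DistanceMatrix(["A", "B", "C", "OG"],
                        np.array([[0, 0.2, 0.4, 1.0],
                                  [0.2, 0, 0.4, 1.0],
                                  [0.4, 0.4, 0, 1.0],
                                  [1.0, 1.0, 1.0, 0]]))
    nwk = nj_tree(dm, outgroup="OG")
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    children = tree.seed_node.child_nodes()
    labels = {c.taxon.label for c in children if c.taxon is not None}
    assert "OG" in labels


class TestLineage:
    def test_seeded_family_recovers_lineage(self):
        rng = np.random.default_rng(4)
        refs = lineage_references()
        for name, sf, seq in refs[:4]:
            fam = Family("f", ["e"], superfamily=sf)
            res = assign_lineage(fam, refs, rt_region=mutate(seq, 0.05, rng))
            assert res.lineage == name

    def test_trim_family_unassigned(self):
        fam = Family("f", ["e"], superfamily="TRIM")
        assert assign_lineage(fam).lineage == "unassigned"

    def test_distant_family_unassigned(self):
        rng = np.random.default_rng(5)
        fam = Family("f", ["e"], superfamily="Copia")
        res = assign_lineage(fam, rt_region="A" * 300 + "C" * 300)
        assert res.lineage == "unassigned"

    def test_reference_order_invariant(self):
        rng = np.random.default_rng(6)
        refs = lineage_references()
        fam = Family("f", ["e"], superfamily="Gypsy")
        rt = mutate([r for r in refs if r[1] == "Gypsy"][2][2], 0.05, rng)
        a = assign_lineage(fam, refs, rt_region=rt)
        b = assign_lineage(fam, list(reversed(refs)), rt_region=rt)
        assert (a.lineage, a.reference_id) == (b.lineage, b.reference_id)

    def test_exact_tie_flagged(self):
        ref_seq = "ACGT" * 50
        refs = [("Aaa", "Copia", ref_seq), ("Bbb", "Copia", ref_seq)]
        fam = Family("f", ["e"], superfamily="Copia")
        res = assign_lineage(fam, refs, rt_region=ref_seq)
        assert res.lineage == "Aaa" and res.tie
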