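import numpy as np
import pytest

from ltrscape.annotate import LTRElement
from ltrscape.families import (
    Family,
    assign_superfamily,
    build_consensus,
    cluster_families,
    structure_ratio,
    summarize_superfamilies,
)
from ltrscape.io import GenomeSequence
from ltrscape.motifs import reverse_translate, superfamily_motifs
from ltrscape.pipeline import adjusted_rand_index
from ltrscape.synthetic import _random_seq, mutate


def _elements_from_ltrs(ltrs):
    """One pseudo-chromosome holding the given LTR sequences as solo elements."""
    rng = np.random.default_rng(1)
    seq = ""
    elements = []
    for i, ltr in enumerate(ltrs):
        seq += _random_seq(rng, 100)
        start = len(seq)
        seq += ltr
        elements.append(
            LTRElement("c", start, len(seq), ltr5=(start, len(seq)),
                       n_ltrs=1, element_id=f"e{i}")
        )
    seq += _random_seq(rng, 100)
    return {"c": GenomeSequence("c", seq)}, elements


def test_identical_ltrs_same_family():
    rng = np.random.default_rng(2)
    ltr = _random_seq(rng, 300)
    genomes, els = _elements_from_ltrs([ltr, ltr])
    fams = cluster_families(els, genomes)
    assert len(fams) == 1


def test_low_identity_split():
    rng = np.random.default_rng(3)
    a = _random_seq(rng, 300)
    b = mutate(a, 0.45, rng)  # ~70% identity
    genomes, els = _elements_from_ltrs([a, b])
    assert len(cluster_families(els, genomes)) == 2


def test_single_linkage_chain():
    rng = np.random.default_rng(4)
    a = _random_seq(rng, 400)
    b = mutate(a, 0.18, rng)   # ~85% to a
    c = mutate(b, 0.18, rng)   # ~85% to b, ~72% to a
    genomes, els = _elements_from_ltrs([a, b, c])
    assert len(cluster_families(els, genomes)) == 1


def test_clustering_order_independent():
    rng = np.random.default_rng(5)
    anc1, anc2 = _random_seq(rng, 300), _random_seq(rng, 300)
    ltrs = [mutate(anc1, 0.05, rng) for _ in range(3)] + [
        mutate(anc2, 0.05, rng) for _ in range(3)
    ]
    genomes, els = _elements_from_ltrs(ltrs)
    cluster_families(els, genomes)
    labels1 = [e.family_id for e in els]
    perm = [3, 0, 5, 2, 4, 1]
    els_perm = [els[i] for i in perm]
    cluster_families(els_perm, genomes)
    labels2 = [e.family_id for e in els]
    assert adjusted_rand_index(labels1, labels2) == 1.0


def test_planted_families_recovered(classified):
    _, manifest, elements, families = classified
    truth, called = [], []
    by_pos = {(e.seq_id, e.start): e for e in elements}
    for _, t in manifest.iterrows():
        hit = [e for e in elements if abs(e.start - t.start) <= 5]
        if hit:
            truth.append(t.family)
            called.append(hit[0].family_id)
    assert len(truth) >= 0.9 * len(manifest)
    assert adjusted_rand_index(truth, called) >= 0.95


def test_consensus_single_member():
    assert build_consensus(["ACGT"]) == "ACGT"


def test_consensus_majority_vote():
    assert build_consensus(["AACGT", "AACGT", "AGCGT"]) == "AACGT"


def test_consensus_recovers_ancestor():
    rng = np.random.default_rng(6)
    anc = _random_seq(rng, 500)
    members = [mutate(anc, 0.02, rng) for _ in range(7)]
    cons = build_consensus(members)
    same = sum(a == b for a, b in zip(cons, anc))
    assert same / len(anc) >= 0.99


class TestSuperfamily:
    def _family(self, internal, element_len=8000):
        fam = Family("f0", ["e0"], consensus_internal=internal,
                     mean_element_len=element_len)
        return fam

    def test_copia_domain_order(self):
        rng = np.random.default_rng(7)
        motifs = superfamily_motifs()
        int_nt = reverse_translate(motifs["Copia"]["INT"], rng)
        rt_nt = reverse_translate(motifs["Copia"]["RT"], rng)
        internal = (_random_seq(rng, 500) + int_nt + _random_seq(rng, 800)
                    + rt_nt + _random_seq(rng, 500))
        assert assign_superfamily(self._family(internal)) == "Copia"

    def test_gypsy_domain_order(self):
        rng = np.random.default_rng(8)
        motifs = superfamily_motifs()
        int_nt = reverse_translate(motifs["Gypsy"]["INT"], rng)
        rt_nt = reverse_translate(motifs["Gypsy"]["RT"], rng)
        internal = (_random_seq(rng, 500) + rt_nt + _random_seq(rng, 800)
                    + int_nt + _random_seq(rng, 500))
        assert assign_superfamily(self._family(internal)) == "Gypsy"

    def test_lard_large_noncoding(self):
        rng = np.random.default_rng(9)
        assert assign_superfamily(self._family(_random_seq(rng, 5000))) == "LARD"

    def test_trim_small(self):
        rng = np.random.default_rng(10)
        fam = self._family(_random_seq(rng, 600), element_len=1800)
        assert assign_superfamily(fam) == "TRIM"

    def test_motif_free_midsize_unknown(self):
        rng = np.random.default_rng(11)
        fam = self._family(_random_seq(rng, 2500), element_len=3500)
        assert assign_superfamily(fam) == "unknown"

    def test_no_internal_unknown(self):
        assert assign_superfamily(Family("f", ["e"])) == "unknown"


@pytest.mark.parametrize(
    "counts,expected",
    [((1326, 948, 241, 160), "0.71"),   # Copia-like row
     ((619, 1060, 123, 112), "1.58"),   # Gypsy-like row
     ((3221, 2896, 578, 552), "0.91"),  # totals
     ((20, 175, 7, 12), "6.93"),        # Tekay lineage
     ((12, 55, 2, 4), "4.21"),          # TAR lineage
     ((76, 318, 22, 33), "3.58"),       # Athila lineage
     ((0, 5, 0, 0), "/")],              # no intact members
)
def test_structure_ratio(counts, expected):
    it, st, in_t, sn_t = counts
    assert structure_ratio(it, st, in_t, sn_t) == expected


def test_summary_partition_and_ratio(annotated_df):
    _, df = annotated_df
    df = df.copy()
    df["superfamily"] = ["A" if i % 2 else "B" for i in range(len(df))]
    summary = summarize_superfamilies(df)
    total = summary[summary.superfamily == "Total"].iloc[0]
    assert total.subtotal == len(df)
    per = summary[summary.superfamily != "Total"]
    assert per.subtotal.sum() == len(df)
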