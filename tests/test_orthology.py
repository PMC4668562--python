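import itertools

import numpy as np
import pytest

from ltrscape.annotate import annotate_genome
from ltrscape.dating import ltr_divergence
from ltrscape.orthology import (
    OrthologCall,
    STOPS,
    call_orthologs,
    codon_site_counts,
    divergence_time,
    extract_junctions,
    intra_inter_contrast,
    is_synonymous,
    ng86_ka_ks,
)
from ltrscape.synthetic import (
    CODONS,
    PlantSpec,
    _random_seq,
    diverge_genomes,
    generate_background,
    mutate,
    plant_elements,
)


@pytest.fixture(scope="module")
def genome_pair():
    """Two diverged genomes (1% substitutions each) sharing half the insertions."""
    bg = generate_background(2_000_000, 0.4, seed=31)
    spec = PlantSpec(n_intact=30, n_solo=10, target_K=0.02, seed=31)
    g0, man0 = plant_elements(bg, spec)
    ga, ma, gb, mb = diverge_genomes(g0, man0, ortholog_fraction=0.5,
                                     point_divergence=0.01, seed=32)
    elements = annotate_genome([ga])
    return ga, ma, gb, mb, elements


def test_junction_extraction_matches_truth(genome_pair):
    ga, ma, _, _, elements = genome_pair
    genomes = {ga.id: ga}
    extracted = 0
    for el in elements:
        j = extract_junctions(el, genomes)
        if j is None:
            continue
        extracted += 1
        left, right = j
        assert len(left) == len(right) == 100
        assert left[50:] == ga.residues[el.start : el.start + 50]
        assert right[:50] == ga.residues[el.end - 50 : el.end]
    assert extracted >= 0.9 * len(elements)


def test_junction_skips_contig_edge():
    rng = np.random.default_rng(33)
    from ltrscape.annotate import LTRElement
    from ltrscape.io import GenomeSequence

    seq = _random_seq(rng, 400)
    g = GenomeSequence("c", seq)
    el = LTRElement("c", 30, 200, ltr5=(30, 100), n_ltrs=1)
    assert extract_junctions(el, {"c": g}) is None


def test_junction_skips_duplicated_locus():
    rng = np.random.default_rng(34)
    from ltrscape.annotate import LTRElement
    from ltrscape.io import GenomeSequence

    unit = _random_seq(rng, 600)
    seq = _random_seq(rng, 500) + unit + _random_seq(rng, 500) + unit + _random_seq(rng, 500)
    g = GenomeSequence("c", seq)
    el = LTRElement("c", 600, 1000, ltr5=(600, 1000), n_ltrs=1)
    assert extract_junctions(el, {"c": g}) is None


def test_ortholog_links_against_manifest(genome_pair):
    ga, ma, gb, mb, elements = genome_pair
    calls = call_orthologs(elements, {ga.id: ga}, gb)
    kept = {}
    for _, r in ma.iterrows():
        kept[int(r.start)] = r.ortholog_partner != ""
    by_id = {e.element_id: e for e in elements}
    tp = fp = 0
    for c in calls:
        el = by_id[c.element_id]
        truth = [v for k, v in kept.items() if abs(k - el.start) <= 8]
        if not truth:
            continue
        if c.status == "orthologous":
            tp += truth[0]
            fp += not truth[0]
    n_links = sum(kept.values())
    assert tp / (tp + fp) >= 0.95
    assert tp >= 0.85 * n_links


def test_deleted_insertion_called_absent(genome_pair):
    ga, ma, gb, mb, elements = genome_pair
    calls = call_orthologs(elements, {ga.id: ga}, gb)
    kept = {int(r.start): r.ortholog_partner != "" for _, r in ma.iterrows()}
    by_id = {e.element_id: e for e in elements}
    absent_truth = [
        c for c in calls
        if any(abs(k - by_id[c.element_id].start) <= 8 and not v for k, v in kept.items())
    ]
    assert absent_truth
    frac_absent = np.mean([c.status == "absent" for c in absent_truth])
    assert frac_absent >= 0.8


def test_intra_inter_contrast_detects_older_insertion():
    """Elements inserted well before the split: intra >> inter divergence."""
    rng = np.random.default_rng(35)
    calls = []
    for i in range(20):
        anc = _random_seq(rng, 400)
        l5, l3 = mutate(anc, 0.026, rng), mutate(anc, 0.026, rng)
        a5, a3 = mutate(l5, 0.013, rng), mutate(l3, 0.013, rng)
        b5, b3 = mutate(l5, 0.013, rng), mutate(l3, 0.013, rng)
        c = OrthologCall(f"e{i}", "orthologous")
        c.K_intra_A = ltr_divergence(a5, a3)[1]
        c.K_intra_B = ltr_divergence(b5, b3)[1]
        c.K_inter_5 = ltr_divergence(a5, b5)[1]
        c.K_inter_3 = ltr_divergence(a3, b3)[1]
        calls.append(c)
    res = intra_inter_contrast(calls)
    assert res["mean_intra_A"] > res["mean_inter"]
    assert res["intra_A_vs_inter"]["p"] < 0.01
    assert res["intra_A_vs_intra_B"]["p"] > 0.01  # genomes evolve alike


def test_intra_inter_needs_two():
    with pytest.raises(ValueError):
        intra_inter_contrast([])


class TestNG86:
    def test_identical(self):
        r = ng86_ka_ks("ATGAAA", "ATGAAA")
        assert r.Ks == r.Ka == 0.0

    def test_phe_synonymous_case(self):
        r = ng86_ka_ks("TTT" * 11, "TTC" + "TTT" * 10)
        assert (r.Sd, r.Nd) == (1.0, 0.0)
        assert r.Ka == 0.0 and r.Ks > 0
        assert r.S == pytest.approx(11 / 3)

    def test_site_counts_sum(self):
        rng = np.random.default_rng(36)
        cds = "".join(CODONS[i] for i in rng.integers(0, len(CODONS), 50))
        s, n = codon_site_counts(cds)
        assert s + n == pytest.approx(150)

    def test_errors(self):
        with pytest.raises(ValueError):
            ng86_ka_ks("ATG", "ATGAAA")
        with pytest.raises(ValueError):
            ng86_ka_ks("ATGA", "ATGA")
        with pytest.raises(ValueError):
            ng86_ka_ks("TAAAAA", "TAAAAA")
        with pytest.raises(ValueError):
            ng86_ka_ks("ATN", "ATG")

    def test_agrees_with_path_enumeration_oracle(self):
        """Exact (S, N, Sd, Nd) equality on random short codon pairs."""
        rng = np.random.default_rng(37)
        for _ in range(300):
            ncod = int(rng.integers(1, 6))
            c1 = "".join(CODONS[i] for i in rng.integers(0, len(CODONS), ncod))
            c2 = _mutate_cds(c1, int(rng.integers(0, 4)), rng)
            r = ng86_ka_ks(c1, c2)
            S, N, Sd, Nd = _oracle(c1, c2)
            assert (r.S, r.N, r.Sd, r.Nd) == pytest.approx((S, N, Sd, Nd), abs=1e-12)


def _mutate_cds(cds, n_changes, rng):
    out = list(cds)
    for _ in range(n_changes):
        for _attempt in range(50):
            p = int(rng.integers(0, len(out)))
            b = "ACGT"[int(rng.integers(0, 4))]
            cand = out.copy()
            cand[p] = b
            codon = "".join(cand[3 * (p // 3) : 3 * (p // 3) + 3])
            if codon not in STOPS:
                out = cand
                break
    return "".join(out)


def _oracle(c1, c2):
    """Brute-force NG86 counts by full path enumeration."""

    def sites(cds):
        s = 0.0
        for i in range(0, len(cds), 3):
            cod = cds[i : i + 3]
            for pos in range(3):
                for b in "ACGT":
                    if b == cod[pos]:
                        continue
                    alt = cod[:pos] + b + cod[pos + 1 :]
                    if alt not in STOPS and is_synonymous(cod, alt):
                        s += 1 / 3
        return s

    Sd = Nd = 0.0
    for i in range(0, len(c1), 3):
        a, b = c1[i : i + 3], c2[i : i + 3]
        diff = [j for j in range(3) if a[j] != b[j]]
        if not diff:
            continue
        paths = []
        for perm in itertools.permutations(diff):
            cur, sd, nd, blocked = a, 0, 0, False
            for pos in perm:
                nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
                if nxt in STOPS:
                    blocked = True
                sd += is_synonymous(cur, nxt)
                nd += not is_synonymous(cur, nxt)
                cur = nxt
            paths.append((sd, nd, blocked))
        ok = [(s, n) for s, n, bl in paths if not bl] or [(s, n) for s, n, _ in paths]
        Sd += sum(s for s, _ in ok) / len(ok)
        Nd += sum(n for _, n in ok) / len(ok)
    S1, S2 = sites(c1), sites(c2)
    S = (S1 + S2) / 2
    return S, len(c1) - S, Sd, Nd


class TestDivergenceTime:
    def test_modal_bin_ltr_rate(self):
        vals = [0.025] * 30 + [0.012] * 20
        est = divergence_time(vals, 1.3e-8)
        assert est.modal_bin == (0.02, 0.03)
        assert est.time_range_my == (0.77, 1.15)

    def test_modal_bin_gene_rate(self):
        vals = [0.015] * 30 + [0.025] * 10
        est = divergence_time(vals, 6.03e-9)
        assert est.modal_bin == (0.01, 0.02)
        assert est.time_range_my == (0.83, 1.66)

    def test_all_zero(self):
        est = divergence_time([0.0] * 12, 1.3e-8)
        assert est.modal_bin == (0.0, 0.01)
        assert est.time_range_my == (0.0, 0.38)

    def test_tie_goes_to_lower_bin(self):
        vals = [0.005] * 10 + [0.015] * 10
        assert divergence_time(vals, 1.3e-8).modal_bin == (0.0, 0.01)

    def test_order_invariant(self):
        rng = np.random.default_rng(38)
        vals = list(rng.uniform(0, 0.06, 50))
        a = divergence_time(vals, 1.3e-8)
        b = divergence_time(vals[::-1], 1.3e-8)
        assert a == b

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            divergence_time([0.01] * 5, 1.3e-8)
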