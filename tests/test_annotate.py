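import numpy as np
import pytest

from ltrscape.align import revcomp
from ltrscape.annotate import (
    DetectionParams,
    LTRElement,
    annotate_genome,
    classify_structure,
    detect_tsd,
    elements_from_dataframe,
    elements_to_dataframe,
    find_homology_elements,
    find_intact_candidates,
)
from ltrscape.io import GenomeSequence
from ltrscape.pipeline import evaluate_against_truth
from ltrscape.synthetic import PlantSpec, generate_background, plant_elements


def _match(manifest, df, category, tol=5):
    """Count truth rows of a category matched by a same-category call."""
    hits = 0
    for _, t in manifest[manifest.category == category].iterrows():
        m = df[(df.category == category) & (abs(df.start - t.start) <= tol)
               & (abs(df.end - t.end) <= tol)]
        hits += len(m) > 0
    return hits


def test_planted_intact_recovery(annotated_df):
    manifest, df = annotated_df
    n_it = (manifest.category == "IT").sum()
    assert _match(manifest, df, "IT") >= 0.9 * n_it
    # boundaries of matched calls within +-5 bp already enforced by _match


def test_category_partition(annotated_df):
    _, df = annotated_df
    counted = df.category.isin(["IT", "InT", "ST", "SnT", "complex"]).sum()
    assert counted == len(df)


def test_detection_deterministic(planted):
    genome, _ = planted
    a = elements_to_dataframe(annotate_genome([genome]))
    b = elements_to_dataframe(annotate_genome([genome]))
    assert a.equals(b)


def test_no_call_in_heavy_n_regions(annotated):
    genome, _, elements = annotated
    for el in elements:
        span = genome.residues[el.start : el.end]
        assert span.count("N") <= 0.1 * len(span)


def test_repeat_free_genome_no_candidates():
    g = generate_background(20_000, 0.5, seed=99)
    assert find_intact_candidates(g) == []


def test_microsatellite_not_called():
    rng = np.random.default_rng(100)
    from ltrscape.synthetic import _random_seq

    seq = _random_seq(rng, 2000) + "ACGT" * 300 + _random_seq(rng, 2000)
    assert find_intact_candidates(GenomeSequence("c", seq)) == []


def test_complex_recovery(annotated_df):
    manifest, df = annotated_df
    n = (manifest.category == "complex").sum()
    assert n >= 1
    got = df[df.category == "complex"]
    assert len(got) == n
    assert (got.n_ltrs >= 3).all()


def test_adjacent_elements_not_merged():
    """Two same-family intact elements 100 bp apart stay separate calls."""
    rng = np.random.default_rng(21)
    from ltrscape.synthetic import _random_seq, mutate

    ltr = _random_seq(rng, 300)
    internal = _random_seq(rng, 800)
    tsd1, tsd2 = _random_seq(rng, 5), _random_seq(rng, 5)

    def element(tsd):
        l5 = mutate(ltr, 0.01, rng)
        l3 = mutate(ltr, 0.01, rng)
        return tsd + l5 + mutate(internal, 0.01, rng) + l3 + tsd

    seq = (_random_seq(rng, 3000) + element(tsd1) + _random_seq(rng, 100)
           + element(tsd2) + _random_seq(rng, 3000))
    genome = GenomeSequence("c", seq)
    calls = annotate_genome([genome])
    intact = [c for c in calls if c.category in ("IT", "InT")]
    assert len(intact) == 2
    assert all(c.category == "IT" for c in intact)
    assert not any(c.category == "complex" for c in calls)


class TestTSD:
    def _genome(self, left, right, core_len=500):
        rng = np.random.default_rng(3)
        from ltrscape.synthetic import _random_seq

        core = _random_seq(rng, core_len)
        seq = _random_seq(rng, 60) + left + core + right + _random_seq(rng, 60)
        start = 60 + len(left)
        return GenomeSequence("c", seq), start, start + core_len

    def test_exact_five_bp(self):
        g, s, e = self._genome("TACGT", "TACGT")
        assert detect_tsd(g, s, e) == "TACGT"

    def test_one_mismatch_accepted(self):
        g, s, e = self._genome("TACGT", "TACCT")
        assert detect_tsd(g, s, e) == "TACGT"

    def test_two_mismatches_rejected(self):
        g, s, e = self._genome("TAAAA", "CCCAA")
        assert detect_tsd(g, s, e) is None

    def test_contig_edge_returns_none(self):
        rng = np.random.default_rng(4)
        from ltrscape.synthetic import _random_seq

        seq = _random_seq(rng, 100)
        g = GenomeSequence("c", seq)
        assert detect_tsd(g, 0, 100) is None

    def test_n_counts_as_mismatch(self):
        g, s, e = self._genome("NNCGT", "TACGT")
        assert detect_tsd(g, s, e) is None


@pytest.mark.parametrize(
    "n_ltrs,tsd,expected",
    [(2, "ACGT", "IT"), (2, None, "InT"), (1, "ACGT", "ST"),
     (1, None, "SnT"), (3, "ACGT", "complex")],
)
def test_classify_structure(n_ltrs, tsd, expected):
    el = LTRElement("c", 0, 100, ltr5=(0, 50), n_ltrs=n_ltrs, tsd=tsd)
    assert classify_structure(el) == expected


def test_classify_structure_zero_ltrs_error():
    el = LTRElement("c", 0, 100, ltr5=(0, 50), n_ltrs=0)
    with pytest.raises(ValueError):
        classify_structure(el)


class TestHomologyScan:
    def _setup(self, transform):
        rng = np.random.default_rng(8)
        from ltrscape.synthetic import _random_seq, mutate

        ltr = _random_seq(rng, 300)
        copy = transform(mutate(ltr, 0.02, rng))
        seq = _random_seq(rng, 2000) + copy + _random_seq(rng, 2000)
        return GenomeSequence("c", seq), [("lib0", ltr)]

    def test_forward_hit(self):
        genome, lib = self._setup(lambda s: s)
        hits = find_homology_elements(genome, lib)
        assert len(hits) == 1 and hits[0].strand == "+"
        assert abs(hits[0].start - 2000) <= 3

    def test_reverse_strand_hit(self):
        genome, lib = self._setup(revcomp)
        hits = find_homology_elements(genome, lib)
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_low_identity_not_reported(self):
        rng = np.random.default_rng(9)
        from ltrscape.synthetic import mutate

        genome, lib = self._setup(lambda s: mutate(s, 0.45, rng))
        assert find_homology_elements(genome, lib) == []

    def test_exclusion_spans(self):
        genome, lib = self._setup(lambda s: s)
        hits = find_homology_elements(genome, lib, exclude_spans=[(1900, 2500)])
        assert hits == []


def test_solo_recovery(annotated_df):
    manifest, df = annotated_df
    n_solo = manifest.category.isin(["ST", "SnT"]).sum()
    called = df.category.isin(["ST", "SnT"]).sum()
    assert called >= 0.8 * n_solo


def test_elements_dataframe_roundtrip(annotated):
    _, _, elements = annotated
    df = elements_to_dataframe(elements)
    back = elements_from_dataframe(df)
    assert len(back) == len(elements)
    for a, b in zip(elements, back):
        assert (a.start, a.end, a.category, a.tsd, a.ltr5, a.ltr3) == (
            b.start, b.end, b.category, b.tsd, b.ltr5, b.ltr3
        )


def test_detection_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(min_ltr_len=500, max_ltr_len=100)
    with pytest.raises(ValueError):
        DetectionParams(min_ltr_identity=0.0)
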