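"""Synthetic genomes with planted LTR retrotransposons and known truth.

The generator builds a random background chromosome, plants intact
elements (TSD + LTR + internal + LTR' + TSD), solo LTRs, intact/solo
variants without TSDs, and multi-LTR "complex" loci, then optionally
derives a second genome that shares a chosen fraction of insertions at
homologous positions and has accumulated independent point substitutions.
Every planted feature is recorded in a manifest with its realized (not
merely requested) LTR-LTR divergence, so detection, dating, family and
orthology stages can all be scored against exact truth.

Substitutions follow the Jukes-Cantor transition kernel, which makes
divergence additive across mutation rounds: planting an element at
divergence K1 and then ageing both genomes by K2 yields expected pairwise
divergences that simply sum.  Indels are off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import hamming_identity, jc_distance, jc_p_from_k
from .io import GenomeSequence
from .motifs import reverse_translate, superfamily_motifs

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "PlantSpec",
    "generate_background",
    "mutate",
    "plant_elements",
    "diverge_genomes",
    "generate_gene_pairs",
]


@dataclass
class PlantSpec:
    """What to plant: counts, geometry and divergence of synthetic elements."""

    n_intact: int = 20
    n_solo: int = 5
    n_intact_no_tsd: int = 0
    n_solo_no_tsd: int = 0
    n_complex: int = 0
    ltr_length: tuple[int, int] = (200, 600)
    internal_length: tuple[int, int] = (2000, 6000)
    tsd_length: tuple[int, int] = (4, 6)
    target_K: float = 0.02
    superfamily_profile: dict[str, float] = field(
        default_factory=lambda: {"Copia": 0.4, "Gypsy": 0.3, "TRIM": 0.2, "LARD": 0.1}
    )
    family_divergence: float = 0.03  # ancestor->element LTR divergence within a family
    elements_per_family: int = 10
    min_flank: int = 300  # clear background guaranteed on each side of an insertion
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_intact", "n_solo", "n_intact_no_tsd", "n_solo_no_tsd", "n_complex"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.target_K <= 0.5:
            raise ValueError("target_K must be in [0, 0.5]")
        lo, hi = self.tsd_length
        if not (4 <= lo <= hi <= 6):
            raise ValueError("tsd_length must lie in 4..6")
        total = sum(self.superfamily_profile.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError("superfamily proportions must sum to 1")


def generate_background(
    length: int,
    gc: float = 0.4,
    seed: int = 0,
    n_gaps: list[tuple[int, int]] | None = None,
) -> GenomeSequence:
    """An i.i.d. random chromosome at the requested GC, with optional N runs."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = BASES[rng.choice(4, size=length, p=p)]
    if n_gaps:
        for start, glen in n_gaps:
            if start < 0 or start + glen > length:
                raise ValueError("N gap outside sequence")
            arr[start : start + glen] = ord("N")
    return GenomeSequence("chr1", arr.tobytes().decode())


def mutate(seq: str, k: float, rng: np.random.Generator) -> str:
    """Apply JC substitutions at expected divergence k; N sites untouched."""
    if k <= 0:
        return seq
    a = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    p = jc_p_from_k(k)
    hit = (rng.random(a.size) < p) & (a != ord("N"))
    idx = np.nonzero(hit)[0]
    if idx.size:
        # replace with a uniformly chosen different base
        cur = a[idx]
        shift = rng.integers(1, 4, size=idx.size)
        code = np.zeros(idx.size, dtype=np.intp)
        for i, b in enumerate(BASES):
            code[cur == b] = i
        a[idx] = BASES[(code + shift) % 4]
    return a.tobytes().decode()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass
class _Family:
    label: str
    superfamily: str
    ltr: str
    internal: str


def _make_families(spec: PlantSpec, rng: np.random.Generator, n_elements: int) -> list[_Family]:
    """Ancestor LTR/internal sequences, one per family, motifs embedded."""
    supers = list(spec.superfamily_profile)
    probs = np.array([spec.superfamily_profile[s] for s in supers])
    n_fam = max(1, math.ceil(n_elements / spec.elements_per_family))
    fams: list[_Family] = []
    motifs = superfamily_motifs()
    for i in range(n_fam):
        sf = supers[rng.choice(len(supers), p=probs)]
        if sf == "TRIM":
            # very small elements: short LTRs, tiny non-coding internal
            ltr_len = int(rng.integers(130, 250))
            internal = _random_seq(rng, int(rng.integers(200, 900)))
        elif sf == "LARD":
            ltr_len = int(rng.integers(*spec.ltr_length))
            internal = _random_seq(rng, int(rng.integers(4200, 6500)))
        else:
            ltr_len = int(rng.integers(*spec.ltr_length))
            internal_len = int(rng.integers(*spec.internal_length))
            internal = _random_seq(rng, internal_len)
            int_nt = reverse_translate(motifs[sf]["INT"], rng)
            rt_nt = reverse_translate(motifs[sf]["RT"], rng)
            # Copia: integrase upstream of reverse transcriptase; Gypsy: reversed
            first, second = (int_nt, rt_nt) if sf == "Copia" else (rt_nt, int_nt)
            a = internal_len // 6
            b = internal_len // 2
            internal = (
                internal[:a]
                + first
                + internal[a + len(first) : b]
                + second
                + internal[b + len(second) :]
            )
        fams.append(_Family(f"fam{i:03d}", sf, _random_seq(rng, ltr_len), internal))
    return fams


def _measured_k(a: str, b: str) -> float:
    p = 1.0 - hamming_identity(a, b)
    return jc_distance(min(p, 0.7499))


def plant_elements(
    genome: GenomeSequence, spec: PlantSpec
) -> tuple[GenomeSequence, pd.DataFrame]:
    """Insert the requested elements at uniform non-N positions.

    Returns the new chromosome and a manifest with one row per planted
    element (final-genome coordinates; element span excludes TSDs).
    """
    rng = np.random.default_rng(spec.seed)
    n_total = (
        spec.n_intact + spec.n_solo + spec.n_intact_no_tsd + spec.n_solo_no_tsd + spec.n_complex
    )
    if n_total == 0:
        return genome, _empty_manifest()

    fams = _make_families(spec, rng, n_total)
    categories = (
        ["IT"] * spec.n_intact
        + ["ST"] * spec.n_solo
        + ["InT"] * spec.n_intact_no_tsd
        + ["SnT"] * spec.n_solo_no_tsd
        + ["complex"] * spec.n_complex
    )
    # families cycle over intact elements first so every family used by a
    # solo LTR also has an intact exemplar to seed the homology library
    fam_for: list[_Family] = [fams[i % len(fams)] for i in range(len(categories))]

    # build element strings
    built: list[dict] = []
    for cat, fam in zip(categories, fam_for):
        base_ltr = mutate(fam.ltr, spec.family_divergence, rng)
        tsd_len = int(rng.integers(spec.tsd_length[0], spec.tsd_length[1] + 1))
        tsd = _random_seq(rng, tsd_len)
        half = spec.target_K / 2.0
        if cat in ("IT", "InT"):
            ltr5 = mutate(base_ltr, half, rng)
            ltr3 = mutate(base_ltr, half, rng)
            internal = mutate(fam.internal, spec.family_divergence, rng)
            core = ltr5 + internal + ltr3
            n_ltrs = 2
            k = _measured_k(ltr5, ltr3)
            lens = [len(ltr5), len(internal), len(ltr3)]
        elif cat in ("ST", "SnT"):
            ltr = mutate(base_ltr, half, rng)
            core = ltr
            n_ltrs = 1
            k = float("nan")
            lens = [len(ltr)]
        else:  # complex: LTR-internal-LTR-internal-LTR
            ltrs = [mutate(base_ltr, half, rng) for _ in range(3)]
            internals = [mutate(fam.internal, spec.family_divergence, rng) for _ in range(2)]
            core = ltrs[0] + internals[0] + ltrs[1] + internals[1] + ltrs[2]
            n_ltrs = 3
            k = _measured_k(ltrs[0], ltrs[2])
            lens = [len(ltrs[0]), len(internals[0]), len(ltrs[1]), len(internals[1]), len(ltrs[2])]
        has_tsd = cat in ("IT", "ST", "complex")
        built.append(
            dict(
                category=cat,
                family=fam.label,
                superfamily=fam.superfamily,
                core=core,
                tsd=tsd if has_tsd else "",
                n_ltrs=n_ltrs,
                planted_K=k,
                part_lengths=",".join(map(str, lens)),
            )
        )

    positions = _choose_positions(genome.residues, [len(b["core"]) for b in built], spec, rng)
    order = np.argsort(positions)
    pieces: list[str] = []
    rows: list[dict] = []
    cursor = 0
    offset = 0
    for rank, idx in enumerate(order):
        pos = positions[idx]
        b = built[idx]
        tsd = b["tsd"]
        insert = tsd + b["core"] + tsd if tsd else b["core"]
        pieces.append(genome.residues[cursor:pos])
        pieces.append(insert)
        start = pos + offset + len(tsd)  # element span excludes the TSDs
        rows.append(
            dict(
                truth_id=f"t{rank:04d}",
                seq_id=genome.id,
                start=start,
                end=start + len(b["core"]),
                category=b["category"],
                family=b["family"],
                superfamily=b["superfamily"],
                n_ltrs=b["n_ltrs"],
                tsd=tsd,
                planted_K=b["planted_K"],
                part_lengths=b["part_lengths"],
                ortholog_partner="",
            )
        )
        cursor = pos
        offset += len(insert)
    pieces.append(genome.residues[cursor:])
    out = GenomeSequence(genome.id, "".join(pieces))
    manifest = pd.DataFrame(rows)
    return out, manifest


def _empty_manifest() -> pd.DataFrame:
    cols = [
        "truth_id", "seq_id", "start", "end", "category", "family", "superfamily",
        "n_ltrs", "tsd", "planted_K", "part_lengths", "ortholog_partner",
    ]
    return pd.DataFrame(columns=cols)


def _choose_positions(
    background: str, lengths: list[int], spec: PlantSpec, rng: np.random.Generator
) -> list[int]:
    """Uniform non-overlapping insertion points over non-N background."""
    arr = np.frombuffer(background.encode(), dtype=np.uint8)
    ok = arr != ord("N")
    # insertion point must have min_flank of clean sequence on both sides
    m = spec.min_flank
    candidates = np.nonzero(ok)[0]
    candidates = candidates[(candidates > m) & (candidates < len(arr) - m)]
    need = len(lengths)
    min_sep = m  # background separation between neighbouring insertion points
    if candidates.size < need * 2:
        raise ValueError(
            f"infeasible packing: {need} insertions requested, "
            f"{candidates.size} candidate positions available"
        )
    for _ in range(200):
        picks = np.sort(rng.choice(candidates, size=need, replace=False))
        if need == 1 or np.all(np.diff(picks) >= min_sep):
            perm = rng.permutation(need)
            return [int(picks[i]) for i in perm]
    raise ValueError(
        f"infeasible packing: could not place {need} insertions with "
        f"{min_sep}-bp separation in {candidates.size} candidate positions"
    )


# --- second genome --------------------------------------------------------

def diverge_genomes(
    genome: GenomeSequence,
    manifest: pd.DataFrame,
    ortholog_fraction: float,
    point_divergence: float,
    seed: int = 0,
) -> tuple[GenomeSequence, pd.DataFrame, GenomeSequence, pd.DataFrame]:
    """Derive a sister genome sharing a fraction of insertions.

    Each element is retained in the sister genome with probability
    ``ortholog_fraction``; non-retained insertions are deleted cleanly
    (element plus one TSD copy removed, restoring the pre-insertion site).
    Both genomes then accumulate independent substitutions at divergence
    ``point_divergence`` each, so orthologous sequence diverges by
    2 x point_divergence in expectation.

    Returns (genome_a, manifest_a, genome_b, manifest_b); manifest rows of
    retained elements are linked through ``ortholog_partner``.
    """
    if not 0.0 <= ortholog_fraction <= 1.0:
        raise ValueError("ortholog_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    man_a = manifest.sort_values("start").reset_index(drop=True)
    keep = rng.random(len(man_a)) < ortholog_fraction

    seq_a = genome.residues
    pieces: list[str] = []
    cursor = 0
    rows_b: list[dict] = []
    offset = 0
    partners_a = [""] * len(man_a)
    for i, row in man_a.iterrows():
        if not keep[i]:
            # delete element plus one TSD copy, rejoining the flanks
            del_start = int(row.start)
            del_end = int(row.end) + len(row.tsd)
            pieces.append(seq_a[cursor:del_start])
            cursor = del_end
            offset -= del_end - del_start
            continue
        partner = f"b_{row.truth_id}"
        partners_a[i] = partner
        new = dict(row)
        new["truth_id"] = partner
        new["start"] = int(row.start) + offset
        new["end"] = int(row.end) + offset
        new["ortholog_partner"] = row.truth_id
        rows_b.append(new)
    pieces.append(seq_a[cursor:])
    seq_b = "".join(pieces)

    man_a = man_a.copy()
    man_a["ortholog_partner"] = partners_a

    out_a = GenomeSequence(genome.id, mutate(seq_a, point_divergence, rng))
    out_b = GenomeSequence(genome.id, mutate(seq_b, point_divergence, rng))
    man_b = pd.DataFrame(rows_b) if rows_b else _empty_manifest()

    for man, g in ((man_a, out_a), (man_b, out_b)):
        _refresh_realized_k(man, g)
    return out_a, man_a, out_b, man_b


def element_parts(row: pd.Series) -> list[tuple[int, int]]:
    """(start, end) spans of the alternating LTR/internal parts of a row."""
    lens = [int(x) for x in str(row.part_lengths).split(",")]
    spans = []
    pos = int(row.start)
    for n in lens:
        spans.append((pos, pos + n))
        pos += n
    return spans


def _refresh_realized_k(man: pd.DataFrame, genome: GenomeSequence) -> None:
    """Re-measure LTR-LTR divergence on the (possibly mutated) sequence."""
    ks = []
    for _, row in man.iterrows():
        if row.n_ltrs < 2:
            ks.append(float("nan"))
            continue
        parts = element_parts(row)
        l5 = genome.residues[parts[0][0] : parts[0][1]]
        l3 = genome.residues[parts[-1][0] : parts[-1][1]]
        ks.append(_measured_k(l5, l3))
    man["planted_K"] = ks


# --- ortholog CDS pairs ---------------------------------------------------

STOPS = {"TAA", "TAG", "TGA"}
CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in STOPS]


def _random_cds(rng: np.random.Generator, codons: int) -> str:
    return "".join(CODONS[i] for i in rng.integers(0, len(CODONS), size=codons))


def generate_gene_pairs(
    n: int,
    ks_target: float,
    omega: float,
    codons: int = 300,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Ortholog CDS pairs whose expected Ka/Ks match (omega*ks, ks).

    Synonymous and nonsynonymous single-site changes are planted at counts
    drawn from Poisson laws with means pS*S and pN*N, where pS/pN invert
    the JC correction of the targets, so an NG86 estimator applied to the
    pairs recovers ks_target and omega in expectation.
    """
    if n <= 0 or codons <= 10:
        raise ValueError("need n > 0 and codons > 10")
    from .orthology import codon_site_counts, is_synonymous  # local to avoid cycle

    rng = np.random.default_rng(seed)
    pairs = []
    ps = jc_p_from_k(ks_target) if ks_target > 0 else 0.0
    pn = jc_p_from_k(omega * ks_target) if omega * ks_target > 0 else 0.0
    for g in range(n):
        cds = _random_cds(rng, codons)
        s_sites, n_sites = codon_site_counts(cds)
        a = _apply_changes(cds, rng.poisson(ps * s_sites / 2), rng.poisson(pn * n_sites / 2), rng)
        b = _apply_changes(cds, rng.poisson(ps * s_sites / 2), rng.poisson(pn * n_sites / 2), rng)
        pairs.append((f"gene{g:04d}", a, b))
    return pairs


def _apply_changes(cds: str, n_syn: int, n_non: int, rng: np.random.Generator) -> str:
    from .orthology import is_synonymous

    seq = list(cds)
    n_codons = len(cds) // 3
    placed_syn = placed_non = 0
    attempts = 0
    while (placed_syn < n_syn or placed_non < n_non) and attempts < 50 * (n_syn + n_non + 1):
        attempts += 1
        ci = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        old = codon[pos]
        new = "ACGT"[int(rng.integers(0, 4))]
        if new == old:
            continue
        cand = codon[:pos] + new + codon[pos + 1 :]
        if cand in STOPS:
            continue
        syn = is_synonymous(codon, cand)
        if syn and placed_syn < n_syn:
            placed_syn += 1
        elif not syn and placed_non < n_non:
            placed_non += 1
        else:
            continue
        seq[3 * ci + pos] = new
    return "".join(seq)


def write_gene_pairs(pairs: list[tuple[str, str, str]], path) -> None:
    """Paired in-frame CDS FASTA: records <id>_A and <id>_B interleaved."""
    with open(path, "w") as fh:
        for gid, a, b in pairs:
            fh.write(f">{gid}_A\n{a}\n>{gid}_B\n{b}\n")


def read_gene_pairs(path) -> list[tuple[str, str, str]]:
    from Bio import SeqIO

    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) % 2:
        raise ValueError("paired CDS FASTA must hold an even number of records")
    pairs = []
    for ra, rb in zip(recs[::2], recs[1::2]):
        gid = ra.id.rsplit("_", 1)[0]
        pairs.append((gid, str(ra.seq).upper(), str(rb.seq).upper()))
    return pairs
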