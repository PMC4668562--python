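"""Comparative analysis of two genomes.

Orthologous insertions are established through junction sequences: for
each element with TSD-defined boundaries, two 100-bp junctions are taken
(50 bp flank + 50 bp element terminus).  An insertion is orthologous when
each junction occurs exactly once in the sister genome (>= 90% identity
over the 100 bp, both strands) and the two hits are mutually consistent;
it is absent when the rejoined flanks match but the element side does
not.  Divergence of ortholog CDS pairs is estimated with the
Nei-Gojobori (1986) counting method with Jukes-Cantor correction, and
modal-bin histograms of K / Ks convert into divergence-time ranges via
T = K / (2 r).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .align import infix_loci, jc_distance, revcomp
from .annotate import LTRElement
from .dating import ltr_divergence
from .io import GenomeSequence

__all__ = [
    "OrthologCall",
    "KaKsResult",
    "DivergenceEstimate",
    "extract_junctions",
    "call_ortholog",
    "call_orthologs",
    "intra_inter_contrast",
    "ng86_ka_ks",
    "divergence_time",
    "codon_site_counts",
    "is_synonymous",
]

JUNCTION_FLANK = 50
JUNCTION_LEN = 100


@dataclass
class OrthologCall:
    element_id: str
    status: str  # orthologous | absent | ambiguous
    junction_left: str = ""
    junction_right: str = ""
    b_seq_id: str = ""
    b_start: int = -1
    b_end: int = -1
    b_strand: str = "+"
    K_intra_A: float = float("nan")
    K_intra_B: float = float("nan")
    K_inter_5: float = float("nan")
    K_inter_3: float = float("nan")


def _count_occurrences(needle: str, haystacks: list[str]) -> int:
    total = 0
    rc = revcomp(needle)
    for hs in haystacks:
        for q in (needle, rc):
            start = 0
            while True:
                i = hs.find(q, start)
                if i < 0:
                    break
                total += 1
                if total > 1:
                    return total
                start = i + 1
    return total


def extract_junctions(
    element: LTRElement, genomes: dict[str, GenomeSequence]
) -> tuple[str, str] | None:
    """The two 100-bp junctions of an element, or None if unusable.

    Unusable: < 50 bp of flank on either side, an N inside a junction, or
    a junction whose exact sequence occurs more than once in the genome
    (either strand) -- non-unique junctions cannot anchor orthology.
    """
    seq = genomes[element.seq_id].residues
    s, e = element.start, element.end
    if s < JUNCTION_FLANK or e + JUNCTION_FLANK > len(seq):
        return None
    left = seq[s - JUNCTION_FLANK : s + JUNCTION_FLANK]
    right = seq[e - JUNCTION_FLANK : e + JUNCTION_FLANK]
    if "N" in left or "N" in right:
        return None
    haystacks = [g.residues for g in genomes.values()]
    if _count_occurrences(left, haystacks) != 1 or _count_occurrences(right, haystacks) != 1:
        return None
    return left, right


def _junction_loci(junction: str, genome_b: GenomeSequence, max_edits: int):
    """Qualifying loci of a junction in B, both strands, as
    (start, end, edits, strand) in forward coordinates."""
    fwd = infix_loci(junction, genome_b.residues, max_edits)
    rev = infix_loci(junction, revcomp(genome_b.residues), max_edits)
    n = len(genome_b.residues)
    out = [(s, e, d, "+") for s, e, d in fwd]
    out += [(n - e, n - s, d, "-") for s, e, d in rev]
    return sorted(out)


def call_ortholog(
    junctions: tuple[str, str],
    genome_b: GenomeSequence,
    element_length: int,
    min_identity: float = 0.90,
) -> OrthologCall:
    """Classify one insertion as orthologous / absent / ambiguous in B."""
    left, right = junctions
    max_edits = int(round((1 - min_identity) * JUNCTION_LEN))
    loci_l = _junction_loci(left, genome_b, max_edits)
    loci_r = _junction_loci(right, genome_b, max_edits)
    call = OrthologCall("", "ambiguous", left, right)
    if len(loci_l) == 1 and len(loci_r) == 1:
        (ls, le, _, lst) = loci_l[0]
        (rs, re, _, rst) = loci_r[0]
        if lst == rst:
            if lst == "+":
                inner_start, inner_end = ls + JUNCTION_FLANK, re - JUNCTION_FLANK
            else:
                inner_start, inner_end = rs + JUNCTION_FLANK, le - JUNCTION_FLANK
            if 0 < inner_end - inner_start <= 2 * max(element_length, JUNCTION_LEN):
                call.status = "orthologous"
                call.b_seq_id = genome_b.id
                call.b_start, call.b_end = inner_start, inner_end
                call.b_strand = lst
                return call
    if not loci_l and not loci_r:
        # element side may have diverged or the insertion may be missing:
        # look for the rejoined flanks
        flank_l = left[:JUNCTION_FLANK]
        flank_r = right[JUNCTION_FLANK:]
        fl = _junction_loci(flank_l, genome_b, max_edits=5)
        fr = _junction_loci(flank_r, genome_b, max_edits=5)
        if len(fl) == 1 and len(fr) == 1 and fl[0][3] == fr[0][3]:
            gap = fr[0][0] - fl[0][1] if fl[0][3] == "+" else fl[0][0] - fr[0][1]
            if -10 <= gap <= 20:  # flanks rejoined (up to one TSD copy between)
                call.status = "absent"
                return call
    return call


def call_orthologs(
    elements: list[LTRElement],
    genomes_a: dict[str, GenomeSequence],
    genome_b: GenomeSequence,
    min_identity: float = 0.90,
    categories: tuple[str, ...] = ("IT", "ST", "InT", "SnT"),
) -> list[OrthologCall]:
    """Junction-orthology calls for structurally delimited elements of A.

    All four structural categories are eligible by default: junctions
    only need well-defined element boundaries, which structural detection
    provides whether or not the TSD survived later point substitution.
    """
    calls = []
    for el in elements:
        if el.category not in categories:
            continue
        junctions = extract_junctions(el, genomes_a)
        if junctions is None:
            continue
        call = call_ortholog(junctions, genome_b, el.length, min_identity)
        call.element_id = el.element_id
        calls.append(call)
    return calls


def compute_pair_divergences(
    element: LTRElement,
    call: OrthologCall,
    genomes_a: dict[str, GenomeSequence],
    genome_b: GenomeSequence,
) -> None:
    """Fill intra- and inter-genome LTR divergences for an orthologous pair.

    The element's LTR spans carry over to B by offset from the matched
    locus (the default generator plants no indels, so offsets align).
    """
    if call.status != "orthologous" or element.ltr3 is None:
        return
    seq_a = genomes_a[element.seq_id].residues
    a5 = seq_a[element.ltr5[0] : element.ltr5[1]]
    a3 = seq_a[element.ltr3[0] : element.ltr3[1]]
    seq_b = genome_b.residues[call.b_start : call.b_end]
    if call.b_strand == "-":
        seq_b = revcomp(seq_b)
    off5 = element.ltr5[0] - element.start
    off3 = element.ltr3[0] - element.start
    b5 = seq_b[off5 : off5 + (element.ltr5[1] - element.ltr5[0])]
    b3 = seq_b[off3 : off3 + (element.ltr3[1] - element.ltr3[0])]
    try:
        call.K_intra_A = ltr_divergence(a5, a3)[1]
        call.K_intra_B = ltr_divergence(b5, b3)[1]
        call.K_inter_5 = ltr_divergence(a5, b5)[1]
        call.K_inter_3 = ltr_divergence(a3, b3)[1]
    except ValueError:
        pass


def intra_inter_contrast(calls: list[OrthologCall]) -> dict:
    """Paired t-tests of within-element vs between-genome LTR divergence.

    For each orthologous intact element: K_intra in each genome, and
    K_inter as the mean of the 5' and 3' cross-genome LTR divergences.
    """
    rows = [
        c
        for c in calls
        if c.status == "orthologous" and not np.isnan(c.K_intra_A) and not np.isnan(c.K_intra_B)
    ]
    if len(rows) < 2:
        raise ValueError("need >= 2 orthologous intact elements with divergences")
    intra_a = np.array([c.K_intra_A for c in rows])
    intra_b = np.array([c.K_intra_B for c in rows])
    inter = np.array([(c.K_inter_5 + c.K_inter_3) / 2 for c in rows])

    def _paired(x, y):
        t, p = stats.ttest_rel(x, y)
        return {"t": float(t), "p": float(p)}

    return {
        "n": len(rows),
        "mean_intra_A": float(intra_a.mean()),
        "sd_intra_A": float(intra_a.std(ddof=1)),
        "mean_intra_B": float(intra_b.mean()),
        "sd_intra_B": float(intra_b.std(ddof=1)),
        "mean_inter": float(inter.mean()),
        "sd_inter": float(inter.std(ddof=1)),
        "intra_A_vs_inter": _paired(intra_a, inter),
        "intra_B_vs_inter": _paired(intra_b, inter),
        "intra_A_vs_intra_B": _paired(intra_a, intra_b),
    }


# --- NG86 Ka/Ks -----------------------------------------------------------

STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE: dict[str, str] = {}


def _aa(codon: str) -> str:
    if codon not in _CODON_TABLE:
        _CODON_TABLE[codon] = str(Seq(codon).translate())
    return _CODON_TABLE[codon]


def is_synonymous(c1: str, c2: str) -> bool:
    return _aa(c1) == _aa(c2)


def codon_site_counts(cds: str) -> tuple[float, float]:
    """(S, N): synonymous and nonsynonymous site counts of one sequence.

    At each codon position the synonymous fraction is the share of the
    three possible changes that preserve the amino acid; changes creating
    a stop codon count as nonsynonymous.
    """
    s = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        for pos in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt not in STOPS and is_synonymous(codon, alt):
                    syn += 1
            s += syn / 3.0
    return s, len(cds) - s


def _codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(sd, nd) for one codon pair, averaged over minimal mutational paths.

    Paths passing through stop codons are excluded; if every ordering is
    blocked, all orderings are used (so the counts remain defined).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                blocked = True
            if is_synonymous(cur, nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    usable = [(s, n) for s, n, b in paths if not b]
    if not usable:
        usable = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    omega: float
    flags: list[str] = field(default_factory=list)


def ng86_ka_ks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Site counts are averaged over the two sequences; multi-hit codons are
    averaged over all minimal mutational paths.  Raises on unequal or
    out-of-frame lengths, internal stops or ambiguity codes.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS lengths differ")
    if len(cds_a) % 3:
        raise ValueError("CDS length not divisible by 3")
    if set(cds_a + cds_b) - set("ACGT"):
        raise ValueError("ambiguity codes not supported")
    for cds in (cds_a, cds_b):
        for i in range(0, len(cds) - 3, 3):
            if cds[i : i + 3] in STOPS:
                raise ValueError("internal stop codon")
    s_a, n_a = codon_site_counts(cds_a)
    s_b, n_b = codon_site_counts(cds_b)
    S, N = (s_a + s_b) / 2, (n_a + n_b) / 2
    Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        sd, nd = _codon_path_counts(cds_a[i : i + 3], cds_b[i : i + 3])
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    flags = []
    if pS >= 0.75:
        Ks = float("nan")
        flags.append("pS saturated")
    else:
        Ks = jc_distance(pS)
    if pN >= 0.75:
        Ka = float("nan")
        flags.append("pN saturated")
    else:
        Ka = jc_distance(pN)
    omega = Ka / Ks if Ks and Ks > 0 else float("nan")
    return KaKsResult(S, N, Sd, Nd, pS, pN, Ks, Ka, omega, flags)


# --- divergence-time histogram --------------------------------------------

@dataclass
class DivergenceEstimate:
    metric: str
    n: int
    bin_width: float
    counts: list[int]
    modal_bin: tuple[float, float]
    modal_fraction: float
    time_range_my: tuple[float, float]


def divergence_time(
    values: list[float],
    rate: float,
    bin_width: float = 0.01,
    metric: str = "K",
) -> DivergenceEstimate:
    """Locate the modal divergence bin and convert it to a time range.

    Bins are [0, w), [w, 2w), ...; ties go to the lower bin; the time
    range is the bin edges divided by 2*rate, reported in My (2 d.p.).
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 10:
        raise ValueError("need >= 10 divergence values")
    n_bins = max(1, int(np.floor(vals.max() / bin_width)) + 1)
    counts, edges = np.histogram(vals, bins=n_bins, range=(0, n_bins * bin_width))
    modal = int(np.argmax(counts))  # argmax returns the first (lower) tie
    lo, hi = edges[modal], edges[modal + 1]
    t_lo = round(lo / (2 * rate) / 1e6, 2)
    t_hi = round(hi / (2 * rate) / 1e6, 2)
    return DivergenceEstimate(
        metric=metric,
        n=int(vals.size),
        bin_width=bin_width,
        counts=counts.tolist(),
        modal_bin=(float(lo), float(hi)),
        modal_fraction=float(counts[modal] / vals.size),
        time_range_my=(t_lo, t_hi),
    )
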