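"""Structural detection of LTR retrotransposons.

The finder locates pairs of direct repeats by exact k-mer seeding (2-bit
encoded, numpy-sorted), merges co-diagonal seeds into repeat runs, and
refines repeat boundaries with an X-drop extension that compares the two
copies base by base.  Candidates are filtered on LTR length, element
length, repeat identity and N content, then competing overlapping
candidates are resolved (identity, then length, then leftmost).  Target
site duplications (TSDs) are searched at 6, then 5, then 4 bp with at
most one mismatch, and each call is classified as:

  IT   intact element (two LTRs) with TSD
  InT  intact element without TSD
  ST   solo LTR with TSD
  SnT  solo LTR without TSD
  complex  a single locus with >= 3 alternating LTR/internal segments

Solo LTRs are found by scanning the genome against a library of LTR
exemplars taken from the structurally detected intact elements (80%
identity over 80% of the library sequence, both strands).  Truncated
fragments below those thresholds are deliberately not called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import best_infix_match, hamming_identity, kmer_codes, revcomp
from .io import GenomeSequence

__all__ = [
    "DetectionParams",
    "LTRElement",
    "find_intact_candidates",
    "detect_tsd",
    "detect_complex",
    "classify_structure",
    "find_homology_elements",
    "annotate_genome",
    "elements_to_dataframe",
    "elements_from_dataframe",
]


@dataclass
class DetectionParams:
    min_ltr_len: int = 100
    max_ltr_len: int = 3000
    min_element_len: int = 300
    max_element_len: int = 15000
    min_ltr_identity: float = 0.80
    seed_word: int = 12
    tsd_len_range: tuple[int, int] = (4, 6)
    tsd_max_mismatch: int = 1
    seed_merge_gap: int = 300
    max_n_fraction: float = 0.10
    homology_identity: float = 0.80
    homology_coverage: float = 0.80
    xdrop: int = 10

    def __post_init__(self) -> None:
        if self.min_ltr_len >= self.max_ltr_len:
            raise ValueError("min_ltr_len must be < max_ltr_len")
        if self.min_element_len >= self.max_element_len:
            raise ValueError("min_element_len must be < max_element_len")
        if not 0.0 < self.min_ltr_identity <= 1.0:
            raise ValueError("min_ltr_identity must be in (0, 1]")


@dataclass
class LTRElement:
    """One annotated insertion; all spans 0-based half-open, TSD excluded."""

    seq_id: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int] | None = None
    internal: tuple[int, int] | None = None
    tsd: str | None = None
    category: str = ""
    n_ltrs: int = 1
    strand: str = "+"
    identity: float = float("nan")
    element_id: str = ""
    family_id: str = ""
    superfamily: str = "unknown"
    K: float | None = None
    age_years: float | None = None
    ltr_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


# --- seeding --------------------------------------------------------------

def _repeat_seed_pairs(seq: str, params: DetectionParams) -> list[tuple[int, int]]:
    """(pos1, distance) for every same-strand k-mer pair within element range."""
    k = params.seed_word
    codes, valid = kmer_codes(seq, k)
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        return []
    sub = codes[idx]
    order = np.argsort(sub, kind="stable")
    sorted_codes = sub[order]
    sorted_pos = idx[order]
    boundaries = np.nonzero(np.diff(sorted_codes))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [sorted_codes.size]])
    max_d = params.max_element_len
    min_d = 2 * k  # repeats closer than this cannot be two separate LTRs
    pairs: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if e - s < 2 or e - s > 500:  # singleton or low-complexity blowup
            continue
        group = np.sort(sorted_pos[s:e])
        for i in range(group.size - 1):
            for j in range(i + 1, group.size):
                d = int(group[j] - group[i])
                if d > max_d:
                    break
                if d >= min_d:
                    pairs.append((int(group[i]), d))
    return pairs


def _seed_runs(pairs: list[tuple[int, int]], params: DetectionParams, k: int) -> list[tuple[int, int, int]]:
    """Merge co-diagonal seeds into runs: (start, end, distance)."""
    by_d: dict[int, list[int]] = {}
    for p, d in pairs:
        by_d.setdefault(d, []).append(p)
    runs = []
    for d, ps in by_d.items():
        ps.sort()
        run_start = prev = ps[0]
        for p in ps[1:]:
            # small gaps only: mismatch clusters are bridged later by the
            # X-drop extension, while a large gap on one diagonal means
            # two distinct same-family loci that must not be chained
            if p - prev <= params.seed_merge_gap:
                prev = p
            else:
                runs.append((run_start, prev + k, d))
                run_start = prev = p
        runs.append((run_start, prev + k, d))
    return runs


def _xdrop_extend(seq: str, i: int, j: int, step: int, params: DetectionParams) -> int:
    """Extend the copy1/copy2 comparison from (i, j) in direction step.

    Returns how many positions beyond the starting point belong to the
    repeat (offset of the best-scoring extension point).
    """
    n = len(seq)
    score = best = 0
    off = best_off = 0
    run = 0  # consecutive matches ending at the current offset
    while True:
        i += step
        j += step
        if i < 0 or j < 0 or i >= n or j >= n:
            break
        a, b = seq[i], seq[j]
        if a == b and a != "N":
            score += 1
            run += 1
        else:
            score -= 2
            run = 0
        off += 1
        # accept a new boundary only on a >=3 match run, so one or two
        # chance flank matches cannot drag the repeat edge outward
        if score > best and run >= 3:
            best, best_off = score, off
        if score < best - params.xdrop:
            break
    return best_off


def _n_fraction(seq: str, start: int, end: int) -> float:
    span = seq[start:end]
    return span.count("N") / max(1, len(span))


def _is_simple_repeat(seq: str, start: int, end: int, max_period: int = 30) -> bool:
    """True when the span is self-periodic at a tiny period (SSR array)."""
    arr = np.frombuffer(seq[start:end].encode(), dtype=np.uint8)
    for p in range(1, min(max_period, arr.size - 1) + 1):
        if np.mean(arr[:-p] == arr[p:]) >= 0.9:
            return True
    return False


def find_intact_candidates(
    genome: GenomeSequence, params: DetectionParams | None = None, resolve: bool = True
) -> list[LTRElement]:
    """Direct-repeat candidates (two LTR spans + internal span) in one sequence.

    With ``resolve=True`` overlapping candidates are reduced to a
    compatible set; pass ``resolve=False`` to keep every raw candidate,
    which :func:`detect_complex` needs to see multi-LTR loci.
    """
    params = params or DetectionParams()
    seq = genome.residues
    k = params.seed_word
    pairs = _repeat_seed_pairs(seq, params)
    if not pairs:
        return []
    raw: dict[tuple[int, int, int, int], LTRElement] = {}
    for run_start, run_end, d in _seed_runs(pairs, params, k):
        left = _xdrop_extend(seq, run_start, run_start + d, -1, params)
        right = _xdrop_extend(seq, run_end - 1, run_end - 1 + d, +1, params)
        s1, e1 = run_start - left, run_end + right
        s2, e2 = s1 + d, e1 + d
        ltr_len = e1 - s1
        if e1 >= s2:
            # self-overlapping extension: a tandem array with period d,
            # i.e. a multi-LTR (LTR-internal-)n-LTR locus whose LTR length
            # equals the overlap
            cand = _tandem_to_complex(genome, s1, e1, s2, e2, d, params)
            if cand is not None:
                key = (cand.start, cand.end, cand.n_ltrs, 0)
                raw.setdefault(key, cand)
            continue
        if not params.min_ltr_len <= ltr_len <= params.max_ltr_len:
            continue
        if not params.min_element_len <= e2 - s1 <= params.max_element_len:
            continue
        ident = hamming_identity(seq[s1:e1], seq[s2:e2])
        if ident < params.min_ltr_identity:
            continue
        if _n_fraction(seq, s1, e2) > params.max_n_fraction:
            continue
        if _is_simple_repeat(seq, s1, e2):
            continue
        key = (s1, e1, s2, e2)
        if key not in raw:
            raw[key] = LTRElement(
                seq_id=genome.id,
                start=s1,
                end=e2,
                ltr5=(s1, e1),
                ltr3=(s2, e2),
                internal=(e1, s2),
                n_ltrs=2,
                identity=ident,
                ltr_spans=[(s1, e1), (s2, e2)],
            )
    candidates = list(raw.values())
    if resolve:
        candidates = resolve_overlaps(candidates)
    candidates.sort(key=lambda c: c.start)
    return candidates


def _tandem_to_complex(
    genome: GenomeSequence, s1: int, e1: int, s2: int, e2: int, period: int,
    params: DetectionParams,
) -> LTRElement | None:
    """Interpret a self-overlapping repeat extension as a multi-LTR locus.

    The overlap of the two maximally extended copies is one LTR; the
    extension period is LTR + internal; the array spans n_ltrs LTRs.
    """
    seq = genome.residues
    u = e1 - s2  # LTR length
    if not params.min_ltr_len <= u <= params.max_ltr_len:
        return None
    internal_len = period - u
    if internal_len < 20:  # plain tandem repeat, no internal region
        return None
    span_len = e2 - s1
    n_units = round((span_len - u) / period)
    if n_units < 2:
        return None
    n_ltrs = n_units + 1
    spans = [(s1 + k * period, s1 + k * period + u) for k in range(n_ltrs)]
    if abs(spans[-1][1] - e2) > 10:
        return None  # span is not an integer number of periods
    if _is_simple_repeat(seq, s1, e2):
        return None
    first = seq[spans[0][0] : spans[0][1]]
    last = seq[spans[-1][0] : spans[-1][1]]
    ident = hamming_identity(first, last)
    if ident < params.min_ltr_identity:
        return None
    if _n_fraction(seq, s1, e2) > params.max_n_fraction:
        return None
    return LTRElement(
        seq_id=genome.id,
        start=spans[0][0],
        end=spans[-1][1],
        ltr5=spans[0],
        ltr3=spans[-1],
        internal=(spans[0][1], spans[-1][0]),
        n_ltrs=n_ltrs,
        identity=ident,
        ltr_spans=spans,
    )


def resolve_overlaps(candidates: list[LTRElement], rank_key=None) -> list[LTRElement]:
    """Greedy selection: higher identity, then longer, then leftmost wins.

    ``rank_key`` overrides the ranking (used by the annotation driver to
    prefer TSD-corroborated candidates).
    """
    ranked = sorted(candidates, key=rank_key or (lambda c: (-c.identity, -c.length, c.start)))
    accepted: list[LTRElement] = []
    for cand in ranked:
        if all(cand.end <= a.start or cand.start >= a.end for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda c: c.start)
    return accepted


# --- TSD ------------------------------------------------------------------

def detect_tsd(genome: GenomeSequence, start: int, end: int, params: DetectionParams | None = None) -> str | None:
    """TSD flanking [start, end): longest L in 6,5,4 with <= 1 mismatch.

    N counts as a mismatch; an element at a contig edge has no TSD.  The
    left-flank copy of the duplication is returned.  A 4-bp duplication
    must match exactly: with one mismatch allowed, one random flank pair
    in twenty would carry a spurious 4-bp "TSD".
    """
    params = params or DetectionParams()
    seq = genome.residues
    lo, hi = params.tsd_len_range
    for L in range(hi, lo - 1, -1):
        if start - L < 0 or end + L > len(seq):
            continue
        left = seq[start - L : start]
        right = seq[end : end + L]
        mism = sum(1 for a, b in zip(left, right) if a != b or a == "N")
        allowed = params.tsd_max_mismatch if L >= 5 else 0
        if mism <= allowed:
            return left
    return None


def _outward_consistent(
    seq: str, start: int, end: int, dl: int, dr: int,
    copy_offsets: tuple[int, int],
) -> bool:
    """Do outward boundary shifts stay consistent with the repeat copies?

    Moving a boundary outward claims the uncovered columns as LTR
    sequence, so they must (nearly) match between the two LTR copies.
    At most one mismatch per side is tolerated (a terminal substitution
    is usually what caused the boundary to be trimmed inward).
    """
    d_start, d_end = copy_offsets
    if dl < 0:
        a = seq[start + dl : start]
        b = seq[start + d_start + dl : start + d_start]
        allowed = 1 if -dl < 5 else 2
        if len(a) != len(b) or sum(x != y or x == "N" for x, y in zip(a, b)) > allowed:
            return False
    if dr > 0:
        a = seq[end : end + dr]
        b = seq[end - d_end : end - d_end + dr]
        allowed = 1 if dr < 5 else 2
        if len(a) != len(b) or sum(x != y or x == "N" for x, y in zip(a, b)) > allowed:
            return False
    return True


def refine_tsd(
    genome: GenomeSequence,
    start: int,
    end: int,
    params: DetectionParams | None = None,
    max_shift: int = 2,
    max_shift_out: int = 9,
    copy_offsets: tuple[int, int] | None = None,
) -> tuple[str | None, int, int]:
    """TSD search with boundary refinement.

    Repeat-extension boundaries can sit a few bases off the true element
    edge (chance flank matches extend them outward; terminal LTR
    substitutions trim them inward), which would misalign the TSD
    comparison.  The exact boundary is tried first (one mismatch
    allowed); failing that, shifted boundaries are tried in order of
    increasing total shift with an exact TSD match demanded, the shorter
    the duplication the smaller the allowed shift.  Outward shifts up to
    ``max_shift_out`` are additionally allowed for two-LTR elements when
    the uncovered columns agree between the LTR copies (``copy_offsets``
    = distance between the copies at the start and end boundaries).
    Returns (tsd or None, refined_start, refined_end).
    """
    params = params or DetectionParams()
    tsd = detect_tsd(genome, start, end, params)
    if tsd is not None:
        return tsd, start, end
    seq = genome.residues
    lo, hi = params.tsd_len_range
    reach = max_shift_out if copy_offsets is not None else max_shift
    shifts = sorted(
        ((dl, dr) for dl in range(-reach, reach + 1)
         for dr in range(-reach, reach + 1) if (dl, dr) != (0, 0)),
        key=lambda s: (abs(s[0]) + abs(s[1]), s),
    )
    for dl, dr in shifts:
        s, e = start + dl, end + dr
        if s <= 0 or e >= len(seq) or e - s <= 0:
            continue
        total_shift = abs(dl) + abs(dr)
        plain_ok = abs(dl) <= max_shift and abs(dr) <= max_shift
        outward_ok = (
            copy_offsets is not None
            and dl <= 0 <= dr
            and _outward_consistent(seq, start, end, dl, dr, copy_offsets)
        )
        # overrun corrections move boundaries inward; rescued by TSD
        # evidence alone, so short duplications get a short leash
        inward_l4 = 0 <= dl <= 3 and -3 <= dr <= 0
        inward_ok = 0 <= dl <= 8 and -8 <= dr <= 0
        for L in range(hi, lo - 1, -1):
            # shorter duplications are weaker evidence: the farther the
            # boundary moves, the stronger the corroboration demanded
            if L == 4 and total_shift > 2 and not (outward_ok or inward_l4):
                continue
            if L > 4 and not (plain_ok or outward_ok or inward_ok):
                continue
            if s - L < 0 or e + L > len(seq):
                continue
            left = seq[s - L : s]
            right = seq[e : e + L]
            if "N" not in left and left == right:
                return left, s, e
    return None, start, end


def classify_structure(element: LTRElement) -> str:
    """IT / InT / ST / SnT / complex from LTR count and TSD presence."""
    if element.n_ltrs <= 0:
        raise ValueError("malformed element: no LTR spans")
    if element.n_ltrs >= 3:
        return "complex"
    has_tsd = element.tsd is not None
    if element.n_ltrs == 2:
        return "IT" if has_tsd else "InT"
    return "ST" if has_tsd else "SnT"


# --- complex loci ---------------------------------------------------------

def detect_complex(
    candidates: list[LTRElement], genome: GenomeSequence, params: DetectionParams | None = None
) -> tuple[list[LTRElement], list[LTRElement]]:
    """Validate and deduplicate multi-LTR complex calls.

    Raw candidates include multi-LTR loci derived from self-overlapping
    repeat extensions (see :func:`find_intact_candidates`).  The same
    locus is often re-detected at multiples of the unit period (period
    2d seeds the LTR1/LTR3 pair of a 5-LTR array), so overlapping
    complex candidates collapse to the one with the most LTRs, ties to
    the leftmost.  Two independent neighbouring insertions never form a
    tandem array (the intervening host sequence breaks the period), so
    they are not at risk of being merged.  Returns
    (complex_elements, remaining_two_LTR_candidates).
    """
    params = params or DetectionParams()
    multi = sorted(
        (c for c in candidates if c.n_ltrs >= 3),
        key=lambda c: (-c.n_ltrs, c.start),
    )
    remaining = [c for c in candidates if c.n_ltrs == 2]
    complexes: list[LTRElement] = []
    for cand in multi:
        if any(cand.start < x.end and cand.end > x.start for x in complexes):
            continue
        offs = (cand.ltr3[0] - cand.ltr5[0], cand.ltr3[1] - cand.ltr5[1])
        tsd, start, end = refine_tsd(genome, cand.start, cand.end, params, copy_offsets=offs)
        spans = list(cand.ltr_spans)
        spans[0] = (start, spans[0][1])
        spans[-1] = (spans[-1][0], end)
        cand.start, cand.end = start, end
        cand.ltr_spans = spans
        cand.ltr5, cand.ltr3 = spans[0], spans[-1]
        cand.internal = (spans[0][1], spans[-1][0])
        cand.tsd = tsd
        cand.category = "complex"
        complexes.append(cand)
    complexes.sort(key=lambda c: c.start)
    return complexes, remaining


# --- homology scan for solo LTRs ------------------------------------------

def find_homology_elements(
    genome: GenomeSequence,
    ltr_library: list[tuple[str, str]],
    params: DetectionParams | None = None,
    exclude_spans: list[tuple[int, int]] | None = None,
) -> list[LTRElement]:
    """Solo-LTR candidates: library matches at >=80% identity over >=80% length.

    ``ltr_library`` holds (name, sequence) exemplars from detected intact
    elements.  Both strands are scanned; hits overlapping ``exclude_spans``
    (already-called elements) are dropped.
    """
    params = params or DetectionParams()
    if not ltr_library:
        return []
    seq = genome.residues
    k = params.seed_word
    codes, valid = kmer_codes(seq, k)
    idx = np.nonzero(valid)[0]
    sub = codes[idx]
    order = np.argsort(sub, kind="stable")
    sorted_codes = sub[order]
    sorted_pos = idx[order]

    loci: list[tuple[int, int, float, str]] = []  # start, end, identity, strand
    for _name, lib in ltr_library:
        for strand, query in (("+", lib), ("-", revcomp(lib))):
            qcodes, qvalid = kmer_codes(query, k)
            qidx = np.nonzero(qvalid)[0]
            if qidx.size == 0:
                continue
            lo = np.searchsorted(sorted_codes, qcodes[qidx], side="left")
            hi = np.searchsorted(sorted_codes, qcodes[qidx], side="right")
            diag_hits: dict[int, int] = {}
            for qi, l, h in zip(qidx, lo, hi):
                if h - l > 200:
                    continue
                for gp in sorted_pos[l:h]:
                    diag_hits[int(gp) - int(qi)] = diag_hits.get(int(gp) - int(qi), 0) + 1
            # collapse nearby diagonals, keep well-seeded ones
            for diag, nhits in sorted(diag_hits.items()):
                if nhits < 2:
                    continue
                start = max(0, diag)
                end = min(len(seq), diag + len(query))
                if end - start < params.homology_coverage * len(query):
                    continue
                pad = 30
                window = seq[max(0, start - pad) : min(len(seq), end + pad)]
                res = best_infix_match(
                    query, window, max_edits=int((1 - params.min_ltr_identity) * len(query))
                )
                if res is None:
                    continue
                ident = 1.0 - res["editDistance"] / len(query)
                if ident < params.homology_identity:
                    continue
                s_loc, e_loc = res["locations"][0]
                s_abs = max(0, start - pad) + (s_loc or 0)
                e_abs = max(0, start - pad) + e_loc + 1
                if (e_abs - s_abs) < params.homology_coverage * len(query):
                    continue
                loci.append((s_abs, e_abs, ident, strand))

    # merge overlapping loci across library entries, keeping the best identity
    loci.sort()
    merged: list[tuple[int, int, float, str]] = []
    for s, e, ident, strand in loci:
        if merged and s < merged[-1][1]:
            ps, pe, pi, pst = merged[-1]
            if ident > pi:
                merged[-1] = (min(s, ps), max(e, pe), ident, strand)
            else:
                merged[-1] = (min(s, ps), max(e, pe), pi, pst)
        else:
            merged.append((s, e, ident, strand))

    exclude_spans = exclude_spans or []
    out: list[LTRElement] = []
    for s, e, ident, strand in merged:
        if any(s < xe and e > xs for xs, xe in exclude_spans):
            continue
        if _n_fraction(seq, s, e) > params.max_n_fraction:
            continue
        out.append(
            LTRElement(
                seq_id=genome.id,
                start=s,
                end=e,
                ltr5=(s, e),
                n_ltrs=1,
                strand=strand,
                identity=ident,
                ltr_spans=[(s, e)],
            )
        )
    return out


# --- driver ---------------------------------------------------------------

def annotate_genome(
    genomes: list[GenomeSequence], params: DetectionParams | None = None
) -> list[LTRElement]:
    """Full structural annotation of one genome (all chromosomes).

    Structural pass first (intact + complex), then a homology pass with the
    LTR library of the intact calls to pick up solo LTRs.  Deterministic:
    no randomness anywhere in detection.
    """
    params = params or DetectionParams()
    all_elements: list[LTRElement] = []
    library: list[tuple[str, str]] = []
    per_genome_calls: dict[str, list[LTRElement]] = {}
    for genome in genomes:
        raw = find_intact_candidates(genome, params, resolve=False)
        complexes, rest = detect_complex(raw, genome, params)
        # TSD evidence feeds the overlap ranking: a corroborated element
        # beats a longer chimeric repeat pair bridging two insertions
        refined: dict[tuple[int, int], tuple[str | None, int, int]] = {}
        for c in rest:
            offs = (c.ltr3[0] - c.ltr5[0], c.ltr3[1] - c.ltr5[1])
            refined[(c.start, c.end)] = refine_tsd(
                genome, c.start, c.end, params, copy_offsets=offs
            )
        intact = resolve_overlaps(
            rest,
            rank_key=lambda c: (
                refined[(c.start, c.end)][0] is None,
                -c.identity,
                -c.length,
                c.start,
            ),
        )
        intact = [
            c
            for c in intact
            if all(c.end <= x.start or c.start >= x.end for x in complexes)
        ]
        for c in intact:
            tsd, s, e = refined[(c.start, c.end)]
            if (s, e) != (c.start, c.end):
                dl, dr = s - c.start, e - c.end
                c.ltr5 = (c.ltr5[0] + dl, c.ltr5[1] + dr)
                c.ltr3 = (c.ltr3[0] + dl, c.ltr3[1] + dr)
                c.internal = (c.ltr5[1], c.ltr3[0])
                c.ltr_spans = [c.ltr5, c.ltr3]
                c.start, c.end = s, e
            c.tsd = tsd
            c.category = classify_structure(c)
        calls = sorted(complexes + intact, key=lambda c: c.start)
        per_genome_calls[genome.id] = calls
        # library LTRs come from TSD-confirmed elements whose boundaries
        # are exact; unconfirmed (InT) boundaries would propagate their
        # jitter into every homology hit
        tsd_lib = [c for c in calls if c.n_ltrs >= 2 and c.tsd is not None]
        lib_source = tsd_lib if tsd_lib else [c for c in calls if c.n_ltrs >= 2]
        for c in lib_source:
            s, e = c.ltr5
            library.append((f"{genome.id}:{s}-{e}", genome.residues[s:e]))

    for genome in genomes:
        calls = per_genome_calls[genome.id]
        solos = find_homology_elements(
            genome, library, params, exclude_spans=[(c.start, c.end) for c in calls]
        )
        for s in solos:
            tsd, ns, ne = refine_tsd(genome, s.start, s.end, params)
            s.start, s.end = ns, ne
            s.ltr5 = (ns, ne)
            s.ltr_spans = [s.ltr5]
            s.tsd = tsd
            s.category = classify_structure(s)
        all_elements.extend(sorted(calls + solos, key=lambda c: c.start))

    for i, el in enumerate(all_elements):
        el.element_id = f"e{i:04d}"
    return all_elements


# --- tabular round trip ---------------------------------------------------

def elements_to_dataframe(elements: list[LTRElement]) -> pd.DataFrame:
    rows = []
    for el in elements:
        rows.append(
            dict(
                element_id=el.element_id,
                seq_id=el.seq_id,
                start=el.start,
                end=el.end,
                strand=el.strand,
                category=el.category,
                n_ltrs=el.n_ltrs,
                ltr5_start=el.ltr5[0],
                ltr5_end=el.ltr5[1],
                ltr3_start=el.ltr3[0] if el.ltr3 else -1,
                ltr3_end=el.ltr3[1] if el.ltr3 else -1,
                tsd=el.tsd or "",
                identity=el.identity,
                family_id=el.family_id,
                superfamily=el.superfamily,
                K=el.K if el.K is not None else float("nan"),
                age_years=el.age_years if el.age_years is not None else float("nan"),
            )
        )
    return pd.DataFrame(rows)


def elements_from_dataframe(df: pd.DataFrame) -> list[LTRElement]:
    out = []
    for _, r in df.iterrows():
        ltr3 = (int(r.ltr3_start), int(r.ltr3_end)) if r.ltr3_start >= 0 else None
        ltr5 = (int(r.ltr5_start), int(r.ltr5_end))
        el = LTRElement(
            seq_id=r.seq_id,
            start=int(r.start),
            end=int(r.end),
            ltr5=ltr5,
            ltr3=ltr3,
            internal=(ltr5[1], ltr3[0]) if ltr3 else None,
            tsd=(r.tsd if isinstance(r.tsd, str) and r.tsd else None),
            category=r.category,
            n_ltrs=int(r.n_ltrs),
            strand=r.strand,
            identity=float(r.identity),
            element_id=r.element_id,
            family_id=r.family_id if isinstance(r.family_id, str) else "",
            superfamily=r.superfamily if isinstance(r.superfamily, str) else "unknown",
            K=None if pd.isna(r.K) else float(r.K),
            age_years=None if pd.isna(r.age_years) else float(r.age_years),
            ltr_spans=[ltr5] + ([ltr3] if ltr3 else []),
        )
        out.append(el)
    return out
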