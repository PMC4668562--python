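"""Shared sequence-comparison primitives.

Pairwise global alignment goes through Bio.Align.PairwiseAligner; fast
approximate substring search goes through edlib; exact k-mer machinery is
2-bit-encoded numpy.  Everything downstream (detection, dating, family
clustering, orthology) builds on these helpers so scoring conventions stay
in one place.
"""

from __future__ import annotations

import math
from functools import lru_cache

import edlib
import numpy as np
from Bio import Align

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Default global-alignment scoring for LTR/LTR comparisons.
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -5.0, -1.0


def revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def global_alignment_columns(
    a: str,
    b: str,
    match: float = MATCH,
    mismatch: float = MISMATCH,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> tuple[int, int]:
    """Globally align two sequences and count usable columns.

    Returns (mismatches, aligned_sites) where aligned_sites are columns
    containing neither a gap nor an N; mismatches are counted over those
    columns only.
    """
    al = _aligner(match, mismatch, gap_open, gap_extend)
    aln = next(iter(al.align(a, b)))
    sa, sb = aln[0], aln[1]
    mismatches = 0
    sites = 0
    for ca, cb in zip(sa, sb):
        if ca == "-" or cb == "-" or ca == "N" or cb == "N":
            continue
        sites += 1
        if ca != cb:
            mismatches += 1
    return mismatches, sites


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction K = -(3/4) ln(1 - 4p/3); p must be < 0.75."""
    if p < 0:
        raise ValueError("mismatch proportion must be non-negative")
    if p >= 0.75:
        raise ValueError("JC undefined for p >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_p_from_k(k: float) -> float:
    """Inverse of the JC correction: the mismatch proportion giving divergence k."""
    return 0.75 * (1.0 - math.exp(-4.0 * k / 3.0))


def hamming_identity(a: str, b: str) -> float:
    """Identity of two equal-length strings; N never matches."""
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if not a:
        return 0.0
    same = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return same / len(a)


# --- edlib wrappers -------------------------------------------------------

def best_infix_match(query: str, target: str, max_edits: int) -> dict | None:
    """Best approximate occurrence of query inside target (edlib HW task)."""
    res = edlib.align(query, target, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return None
    return res


def infix_loci(query: str, target: str, max_edits: int) -> list[tuple[int, int, int]]:
    """All distinct loci where query occurs in target within max_edits.

    edlib reports every optimal end position; overlapping locations are
    merged into loci and each locus keeps its best (start, end, edits).
    Sub-optimal secondary loci are recovered by masking and re-searching.
    """
    found: list[tuple[int, int, int]] = []
    work = target
    offset_map = np.arange(len(target))
    # iterative best-hit + mask; bounded to avoid pathological repeats
    for _ in range(32):
        res = edlib.align(query, work, mode="HW", task="locations", k=max_edits)
        if res["editDistance"] < 0:
            break
        # merge optimal locations that overlap into loci
        locs = sorted(res["locations"])
        groups: list[list[tuple[int, int]]] = []
        for s, e in locs:
            s = 0 if s is None else s
            if groups and s <= groups[-1][-1][1]:
                groups[-1].append((s, e))
            else:
                groups.append([(s, e)])
        masked = list(work)
        for g in groups:
            s = min(x for x, _ in g)
            e = max(y for _, y in g) + 1
            found.append((int(offset_map[s]), int(offset_map[e - 1]) + 1, res["editDistance"]))
            for i in range(s, e):
                masked[i] = "\x00"
        work = "".join(masked)
    found.sort()
    return found


# --- k-mer machinery ------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for i, c in enumerate("ACGT"):
    _CODE[ord(c)] = i


def encode(seq: str) -> np.ndarray:
    """2-bit codes per base; 255 marks N (and anything non-ACGT)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers of seq and a validity mask (no N inside).

    Returns (codes, valid) of length len(seq)-k+1; invalid positions hold 0.
    """
    a = encode(seq)
    n = len(a) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + np.where(a[j : j + n] == 255, 0, a[j : j + n]).astype(np.int64)
    bad = (a == 255).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid
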