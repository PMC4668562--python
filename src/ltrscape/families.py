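"""Family clustering and superfamily assignment.

Families are single-linkage clusters of elements whose LTRs align at
>= 80% identity over >= 80% of the shorter LTR with >= 80 aligned bp
(the classic 80-80-80 rule).  LTRs, not internal regions, carry the
linkage so that solo LTRs cluster with the intact elements they derive
from.  Superfamilies follow domain order in the internal region: an
integrase core upstream of the reverse-transcriptase core marks Copia,
the reverse order marks Gypsy; families with motif-free internals are
TRIM (tiny internal, small element) or LARD (internal > 4 kb).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .align import _aligner, GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH, revcomp
from .annotate import LTRElement
from .io import GenomeSequence
from .motifs import superfamily_motifs

LARD_MIN_INTERNAL = 4000
TRIM_MAX_INTERNAL = 1000
TRIM_MAX_ELEMENT = 2500
MOTIF_SCORE_FRACTION = 0.40

__all__ = [
    "Family",
    "cluster_families",
    "assign_superfamily",
    "build_consensus",
    "summarize_superfamilies",
    "structure_ratio",
]


@dataclass
class Family:
    family_id: str
    member_ids: list[str]
    consensus_ltr: str = ""
    consensus_internal: str = ""
    superfamily: str = "unknown"
    lineage: str = "unassigned"
    mean_element_len: float = 0.0
    rt_hit: dict | None = field(default=None, repr=False)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _ltr_seq(el: LTRElement, genomes: dict[str, GenomeSequence]) -> str:
    s, e = el.ltr5
    seq = genomes[el.seq_id].residues[s:e]
    return revcomp(seq) if el.strand == "-" else seq


def _linked(a: str, b: str, identity: float, coverage: float, min_align: int) -> bool:
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if len(short) < min_align:
        return False
    max_edits = int((1 - identity) * len(short))
    for target in (long_, revcomp(long_)):
        res = edlib.align(short, target, mode="HW", task="distance", k=max_edits)
        if res["editDistance"] >= 0:
            ident = 1 - res["editDistance"] / len(short)
            if ident >= identity and len(short) >= coverage * len(short):
                return True
    return False


def cluster_families(
    elements: list[LTRElement],
    genomes: dict[str, GenomeSequence],
    identity_threshold: float = 0.80,
    coverage_threshold: float = 0.80,
    min_align: int = 80,
) -> list[Family]:
    """Single-linkage clustering of elements by LTR similarity.

    Family ids are assigned by decreasing size, ties broken by leftmost
    member, so the labelling is invariant to input order.  Element
    ``family_id`` fields are written back.
    """
    seqs = [_ltr_seq(el, genomes) for el in elements]
    n = len(elements)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j):
                continue
            if _linked(seqs[i], seqs[j], identity_threshold, coverage_threshold, min_align):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    ordered = sorted(
        groups.values(),
        key=lambda idxs: (-len(idxs), min((elements[i].seq_id, elements[i].start) for i in idxs)),
    )
    families: list[Family] = []
    for rank, idxs in enumerate(ordered):
        fid = f"fam{rank:03d}"
        members = sorted(idxs, key=lambda i: (elements[i].seq_id, elements[i].start))
        for i in members:
            elements[i].family_id = fid
        fam = Family(fid, [elements[i].element_id for i in members])
        fam.consensus_ltr = build_consensus([seqs[i] for i in members])
        internals = [
            genomes[elements[i].seq_id].residues[
                elements[i].internal[0] : elements[i].internal[1]
            ]
            for i in members
            if elements[i].internal is not None and elements[i].n_ltrs >= 2
        ]
        if internals:
            fam.consensus_internal = build_consensus(internals)
        lens = [elements[i].length for i in members if elements[i].n_ltrs >= 2]
        fam.mean_element_len = float(np.mean(lens)) if lens else 0.0
        families.append(fam)
    return families


def build_consensus(sequences: list[str]) -> str:
    """Majority-rule consensus over a star alignment to the longest member.

    Ties break alphabetically; columns where the majority is a gap are
    dropped.  A single member is its own consensus.
    """
    if not sequences:
        raise ValueError("no sequences")
    if len(sequences) == 1:
        return sequences[0]
    center = max(sequences, key=len)
    columns: list[list[str]] = [[] for _ in range(len(center))]
    al = _aligner(MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)
    for seq in sequences:
        if seq is center:
            for i, c in enumerate(center):
                columns[i].append(c)
            continue
        aln = next(iter(al.align(center, seq)))
        sa, sb = aln[0], aln[1]
        ci = 0
        for ca, cb in zip(sa, sb):
            if ca == "-":
                continue  # insertion relative to center: outside star columns
            columns[ci].append(cb)
            ci += 1
    out = []
    for col in columns:
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        if best != "-":
            out.append(best)
    return "".join(out)


# --- superfamily by domain order ------------------------------------------

_AA_CODE = {c: i for i, c in enumerate("ACDEFGHIKLMNPQRSTVWY*X")}


def _translate_six_frames(nt: str) -> list[tuple[str, int, int]]:
    """(peptide, frame_offset, direction) for the six reading frames."""
    from Bio.Seq import Seq

    frames = []
    rc = revcomp(nt)
    for off in range(3):
        n_codons = (len(nt) - off) // 3
        fwd = str(Seq(nt[off : off + 3 * n_codons]).translate())
        frames.append((fwd, off, +1))
        rev = str(Seq(rc[off : off + 3 * n_codons]).translate())
        frames.append((rev, off, -1))
    return frames


def _best_ungapped_hit(peptide_frame: str, motif: str) -> tuple[float, int]:
    """Best ungapped local +1/-1 match of motif within a translated frame.

    Returns (score, aa_midpoint_in_frame); score is the best contiguous
    segment score over all offsets (Kadane along the motif).
    """
    t = np.frombuffer(peptide_frame.encode(), dtype=np.uint8)
    q = np.frombuffer(motif.encode(), dtype=np.uint8)
    n, m = t.size, q.size
    if n < 5:
        return -1.0, 0
    n_off = n - min(m, n) + 1
    if n_off <= 0:
        n_off = 1
    offsets = np.arange(n_off)
    width = min(m, n)
    idx = offsets[:, None] + np.arange(width)[None, :]
    scores = np.where(t[idx] == q[:width][None, :], 1.0, -1.0)
    run = np.zeros(n_off)
    best = np.full(n_off, -1.0)
    best_end = np.zeros(n_off, dtype=int)
    for j in range(width):
        run = np.maximum(run + scores[:, j], scores[:, j])
        upd = run > best
        best = np.where(upd, run, best)
        best_end = np.where(upd, j, best_end)
    i = int(np.argmax(best))
    return float(best[i]), int(offsets[i] + best_end[i])


def _motif_scan(internal_nt: str, motif: str) -> tuple[float, int]:
    """Best hit of a peptide motif over six frames; returns (score_fraction,
    approximate nucleotide midpoint on the forward strand)."""
    best_frac, best_pos = -1.0, -1
    for pep, off, direction in _translate_six_frames(internal_nt):
        score, aa_end = _best_ungapped_hit(pep, motif)
        frac = score / len(motif)
        if frac > best_frac:
            nt_pos = off + 3 * aa_end
            if direction < 0:
                nt_pos = len(internal_nt) - nt_pos
            best_frac, best_pos = frac, nt_pos
    return best_frac, best_pos


def assign_superfamily(family: Family, motifs: dict | None = None) -> str:
    """Superfamily of a family from its consensus internal region.

    Both superfamilies' INT and RT motifs are scanned; the best-scoring
    hit per domain (threshold: 40% of the motif self-score) decides
    presence, and the order of the two domains decides Copia vs Gypsy.
    """
    motifs = motifs or superfamily_motifs()
    internal = family.consensus_internal
    if not internal:
        family.superfamily = "unknown"
        return family.superfamily
    best: dict[str, tuple[float, int]] = {"INT": (-1.0, -1), "RT": (-1.0, -1)}
    for sf in motifs:
        for domain, pep in motifs[sf].items():
            frac, pos = _motif_scan(internal, pep)
            if frac > best[domain][0]:
                best[domain] = (frac, pos)
    int_ok = best["INT"][0] >= MOTIF_SCORE_FRACTION
    rt_ok = best["RT"][0] >= MOTIF_SCORE_FRACTION
    if int_ok and rt_ok:
        sf = "Copia" if best["INT"][1] < best["RT"][1] else "Gypsy"
        family.rt_hit = {"score_fraction": best["RT"][0], "nt_pos": best["RT"][1]}
    elif len(internal) > LARD_MIN_INTERNAL:
        sf = "LARD"
    elif len(internal) < TRIM_MAX_INTERNAL and (
        family.mean_element_len == 0 or family.mean_element_len < TRIM_MAX_ELEMENT
    ):
        sf = "TRIM"
    else:
        sf = "unknown"
    family.superfamily = sf
    return sf


def classify_elements(
    elements: list[LTRElement],
    genomes: dict[str, GenomeSequence],
    **cluster_kwargs,
) -> list[Family]:
    """Cluster into families, assign superfamilies, push labels to elements."""
    families = cluster_families(elements, genomes, **cluster_kwargs)
    by_id = {f.family_id: f for f in families}
    for fam in families:
        assign_superfamily(fam)
    for el in elements:
        if el.family_id in by_id:
            el.superfamily = by_id[el.family_id].superfamily
    return families


# --- summary tables -------------------------------------------------------

def structure_ratio(it: int, st: int, in_t: int, sn_t: int) -> str:
    """(ST+SnT)/(IT+InT) to 2 decimals; '/' when the denominator is zero."""
    denom = it + in_t
    if denom == 0:
        return "/"
    return f"{(st + sn_t) / denom:.2f}"


def summarize_superfamilies(elements_df: pd.DataFrame) -> pd.DataFrame:
    """Per-superfamily summary: family and category counts, the
    (ST+SnT)/(IT+InT) ratio and the mean insertion age in My."""
    rows = []
    cats = ["IT", "ST", "InT", "SnT"]
    for sf, grp in elements_df.groupby("superfamily"):
        counts = {c: int((grp.category == c).sum()) for c in cats}
        ages = grp.age_years.dropna()
        rows.append(
            dict(
                superfamily=sf,
                n_families=grp.family_id.nunique(),
                **counts,
                n_complex=int((grp.category == "complex").sum()),
                subtotal=len(grp),
                ratio=structure_ratio(counts["IT"], counts["ST"], counts["InT"], counts["SnT"]),
                mean_age_my=round(float(ages.mean()) / 1e6, 2) if len(ages) else float("nan"),
            )
        )
    out = pd.DataFrame(rows).sort_values("subtotal", ascending=False).reset_index(drop=True)
    total_counts = {c: int((elements_df.category == c).sum()) for c in cats}
    ages = elements_df.age_years.dropna()
    total = dict(
        superfamily="Total",
        n_families=elements_df.family_id.nunique(),
        **total_counts,
        n_complex=int((elements_df.category == "complex").sum()),
        subtotal=len(elements_df),
        ratio=structure_ratio(
            total_counts["IT"], total_counts["ST"], total_counts["InT"], total_counts["SnT"]
        ),
        mean_age_my=round(float(ages.mean()) / 1e6, 2) if len(ages) else float("nan"),
    )
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)
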