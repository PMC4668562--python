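"""Neighbor-joining trees of family RT regions and lineage assignment.

Distances are Jukes-Cantor on pairwise global alignments (same engine as
insertion dating); trees are built with the Saitou-Nei neighbor-joining
algorithm and emitted as Newick.  Each Copia/Gypsy family is assigned to
the named lineage of its nearest reference RT sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import global_alignment_columns, jc_distance
from .families import Family, _best_ungapped_hit, _translate_six_frames
from .motifs import lineage_references, superfamily_motifs

SATURATION_CAP = 3.0
LINEAGE_DISTANCE_CAP = 1.5

__all__ = [
    "DistanceMatrix",
    "LineageAssignment",
    "pairwise_distances",
    "nj_tree",
    "assign_lineage",
    "extract_rt_region",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    capped_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class LineageAssignment:
    family_id: str
    lineage: str
    reference_id: str = ""
    distance: float = float("nan")
    tie: bool = False


def pairwise_distances(sequences: dict[str, str]) -> DistanceMatrix:
    """JC distance matrix over all pairs of named sequences.

    Saturated pairs (p >= 0.75) get the documented cap of 3.0 and are
    listed in ``capped_pairs``.
    """
    ids = list(sequences)
    if len(ids) < 3:
        raise ValueError("need >= 3 sequences")
    for name, seq in sequences.items():
        if len(seq) < 100:
            raise ValueError(f"sequence {name} shorter than 100 bp")
    n = len(ids)
    mat = np.zeros((n, n))
    capped = []
    for i in range(n):
        for j in range(i + 1, n):
            mism, sites = global_alignment_columns(sequences[ids[i]], sequences[ids[j]])
            p = mism / sites if sites else 1.0
            if p >= 0.75:
                d = SATURATION_CAP
                capped.append((ids[i], ids[j]))
            else:
                d = jc_distance(p)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids, mat, capped)


def nj_tree(dm: DistanceMatrix, outgroup: str | None = None) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.  With an outgroup the emitted tree is rooted on
    that taxon's branch; otherwise the root is the final trifurcation.
    """
    if not np.allclose(dm.matrix, dm.matrix.T):
        raise ValueError("distance matrix is not symmetric")
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes = [f"{_escape(t)}" for t in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = divmod(int(np.argmin(q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        gi, gj = active[i_loc], active[j_loc]
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k_loc, gk in enumerate(active):
            if k_loc in (i_loc, j_loc):
                continue
            d[new, gk] = d[gk, new] = 0.5 * (sub[i_loc, k_loc] + sub[j_loc, k_loc] - dij)
        nodes.append(f"({nodes[gi]}:{li:.10g},{nodes[gj]}:{lj:.10g})")
        active = [g for g in active if g not in (gi, gj)] + [new]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb = _clamp_pair(la, lb)
    lb, lc = _clamp_pair(lb, lc)
    newick = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"
    if outgroup is not None:
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        og = tree.find_node_with_taxon_label(outgroup)
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        tree.to_outgroup_position(og, update_bipartitions=False)
        newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return newick


def _clamp_pair(x: float, y: float) -> tuple[float, float]:
    if x < 0:
        y += -x
        x = 0.0
    if y < 0:
        x += -y
        y = 0.0
    return x, y


def _escape(taxon: str) -> str:
    return taxon.replace(" ", "_")


# --- RT region and lineage ------------------------------------------------

def extract_rt_region(family: Family, window_nt: int = 600) -> str | None:
    """Best-scoring RT-motif window of the family's consensus internal."""
    internal = family.consensus_internal
    if not internal:
        return None
    motifs = superfamily_motifs()
    best_frac, best_pos = -1.0, -1
    for sf in motifs:
        for pep, off, direction in _translate_six_frames(internal):
            score, aa_end = _best_ungapped_hit(pep, motifs[sf]["RT"])
            frac = score / len(motifs[sf]["RT"])
            if frac > best_frac:
                nt_pos = off + 3 * aa_end
                if direction < 0:
                    nt_pos = len(internal) - nt_pos
                best_frac, best_pos = frac, nt_pos
    if best_frac < 0.3:
        return None
    s = max(0, best_pos - window_nt // 2)
    return internal[s : s + window_nt]


def assign_lineage(
    family: Family,
    references: list[tuple[str, str, str]] | None = None,
    rt_region: str | None = None,
) -> LineageAssignment:
    """Nearest-reference lineage for one Copia/Gypsy family.

    Distances are JC over pairwise alignments to references of the
    family's superfamily; min distance above the cap, or no recoverable
    RT region, yields "unassigned".  Ties break by lexicographic
    reference id and are flagged.
    """
    if family.superfamily not in ("Copia", "Gypsy"):
        return LineageAssignment(family.family_id, "unassigned")
    refs = references if references is not None else lineage_references()
    refs = [r for r in refs if r[1] == family.superfamily]
    rt = rt_region if rt_region is not None else extract_rt_region(family)
    if rt is None or not refs:
        return LineageAssignment(family.family_id, "unassigned")
    scored = []
    for name, _sf, seq in refs:
        mism, sites = global_alignment_columns(rt, seq)
        p = mism / sites if sites else 1.0
        d = SATURATION_CAP if p >= 0.75 else jc_distance(p)
        scored.append((d, name))
    scored.sort(key=lambda t: (round(t[0], 12), t[1]))
    best_d, best_name = scored[0]
    tie = len(scored) > 1 and abs(scored[1][0] - best_d) < 1e-12
    if best_d > LINEAGE_DISTANCE_CAP:
        return LineageAssignment(family.family_id, "unassigned", best_name, best_d, tie)
    lineage = best_name.split("|")[0]
    out = LineageAssignment(family.family_id, lineage, best_name, best_d, tie)
    family.lineage = lineage
    return out
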