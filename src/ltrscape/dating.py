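"""Insertion-age estimation from LTR-LTR divergence.

The two LTRs of an element are identical at insertion and diverge
thereafter, so the per-site divergence K between them, combined with a
substitution rate r (default 1.3e-8 substitutions per site per year),
dates the insertion as T = K / (2 r).  Divergence is measured on a global
affine-gap alignment of the two LTRs, excluding gap and N columns, and
corrected with the Jukes-Cantor formula K = -(3/4) ln(1 - 4p/3).
A Kimura two-parameter correction is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .align import global_alignment_columns, jc_distance
from .annotate import LTRElement
from .io import GenomeSequence

DEFAULT_RATE = 1.3e-8  # substitutions per site per year

__all__ = [
    "AgeEstimate",
    "ltr_divergence",
    "insertion_time",
    "date_elements",
    "age_distribution",
    "DEFAULT_RATE",
]


@dataclass
class AgeEstimate:
    element_id: str
    p: float
    K: float
    r: float
    T: float
    aligned_sites: int


def _k2p(a_aln: str, b_aln: str) -> float:
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    s = v = n = 0
    for ca, cb in zip(a_aln, b_aln):
        if ca in "-N" or cb in "-N":
            continue
        n += 1
        if ca == cb:
            continue
        if (ca, cb) in transitions:
            s += 1
        else:
            v += 1
    P, Q = s / n, v / n
    return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))


def ltr_divergence(ltr5: str, ltr3: str, model: str = "JC") -> tuple[float, float, int]:
    """(p, K, aligned_sites) between two LTR sequences.

    Columns with a gap or N are excluded from the site count; p is the
    mismatch proportion over the remaining columns.
    """
    if len(ltr5) < 50 or len(ltr3) < 50:
        raise ValueError("LTR sequences must be >= 50 bp")
    mismatches, sites = global_alignment_columns(ltr5, ltr3)
    if sites < 50:
        raise ValueError(f"only {sites} aligned sites; need >= 50")
    p = mismatches / sites
    if p >= 0.75:
        raise ValueError("JC undefined: mismatch proportion >= 0.75")
    if model == "JC":
        k = jc_distance(p)
    elif model == "K2P":
        # re-align once more to recover column pairs for the ts/tv split
        from .align import _aligner, GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH

        aln = next(iter(_aligner(MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND).align(ltr5, ltr3)))
        k = _k2p(aln[0], aln[1])
    else:
        raise ValueError(f"unknown model {model!r}")
    return p, k, sites


def insertion_time(k: float, r: float = DEFAULT_RATE) -> float:
    """T = K / (2 r), in years."""
    if k < 0:
        raise ValueError("divergence must be non-negative")
    if r <= 0:
        raise ValueError("rate must be positive")
    return k / (2.0 * r)


def date_elements(
    elements: list[LTRElement],
    genomes: dict[str, GenomeSequence],
    r: float = DEFAULT_RATE,
    model: str = "JC",
) -> list[AgeEstimate]:
    """Date every element with two LTR spans; K and age are written back."""
    out: list[AgeEstimate] = []
    for el in elements:
        if el.ltr3 is None or el.n_ltrs < 2:
            continue
        seq = genomes[el.seq_id].residues
        l5 = seq[el.ltr5[0] : el.ltr5[1]]
        l3 = seq[el.ltr3[0] : el.ltr3[1]]
        try:
            p, k, sites = ltr_divergence(l5, l3, model=model)
        except ValueError:
            continue
        t = insertion_time(k, r)
        el.K = k
        el.age_years = t
        out.append(AgeEstimate(el.element_id, p, k, r, t, sites))
    return out


def age_distribution(ages_years: list[float], bin_my: float = 0.5) -> dict:
    """Histogram of ages plus linear and exponential decay diagnostics.

    Returns per-bin counts, the Pearson correlation of count vs bin
    midpoint (linear diagnostic) and of ln(count) vs midpoint over
    positive bins (exponential diagnostic), each with a two-sided p-value.
    """
    if len(ages_years) == 0:
        raise ValueError("no ages supplied")
    my = np.asarray(ages_years, dtype=float) / 1e6
    n_bins = max(1, int(np.ceil((my.max() + 1e-12) / bin_my)))
    counts, edges = np.histogram(my, bins=n_bins, range=(0, n_bins * bin_my))
    mids = 0.5 * (edges[:-1] + edges[1:])
    result = {
        "bin_my": bin_my,
        "bin_mid_my": mids.tolist(),
        "counts": counts.tolist(),
        "linear": None,
        "exponential": None,
    }
    nonempty = counts > 0
    if nonempty.sum() < 2:
        result["flag"] = "fits undefined: fewer than 2 non-empty bins"
        return result
    r_lin, p_lin = stats.pearsonr(mids, counts)
    result["linear"] = {"r": float(r_lin), "p": float(p_lin)}
    pos = counts > 0
    if pos.sum() >= 2:
        r_exp, p_exp = stats.pearsonr(mids[pos], np.log(counts[pos]))
        result["exponential"] = {"r": float(r_exp), "p": float(p_exp)}
    return result
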