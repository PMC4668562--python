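"""Chromosomal distribution: window profiles, randomization test,
Marey-map recombination rates and density correlations.

Chromosomes are tiled with fixed windows (the trailing partial window is
dropped); a feature belongs to the window holding its midpoint.  Windows
whose N content exceeds half the window are ineligible.  The null model
of the randomization test places the observed number of midpoints
uniformly over the eligible windows and scores each window by the
two-sided extremeness of its count.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "window_counts",
    "randomization_test",
    "marey_rates",
    "density_correlation",
]


def window_counts(
    midpoints: dict[str, np.ndarray],
    seq_lengths: dict[str, int],
    window_size: int,
    n_runs: dict[str, list[tuple[int, int]]] | None = None,
    gene_midpoints: dict[str, np.ndarray] | None = None,
    n_fraction_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-window feature counts.

    ``midpoints`` maps seq_id -> feature midpoints (bp).  ``n_runs`` maps
    seq_id -> [(start, length)] of N runs for eligibility bookkeeping.
    Features falling in the dropped trailing window are excluded (their
    number is recoverable as total minus the table sum).
    """
    rows = []
    n_runs = n_runs or {}
    for seq_id, length in seq_lengths.items():
        n_win = length // window_size
        if n_win == 0:
            logger.warning("%s shorter than one %d-bp window", seq_id, window_size)
            continue
        span = n_win * window_size
        n_bp = np.zeros(n_win, dtype=np.int64)
        for start, glen in n_runs.get(seq_id, []):
            for w in range(max(0, start // window_size), min(n_win - 1, (start + glen - 1) // window_size) + 1):
                ws, we = w * window_size, (w + 1) * window_size
                n_bp[w] += max(0, min(start + glen, we) - max(start, ws))
        mids = np.asarray(midpoints.get(seq_id, []), dtype=np.int64)
        counts = np.bincount(mids[mids < span] // window_size, minlength=n_win)
        if gene_midpoints is not None:
            gm = np.asarray(gene_midpoints.get(seq_id, []), dtype=np.int64)
            gcounts = np.bincount(gm[gm < span] // window_size, minlength=n_win)
        else:
            gcounts = np.zeros(n_win, dtype=np.int64)
        for w in range(n_win):
            rows.append(
                dict(
                    seq_id=seq_id,
                    window=w,
                    start=w * window_size,
                    end=(w + 1) * window_size,
                    n_bp_N=int(n_bp[w]),
                    eligible=bool(n_bp[w] <= n_fraction_threshold * window_size),
                    element_count=int(counts[w]),
                    gene_count=int(gcounts[w]),
                )
            )
    return pd.DataFrame(rows)


def randomization_test(
    profiles: pd.DataFrame,
    n_sim: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    count_col: str = "element_count",
) -> tuple[pd.DataFrame, dict]:
    """Monte-Carlo test of uniform placement over eligible windows.

    The observed total count over eligible windows is re-placed uniformly
    ``n_sim`` times; each window's empirical two-sided p-value is
    (1 + #{sims with |count - expected| >= |observed - expected|}) / (n_sim + 1).
    Returns the profile table with an ``empirical_p`` column and a summary
    with the fraction of eligible windows consistent with randomness.
    """
    elig = profiles.eligible.to_numpy()
    m = int(elig.sum())
    if m == 0:
        raise ValueError("no eligible windows")
    obs = profiles.loc[profiles.eligible, count_col].to_numpy()
    total = int(obs.sum())
    if total == 0:
        raise ValueError("no features in eligible windows")
    rng = np.random.default_rng(seed)
    expected = total / m
    sims = rng.multinomial(total, np.full(m, 1.0 / m), size=n_sim)
    obs_dev = np.abs(obs - expected)
    sim_dev = np.abs(sims - expected)
    p = (1 + (sim_dev >= obs_dev[None, :]).sum(axis=0)) / (n_sim + 1)
    out = profiles.copy()
    out["empirical_p"] = np.nan
    out.loc[out.eligible, "empirical_p"] = p
    frac_random = float((p >= alpha).mean())
    summary = {
        "n_eligible_windows": m,
        "n_features": total,
        "alpha": alpha,
        "n_sim": n_sim,
        "fraction_consistent_with_random": frac_random,
        "n_windows_nonrandom": int((p < alpha).sum()),
    }
    return out, summary


def _longest_nondecreasing(values: np.ndarray) -> np.ndarray:
    """Indices of one longest non-decreasing subsequence (patience sort)."""
    import bisect

    n = len(values)
    tails: list[float] = []
    tail_idx: list[int] = []
    prev = np.full(n, -1)
    for i, v in enumerate(values):
        j = bisect.bisect_right(tails, v)
        if j == len(tails):
            tails.append(v)
            tail_idx.append(i)
        else:
            tails[j] = v
            tail_idx[j] = i
        prev[i] = tail_idx[j - 1] if j > 0 else -1
    out = []
    i = tail_idx[-1]
    while i >= 0:
        out.append(i)
        i = prev[i]
    return np.array(out[::-1])


def marey_rates(
    markers: pd.DataFrame,
    windows: pd.DataFrame,
    k_neighbors: int = 7,
    min_markers: int = 5,
) -> pd.DataFrame:
    """Local recombination rate (cM/Mb) at each window midpoint.

    Markers are reduced to a monotone Marey series (longest non-decreasing
    cM subsequence along bp); the local rate is the least-squares slope
    over the ``k_neighbors`` markers nearest the window midpoint, clamped
    at zero.  Chromosomes with < ``min_markers`` usable markers get NaN.
    """
    out = windows.copy()
    out["gr_rate"] = np.nan
    for chrom, grp in markers.groupby("chrom"):
        grp = grp.sort_values("bp")
        bp = grp.bp.to_numpy(dtype=float)
        cm = grp.cM.to_numpy(dtype=float)
        keep = _longest_nondecreasing(cm)
        bp, cm = bp[keep], cm[keep]
        if len(bp) < min_markers:
            continue
        mask = out.seq_id == chrom
        mids = ((out.loc[mask, "start"] + out.loc[mask, "end"]) / 2).to_numpy(dtype=float)
        rates = np.empty(mids.size)
        for i, mid in enumerate(mids):
            order = np.argsort(np.abs(bp - mid), kind="stable")[:k_neighbors]
            x, y = bp[order], cm[order]
            if np.ptp(x) == 0:
                rates[i] = np.nan
                continue
            slope = np.polyfit(x, y, 1)[0] * 1e6  # cM per bp -> cM per Mb
            rates[i] = max(0.0, slope)
        out.loc[mask, "gr_rate"] = rates
    return out


def density_correlation(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
) -> dict:
    """Pearson correlation of two per-window densities with a percentile
    bootstrap confidence interval over windows."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise ValueError("need >= 10 paired windows")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "ci": (float("nan"), float("nan")),
                "flag": "zero variance"}
    r, p = stats.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    n = x.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = stats.pearsonr(xb, yb)[0]
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return {"r": float(r), "p": float(p), "ci": (float(lo), float(hi)), "n": int(n)}
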