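"""Higher-order chromatin stability metrics.

TAD and compartment interval tracks from different time points are compared
by 90% reciprocal overlap; A/B eigen-score vectors by pairwise Pearson
correlation regressed against time separation; and dense contact matrices
by a simplified stratum-adjusted correlation coefficient (SCC): Pearson r
per off-diagonal stratum, combined with weights N_d * sd_a,d * sd_b,d.
The 2D smoothing of the original SCC formulation is deliberately omitted.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "reciprocal_overlap_fraction",
    "merge_intervals",
    "compartment_corr_trend",
    "scc",
]


def reciprocal_overlap_fraction(track_a: pd.DataFrame, track_b: pd.DataFrame,
                                min_frac: float = 0.9) -> float:
    """Fraction of intervals in ``track_a`` reciprocally matched in ``track_b``.

    An interval i in a counts if some j in b overlaps it by at least
    ``min_frac`` of *both* lengths. Asymmetric by design: the denominator
    is |a|.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    if len(track_a) == 0:
        raise ValueError("empty track_a")
    hits = 0
    for _, ia in track_a.iterrows():
        la = ia["end"] - ia["start"]
        sub = track_b[track_b["chrom"] == ia["chrom"]] if "chrom" in track_b else track_b
        for _, jb in sub.iterrows():
            ov = min(ia["end"], jb["end"]) - max(ia["start"], jb["start"])
            lb = jb["end"] - jb["start"]
            if ov >= min_frac * la and ov >= min_frac * lb:
                hits += 1
                break
    return hits / len(track_a)


def merge_intervals(tracks: list[pd.DataFrame]) -> pd.DataFrame:
    """Single-linkage union of overlapping intervals across tracks.

    Used for reporting merged TAD/compartment counts across the time course.
    """
    allv = pd.concat(tracks, ignore_index=True).sort_values(["chrom", "start"])
    rows = []
    for chrom, sub in allv.groupby("chrom"):
        cur_s, cur_e = None, None
        for _, iv in sub.iterrows():
            if cur_s is None:
                cur_s, cur_e = iv["start"], iv["end"]
            elif iv["start"] <= cur_e:
                cur_e = max(cur_e, iv["end"])
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = iv["start"], iv["end"]
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def compartment_corr_trend(scores: pd.DataFrame) -> dict:
    """Pairwise eigen-score correlations against time separation.

    ``scores``: bins x samples, columns labelled by time in minutes (shared
    bin grid). Eigen-score signs are oriented so each sample correlates
    non-negatively with the first before the trend fit. Returns the pair
    table, OLS slope and intercept of r vs |delta t|.
    """
    if scores.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if scores.shape[0] < 2:
        raise ValueError("need >= 2 shared bins")
    X = scores.to_numpy(dtype=float).copy()
    times = np.asarray(scores.columns, dtype=float)
    for j in range(1, X.shape[1]):
        if np.corrcoef(X[:, 0], X[:, j])[0, 1] < 0:
            X[:, j] = -X[:, j]
    rows = []
    for i, j in itertools.combinations(range(X.shape[1]), 2):
        r = float(np.corrcoef(X[:, i], X[:, j])[0, 1])
        rows.append((times[i], times[j], abs(times[j] - times[i]), r))
    pairs = pd.DataFrame(rows, columns=["t1", "t2", "dt", "r"])
    if pairs["dt"].nunique() > 1:
        fit = stats.linregress(pairs["dt"], pairs["r"])
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope, intercept = 0.0, float(pairs["r"].mean())
    return {"pairs": pairs, "slope": slope, "intercept": intercept}


def scc(matrix_a: np.ndarray, matrix_b: np.ndarray, max_dist_bins: int | None = None) -> float:
    """Simplified stratum-adjusted correlation between two contact matrices.

    For each off-diagonal stratum d = 1..max_dist_bins, Pearson r_d over the
    paired entries; SCC = sum(w_d r_d) / sum(w_d) with
    w_d = N_d * sd_a,d * sd_b,d. Zero-variance strata are skipped.
    """
    A = np.asarray(matrix_a, dtype=float)
    B = np.asarray(matrix_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and same shape")
    n = A.shape[0]
    if max_dist_bins is None:
        max_dist_bins = n - 1
    num, den = 0.0, 0.0
    for d in range(1, min(max_dist_bins, n - 1) + 1):
        ia = np.arange(n - d)
        a = A[ia, ia + d]
        b = B[ia, ia + d]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0 or len(a) < 2:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        w = len(a) * sa * sb
        num += w * r
        den += w
    if den == 0:
        return np.nan
    return num / den
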