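"""Independent brute-force oracles used by the unit and acceptance tests.

Each function reimplements an operation naively (loops, polyfit, exhaustive
scans) with no code shared with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def naive_gaussian_smooth(values: np.ndarray, window: int, sigma: float) -> np.ndarray:
    """O(n*w) truncated-renormalized Gaussian rolling mean."""
    if window % 2 == 0:
        window += 1
    half = window // 2
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        d = np.arange(lo, hi) - i
        w = np.exp(-0.5 * (d / sigma) ** 2)
        out[i] = np.sum(w * values[lo:hi]) / w.sum()
    return out


def irls_logistic_fit(obs: pd.DataFrame):
    """statsmodels IRLS fit of the four-coefficient model (beta, se)."""
    import statsmodels.api as sm_api

    bcode = {"Wine": -0.5, "Oak": 0.5}
    y = obs["wine_smooth"] / (obs["oak_smooth"] + obs["wine_smooth"])
    w = (obs["oak_smooth"] + obs["wine_smooth"]).to_numpy()
    b = obs["background"].map(bcode).to_numpy()
    s = obs["selection"].to_numpy()
    X = np.column_stack([np.ones(len(obs)), s, b, s * b])
    res = sm_api.GLM(y, X, family=sm_api.families.Binomial(), freq_weights=w).fit()
    return np.asarray(res.params), np.asarray(res.bse)


def naive_slope(abs_z: np.ndarray, window: int) -> np.ndarray:
    """Per-position OLS slope via numpy.polyfit in a truncated window."""
    half = window // 2
    n = len(abs_z)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        x = np.arange(lo, hi, dtype=float)
        if len(x) < 2 or np.ptp(x) == 0:
            out[i] = 0.0
        else:
            out[i] = np.polyfit(x, abs_z[lo:hi], 1)[0]
    return out


def naive_call_peaks(z: np.ndarray, pos: np.ndarray, threshold: float,
                     window: int) -> list[tuple[int, float]]:
    """Full slope/segment/max peak procedure, O(n^2), loop-based."""
    abs_z = np.abs(z)
    slopes = naive_slope(abs_z, window)
    boundaries = [0]
    for i in range(1, len(slopes)):
        if slopes[i - 1] < 0 and slopes[i] > 0:
            boundaries.append(i)
    boundaries.append(len(z))
    peaks = []
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        best = lo
        for j in range(lo, hi):
            if abs_z[j] > abs_z[best]:
                best = j
        if abs_z[best] >= threshold:
            peaks.append((int(pos[best]), float(z[best])))
    return peaks


def naive_dominance_filter(trace: pd.DataFrame, thr_interaction: float) -> pd.DataFrame:
    """Row-by-row filter for dominant interactions."""
    keep = []
    for i, row in trace.iterrows():
        zi, zs = abs(row["z3"]), abs(row["z1"])
        if np.isfinite(zi) and zi >= thr_interaction and zi > zs:
            keep.append(i)
    return trace.loc[keep].reset_index(drop=True)


def greedy_nearest_pairs(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int, float]]:
    """Exhaustive greedy minimal-distance assignment (positions of one chromosome)."""
    a_left = list(enumerate(a))
    b_left = list(enumerate(b))
    pairs = []
    while a_left and b_left:
        best = min(((i, j, abs(x - y)) for i, x in a_left for j, y in b_left),
                   key=lambda t: t[2])
        pairs.append((int(a[best[0]]), int(b[best[1]]), float(best[2])))
        a_left = [(i, x) for i, x in a_left if i != best[0]]
        b_left = [(j, y) for j, y in b_left if j != best[1]]
    return pairs
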