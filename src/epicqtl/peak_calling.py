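"""QTL peak calling by slope-based segmentation of the |z| trace.

Within each chromosome the local slope of the absolute z-score trace is
estimated by ordinary least squares in a sliding window of SNPs (default
700, truncated at chromosome ends). Segment boundaries sit at chromosome
ends and at local minima — positions where the local slope shifts strictly
from negative to positive. The maximum |z| within each segment is called a
peak when it clears the effect's FDR threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from epicqtl.glm_scan import EFFECTS
from epicqtl.permutation_fdr import FdrThresholds

logger = logging.getLogger(__name__)

DEFAULT_SLOPE_WINDOW = 700

PEAK_COLUMNS = ["effect", "chrom", "pos", "zscore",
                "segment_start", "segment_end", "rank"]


def local_slope(abs_z: np.ndarray, window: int = DEFAULT_SLOPE_WINDOW) -> np.ndarray:
    """OLS slope of |z| against SNP index in a centered sliding window.

    The window is truncated at the ends of the trace. Computed with
    cumulative sums, O(n). A trace with fewer than 2 points yields an
    empty slope trace (with a warning).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    y = np.asarray(abs_z, float)
    n = len(y)
    if n < 2:
        logger.warning("trace of length %d: empty slope trace", n)
        return np.empty(0)

    half = window // 2
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)        # exclusive

    x = idx.astype(float)
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])

    m = (hi - lo).astype(float)
    sx = cx[hi] - cx[lo]
    sxx = cxx[hi] - cxx[lo]
    sy = cy[hi] - cy[lo]
    sxy = cxy[hi] - cxy[lo]

    denom = m * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (m * sxy - sx * sy) / denom
    slope[denom == 0] = 0.0                    # single-point window
    return slope


def segment_chromosome(slopes: np.ndarray) -> list[tuple[int, int]]:
    """Partition a chromosome trace into segments between local minima.

    A boundary falls at index i when ``slope[i-1] < 0 and slope[i] > 0``
    (strict sign change; zero-slope plateaus do not split). Returns a list
    of half-open (start, stop) index ranges covering the whole trace.
    """
    s = np.asarray(slopes, float)
    n = len(s)
    if n == 0:
        return []
    cuts = np.flatnonzero((s[:-1] < 0) & (s[1:] > 0)) + 1
    bounds = [0, *cuts.tolist(), n]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def call_peaks(trace: pd.DataFrame, thresholds: FdrThresholds | dict, effect: str,
               slope_window: int = DEFAULT_SLOPE_WINDOW,
               top_k: int | None = None) -> pd.DataFrame:
    """Call peaks for one effect from an effect trace.

    Per chromosome: drop non-converged positions, compute the local slope
    of |z|, split into segments at local minima, and emit the per-segment
    maximum of |z| (leftmost on ties) whenever it is at or above the
    effect's threshold. The signed z-score at the maximum is reported;
    ``rank`` orders a chromosome's peaks by decreasing |z| (1 = highest),
    and ``top_k`` keeps only the k highest-ranked peaks per chromosome
    (all segments by default, so shoulder peaks are reported too).

    Returns a DataFrame with columns :data:`PEAK_COLUMNS`; segment bounds
    are in bp of the same chromosome.
    """
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    k = EFFECTS.index(effect)
    thr = thresholds[effect] if not isinstance(thresholds, (int, float)) else thresholds

    records = []
    for chrom, grp in trace.groupby("chrom", sort=False, observed=True):
        grp = grp.sort_values("pos", kind="mergesort")
        if "converged" in grp:
            grp = grp[grp["converged"]]
        z = grp[f"z{k}"].to_numpy(float)
        pos = grp["pos"].to_numpy()
        keep = np.isfinite(z)
        z, pos = z[keep], pos[keep]
        if len(z) == 0:
            continue
        if len(z) < 2:
            segments = [(0, 1)]
        else:
            segments = segment_chromosome(local_slope(np.abs(z), slope_window))
        for start, stop in segments:
            seg_z = np.abs(z[start:stop])
            i = start + int(np.argmax(seg_z))   # argmax takes the leftmost tie
            if np.abs(z[i]) >= thr:
                records.append((effect, chrom, int(pos[i]), float(z[i]),
                                int(pos[start]), int(pos[stop - 1])))

    peaks = pd.DataFrame(records, columns=PEAK_COLUMNS[:-1])
    if peaks.empty:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    peaks["rank"] = (
        peaks.groupby("chrom")["zscore"]
        .transform(lambda v: (-v.abs()).rank(method="first").astype(int))
    )
    if top_k is not None:
        peaks = peaks[peaks["rank"] <= top_k]
    return peaks.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def colocalize_peaks(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame,
                     tol_bp: int = 1500) -> pd.DataFrame:
    """Greedy nearest-neighbor matching of two peak sets per chromosome.

    Pairs are matched in order of increasing bp distance (each peak used at
    most once); a pair with distance <= ``tol_bp`` is flagged colocalized.
    Returns columns chrom, pos_a, pos_b, distance, colocalized.
    """
    records = []
    chroms = set(peaks_a["chrom"]) & set(peaks_b["chrom"]) if len(peaks_a) and len(peaks_b) else set()
    for chrom in sorted(chroms):
        a = peaks_a.loc[peaks_a["chrom"] == chrom, "pos"].to_numpy()
        b = peaks_b.loc[peaks_b["chrom"] == chrom, "pos"].to_numpy()
        dist = np.abs(a[:, None] - b[None, :]).astype(float)
        while np.isfinite(dist).any():
            i, j = np.unravel_index(np.argmin(dist), dist.shape)
            d = dist[i, j]
            records.append((chrom, int(a[i]), int(b[j]), float(d), bool(d <= tol_bp)))
            dist[i, :] = np.inf
            dist[:, j] = np.inf
    return pd.DataFrame(records, columns=["chrom", "pos_a", "pos_b", "distance", "colocalized"])
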