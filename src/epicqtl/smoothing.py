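"""Gaussian-weighted rolling-mean smoothing of parental read counts.

Adjacent SNPs in an F2 cross carry nearly identical information (linkage),
so per-bulk parental read counts are smoothed along each chromosome with a
Gaussian-weighted rolling mean over windows of a fixed number of SNPs
(default 200). Windows live in SNP-index space, never span chromosomes, and
are truncated and renormalized at chromosome ends; smoothing is applied
independently per (selection, background, replicate, chromosome, allele).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 200
GROUP_KEYS = ["selection", "background", "replicate", "chrom"]


def gaussian_weights(window: int, sigma: float) -> np.ndarray:
    """Normalized Gaussian kernel over an odd window of SNP offsets.

    An even ``window`` is widened to the next odd value (with a warning) so
    the kernel has a center. Weights are symmetric, positive, maximal at the
    center, and sum to 1.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if window % 2 == 0:
        logger.warning("even window %d widened to %d", window, window + 1)
        window += 1
    half = window // 2
    d = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (d / sigma) ** 2)
    return w / w.sum()


def _smooth_series(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Truncated-renormalized kernel mean of one per-chromosome series.

    Full convolution sliced at the kernel center handles kernels wider than
    the series (short chromosomes) as well as ordinary edge truncation.
    """
    n = len(values)
    half = len(kernel) // 2
    num = np.convolve(values, kernel, mode="full")[half:half + n]
    den = np.convolve(np.ones(n), kernel, mode="full")[half:half + n]
    return num / den


def smooth_counts(table: pd.DataFrame, window: int = DEFAULT_WINDOW,
                  sigma: float | None = None) -> pd.DataFrame:
    """Smooth oak/wine read counts along each chromosome.

    Parameters
    ----------
    table
        Polarized variant table (columns per ``core_io.VARIANT_COLUMNS``),
        positions sorted ascending within chromosome.
    window
        Window size in SNPs. Chromosomes with fewer SNPs than the window use
        a full-chromosome truncated kernel (logged).
    sigma
        Kernel standard deviation in SNPs. Default ``window / 6``, the
        "±3σ spans the window" convention, so weight effectively vanishes at
        window edges.

    Returns
    -------
    pandas.DataFrame
        Input columns plus ``oak_smooth`` / ``wine_smooth``; each smoothed
        value is bounded by the min and max raw count in its window.
    """
    if sigma is None:
        sigma = window / 6
    kernel = gaussian_weights(window, sigma)

    out = table.sort_values(GROUP_KEYS + ["pos"], kind="mergesort").reset_index(drop=True)
    oak = np.empty(len(out))
    wine = np.empty(len(out))
    short_chroms: set[str] = set()
    for _, idx in out.groupby(GROUP_KEYS, sort=False).indices.items():
        vals_o = out["oak_reads"].to_numpy(float)[idx]
        vals_w = out["wine_reads"].to_numpy(float)[idx]
        if len(idx) < len(kernel):
            short_chroms.add(str(out["chrom"].iloc[idx[0]]))
        oak[idx] = _smooth_series(vals_o, kernel)
        wine[idx] = _smooth_series(vals_w, kernel)
    if short_chroms:
        logger.warning("chromosome(s) shorter than window %d: full-chromosome kernel on %s",
                       window, sorted(short_chroms))
    out["oak_smooth"] = oak
    out["wine_smooth"] = wine
    return out
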