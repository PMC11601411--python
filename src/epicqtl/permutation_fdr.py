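"""Permutation null distribution and FDR thresholds for the genome scan.

The null is built exclusively from unselected bulks, on the assumption that
without selection no locus is associated with the trait. Each permutation
shuffles the position labels of (oak, wine) smoothed-count pairs within each
(background, replicate) unselected series, assigns the shuffled series
randomly to pseudo-bulk slots replicating the original four-bulk design, and
reruns the genome scan; pooled absolute z-scores per effect form the null.
Chromosomes fixed in the experiment — and any chromosomes carrying
engineered, non-segregating regions — are excluded before shuffling.

The per-effect threshold at level ``alpha`` is the empirical
exceedance-ratio construction: the smallest observed |z| value t such that

    (mean per-permutation count of null |z| >= t) / (observed count of |z| >= t)

is at most alpha. A simpler (1 - alpha) null-quantile rule is available
behind ``method="null_quantile"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epicqtl.glm_scan import EFFECTS, scan_genome

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
DEFAULT_ALPHA = 0.05


@dataclass
class NullDistribution:
    """Pooled permutation null of absolute z-scores, per effect."""
    zabs: dict[str, np.ndarray]
    n_perm: int
    seed: int | None
    excluded_chroms: tuple[str, ...]

    def __post_init__(self):
        for effect, arr in self.zabs.items():
            self.zabs[effect] = np.sort(np.asarray(arr, float))


@dataclass
class FdrThresholds:
    """Per-effect absolute-z cutoffs at a given FDR level."""
    q: dict[str, float]
    alpha: float = DEFAULT_ALPHA
    method: str = "exceedance_ratio"
    n_perm: int = 0

    def __getitem__(self, effect: str) -> float:
        return self.q[effect]


def _unselected_series(smoothed: pd.DataFrame, excluded: set[str]):
    """Split unselected rows into per-(background, replicate) position series.

    Each series is a frame sorted by (chrom, pos) carrying the oak/wine
    smoothed pair per position; all series share one position frame.
    """
    un = smoothed[(smoothed["selection"] == 0) & (~smoothed["chrom"].isin(excluded))]
    if un.empty:
        raise ValueError("no unselected rows remain after chromosome exclusion")
    series: dict[tuple[str, int], np.ndarray] = {}
    positions = None
    for (bg, rep), grp in un.groupby(["background", "replicate"], sort=True, observed=True):
        grp = grp.sort_values(["chrom", "pos"], kind="mergesort")
        key_frame = grp[["chrom", "pos"]].reset_index(drop=True)
        if positions is None:
            positions = key_frame
        elif not positions.equals(key_frame):
            raise ValueError("unselected series do not share one position set")
        series[(bg, rep)] = grp[["oak_smooth", "wine_smooth"]].to_numpy()
    return positions, series


def permute_null(smoothed_unselected: pd.DataFrame, excluded: set[str] | None = None,
                 n_perm: int = DEFAULT_N_PERM, seed: int | None = None) -> NullDistribution:
    """Build the permutation null of |z| per effect from unselected bulks.

    Parameters
    ----------
    smoothed_unselected
        Smoothed table; only rows with ``selection == 0`` are used, so the
        full experiment table may be passed.
    excluded
        Chromosomes to drop before shuffling (the fixed chromosome(s) plus
        any engineered chromosomes).
    n_perm
        Number of permuted genome scans pooled into the null.
    seed
        Seed for the shuffles and slot assignment; same seed and inputs give
        a bit-identical null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    excluded = set(excluded or ())
    positions, series = _unselected_series(smoothed_unselected, excluded)
    backgrounds = sorted({bg for bg, _ in series})
    reps_per_bg = {bg: sorted(r for b, r in series if b == bg) for bg in backgrounds}
    for bg, reps in reps_per_bg.items():
        if len(reps) < 2:
            logger.warning("background %s has %d unselected replicate(s); "
                           "pseudo-bulk slots resample the same series with replacement",
                           bg, len(reps))

    rng = np.random.default_rng(seed)
    n_pos = len(positions)
    pooled: dict[str, list[np.ndarray]] = {e: [] for e in EFFECTS}

    base = positions.copy()
    for _ in range(n_perm):
        rows = []
        for bg in backgrounds:
            reps = reps_per_bg[bg]
            # one freshly shuffled series per slot, sources cycling over the
            # observed replicates so slot counts match the original design
            n_slots = 2 * len(reps)
            sources = [reps[i % len(reps)] for i in range(n_slots)]
            shuffled = [series[(bg, src)][rng.permutation(n_pos)] for src in sources]
            order = rng.permutation(n_slots)
            slots = [(sel, rep) for sel in (0, 1) for rep in reps]
            for (sel, rep), which in zip(slots, order):
                counts = shuffled[which]
                frame = base.copy()
                frame["selection"] = sel
                frame["background"] = bg
                frame["replicate"] = rep
                frame["oak_smooth"] = counts[:, 0]
                frame["wine_smooth"] = counts[:, 1]
                rows.append(frame)
        pseudo = pd.concat(rows, ignore_index=True)
        trace = scan_genome(pseudo)
        for k, effect in enumerate(EFFECTS):
            z = trace[f"z{k}"].to_numpy()
            pooled[effect].append(np.abs(z[np.isfinite(z)]))

    zabs = {e: np.concatenate(v) if v else np.array([]) for e, v in pooled.items()}
    return NullDistribution(zabs=zabs, n_perm=n_perm, seed=seed,
                            excluded_chroms=tuple(sorted(excluded)))


def fdr_threshold(trace: pd.DataFrame, null: NullDistribution,
                  alpha: float = DEFAULT_ALPHA,
                  method: str = "exceedance_ratio") -> FdrThresholds:
    """Per-effect absolute-z cutoff controlling the FDR at ``alpha``.

    ``exceedance_ratio`` (default) returns, per effect, the smallest
    observed |z| at which the estimated FDR — mean per-permutation null
    exceedances over observed exceedances — drops to ``alpha`` or below;
    ``numpy.inf`` (no discoveries) if no such value exists.
    ``null_quantile`` returns the (1 - alpha) quantile of the pooled null.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    q: dict[str, float] = {}
    for k, effect in enumerate(EFFECTS):
        null_z = null.zabs.get(effect)
        if null_z is None or len(null_z) == 0:
            raise ValueError(
                f"empty permutation null for effect {effect!r}; increase n_perm")
        if method == "null_quantile":
            q[effect] = float(np.quantile(null_z, 1 - alpha))
            continue
        if method != "exceedance_ratio":
            raise ValueError(f"unknown method {method!r}")
        obs = np.abs(trace[f"z{k}"].to_numpy())
        obs = np.sort(obs[np.isfinite(obs)])
        n_obs = len(obs)
        if n_obs == 0:
            q[effect] = float("inf")
            continue
        # candidates are the observed |z| ascending; counts >= t via searchsorted
        obs_ge = n_obs - np.searchsorted(obs, obs, side="left")  # ties share the left count
        null_ge = len(null_z) - np.searchsorted(null_z, obs, side="left")
        fdr = (null_ge / null.n_perm) / obs_ge
        passing = np.flatnonzero(fdr <= alpha)
        q[effect] = float(obs[passing[0]]) if len(passing) else float("inf")
    return FdrThresholds(q=q, alpha=alpha, method=method, n_perm=null.n_perm)
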