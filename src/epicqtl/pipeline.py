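"""End-to-end orchestration: load/simulate -> smooth -> scan -> FDR -> peaks -> classify.

A run is fully determined by its :class:`RunConfig` (all tunables default to
the analysis' standard values: smoothing window 200 SNPs, slope window 700
SNPs, FDR 5%, permutation exclusions of the fixed and engineered
chromosomes) and its seed; the manifest written alongside the result tables
echoes every parameter, per-stage row counts, non-convergence counts,
thresholds and peak counts, which suffices to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epicqtl import core_io
from epicqtl.glm_scan import EFFECTS, scan_genome, trace_to_long
from epicqtl.smoothing import smooth_counts, DEFAULT_WINDOW
from epicqtl.permutation_fdr import permute_null, fdr_threshold, DEFAULT_ALPHA
from epicqtl.peak_calling import call_peaks, DEFAULT_SLOPE_WINDOW
from epicqtl.epistasis_classify import classify_peaks

logger = logging.getLogger(__name__)

#: chromosomes excluded from the permutation null in the real experiments:
#: the two fixable chromosomes plus the two carrying engineered regions
DEFAULT_EXCLUDE = ("I", "VIII", "III", "V")


@dataclass
class RunConfig:
    """All tunables of one pipeline run."""
    counts_path: str | None = None
    parents_path: str | None = None
    schema: dict | None = None
    fixed_chrom: str = "VIII"
    smoothing_window: int = DEFAULT_WINDOW
    smoothing_sigma: float | None = None
    slope_window: int = DEFAULT_SLOPE_WINDOW
    n_perm: int = 100
    alpha: float = DEFAULT_ALPHA
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE
    fdr_method: str = "exceedance_ratio"
    max_alt_alleles: int = 2
    seed: int | None = None
    out_dir: str = "epicqtl_out"

    @classmethod
    def from_yaml(cls, path: str, overrides: dict | None = None) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides or {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "exclude" in raw and isinstance(raw["exclude"], (list, tuple)):
            raw["exclude"] = tuple(raw["exclude"])
        return cls(**raw)


@dataclass
class RunResult:
    """In-memory bundle of one pipeline run."""
    smoothed: pd.DataFrame
    trace: pd.DataFrame
    thresholds: object
    additive_peaks: pd.DataFrame
    interaction_peaks: pd.DataFrame
    calls: pd.DataFrame
    manifest: dict
    paths: dict = field(default_factory=dict)


def run_epicqtl(config: RunConfig, variant_table: pd.DataFrame | None = None,
                write: bool = True) -> RunResult:
    """Run the full analysis on a loaded (or provided) variant table.

    ``variant_table`` may be passed directly (e.g. straight from the
    simulator); otherwise it is loaded from ``config.counts_path`` /
    ``config.parents_path``. Identical config + seed + input produce an
    identical bundle.
    """
    manifest: dict = {"config": _jsonable(dataclasses.asdict(config)),
                      "version": _version(), "stages": {}}

    if variant_table is None:
        if config.counts_path is None or config.parents_path is None:
            raise ValueError("need counts_path and parents_path (or a variant_table)")
        raw = core_io.read_counts_table(config.counts_path, config.schema)
        manifest["stages"]["load"] = {"rows": len(raw)}
        raw = core_io.filter_biallelic(raw, config.max_alt_alleles)
        manifest["stages"]["filter"] = {"rows": len(raw)}
        parents = pd.read_csv(config.parents_path, sep="\t")
        variant_table = core_io.polarize_alleles(raw, parents)
    manifest["stages"]["variants"] = {"rows": len(variant_table)}

    logger.info("smoothing %d rows (window=%d)", len(variant_table), config.smoothing_window)
    smoothed = smooth_counts(variant_table, config.smoothing_window, config.smoothing_sigma)

    logger.info("scanning genome (fixed chromosome %s excluded)", config.fixed_chrom)
    trace = scan_genome(smoothed, fixed_chroms={config.fixed_chrom})
    manifest["stages"]["scan"] = {
        "positions": len(trace),
        "non_converged": int((~trace["converged"]).sum()),
    }

    logger.info("permutation null: n_perm=%d, excluding %s", config.n_perm, config.exclude)
    null = permute_null(smoothed, set(config.exclude) | {config.fixed_chrom},
                        n_perm=config.n_perm, seed=config.seed)
    thresholds = fdr_threshold(trace, null, alpha=config.alpha, method=config.fdr_method)
    manifest["thresholds"] = {e: thresholds.q[e] for e in EFFECTS}

    additive = call_peaks(trace, thresholds, "Bulk", config.slope_window)
    interaction = call_peaks(trace, thresholds, "Interaction", config.slope_window)
    manifest["peaks"] = {"Bulk": len(additive), "Interaction": len(interaction)}

    calls = classify_peaks(interaction, smoothed, trace, additive)

    paths: dict = {}
    if write:
        long = trace_to_long(trace, config.fixed_chrom, thresholds.q)
        paths = core_io.write_results(long, additive, interaction, calls,
                                      config.out_dir, config.fixed_chrom)
        mpath = os.path.join(config.out_dir, "manifest.json")
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, default=_jsonable)
        paths["manifest.json"] = mpath

    return RunResult(smoothed=smoothed, trace=trace, thresholds=thresholds,
                     additive_peaks=additive, interaction_peaks=interaction,
                     calls=calls, manifest=manifest, paths=paths)


def validate_against_s1(s1_path: str, experiment: str | None = None,
                        slope_window: int = DEFAULT_SLOPE_WINDOW,
                        s2_path: str | None = None,
                        s3_path: str | None = None) -> dict:
    """Call peaks directly from a published-style per-SNP z-score table.

    Bypasses smoothing and the GLM: the table's own z-scores and q5
    thresholds drive segmentation and peak calling per effect. If peak
    tables are supplied, reports per-effect nearest-peak distances against
    them. Returns ``{"peaks": {effect: DataFrame}, "counts": {...},
    "comparison": {...}}``.
    """
    s1 = core_io.read_s1_table(s1_path)
    if experiment is not None:
        s1 = s1[s1["chr"].astype(str) == str(experiment)]
        if s1.empty:
            raise ValueError(f"no rows for experiment chr={experiment!r}")

    out: dict = {"peaks": {}, "counts": {}, "comparison": {}}
    for label in s1["label"].unique():
        sub = s1[s1["label"] == label]
        # adapt to the internal trace shape: a single-effect trace
        k = EFFECTS.index(label) if label in EFFECTS else 0
        trace = pd.DataFrame({
            "chrom": sub["CHROM"].to_numpy(),
            "pos": sub["POS"].to_numpy(),
            f"z{k}": sub["zscore"].to_numpy(),
            "converged": True,
        })
        thr = float(sub["q5"].iloc[0]) if np.isfinite(sub["q5"].iloc[0]) else np.inf
        effect = label if label in EFFECTS else "Bulk"
        peaks = call_peaks(trace, {effect: thr}, effect, slope_window)
        out["peaks"][label] = peaks
        out["counts"][label] = len(peaks)

    from epicqtl.peak_calling import colocalize_peaks
    for label, ref_path in (("Bulk", s2_path), ("Interaction", s3_path)):
        if ref_path and label in out["peaks"]:
            ref = pd.read_csv(ref_path, sep="\t").rename(
                columns={"CHROM": "chrom", "POS": "pos"})
            out["comparison"][label] = colocalize_peaks(out["peaks"][label], ref)
    return out


def _version() -> str:
    from epicqtl import __version__
    return __version__


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
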