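"""Sign vs magnitude classification of interaction QTL.

An interaction peak marks a locus whose selection effect depends on the
fixed chromosome's parent. The interaction is *sign* epistasis when the
selection-induced shift of the Wine-allele frequency points in opposite
directions in the two backgrounds (the selected allele-frequency lines
cross between backgrounds), and *magnitude* epistasis when both shifts
point the same way but differ in size. A zero shift in one background does
not count as a reversal, so it classifies as magnitude (conservative rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epicqtl.glm_scan import EFFECTS
from epicqtl.permutation_fdr import FdrThresholds

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "zscore", "crossing", "dominant_interaction",
                "classification", "nearest_additive_pos", "additive_distance",
                "within_6kb"]


@dataclass
class AFQuartet:
    """Replicate-averaged Wine-allele frequencies in the four bulks."""
    chrom: str
    pos: int
    af: dict  # (background, selection) -> frequency in [0, 1], or NaN
    replicate_af: dict = field(default_factory=dict)  # same keys -> list per replicate

    @property
    def complete(self) -> bool:
        return all(np.isfinite(v) for v in self.af.values())


def allele_freq_quartet(smoothed: pd.DataFrame, chrom, pos) -> AFQuartet:
    """Wine-allele frequency per (background, selection) cell at one position.

    Per cell, the frequency is the mean over replicates of
    ``wine_smooth / (oak_smooth + wine_smooth)``. A replicate with zero
    smoothed depth contributes no value; a cell with no finite replicate is
    reported NaN (classification of that peak is deferred, with a warning).
    """
    here = smoothed[(smoothed["chrom"] == chrom) & (smoothed["pos"] == pos)]
    if here.empty:
        raise KeyError(f"position {chrom}:{pos} not in smoothed table")
    af: dict = {}
    rep_af: dict = {}
    for (bg, sel), cell in here.groupby(["background", "selection"], observed=True):
        tot = (cell["oak_smooth"] + cell["wine_smooth"]).to_numpy(float)
        wine = cell["wine_smooth"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(tot > 0, wine / tot, np.nan)
        frac = frac[np.isfinite(frac)]
        rep_af[(bg, sel)] = frac.tolist()
        af[(bg, sel)] = float(frac.mean()) if len(frac) else float("nan")
    for bg in ("Oak", "Wine"):
        for sel in (0, 1):
            af.setdefault((bg, sel), float("nan"))
    q = AFQuartet(chrom=str(chrom), pos=int(pos), af=af, replicate_af=rep_af)
    if not q.complete:
        logger.warning("zero-depth cell at %s:%s; classification deferred", chrom, pos)
    return q


def crossing_test(q: AFQuartet) -> bool:
    """True iff the within-background selection shifts have opposite signs.

    The shift is AF(selected) - AF(unselected) computed within each fixed
    chromosome background; strictly opposite signs mean the selected
    allele-frequency lines cross between backgrounds (sign epistasis).
    Unchanged under relabeling the backgrounds.
    """
    d_oak = q.af[("Oak", 1)] - q.af[("Oak", 0)]
    d_wine = q.af[("Wine", 1)] - q.af[("Wine", 0)]
    return bool(d_oak * d_wine < 0)


def dominance_scan(trace: pd.DataFrame, thresholds: FdrThresholds | dict) -> pd.DataFrame:
    """Positions where the interaction dominates the additive effect.

    Returns rows of ``trace`` with |z_interaction| at or above the
    interaction FDR threshold AND |z_interaction| > |z_selection|. On an
    architecture whose interactions only modulate effect size, this set is
    expected to be empty at well-estimated positions.
    """
    k_sel = EFFECTS.index("Bulk")
    k_int = EFFECTS.index("Interaction")
    thr = thresholds["Interaction"]
    z_int = trace[f"z{k_int}"].abs()
    z_sel = trace[f"z{k_sel}"].abs()
    mask = (z_int >= thr) & (z_int > z_sel)
    return trace[mask.fillna(False)].reset_index(drop=True)


def classify_peaks(interaction_peaks: pd.DataFrame, smoothed: pd.DataFrame,
                   trace: pd.DataFrame, additive_peaks: pd.DataFrame) -> pd.DataFrame:
    """Classify each interaction peak as sign or magnitude epistasis.

    Per peak: the allele-frequency quartet and crossing test decide the
    sign/magnitude label; ``dominant_interaction`` records whether
    |z_interaction| exceeds |z_selection| at the peak position; the nearest
    additive peak on the same chromosome gives the bp distance and the
    within-6-kb flag (no additive peak on the chromosome -> distance NaN,
    flag False). Peaks with an incomplete quartet get a null classification.

    Returns a DataFrame with columns :data:`CALL_COLUMNS`.
    """
    k_sel = EFFECTS.index("Bulk")
    k_int = EFFECTS.index("Interaction")
    zmap = trace.set_index(["chrom", "pos"])

    records = []
    for _, pk in interaction_peaks.iterrows():
        chrom, pos = pk["chrom"], pk["pos"]
        q = allele_freq_quartet(smoothed, chrom, pos)
        if q.complete:
            crossing = crossing_test(q)
            classification = "sign" if crossing else "magnitude"
        else:
            crossing, classification = None, None

        try:
            row = zmap.loc[(chrom, pos)]
            dominant = bool(abs(row[f"z{k_int}"]) > abs(row[f"z{k_sel}"]))
        except KeyError:
            dominant = None

        add_here = additive_peaks[additive_peaks["chrom"] == chrom] if len(additive_peaks) else additive_peaks
        if len(add_here):
            dists = (add_here["pos"] - pos).abs()
            j = dists.idxmin()
            nearest, distance = int(add_here.loc[j, "pos"]), float(dists.loc[j])
            within = bool(distance <= 6000)
        else:
            nearest, distance, within = None, float("nan"), False

        records.append((chrom, pos, pk["zscore"], crossing, dominant,
                        classification, nearest, distance, within))
    return pd.DataFrame(records, columns=CALL_COLUMNS)
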