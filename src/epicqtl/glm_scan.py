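"""Position-wise logistic regression of parental allele odds.

At each smoothed position the log-odds of the Wine allele are modeled as

    log(odds_Wine) = b0 + b1*selection + b2*background + b3*(selection x background)

with selection coded 0 (no copper) / 1 (copper) and background coded
-0.5 (Wine fixed chromosome) / +0.5 (Oak fixed chromosome). b1 is the
additive (selection) effect, b3 the selection-by-background interaction,
i.e. epistasis with the fixed chromosome. Smoothed counts act as binomial
weights on the observed Wine fraction (dispersion fixed at 1), and effects
are summarized by z = beta / se from the Fisher information.

The four-cell design with four coefficients is saturated, so the maximum
likelihood fit has a closed form: fitted cell probabilities equal the
count-weighted empirical Wine fractions, beta = X^-1 logit(p_cell), and
Cov(beta) = X^-1 W^-1 X^-T with W the binomial information weights. Pooling
replicates within a cell is exact here (binomial sufficiency): it yields the
same estimates and standard errors as treating each replicate as its own
observation. The closed form is vectorized across all positions at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit

#: effect labels, in coefficient order, matching the per-SNP output table
EFFECTS = ["Intercept", "Bulk", "Background", "Interaction"]

#: background contrast codes
BACKGROUND_CODE = {"Wine": -0.5, "Oak": 0.5}

# cell order: (selection, background) = (0, Wine), (0, Oak), (1, Wine), (1, Oak)
_CELLS = [(0, "Wine"), (0, "Oak"), (1, "Wine"), (1, "Oak")]
_X = np.array([[1.0, s, BACKGROUND_CODE[b], s * BACKGROUND_CODE[b]] for s, b in _CELLS])
_XINV = np.linalg.inv(_X)


@dataclass
class PositionFit:
    """Coefficients, standard errors and z-scores at one position."""
    chrom: str
    pos: int
    beta: np.ndarray   # (4,) log-odds scale, order per EFFECTS
    se: np.ndarray     # (4,)
    z: np.ndarray      # (4,) beta / se; NaN when not converged
    converged: bool


def _fit_cells(wine: np.ndarray, total: np.ndarray):
    """Closed-form saturated binomial-logit fit for (n, 4) cell counts.

    Returns (beta, se, z, converged), each (n, 4) / (n,). A position fails
    to converge (separation or empty cell) when any cell has zero total or a
    Wine fraction of exactly 0 or 1; its z-scores are NaN.
    """
    wine = np.asarray(wine, float)
    total = np.asarray(total, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = wine / total
    ok = (total > 0).all(axis=1) & (p > 0).all(axis=1) & (p < 1).all(axis=1)

    p_safe = np.where(ok[:, None], p, 0.5)
    t_safe = np.where(ok[:, None], total, 1.0)
    eta = logit(p_safe)
    beta = eta @ _XINV.T
    # Cov = Xinv diag(1/w) Xinv^T, w_c = n_c p_c (1 - p_c)
    w = t_safe * p_safe * (1.0 - p_safe)
    var = (1.0 / w) @ (_XINV ** 2).T
    se = np.sqrt(var)
    z = beta / se
    beta[~ok] = np.nan
    se[~ok] = np.nan
    z[~ok] = np.nan
    return beta, se, z, ok


def _cell_totals(obs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pool one position's per-replicate observations into the 4 cells."""
    wine = np.zeros(4)
    total = np.zeros(4)
    for i, (s, b) in enumerate(_CELLS):
        cell = obs[(obs["selection"] == s) & (obs["background"] == b)]
        if cell.empty:
            raise ValueError(f"no observation for cell (selection={s}, background={b})")
        wine[i] = cell["wine_smooth"].sum()
        total[i] = (cell["oak_smooth"] + cell["wine_smooth"]).sum()
    return wine, total


def fit_position(observations: pd.DataFrame) -> PositionFit:
    """Fit the four-coefficient logistic model at a single position.

    ``observations`` holds one row per (bulk, replicate) with columns
    selection, background, oak_smooth, wine_smooth; all four
    selection x background cells must be present.
    """
    wine, total = _cell_totals(observations)
    beta, se, z, ok = _fit_cells(wine[None, :], total[None, :])
    chrom = str(observations["chrom"].iloc[0]) if "chrom" in observations else ""
    pos = int(observations["pos"].iloc[0]) if "pos" in observations else -1
    return PositionFit(chrom, pos, beta[0], se[0], z[0], bool(ok[0]))


def scan_genome(smoothed: pd.DataFrame, fixed_chroms: set[str] | None = None) -> pd.DataFrame:
    """Fit the logistic model at every smoothed position.

    Parameters
    ----------
    smoothed
        Output of :func:`epicqtl.smoothing.smooth_counts`.
    fixed_chroms
        Chromosomes fixed in the experiment; excluded from the scan (their
        allele odds are degenerate by construction).

    Returns
    -------
    pandas.DataFrame
        Effect trace: one row per position with columns chrom, pos,
        snp_index, beta0..beta3, se0..se3, z0..z3, converged. Coefficient
        order follows :data:`EFFECTS`.
    """
    df = smoothed
    if fixed_chroms:
        df = df[~df["chrom"].isin(set(fixed_chroms))]

    # pivot to (position, cell) pooled counts
    df = df.assign(total_smooth=df["oak_smooth"] + df["wine_smooth"])
    g = df.groupby(["chrom", "pos", "selection", "background"], sort=False, observed=True)[
        ["wine_smooth", "total_smooth"]].sum().reset_index()
    wide_w = g.pivot_table(index=["chrom", "pos"], columns=["selection", "background"],
                           values="wine_smooth", sort=False)
    wide_t = g.pivot_table(index=["chrom", "pos"], columns=["selection", "background"],
                           values="total_smooth", sort=False)
    try:
        wide_w = wide_w[_CELLS]
        wide_t = wide_t[_CELLS]
    except KeyError as err:
        raise ValueError("all four selection x background cells are required") from err

    beta, se, z, ok = _fit_cells(wide_w.to_numpy(), wide_t.to_numpy())

    trace = wide_w.index.to_frame(index=False)
    for k in range(4):
        trace[f"beta{k}"] = beta[:, k]
        trace[f"se{k}"] = se[:, k]
        trace[f"z{k}"] = z[:, k]
    trace["converged"] = ok
    trace = trace.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    from epicqtl.core_io import assign_snp_index
    trace["snp_index"] = assign_snp_index(trace)
    return trace


def trace_to_long(trace: pd.DataFrame, fixed_chrom: str = "",
                  thresholds: dict[str, float] | None = None) -> pd.DataFrame:
    """Reshape an effect trace to the long per-SNP table.

    Columns: label (effect), chr (fixed chromosome of the experiment),
    CHROM, POS, zscore, q5 (the effect's FDR threshold, NaN if not given).
    """
    frames = []
    for k, label in enumerate(EFFECTS):
        q5 = thresholds.get(label, np.nan) if thresholds else np.nan
        frames.append(pd.DataFrame({
            "label": label,
            "chr": fixed_chrom,
            "CHROM": trace["chrom"],
            "POS": trace["pos"],
            "zscore": trace[f"z{k}"],
            "q5": q5,
        }))
    return pd.concat(frames, ignore_index=True)
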