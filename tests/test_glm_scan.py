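import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from epicqtl.glm_scan import EFFECTS, fit_position, scan_genome, trace_to_long
from conftest import make_observations
from oracles import irls_logistic_fit


def _quad(af_by_cell, depth=70, reps=2):
    """Cells {(bg, sel): af} -> observations with wine = af*depth, oak = rest."""
    cells = {}
    for key, af in af_by_cell.items():
        cells[key] = [(depth * (1 - af), depth * af)] * reps
    return make_observations(cells)


def test_identical_counts_give_zero_effects():
    obs = make_observations({(bg, s): [(35, 35)] * 2 for bg in ("Oak", "Wine") for s in (0, 1)})
    fit = fit_position(obs)
    np.testing.assert_allclose(fit.beta, 0.0, atol=1e-12)
    np.testing.assert_allclose(fit.z, 0.0, atol=1e-12)
    assert fit.converged


def test_uniform_selection_shift_loads_only_on_selection_term():
    obs = make_observations({
        ("Oak", 0): [(35, 35)] * 2, ("Wine", 0): [(35, 35)] * 2,
        ("Oak", 1): [(28, 42)] * 2, ("Wine", 1): [(28, 42)] * 2,
    })
    fit = fit_position(obs)
    assert fit.beta[1] == pytest.approx(np.log(1.5), abs=1e-9)   # logit(.6) - logit(.5)
    np.testing.assert_allclose([fit.beta[0], fit.beta[2], fit.beta[3]], 0.0, atol=1e-9)


def test_background_dependent_shift_solves_cell_logit_system():
    obs = make_observations({
        ("Oak", 0): [(35, 35)] * 2, ("Wine", 0): [(35, 35)] * 2,
        ("Oak", 1): [(14, 56)] * 2,   # AF 0.8
        ("Wine", 1): [(28, 42)] * 2,  # AF 0.6
    })
    fit = fit_position(obs)
    assert fit.beta[0] == pytest.approx(0.0, abs=1e-9)
    assert fit.beta[2] == pytest.approx(0.0, abs=1e-9)
    assert fit.beta[1] == pytest.approx((logit(0.8) + logit(0.6)) / 2, abs=1e-6)  # ~0.8959
    assert fit.beta[3] == pytest.approx(logit(0.8) - logit(0.6), abs=1e-6)        # ~0.9808


@pytest.mark.parametrize("trial", range(4))
def test_matches_independent_irls_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    cells = {(bg, s): [(rng.uniform(20, 90), rng.uniform(20, 90)) for _ in range(2)]
             for bg in ("Oak", "Wine") for s in (0, 1)}
    obs = make_observations(cells)
    fit = fit_position(obs)
    beta, se = irls_logistic_fit(obs)
    np.testing.assert_allclose(fit.beta, beta, atol=1e-6)
    np.testing.assert_allclose(fit.se, se, atol=1e-5)


def test_background_relabel_flips_background_terms_only():
    rng = np.random.default_rng(8)
    cells = {(bg, s): [(rng.uniform(20, 90), rng.uniform(20, 90))]
             for bg in ("Oak", "Wine") for s in (0, 1)}
    obs = make_observations(cells)
    swapped = obs.assign(background=obs["background"].map({"Oak": "Wine", "Wine": "Oak"}))
    a, b = fit_position(obs), fit_position(swapped)
    np.testing.assert_allclose(a.beta[[0, 1]], b.beta[[0, 1]], atol=1e-10)
    np.testing.assert_allclose(a.beta[[2, 3]], -b.beta[[2, 3]], atol=1e-10)


def test_doubling_counts_scales_z_by_sqrt2():
    rng = np.random.default_rng(9)
    cells = {(bg, s): [(rng.uniform(20, 90), rng.uniform(20, 90))]
             for bg in ("Oak", "Wine") for s in (0, 1)}
    obs = make_observations(cells)
    doubled = obs.assign(oak_smooth=obs["oak_smooth"] * 2, wine_smooth=obs["wine_smooth"] * 2)
    a, b = fit_position(obs), fit_position(doubled)
    np.testing.assert_allclose(b.beta, a.beta, atol=1e-10)
    np.testing.assert_allclose(b.z, a.z * np.sqrt(2), rtol=1e-10)


def test_single_replicate_fit_is_saturated():
    rng = np.random.default_rng(10)
    cells = {(bg, s): [(rng.uniform(20, 90), rng.uniform(20, 90))]
             for bg in ("Oak", "Wine") for s in (0, 1)}
    obs = make_observations(cells)
    fit = fit_position(obs)
    X = np.array([[1, s, {"Wine": -0.5, "Oak": 0.5}[bg], s * {"Wine": -0.5, "Oak": 0.5}[bg]]
                  for _, row in obs.iterrows()
                  for s, bg in [(row["selection"], row["background"])]])
    fitted = expit(X @ fit.beta)
    empirical = (obs["wine_smooth"] / (obs["oak_smooth"] + obs["wine_smooth"])).to_numpy()
    np.testing.assert_allclose(fitted, empirical, atol=1e-8)


def test_zero_depth_cell_flags_non_convergence():
    cells = {(bg, s): [(35, 35)] for bg in ("Oak", "Wine") for s in (0, 1)}
    cells[("Oak", 1)] = [(0, 0)]
    fit = fit_position(make_observations(cells))
    assert not fit.converged and np.isnan(fit.z).all()


def _toy_smoothed(n_snps=30, seed=2, chroms=("I", "II")):
    rng = np.random.default_rng(seed)
    frames = []
    for chrom in chroms:
        for bg in ("Oak", "Wine"):
            for s in (0, 1):
                for rep in (1, 2):
                    frames.append(pd.DataFrame({
                        "chrom": chrom, "pos": np.arange(1, n_snps + 1) * 100,
                        "selection": s, "background": bg, "replicate": rep,
                        "oak_smooth": rng.uniform(20, 90, n_snps),
                        "wine_smooth": rng.uniform(20, 90, n_snps),
                    }))
    return pd.concat(frames, ignore_index=True)


def test_scan_genome_equals_looped_position_fits():
    smoothed = _toy_smoothed(n_snps=50, chroms=("I",))
    trace = scan_genome(smoothed)
    assert len(trace) == 50
    for pos in (100, 2500, 5000):
        obs = smoothed[smoothed["pos"] == pos]
        fit = fit_position(obs)
        row = trace[trace["pos"] == pos].iloc[0]
        np.testing.assert_allclose([row[f"beta{k}"] for k in range(4)], fit.beta, atol=1e-12)
        np.testing.assert_allclose([row[f"z{k}"] for k in range(4)], fit.z, atol=1e-12)


def test_scan_genome_excludes_fixed_chromosome():
    smoothed = _toy_smoothed()
    trace = scan_genome(smoothed, fixed_chroms={"II"})
    assert set(trace["chrom"]) == {"I"}


def test_trace_to_long_matches_published_table_shape():
    trace = scan_genome(_toy_smoothed(n_snps=5, chroms=("I",)))
    long = trace_to_long(trace, fixed_chrom="VIII", thresholds={"Bulk": 3.0})
    assert list(long.columns) == ["label", "chr", "CHROM", "POS", "zscore", "q5"]
    assert set(long["label"]) == set(EFFECTS)
    assert len(long) == 4 * 5
    bulk = long[long["label"] == "Bulk"]
    assert (bulk["q5"] == 3.0).all()
    np.testing.assert_allclose(bulk["zscore"].to_numpy(), trace["z1"].to_numpy())
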