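import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import binomtest

from epicqtl import synthetic_data as sim


def _genome(n_chrom=2, chrom_bp=20_000, morgans=1.0, seed=0, mode="grid"):
    cfg = sim.SimConfig(n_chrom=n_chrom, chrom_bp=chrom_bp, morgans=morgans,
                        snp_mode=mode, seed=seed)
    return cfg, sim.make_genome(cfg, np.random.default_rng(seed))


class TestGenome:
    def test_snp_counting(self):
        _, g = _genome(n_chrom=2, chrom_bp=20_000)
        assert g.n_snps == 200   # 100 per chromosome at 1/200 bp

    def test_grid_positions(self):
        cfg = sim.SimConfig(n_chrom=1, chrom_bp=10_000, snp_density=1 / 1000)
        g = sim.make_genome(cfg)
        assert g.snp_positions["I"].tolist() == list(range(1000, 10_001, 1000))

    def test_uniform_density_within_binomial_bounds(self):
        cfg = sim.SimConfig(n_chrom=1, chrom_bp=20_000, snp_mode="uniform", seed=5)
        g = sim.make_genome(cfg)
        n = len(g.snp_positions["I"])
        ci = binomtest(n, 20_000, 1 / 200).proportion_ci(0.999)
        assert ci.low <= 1 / 200 <= ci.high

    def test_positions_strictly_increasing_required(self):
        with pytest.raises(ValueError):
            sim.GenomeMap(chrom_ids=["I"], lengths_bp={"I": 100},
                          lengths_morgan={"I": 1.0},
                          snp_positions={"I": np.array([5, 5, 10])})


class TestSegregants:
    def test_fixed_chromosome_is_uniform(self):
        _, g = _genome()
        genos = sim.simulate_segregants(g, "I", "Wine", 200, rng=1)
        assert (genos["I"] == 1).all()
        genos = sim.simulate_segregants(g, "I", "Oak", 200, rng=1)
        assert (genos["I"] == 0).all()

    def test_mendelian_segregation_at_half(self):
        _, g = _genome()
        genos = sim.simulate_segregants(g, "I", "Oak", 10_000, rng=2)
        freq = genos["II"].mean(axis=0)
        ci = binomtest(int(freq[50] * 10_000), 10_000, 0.5).proportion_ci(0.999)
        assert ci.low <= 0.5 <= ci.high

    def test_haldane_recombinant_fraction(self):
        # two SNPs 0.5 Morgans apart: r = (1 - e^-1) / 2 ~ 0.316
        g = sim.GenomeMap(chrom_ids=["I", "II"],
                          lengths_bp={"I": 1000, "II": 10_000},
                          lengths_morgan={"I": 0.1, "II": 1.0},
                          snp_positions={"I": np.array([500]),
                                         "II": np.array([2500, 7500])})
        genos = sim.simulate_segregants(g, "I", "Oak", 20_000, rng=3)
        rec = (genos["II"][:, 0] != genos["II"][:, 1]).mean()
        expected = (1 - np.exp(-1)) / 2
        assert rec == pytest.approx(expected, abs=0.02)

    def test_expected_crossovers_equal_morgan_length(self):
        _, g = _genome(n_chrom=2, morgans=1.5)
        _, xo = sim.simulate_segregants(g, "I", "Oak", 10_000, rng=4,
                                        return_crossovers=True)
        assert xo["II"].mean() == pytest.approx(1.5, abs=0.05)


class TestSurvival:
    def test_no_qtl_baseline(self):
        _, g = _genome()
        genos = sim.simulate_segregants(g, "I", "Oak", 100, rng=5)
        model = sim.QTLModel(mu=float(logit(0.05)), fixed_chrom="I")
        p = sim.survival_probability(genos, model, "Oak", g)
        np.testing.assert_allclose(p, 0.05, atol=1e-12)

    def test_additive_carrier_survival_closed_form(self):
        _, g = _genome()
        genos = sim.simulate_segregants(g, "I", "Oak", 500, rng=6)
        pos = int(g.snp_positions["II"][10])
        model = sim.QTLModel(mu=float(logit(0.05)), fixed_chrom="I",
                             additive=[("II", pos, 2.0)])
        p = sim.survival_probability(genos, model, "Oak", g)
        carriers = genos["II"][:, 10] == 1
        np.testing.assert_allclose(p[carriers], expit(logit(0.05) + 2.0), atol=1e-12)
        np.testing.assert_allclose(p[~carriers], 0.05, atol=1e-12)

    def test_interaction_logit_gap_equals_gamma(self):
        _, g = _genome()
        genos = sim.simulate_segregants(g, "I", "Oak", 500, rng=7)
        pos = int(g.snp_positions["II"][0])
        model = sim.QTLModel(mu=float(logit(0.05)), fixed_chrom="I",
                             interaction=[("II", pos, 3.0)])
        p_oak = sim.survival_probability(genos, model, "Oak", g)
        p_wine = sim.survival_probability(genos, model, "Wine", g)
        carriers = genos["II"][:, 0] == 1
        gap = logit(p_oak[carriers]) - logit(p_wine[carriers])
        np.testing.assert_allclose(gap, 3.0, atol=1e-10)

    def test_interaction_on_fixed_chromosome_rejected(self):
        _, g = _genome()
        model = sim.QTLModel(fixed_chrom="I",
                             interaction=[("I", int(g.snp_positions["I"][0]), 1.0)])
        with pytest.raises(ValueError):
            model.validate(g)


class TestBulks:
    def test_certain_survival_makes_bulks_identical(self):
        cfg, g = _genome()
        genos = sim.simulate_segregants(g, "I", "Oak", 300, rng=8)
        bulks = sim.make_bulks(genos, np.ones(300), cfg, rng=9)
        np.testing.assert_array_equal(bulks[(1, 1)]["II"], bulks[(0, 1)]["II"])

    def test_realized_survival_tracks_mean_probability(self):
        cfg, g = _genome()
        n = 5000
        genos = sim.simulate_segregants(g, "I", "Oak", n, rng=10)
        probs = np.full(n, 0.07)
        bulks = sim.make_bulks(genos, probs, cfg, rng=11)
        frac = bulks[(1, 1, "n")] / n
        ci = binomtest(bulks[(1, 1, "n")], n, 0.07).proportion_ci(0.999)
        assert ci.low <= 0.07 <= ci.high and 0 < frac < 1

    def test_strong_additive_qtl_shifts_selected_af_up_in_both_backgrounds(self):
        _, model = sim.additive_scenario(seed=21, effect=2.0)
        cfg = sim.SimConfig(seed=21, n_segregants=4000)
        table, truth, genome = sim.generate_experiment(cfg, model)
        at = table[(table["chrom"] == "XII") & (table["pos"] == 30_000)]
        for bg in ("Oak", "Wine"):
            sel = at[(at["background"] == bg) & (at["selection"] == 1)]
            uns = at[(at["background"] == bg) & (at["selection"] == 0)]
            af_sel = sel["wine_reads"].sum() / (sel["wine_reads"] + sel["oak_reads"]).sum()
            af_uns = uns["wine_reads"].sum() / (uns["wine_reads"] + uns["oak_reads"]).sum()
            assert af_sel > af_uns

    def test_zero_survivors_raises(self):
        cfg, g = _genome()
        genos = sim.simulate_segregants(g, "I", "Oak", 50, rng=12)
        with pytest.raises(ValueError, match="survivors"):
            sim.make_bulks(genos, np.zeros(50), cfg, rng=13)


class TestSequencing:
    def test_fixed_frequencies_yield_pure_reads(self):
        cfg, g = _genome(n_chrom=1)
        freqs = {(0, 1): {"I": np.ones(100)}, (1, 1): {"I": np.ones(100)}}
        table = sim.sequence_bulks(freqs, g, "Wine", cfg, rng=14)
        assert (table["oak_reads"] == 0).all()

    def test_mean_fraction_near_half_at_depth_70(self):
        cfg, g = _genome(n_chrom=1, chrom_bp=100_000)
        freqs = {(0, 1): {"I": np.full(500, 0.5)}}
        table = sim.sequence_bulks(freqs, g, "Oak", cfg, rng=15)
        frac = table["wine_reads"].sum() / (table["wine_reads"] + table["oak_reads"]).sum()
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_zero_depth_flows_through_scan_as_non_converged(self):
        from epicqtl.glm_scan import scan_genome
        cfg = sim.SimConfig(n_chrom=2, chrom_bp=2000, depth=0.0, n_segregants=100,
                            seed=16)
        model = sim.QTLModel(fixed_chrom="I")
        table, _, _ = sim.generate_experiment(cfg, model)
        assert (table[["oak_reads", "wine_reads"]] == 0).all().all()
        sm = table.assign(oak_smooth=0.0, wine_smooth=0.0)
        trace = scan_genome(sm, {"I"})
        assert (~trace["converged"]).all()


class TestExperiment:
    def test_same_seed_bit_identical(self):
        cfg, model = sim.null_scenario(seed=33)
        cfg = sim.SimConfig(n_chrom=3, chrom_bp=6000, n_segregants=500, seed=33)
        t1, _, _ = sim.generate_experiment(cfg, sim.QTLModel(fixed_chrom="I"))
        t2, _, _ = sim.generate_experiment(cfg, sim.QTLModel(fixed_chrom="I"))
        pd.testing.assert_frame_equal(t1, t2)

    def test_fixed_chromosome_af_is_pure_per_background(self):
        cfg = sim.SimConfig(n_chrom=2, chrom_bp=4000, n_segregants=300, seed=34)
        table, _, _ = sim.generate_experiment(cfg, sim.QTLModel(fixed_chrom="II"))
        on_fixed = table[table["chrom"] == "II"]
        wine_bg = on_fixed[on_fixed["background"] == "Wine"]
        oak_bg = on_fixed[on_fixed["background"] == "Oak"]
        assert (wine_bg["oak_reads"] == 0).all()
        assert (oak_bg["wine_reads"] == 0).all()

    def test_dose_calibration_hits_target_survival(self):
        cfg, model = sim.magnitude_scenario(seed=35)
        cfg = sim.SimConfig(seed=35, n_segregants=8000)
        table, truth, _ = sim.generate_experiment(cfg, model)
        for frac in truth.realized_survival.values():
            assert frac == pytest.approx(0.05, abs=0.02)

    def test_truth_serializes(self):
        cfg = sim.SimConfig(n_chrom=2, chrom_bp=4000, n_segregants=200, seed=36)
        _, truth, _ = sim.generate_experiment(cfg, sim.QTLModel(fixed_chrom="I"))
        import json
        d = json.loads(truth.to_json())
        assert d["fixed_chrom"] == "I" and "realized_survival" in d
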