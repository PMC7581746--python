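import numpy as np
import pandas as pd
import pytest

import tracheidgwas as tg
from tracheidgwas.simulate import ConfigurationError, spline_value


class TestConfigValidation:
    def test_qtl_exceeding_markers_rejected(self):
        cfg = tg.SimulationConfig(n_markers=5, n_qtl=6)
        with pytest.raises(ConfigurationError, match="n_qtl"):
            cfg.validate()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("maf_range", (0.0, 0.5)),
            ("maf_range", (0.1, 0.6)),
            ("knots", (9, 3)),
            ("sigma2_F", -0.1),
            ("missing_rate", 1.0),
            ("n_families", 0),
        ],
    )
    def test_invalid_fields_rejected(self, field, value):
        cfg = tg.SimulationConfig(**{field: value})
        with pytest.raises(ConfigurationError):
            cfg.validate()

    def test_qtl_on_unknown_trait_rejected(self):
        cfg = tg.SimulationConfig(
            qtl_effects=(tg.QtlEffect(marker=0, trait="nope", a=0.1),)
        )
        with pytest.raises(ConfigurationError, match="unknown trait"):
            cfg.validate()


class TestGenotypes:
    def test_hardy_weinberg_at_half(self):
        """At allele frequency 0.5 genotype classes approach 1/4, 1/2, 1/4."""
        cfg = tg.SimulationConfig(
            n_families=3000,
            trees_per_family=2,
            n_markers=2,
            n_qtl=0,
            maf_range=(0.5, 0.5),
            missing_rate=0.0,
            seed=77,
        )
        geno = tg.simulate_genotypes(cfg)
        n = geno.n_trees
        # within-family genotype correlation inflates the binomial SE by < 1.5x
        for j in range(geno.n_markers):
            for g, expected in [(0, 0.25), (1, 0.5), (2, 0.25)]:
                phat = (geno.codes[:, j] == g).mean()
                se = np.sqrt(1.5 * expected * (1 - expected) / n)
                assert abs(phat - expected) < 3 * se

    def test_no_missing_when_rate_zero(self):
        cfg = tg.SimulationConfig(n_families=20, n_markers=50, missing_rate=0.0, seed=2)
        geno = tg.simulate_genotypes(cfg)
        assert (geno.codes != tg.MISSING).all()

    def test_seed_determinism(self, small_cfg):
        a = tg.simulate_genotypes(small_cfg)
        b = tg.simulate_genotypes(small_cfg)
        assert np.array_equal(a.codes, b.codes)
        assert a.meta.equals(b.meta)

    def test_marginal_maf_tracks_drawn_frequency(self):
        cfg = tg.SimulationConfig(
            n_families=1500, trees_per_family=2, n_markers=40, n_qtl=0,
            maf_range=(0.1, 0.5), missing_rate=0.0, seed=5,
        )
        geno = tg.simulate_genotypes(cfg)
        drawn = geno.attrs["true_freqs"]
        observed = geno.codes.mean(axis=0) / 2.0
        se = np.sqrt(1.5 * drawn * (1 - drawn) / (2 * geno.n_trees))
        assert (np.abs(observed - drawn) < 4 * se).all()


class TestPhenotypes:
    def test_degenerate_config_gives_exact_population_spline(self):
        cfg = tg.SimulationConfig(
            n_families=5, trees_per_family=4, n_markers=10, n_qtl=0,
            sigma2_F=0.0, sigma2_SF=0.0, sigma2_e=0.0, noise_sd=0.0,
            site_effects=(0.0, 0.0), block_effect_sd=0.0,
            missing_rate=0.0, seed=3,
        )
        design = tg.simulate_design(cfg)
        geno = tg.simulate_genotypes(cfg)
        rings, _ = tg.simulate_phenotypes(cfg, geno, design)
        means = cfg.spline_means["TWr_Ring"]
        for age, grp in rings.groupby("cambial_age"):
            expected = spline_value(means, age, cfg.knots)
            assert np.allclose(grp["value"], expected, atol=1e-12)

    def test_single_additive_qtl_separates_homozygotes_by_2a(self):
        a = 0.6
        cfg = tg.SimulationConfig(
            n_families=2000, trees_per_family=2, n_markers=5, missing_rate=0.0,
            qtl_effects=(tg.QtlEffect(marker=2, trait="TWr_Ring", a=a, d=0.0),),
            maf_range=(0.4, 0.5), seed=11,
        )
        design = tg.simulate_design(cfg)
        geno = tg.simulate_genotypes(cfg)
        _, truth = tg.simulate_phenotypes(cfg, geno, design)
        lat = truth["latent_traits"]
        x = geno.codes[:, 2]
        b0 = lat["beta0"].to_numpy()
        diff = b0[x == 2].mean() - b0[x == 0].mean()
        assert diff == pytest.approx(2 * a, abs=0.08)

    def test_slope_before_first_knot_is_beta1(self):
        cfg = tg.SimulationConfig(
            n_families=4, trees_per_family=2, n_markers=5, n_qtl=0,
            sigma2_F=0.0, sigma2_SF=0.0, sigma2_e=0.0, noise_sd=0.0,
            site_effects=(0.0, 0.0), block_effect_sd=0.0, missing_rate=0.0,
            knots=(5, 9), seed=4,
        )
        design = tg.simulate_design(cfg)
        geno = tg.simulate_genotypes(cfg)
        rings, _ = tg.simulate_phenotypes(cfg, geno, design)
        one = rings[rings["tree_id"] == rings["tree_id"].iloc[0]].sort_values("cambial_age")
        early = one[one["cambial_age"] <= 5]
        slopes = np.diff(early["value"]) / np.diff(early["cambial_age"])
        assert np.allclose(slopes, cfg.spline_means["TWr_Ring"][1], atol=1e-12)

    def test_variance_decomposition_moment_oracle(self):
        """Cross-site family covariance ~ sigma2_F, within-site extra ~ sigma2_SF,
        within-cell variance ~ sigma2_e (+ measurement noise)."""
        cfg = tg.SimulationConfig(
            n_families=400, trees_per_family=8, n_markers=5, n_qtl=0,
            sigma2_F=0.30, sigma2_SF=0.15, sigma2_e=0.80, noise_sd=0.0,
            site_effects=(0.0, 0.0), block_effect_sd=0.0, missing_rate=0.0,
            seed=21,
        )
        design = tg.simulate_design(cfg)
        geno = tg.simulate_genotypes(cfg)
        rings, _ = tg.simulate_phenotypes(cfg, geno, design)
        age5 = rings[rings["cambial_age"] == 5].merge(design, on="tree_id")
        cell = age5.groupby(["family", "site"])["value"]
        # residual: pooled within (site, family) cell variance
        s2e_hat = cell.var().mean()
        # family: covariance of a family's cell means across the two sites
        wide = cell.mean().unstack("site")
        s2f_hat = wide.cov().iloc[0, 1]
        # family + interaction: variance of cell means minus residual share
        n_cell = cell.size().mean()
        s2fsf_hat = wide.stack().var() - s2e_hat / n_cell
        assert s2e_hat == pytest.approx(0.80, rel=0.10)
        assert s2f_hat == pytest.approx(0.30, rel=0.25)
        assert s2fsf_hat - s2f_hat == pytest.approx(0.15, abs=0.06)

    def test_truth_latents_cover_all_trees(self, small_dataset):
        lat = small_dataset["truth"]["latent_traits"]
        assert set(lat["tree_id"]) == set(small_dataset["design"]["tree_id"])


class TestMfaSeries:
    def test_noise_free_crossing_matches_analytic_inversion(self):
        cfg = tg.SimulationConfig(
            n_families=10, trees_per_family=2, mfa_noise_sd=0.0,
            mfa_pith_sd=0.0, mfa_plateau_sd=0.0, mfa_rate_sd=0.0,
            mfa_pith=30.0, mfa_plateau=10.0, mfa_decay_rate=0.35,
            n_rings=20, knots=(4, 9), seed=6,
        )
        rings, truth = tg.simulate_mfa_series(cfg)
        expected = 1.0 + np.log((30 - 10) / (20 - 10)) / 0.35
        assert np.allclose(truth["crossing_age"], expected)
        one = rings[rings["tree_id"] == rings["tree_id"].iloc[0]]
        vals = one.sort_values("cambial_age")["value"].to_numpy()
        # curve decays monotonically from the pith
        assert (np.diff(vals) < 0).all()
        assert vals[0] == pytest.approx(30.0)

    def test_population_mean_pith_near_thirty_degrees(self):
        cfg = tg.SimulationConfig(n_families=200, trees_per_family=2, seed=8)
        rings, truth = tg.simulate_mfa_series(cfg)
        first = rings[rings["cambial_age"] == 1]["value"]
        assert first.mean() == pytest.approx(30.0, abs=3 * 2.2 / np.sqrt(len(first)) + 0.5)

    def test_plateau_above_threshold_flags_no_crossing(self):
        cfg = tg.SimulationConfig(
            n_families=5, trees_per_family=2, mfa_plateau=25.0,
            mfa_plateau_sd=0.0, mfa_pith=32.0, mfa_pith_sd=0.0, seed=9,
        )
        _, truth = tg.simulate_mfa_series(cfg)
        assert truth["crossing_age"].isna().all()

    def test_determinism(self):
        cfg = tg.SimulationConfig(n_families=5, trees_per_family=2, seed=10)
        r1, t1 = tg.simulate_mfa_series(cfg)
        r2, t2 = tg.simulate_mfa_series(cfg)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1, t2)
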