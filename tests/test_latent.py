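import numpy as np
import pytest

import tracheidgwas as tg
from tracheidgwas.latent import (
    fit_linear_spline,
    latent_table,
    mfa_latent_table,
    mfa_latents,
    select_knots,
    spline_basis,
)


class TestSplineBasis:
    def test_truncation_vanishes_at_knot(self):
        B = spline_basis(np.array([1.0, 3.0, 5.0, 10.0]), (3, 7))
        assert B[1, 2] == 0.0  # (t - K1)+ at t = K1

    def test_truncated_column_arithmetic(self):
        B = spline_basis(np.arange(1, 11), (3, 7))
        assert B[4, 2] == 2.0  # t=5: (5-3)+ = 2
        assert B[4, 3] == 0.0

    def test_full_rank_with_points_in_every_segment(self):
        B = spline_basis(np.arange(1, 16), (4, 9))
        assert np.linalg.matrix_rank(B) == 4

    def test_knots_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            spline_basis(np.arange(1, 10), (0, 5))


class TestFitLinearSpline:
    def test_exact_recovery_on_noise_free_data(self):
        ages = np.arange(1, 16)
        true = np.array([10.0, 1.5, -0.8, 0.3])
        y = spline_basis(ages, (4, 9)) @ true
        fit = fit_linear_spline(ages, y, (4, 9))
        assert np.allclose(fit.betas, true, atol=1e-10)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)

    def test_equals_normal_equations_on_random_data(self):
        rng = np.random.default_rng(1)
        ages = np.arange(1, 16)
        y = rng.normal(size=len(ages))
        B = spline_basis(ages, (4, 9))
        expected = np.linalg.solve(B.T @ B, B.T @ y)
        fit = fit_linear_spline(ages, y, (4, 9))
        assert np.allclose(fit.betas, expected, atol=1e-10)

    def test_no_points_beyond_second_knot_flagged(self):
        ages = np.arange(1, 9)  # K2 = 8 is the maximum age: (t-8)+ = 0 always
        y = ages * 1.0
        fit = fit_linear_spline(ages, y, (3, 8))
        assert fit.rank_deficient
        assert np.isnan(fit.beta3)
        assert fit.beta1 == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4 points"):
            fit_linear_spline([1, 2, 3], [1.0, 2.0, 3.0], (1.5, 2.5))


class TestSelectKnots:
    def _trajs(self, knots, n=20, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ages = np.arange(1, 16)
        B = spline_basis(ages, knots)
        out = []
        for _ in range(n):
            betas = np.array([10, 1.5, -0.8, 0.3]) + rng.normal(0, 0.3, 4)
            out.append((ages, B @ betas + rng.normal(0, noise, len(ages))))
        return out

    def test_recovers_generating_knots_at_low_noise(self):
        trajs = self._trajs((4, 9), noise=0.05, seed=3)
        grid = [(a, b) for a in range(2, 12) for b in range(a + 2, 14)]
        assert select_knots(trajs, grid) == (4, 9)

    def test_single_pair_grid_returned(self):
        trajs = self._trajs((4, 9))
        assert select_knots(trajs, [(5, 10)]) == (5, 10)

    def test_tie_breaks_to_smaller_pair(self):
        # constant trajectories: every knot pair fits exactly, SSE tied at 0
        ages = np.arange(1, 16)
        trajs = [(ages, np.full(len(ages), 7.0))]
        assert select_knots(trajs, [(4, 9), (3, 8), (3, 10)]) == (3, 8)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_knots(self._trajs((4, 9)), [])

    def test_sse_non_increasing_under_grid_refinement(self):
        trajs = self._trajs((4, 9), noise=0.2, seed=5)

        def total_sse(grid):
            k = select_knots(trajs, grid)
            return sum(fit_linear_spline(a, v, k).sse for a, v in trajs)

        coarse = [(3, 10)]
        finer = coarse + [(4, 9), (5, 8)]
        finest = finer + [(4, 10), (3, 9), (4, 8), (5, 9)]
        assert total_sse(finer) <= total_sse(coarse) + 1e-12
        assert total_sse(finest) <= total_sse(finer) + 1e-12


class TestMfaLatents:
    def test_hand_series_crossing_between_rings_two_and_three(self):
        """Series 30,25,19,12,11: the fitted decay crosses 20 degrees between
        ages 2 and 3; core/outer means split the observed values there."""
        lat = mfa_latents([1, 2, 3, 4, 5], [30, 25, 19, 12, 11])
        assert lat.crossed
        assert 2 < lat.mfa_ta < 3
        assert lat.mfa_core == pytest.approx(np.mean([30, 25]))
        assert lat.mfa_outer == pytest.approx(np.mean([19, 12, 11]))

    def test_all_below_threshold_gives_first_age(self):
        lat = mfa_latents([1, 2, 3, 4], [15, 14, 12, 11])
        assert lat.crossed
        assert lat.mfa_ta == 1.0
        assert lat.mfa_core == pytest.approx(15.0)

    def test_all_above_threshold_flags_uncrossed(self):
        lat = mfa_latents([1, 2, 3, 4, 5], [35, 33, 30, 29, 28])
        assert not lat.crossed
        assert np.isnan(lat.mfa_ta)

    def test_core_mean_at_least_outer_mean_for_decaying_series(self):
        rng = np.random.default_rng(2)
        ages = np.arange(1, 16)
        for _ in range(10):
            vals = 30 * np.exp(-0.3 * (ages - 1)) + 10 + rng.normal(0, 0.3, len(ages))
            lat = mfa_latents(ages, vals)
            if lat.crossed and not np.isnan(lat.mfa_outer):
                assert lat.mfa_core >= lat.mfa_outer

    def test_transition_age_recovery_on_noise_free_curves(self):
        """MAE of recovered transition age < 1 ring against the analytic truth."""
        cfg = tg.SimulationConfig(
            n_families=25, trees_per_family=2, mfa_noise_sd=0.0,
            mfa_plateau=11.0, mfa_plateau_sd=0.8, mfa_pith_sd=2.0,
            n_rings=20, knots=(4, 9), seed=13,
        )
        rings, truth = tg.simulate_mfa_series(cfg)
        table = mfa_latent_table(rings)
        merged = table.merge(truth, on="tree_id")
        ok = merged["crossed"] & merged["crossing_age"].notna()
        mae = (merged.loc[ok, "mfa_ta"] - merged.loc[ok, "crossing_age"]).abs().mean()
        assert ok.sum() > 20
        assert mae < 1.0

    def test_mad_screen_discards_spike(self):
        ages = np.arange(1, 13)
        vals = 28.0 * np.exp(-0.35 * (ages - 1)) + 11.0
        spiked = vals.copy()
        spiked[5] += 25.0
        clean = mfa_latents(ages, vals, mad_screen=4.0)
        screened = mfa_latents(ages, spiked, mad_screen=4.0)
        unscreened = mfa_latents(ages, spiked, mad_screen=None)
        assert abs(screened.mfa_ta - clean.mfa_ta) < abs(unscreened.mfa_ta - clean.mfa_ta) + 1e-9


class TestLatentTable:
    def test_family_rows_and_columns(self, small_dataset):
        refined = tg.refine_trajectories(
            small_dataset["rings"], small_dataset["design"], "TWr_Ring"
        )
        table = latent_table(refined.table, small_dataset["cfg"].knots)
        assert len(table) == small_dataset["design"]["family"].nunique()
        assert {"beta0", "beta1", "beta2", "beta3", "sse"} <= set(table.columns)
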