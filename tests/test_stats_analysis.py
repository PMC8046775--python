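"""Statistical layer: strength, Bayesian regressions, GPR, summaries."""

import numpy as np
import pandas as pd
import pytest

from openpref.stats_analysis import (GPRResult, PolynomialDesign,
                                     bayesian_ttest, divergence_windows,
                                     effect_sizes, fit_gpr, fit_polynomial,
                                     preference_strength, running_average)


def strength_frame(t, y, condition="no_choice", participant=None):
    return pd.DataFrame({
        "participant": participant if participant is not None
        else [f"p{i % 20}" for i in range(len(t))],
        "condition": condition, "delay_s": t,
        "rating": np.round(y).astype(int), "scale_max": 30.0,
    })


class TestPreferenceStrength:
    def test_absolute_value_of_signed_ratings(self):
        df = strength_frame([3, 3, 6], [-30, 0, 7])
        out = preference_strength(df)
        assert list(out["strength"]) == [30.0, 0.0, 7.0]

    def test_out_of_scale_rating_rejected(self):
        df = strength_frame([3], [31])
        with pytest.raises(ValueError, match="exceed"):
            preference_strength(df)


class TestPolynomialDesign:
    def test_columns_are_sd_standardized(self):
        t = np.array([3.0, 6.0, 9.0, 18.0, 30.0, 45.0])
        X = PolynomialDesign(time_points=t, order=5).matrix()
        assert X.shape == (6, 6)
        for m in range(1, 6):
            np.testing.assert_allclose(X[:, m], t ** m / np.std(t ** m))

    def test_raw_coefficients_recovered_by_dividing(self):
        """A coefficient on the standardized column equals the raw-scale
        coefficient multiplied by SD(t^m); dividing recovers it."""
        rng = np.random.default_rng(0)
        t = np.repeat([3.0, 6.0, 9.0, 18.0, 30.0, 45.0], 40)
        raw_b = np.array([17.0, 0.2, -0.01])
        y = raw_b[0] + raw_b[1] * t + raw_b[2] * t ** 2 \
            + rng.normal(0, 0.05, len(t))
        data = preference_strength(strength_frame(t, np.zeros_like(t)))
        data["strength"] = y
        post = fit_polynomial(data, "no_choice", order=2, seed=1)
        sds = PolynomialDesign(time_points=t, order=2).column_sds()
        for m, sd in zip((1, 2), sds):
            assert post[f"b{m}"]["mean"] / sd == pytest.approx(
                raw_b[m], rel=0.1)


class TestFitPolynomial:
    def test_recovers_cubic_and_rejects_higher_orders(self):
        """Data simulated from an exact cubic: the cubic HDI excludes zero
        while the quartic and quintic HDIs include it."""
        rng = np.random.default_rng(2)
        t = np.repeat(np.array([3, 6, 9, 14, 20, 27, 35, 45], dtype=float), 60)
        tc = (t - t.mean()) / 10
        y = 17 + 2.0 * tc ** 3 + rng.normal(0, 0.8, len(t))
        data = preference_strength(strength_frame(t, np.zeros_like(t)))
        data["strength"] = y
        post = fit_polynomial(data, "no_choice", order=5, seed=3)
        lo, hi = post["b3"]["hdi95"]
        assert lo > 0 or hi < 0, "cubic effect should be credible"
        for m in (4, 5):
            lo, hi = post[f"b{m}"]["hdi95"]
            assert lo <= 0 <= hi, f"b{m} HDI should include zero"

    def test_duplicated_conditions_centre_difference_at_zero(self):
        rng = np.random.default_rng(4)
        t = np.repeat([3.0, 6.0, 9.0, 18.0, 30.0, 45.0], 50)
        y = 17 + rng.normal(0, 2.0, len(t))
        nc = preference_strength(strength_frame(t, np.zeros_like(t)))
        nc["strength"] = y
        ch = nc.copy()
        ch["condition"] = "choice"
        both = pd.concat([nc, ch], ignore_index=True)
        diff = fit_polynomial(both, None, order=5, seed=5)
        lo, hi = diff["diff_b0"]["hdi95"]
        assert lo <= 0 <= hi

    def test_too_few_delays_rejected(self):
        data = preference_strength(
            strength_frame([3.0, 6.0, 9.0] * 10, np.zeros(30)))
        with pytest.raises(ValueError, match="distinct delays"):
            fit_polynomial(data, "no_choice", order=5)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(6)
        t = np.repeat([3.0, 6.0, 9.0, 18.0, 30.0, 45.0], 20)
        data = preference_strength(strength_frame(t, np.zeros_like(t)))
        data["strength"] = 15 + rng.normal(0, 3, len(t))
        a = fit_polynomial(data, "no_choice", seed=11)
        b = fit_polynomial(data, "no_choice", seed=11)
        np.testing.assert_array_equal(a.draws, b.draws)


class TestBayesianTTest:
    def test_identical_samples_contain_zero(self):
        x = np.r_[np.linspace(10, 20, 40)]
        post = bayesian_ttest(x, x.copy(), seed=1)
        lo, hi = post["mean_diff"]["hdi95"]
        assert lo <= 0 <= hi

    def test_clear_shift_detected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(20, 1, 400)
        post = bayesian_ttest(x + 5, x, seed=2)
        assert post["mean_diff"]["mean"] == pytest.approx(5.0, abs=0.3)
        lo, hi = post["mean_diff"]["hdi95"]
        assert lo > 0

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(8)
        x = rng.normal(16, 2, 100)
        y = rng.normal(18, 2, 100)
        a = bayesian_ttest(x, y, seed=3)
        b = bayesian_ttest(y, x, seed=3)
        assert a["mean_diff"]["mean"] == pytest.approx(
            -b["mean_diff"]["mean"], abs=0.15)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            bayesian_ttest([1.0], [2.0, 3.0])


def make_gpr_data(fn, noise, seed, n_per=50,
                  delays=(3.0, 6.0, 9.0, 18.0, 30.0, 45.0)):
    rng = np.random.default_rng(seed)
    t = np.repeat(np.asarray(delays), n_per)
    participants = np.tile([f"p{i}" for i in range(n_per)], len(delays))
    y = fn(t) + rng.normal(0, noise, len(t))
    df = pd.DataFrame({
        "participant": participants, "condition": "no_choice",
        "delay_s": t, "rating": 0, "scale_max": 30.0})
    df = preference_strength(df)
    df["strength"] = y
    return df


class TestGPR:
    def test_near_zero_noise_interpolates_the_means(self):
        data = make_gpr_data(lambda t: 17 + 2 * np.sin(t / 5), 1e-6, 9)
        res = fit_gpr(data, "no_choice", lengthscale=4.0)
        for d in (3.0, 18.0, 45.0):
            obs = data.loc[data["delay_s"] == d, "strength"].mean()
            k = np.argmin(np.abs(res.grid - d))
            assert res.mean_fn[k] == pytest.approx(obs, abs=1e-3)

    def test_band_contains_mean_everywhere(self):
        data = make_gpr_data(lambda t: 17 + 2 * np.sin(t / 5), 2.0, 10)
        res = fit_gpr(data, "no_choice")
        assert (res.band95[:, 0] <= res.mean_fn + 1e-12).all()
        assert (res.band95[:, 1] >= res.mean_fn - 1e-12).all()

    def test_smaller_noise_never_widens_band(self):
        data = make_gpr_data(lambda t: 17 + 2 * np.sin(t / 5), 2.0, 11)
        wide = fit_gpr(data, "no_choice", lengthscale=5.0)
        data2 = data.copy()
        narrow = fit_gpr(data2, "no_choice", lengthscale=5.0)
        # shrink the noise by hand through the per-delay SEM rule: rescale
        # strengths toward their per-delay means
        m = data2.groupby("delay_s")["strength"].transform("mean")
        data2["strength"] = m + 0.3 * (data2["strength"] - m)
        narrow = fit_gpr(data2, "no_choice", lengthscale=5.0)
        width_wide = wide.band95[:, 1] - wide.band95[:, 0]
        width_narrow = narrow.band95[:, 1] - narrow.band95[:, 0]
        assert (width_narrow <= width_wide + 1e-9).all()

    def test_window_noise_rule_runs_on_continuous_delays(self):
        rng = np.random.default_rng(12)
        t = rng.uniform(2, 50, 600)
        data = make_gpr_data(lambda t: 6 + np.sin(t / 6), 1.0, 13,
                             n_per=1, delays=[3.0])
        data = data.iloc[:0]
        df = pd.DataFrame({
            "participant": [f"p{i % 30}" for i in range(len(t))],
            "condition": "no_choice", "delay_s": t, "rating": 0,
            "scale_max": 10.0})
        df = preference_strength(df)
        df["strength"] = 6 + np.sin(t / 6) + rng.normal(0, 1.0, len(t))
        res = fit_gpr(df, "no_choice", noise_rule="window10s_max_sem",
                      bin_width=1.0)
        assert res.noise_sd > 0
        assert len(res.grid) > 20


class TestDivergenceAndEffects:
    def grid_result(self, mean, half_width, condition):
        g = np.arange(0, 10.0, 0.5)
        mean = np.full_like(g, mean) if np.isscalar(mean) else mean
        band = np.column_stack([mean - half_width, mean + half_width])
        return GPRResult(grid=g, mean_fn=mean, band95=band,
                         lengthscale=1, amplitude=1, noise_sd=1,
                         condition=condition)

    def test_identical_results_produce_no_windows(self):
        a = self.grid_result(17.0, 1.0, "choice")
        b = self.grid_result(17.0, 1.0, "no_choice")
        assert divergence_windows(a, b) == []

    def test_everywhere_above_band_is_one_bolstering_window(self):
        a = self.grid_result(19.5, 1.0, "choice")
        b = self.grid_result(17.0, 1.0, "no_choice")
        wins = divergence_windows(a, b)
        assert len(wins) == 1
        assert wins[0]["direction"] == "bolstering"
        assert wins[0]["start_s"] == 0.0 and wins[0]["end_s"] == 9.5

    def test_out_of_phase_oscillations_alternate_directions(self):
        g = np.arange(0, 10.0, 0.5)
        a = self.grid_result(17 + 2 * np.sin(g), 0.5, "choice")
        b = self.grid_result(17 - 2 * np.sin(g), 0.5, "no_choice")
        wins = divergence_windows(a, b)
        dirs = [w["direction"] for w in wins]
        assert "bolstering" in dirs and "suppression" in dirs

    def test_effect_sizes_scale_with_rating_sd(self):
        a = self.grid_result(19.0, 1.0, "choice")
        b = self.grid_result(17.0, 1.0, "no_choice")
        eff = effect_sizes(a, b, sd_ratings=2.0)
        assert eff["between_max_d"] == pytest.approx(1.0)
        assert eff["within_range_d_choice"] == 0.0
        with pytest.raises(ValueError):
            effect_sizes(a, b, sd_ratings=0.0)


class TestRunningAverage:
    def test_constant_data_stays_constant(self):
        data = make_gpr_data(lambda t: np.full_like(t, 9.0), 0.0, 14)
        traj = running_average(data, "no_choice")
        assert np.allclose(traj.strength[np.isfinite(traj.strength)], 9.0)

    def test_single_observation_plateaus(self):
        df = preference_strength(strength_frame([10.0], [12]))
        traj = running_average(df, grid=np.arange(0, 20.0))
        inside = np.abs(traj.delay - 10.0) <= 3.0
        assert np.allclose(traj.strength[inside], 12.0)
        assert np.isnan(traj.strength[~inside]).all()

    def test_wide_window_converges_to_grand_mean(self):
        rng = np.random.default_rng(15)
        t = rng.uniform(2, 50, 300)
        df = preference_strength(
            strength_frame(t, rng.integers(-30, 31, len(t))))
        traj = running_average(df, half_window=100.0,
                               grid=np.array([10.0, 30.0]))
        assert np.allclose(traj.strength, df["strength"].mean())
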