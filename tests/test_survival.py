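import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from melrad.survival import (
    cox_fit,
    km_estimate,
    logrank_test,
    multivariable_screen,
    one_year_status,
)


class TestKaplanMeier:
    def test_all_events_equals_empirical_survival(self):
        c = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_survival_stays_one(self):
        c = km_estimate([1, 2, 3], [0, 0, 0])
        assert np.all(c.survival == 1.0)

    def test_mixed_censoring_matches_hand_computed_table(self):
        # risk sets: t=1 (n=5,d=1), t=3 (n=3,d=1), t=4 (n=2,d=1)
        c = km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 1, 0])
        np.testing.assert_allclose(c.times, [1, 3, 4])
        np.testing.assert_allclose(c.survival, [0.8, 0.8 * 2 / 3, 0.8 * 2 / 3 * 0.5])
        np.testing.assert_array_equal(c.at_risk, [5, 3, 2])
        # Greenwood at t=1: S^2 * d/(n(n-d)) = 0.64 * 1/20
        assert c.variance[0] == pytest.approx(0.64 / 20)

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        c = km_estimate(t, e)
        assert np.all(c.ci_lower <= c.survival + 1e-9)
        assert np.all(c.survival <= c.ci_upper + 1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_statistic_near_zero(self):
        t = np.arange(1, 21, dtype=float)
        e = np.ones(20, int)
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(5, 30), rng.exponential(10, 25)
        ea, eb = np.ones(30, int), np.ones(25, int)
        c1, p1 = logrank_test(ta, ea, tb, eb)
        c2, p2 = logrank_test(tb, eb, ta, ea)
        assert c1 == pytest.approx(c2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_power_against_fourfold_rate_ratio(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(1.0, 50)
            tb = rng.exponential(4.0, 50)
            _, p = logrank_test(ta, np.ones(50), tb, np.ones(50))
            if p < 0.01:
                rejections += 1
        assert rejections >= 19

    def test_no_events_flagged(self):
        with pytest.warns(UserWarning, match="no events"):
            chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert np.isnan(chi2)

    def test_chi_square_p_agrees_with_permutation_oracle(self):
        """On a small sample, the asymptotic p must sit within Monte-Carlo
        error of a label-permutation p for the same statistic."""
        rng = np.random.default_rng(7)
        n = 30
        times = np.round(rng.exponential(5, n), 2) + 0.01
        events = np.ones(n, int)
        group = np.array([0] * 15 + [1] * 15)

        def chi2_stat(g):
            o_minus_e, var = 0.0, 0.0
            for t in np.unique(times[events == 1]):
                at_risk = times >= t
                d = float(((times == t) & (events == 1)).sum())
                n_t = float(at_risk.sum())
                n1 = float((at_risk & (g == 1)).sum())
                o1 = float(((times == t) & (events == 1) & (g == 1)).sum())
                o_minus_e += o1 - d * n1 / n_t
                if n_t > 1:
                    var += d * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d) / (n_t - 1)
            return o_minus_e**2 / var

        observed = chi2_stat(group)
        chi2, p = logrank_test(
            times[group == 0], events[group == 0],
            times[group == 1], events[group == 1],
        )
        assert chi2 == pytest.approx(observed, rel=1e-6)
        perm = np.array([
            chi2_stat(rng.permutation(group)) for _ in range(10_000)
        ])
        p_perm = (perm >= observed - 1e-12).mean()
        assert abs(p - p_perm) < 0.03


class TestCox:
    def test_binary_covariate_matches_partial_likelihood_oracle(self):
        times = np.array([1.0, 2, 3, 4, 5, 6])
        events = np.ones(6, int)
        x = np.array([1.0, 0, 1, 0, 1, 0])

        def neg_pl(b):
            ll = 0.0
            for i in range(6):
                risk = times >= times[i]
                ll += b * x[i] - np.log(np.exp(b * x[risk]).sum())
            return -ll

        oracle = minimize_scalar(
            neg_pl, bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-12},
        ).x
        fit = cox_fit(
            pd.DataFrame({"t": times, "e": events, "x": x}), "t", "e", ["x"]
        )
        assert fit.summary.loc["x", "coef"] == pytest.approx(oracle, abs=1e-6)
        assert fit.hazard_ratio("x") == pytest.approx(np.exp(oracle), rel=1e-6)

    def test_covariate_rescaling_rescales_coefficient(self):
        rng = np.random.default_rng(3)
        n = 80
        x = rng.standard_normal(n)
        t = rng.exponential(np.exp(-0.7 * x))
        df = pd.DataFrame({"t": t, "e": np.ones(n, int), "x": x})
        f1 = cox_fit(df, "t", "e", ["x"])
        df["x"] = 10.0 * x
        f2 = cox_fit(df, "t", "e", ["x"])
        assert f2.summary.loc["x", "coef"] == pytest.approx(
            f1.summary.loc["x", "coef"] / 10.0, rel=1e-4
        )

    def test_simulated_hazard_ratio_recovered(self):
        hrs = []
        for seed in range(50):
            rng = np.random.default_rng(500 + seed)
            x = rng.integers(0, 2, 95)
            lam = 0.05 * np.exp(np.log(2.7) * x)
            t = rng.exponential(1 / lam)
            horizon = 18.0
            e = (t <= horizon).astype(int)
            tt = np.minimum(t, horizon)
            fit = cox_fit(
                pd.DataFrame({"t": tt, "e": e, "x": x}), "t", "e", ["x"]
            )
            hrs.append(fit.hazard_ratio("x"))
        assert abs(np.mean(hrs) - 2.7) / 2.7 < 0.15

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"t": [1.0, 2, 3], "e": [1, 1, 1], "x": [1, 1, 1]})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, "t", "e", ["x"])

    def test_separation_falls_back_to_penalized_fit(self):
        # covariate perfectly orders the event times: monotone likelihood
        df = pd.DataFrame({
            "t": [1.0, 2, 3, 10, 11, 12],
            "e": [1, 1, 1, 1, 1, 1],
            "x": [1.0, 1, 1, 0, 0, 0],
        })
        with pytest.warns(UserWarning, match="penalizer"):
            fit = cox_fit(df, "t", "e", ["x"])
        assert fit.penalizer > 0
        assert np.isfinite(fit.hazard_ratio("x"))


class TestMultivariableScreen:
    def test_weak_single_covariate_gives_empty_multivariable(self):
        rng = np.random.default_rng(4)
        n = 60
        df = pd.DataFrame({
            "t": rng.exponential(5, n),
            "e": np.ones(n, int),
            "x": rng.integers(0, 2, n),
        })
        res = multivariable_screen(df, "t", "e", ["x"], p_enter=1e-6)
        assert res["entered"] == []
        assert res["multivariable"] is None

    def test_two_strong_covariates_enter_and_keep_sign(self):
        rng = np.random.default_rng(5)
        n = 150
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        t = rng.exponential(np.exp(-(1.0 * a + 1.0 * b)))
        df = pd.DataFrame({"t": t, "e": np.ones(n, int), "a": a, "b": b})
        res = multivariable_screen(df, "t", "e", ["a", "b"], p_enter=0.2)
        assert res["entered"] == ["a", "b"]
        multi = res["multivariable"].summary
        assert multi.loc["a", "coef"] > 0
        assert multi.loc["b", "coef"] > 0

    def test_screen_decision_reproducible_from_univariable_p(self):
        rng = np.random.default_rng(6)
        n = 80
        df = pd.DataFrame({
            "t": rng.exponential(5, n), "e": np.ones(n, int),
            "a": rng.integers(0, 2, n), "b": rng.integers(0, 2, n),
        })
        res = multivariable_screen(df, "t", "e", ["a", "b"], p_enter=0.2)
        expect = [c for c in ("a", "b") if res["univariable"].loc[c, "p"] < 0.2]
        assert res["entered"] == expect


def test_one_year_status_inclusive_cutoff():
    status = one_year_status([11.9, 12.0, 12.1, 5.0], [1, 1, 1, 0])
    np.testing.assert_array_equal(status, [1, 1, 0, 0])
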