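"""Trajectory-mixture likelihood, EM fitting, BIC selection, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import gwgtraj as g
from gwgtraj import gbtm
from gwgtraj.gbtm import (
    GBTMSpec,
    adequacy_diagnostics,
    fit_gbtm,
    loglikelihood,
    select_model,
    simulate_mixture_trajectories,
    trajectory_slopes,
)


def brute_force_loglik(data, pi, beta, sigma):
    """Direct enumeration of sum_i log sum_j pi_j prod_t phi(...)."""
    beta = np.atleast_2d(beta)
    J = beta.shape[0]
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float).ravel(), (J,))
    total = 0.0
    for _, grp in data.groupby("id"):
        t, y = grp["time"].to_numpy(), grp["y"].to_numpy()
        mix = 0.0
        for j in range(J):
            mu = sum(beta[j, p] * t**p for p in range(beta.shape[1]))
            mix += pi[j] * np.prod(norm.pdf(y, mu, sigma[j]))
        total += np.log(mix)
    return total


@pytest.fixture(scope="module")
def three_group_data():
    pi = (0.583, 0.324, 0.093)
    beta = np.array([[57.0, 0.42], [71.0, 0.46], [96.0, 0.35]])
    long, truth = simulate_mixture_trajectories(
        pi, beta, sigma=1.5, n_subjects=2000, times=(0, 10, 22, 34), seed=77
    )
    return long, truth, pi, beta


class TestLoglikelihood:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(5):  # 5 subjects x 3 timepoints
            for t in (0.0, 15.0, 30.0):
                rows.append({"id": f"s{i}", "time": t, "y": 60 + 0.4 * t + rng.normal()})
        data = pd.DataFrame(rows)
        pi = (0.5, 0.3, 0.2)
        beta = np.array([[58, 0.35], [63, 0.40], [80, 0.30]])
        sigma = (1.0, 2.0, 1.5)
        assert loglikelihood(data, pi, beta, sigma) == pytest.approx(
            brute_force_loglik(data, pi, beta, sigma), abs=1e-10
        )

    def test_single_group_equals_gaussian_regression_loglik(self):
        rng = np.random.default_rng(8)
        t = np.tile([0, 10, 20, 30.0], 20)
        ids = np.repeat([f"s{i}" for i in range(20)], 4)
        y = 55 + 0.5 * t + rng.normal(0, 2, t.size)
        data = pd.DataFrame({"id": ids, "time": t, "y": y})
        beta = np.array([[55.0, 0.5]])
        direct = norm.logpdf(y, 55 + 0.5 * t, 2.0).sum()
        assert loglikelihood(data, [1.0], beta, 2.0) == pytest.approx(direct, rel=1e-12)

    def test_identical_groups_collapse_to_one(self):
        rng = np.random.default_rng(9)
        data = pd.DataFrame({
            "id": np.repeat([f"s{i}" for i in range(10)], 3),
            "time": np.tile([5, 15, 25.0], 10),
            "y": rng.normal(70, 3, 30),
        })
        beta = np.array([[70.0, 0.0]])
        one = loglikelihood(data, [1.0], beta, 3.0)
        for pi in ([0.5, 0.5], [0.9, 0.1]):
            two = loglikelihood(data, pi, np.vstack([beta, beta]), 3.0)
            assert two == pytest.approx(one, rel=1e-12)

    def test_rejects_bad_sigma_and_empty_data(self):
        data = pd.DataFrame({"id": ["a"], "time": [1.0], "y": [2.0]})
        with pytest.raises(ValueError):
            loglikelihood(data, [1.0], [[1.0, 0.0]], 0.0)
        with pytest.raises(ValueError):
            loglikelihood(data.iloc[:0], [1.0], [[1.0, 0.0]], 1.0)


class TestFitGBTM:
    def test_single_group_equals_polynomial_ols(self):
        rng = np.random.default_rng(3)
        t = np.tile(np.arange(0, 40, 5, dtype=float), 40)
        ids = np.repeat([f"s{i}" for i in range(40)], 8)
        y = 60 + 0.45 * t + rng.normal(0, 1.3, t.size)
        data = pd.DataFrame({"id": ids, "time": t, "y": y})
        fit = fit_gbtm(data, GBTMSpec(J=1, order=1), n_starts=1, seed=0)
        X = np.stack([np.ones_like(t), t], axis=1)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta[0], beta_ols, rtol=1e-8)
        sigma_ml = np.sqrt(np.mean((y - X @ beta_ols) ** 2))
        assert fit.sigma[0] == pytest.approx(sigma_ml, rel=1e-6)

    def test_parameter_recovery_three_groups(self, three_group_data):
        long, truth, pi_true, beta_true = three_group_data
        fit = fit_gbtm(long, GBTMSpec(J=3, order=1), n_starts=4, seed=1)
        realized = np.bincount(truth, minlength=3) / len(truth)
        for j in range(3):
            assert fit.pi[j] == pytest.approx(realized[j], abs=0.03)
            assert fit.beta[j, 0] == pytest.approx(beta_true[j, 0], abs=0.5)

    def test_em_loglik_monotone(self, three_group_data):
        long, *_ = three_group_data
        fit = fit_gbtm(long, GBTMSpec(J=3, order=1), n_starts=2, seed=4)
        assert np.all(np.diff(fit.loglik_history) >= -1e-7 * abs(fit.loglik))

    def test_determinism_under_seed(self, three_group_data):
        long, *_ = three_group_data
        a = fit_gbtm(long, GBTMSpec(J=3), n_starts=3, seed=9)
        b = fit_gbtm(long, GBTMSpec(J=3), n_starts=3, seed=9)
        np.testing.assert_array_equal(a.posterior, b.posterior)
        assert a.loglik == b.loglik

    def test_posterior_rows_sum_to_one(self, three_group_data):
        long, *_ = three_group_data
        fit = fit_gbtm(long, GBTMSpec(J=3), n_starts=2, seed=2)
        np.testing.assert_allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(fit.assignment, fit.posterior.argmax(axis=1))

    def test_canonical_ordering_by_midgestation_mean(self, three_group_data):
        long, *_ = three_group_data
        fit = fit_gbtm(long, GBTMSpec(J=3), n_starts=2, seed=2)
        at20 = fit.mean_curve(np.array([20.0])).ravel()
        assert np.all(np.diff(at20) > 0)

    def test_label_permutation_leaves_loglik_unchanged(self, three_group_data):
        long, *_ = three_group_data
        fit = fit_gbtm(long, GBTMSpec(J=3), n_starts=2, seed=2)
        perm = [2, 0, 1]
        ll = loglikelihood(long, fit.pi[perm], fit.beta[perm], fit.sigma[0])
        assert ll == pytest.approx(fit.loglik, rel=1e-12)

    def test_polish_does_not_worsen(self, three_group_data):
        long, *_ = three_group_data
        plain = fit_gbtm(long, GBTMSpec(J=2), n_starts=1, seed=0)
        polished = fit_gbtm(long, GBTMSpec(J=2), n_starts=1, seed=0, polish=True)
        assert polished.loglik >= plain.loglik - 1e-6

    def test_too_few_subjects_rejected(self):
        data = pd.DataFrame({"id": ["a", "b"], "time": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="too few"):
            fit_gbtm(data, GBTMSpec(J=2, order=1))


class TestSelectModel:
    def test_two_well_separated_groups(self):
        long, _ = simulate_mixture_trajectories(
            (0.6, 0.4), np.array([[60.0, 0.4], [90.0, 0.4]]), 2.0,
            n_subjects=500, times=(0, 12, 24, 36), seed=5,
        )
        best, table = select_model(long, J_range=(1, 2, 3), order_range=(1,),
                                   seed=0, n_starts=3)
        assert best.spec.J == 2
        assert set(table["J"]) == {1, 2, 3}

    def test_single_group_data_selects_one(self):
        long, _ = simulate_mixture_trajectories(
            (1.0,), np.array([[70.0, 0.4]]), 2.0,
            n_subjects=400, times=(0, 12, 24, 36), seed=6,
        )
        best, _ = select_model(long, J_range=(1, 2, 3), order_range=(1,),
                               seed=0, n_starts=3)
        assert best.spec.J == 1

    def test_useless_parameter_increases_bic(self):
        # same loglik, one more parameter -> BIC strictly larger
        n = 500
        k1, k2 = GBTMSpec(J=1, order=1).n_params, GBTMSpec(J=1, order=2).n_params
        ll = -1234.5
        bic1 = -2 * ll + k1 * np.log(n)
        bic2 = -2 * ll + k2 * np.log(n)
        assert k2 == k1 + 1 and bic2 > bic1

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_model(pd.DataFrame({"id": [], "time": [], "y": []}), J_range=())


class TestAdequacy:
    def test_single_group_is_perfect(self):
        long, _ = simulate_mixture_trajectories(
            (1.0,), np.array([[70.0, 0.4]]), 2.0, 50, (0, 10, 20), seed=1
        )
        fit = fit_gbtm(long, GBTMSpec(J=1), n_starts=1, seed=0)
        diag = adequacy_diagnostics(fit)
        assert diag.loc[0, "mean_posterior"] == pytest.approx(1.0)
        assert diag.loc[0, "observed_share"] == 1.0
        assert diag.loc[0, "expected_share"] == pytest.approx(1.0)

    def test_low_posterior_group_flagged(self, three_group_data):
        long, *_ = three_group_data
        fit = fit_gbtm(long, GBTMSpec(J=3), n_starts=2, seed=2)
        doctored = fit.posterior.copy()
        doctored[:, :] = 1 / 3  # force maximal uncertainty
        fit.posterior = doctored
        fit.assignment = doctored.argmax(axis=1)
        diag = adequacy_diagnostics(fit)
        assert diag["below_threshold"].any()

    def test_well_separated_groups_near_perfect(self, three_group_data):
        long, *_ = three_group_data
        fit = fit_gbtm(long, GBTMSpec(J=3), n_starts=3, seed=3)
        diag = fit.diagnostics
        assert (diag["mean_posterior"] > 0.95).all()
        assert (diag["observed_share"] - diag["expected_share"]).abs().max() < 0.01


class TestSlopes:
    def test_noise_free_slope_exact_with_tight_ci(self):
        t = np.array([0.0, 10, 20, 30])
        long = pd.DataFrame({
            "id": np.repeat([f"s{i}" for i in range(30)], 4),
            "time": np.tile(t, 30),
            "y": np.tile(60 + 2.34 * t / 4.345, 30),  # ~2.34 kg/month as kg/week
        })
        long["y"] += np.random.default_rng(0).normal(0, 1e-6, len(long))
        fit = fit_gbtm(long, GBTMSpec(J=1), n_starts=1, seed=0)
        slopes, _ = trajectory_slopes(fit, long)
        assert slopes.loc[0, "slope"] == pytest.approx(2.34 / 4.345, abs=1e-4)
        assert slopes.loc[0, "ci_hi"] - slopes.loc[0, "ci_lo"] < 1e-4
        assert slopes.loc[0, "ci_lo"] <= slopes.loc[0, "slope"] <= slopes.loc[0, "ci_hi"]

    def test_slope_difference_detected(self):
        # two groups with slopes 2.3 vs 3.0 kg/month (converted to kg/week)
        per_week = np.array([2.3, 3.0]) / 4.345
        long, _ = simulate_mixture_trajectories(
            (0.5, 0.5), np.column_stack([[55.0, 80.0], per_week]), 1.0,
            n_subjects=1000, times=(0, 10, 22, 34), seed=11,
        )
        fit = fit_gbtm(long, GBTMSpec(J=2), n_starts=2, seed=0)
        slopes, pairs = trajectory_slopes(fit, long)
        assert pairs.loc[0, "p"] < 0.01
        for _, row in slopes.iterrows():
            assert row["ci_lo"] <= row["slope"] <= row["ci_hi"]

    def test_order_zero_has_no_slope(self):
        long, _ = simulate_mixture_trajectories(
            (1.0,), np.array([[70.0, 0.0]]), 1.0, 30, (0, 10, 20), seed=2
        )
        fit = fit_gbtm(long, GBTMSpec(J=1, order=0), n_starts=1, seed=0)
        with pytest.raises(ValueError, match="order-0"):
            trajectory_slopes(fit, long)
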