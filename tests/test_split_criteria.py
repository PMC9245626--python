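"""Criterion statistics checked against independent oracles.

The continuous criteria are compared with a from-scratch least-squares
Wald oracle (normal equations solved directly); the hazards fitter with a
brute-force Breslow partial-likelihood maximizer.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from dipmtree import (
    CriterionValue,
    criterion_for,
    fit_hazards,
    g_continuous_multi_arm,
    g_continuous_two_arm,
    g_survival_multi_arm,
    g_survival_two_arm,
    km_estimate,
    optimal_treatment,
    restricted_mean_survival_time,
)
from dipmtree.data_model import Split
from dipmtree.split_criteria import node_arm_summary

from conftest import make_continuous, make_survival


# ---------------------------------------------------------------------------
# independent oracles


def ols_wald_oracle(y, arm, z, K):
    """Interaction Wald statistic via explicit normal equations."""
    n = len(y)
    z = np.asarray(z, float)
    cols = [np.ones(n)]
    cols += [(arm == k).astype(float) for k in range(1, K)]
    cols += [z]
    cols += [(arm == k) * z for k in range(1, K)]
    X = np.column_stack(cols)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (n - X.shape[1])
    cov = s2 * np.linalg.inv(XtX)
    idx = np.arange(K + 1, 2 * K)
    b = beta[idx]
    return float(b @ np.linalg.solve(cov[np.ix_(idx, idx)], b))


def breslow_loglik_oracle(beta, times, delta, X):
    """Brute-force Breslow log partial likelihood (risk-set loop)."""
    beta = np.atleast_1d(beta)
    eta = X @ beta
    ll = 0.0
    for i in range(len(times)):
        if delta[i] == 1:
            risk = times >= times[i]
            ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return ll


# ---------------------------------------------------------------------------
# continuous criteria


class TestContinuousTwoArm:
    def test_parallel_effects_give_zero(self):
        # cell means exactly (0, 1, 2, 3): the interaction contrast vanishes
        arm = np.array([0] * 8 + [1] * 8)
        z = np.array(([0] * 4 + [1] * 4) * 2, dtype=bool)
        means = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.repeat(means, 4) + np.tile([-0.5, 0.5, -0.3, 0.3], 4)
        cv = g_continuous_two_arm(y, arm, z)
        assert cv.converged
        assert cv.g == pytest.approx(0.0, abs=1e-24)

    def test_eight_row_toy_matches_ols_oracle(self):
        y = np.array([0.0, 1, 5, 6, 0, 1, 9, 10])
        arm = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        z = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=bool)
        cv = g_continuous_two_arm(y, arm, z)
        assert cv.converged and cv.df == 1
        assert cv.g == pytest.approx(ols_wald_oracle(y, arm, z, 2), abs=1e-10)

    def test_empty_cell_degenerate(self):
        y = np.arange(8.0)
        arm = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        z = np.array([0, 0, 1, 1, 0, 0, 0, 0], dtype=bool)  # arm 1 never left
        cv = g_continuous_two_arm(y, arm, z)
        assert cv.g == 0.0 and not cv.converged

    def test_zero_residual_variance_degenerate(self):
        y = np.repeat([0.0, 1.0, 2.0, 3.0], 2)
        arm = np.repeat([0, 0, 1, 1], 2)
        z = np.repeat([0, 1, 0, 1], 2).astype(bool)
        cv = g_continuous_two_arm(y, arm, z)
        assert cv.g == 0.0 and not cv.converged

    @given(st.integers(0, 1000),
           st.floats(0.1, 50.0),
           st.floats(-100.0, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        n = 40
        arm = rng.integers(0, 2, n)
        z = rng.integers(0, 2, n).astype(bool)
        y = rng.normal(0, 1, n) + arm * z
        g1 = g_continuous_two_arm(y, arm, z)
        g2 = g_continuous_two_arm(a * y + b, arm, z)
        if g1.converged:
            assert g2.g == pytest.approx(g1.g, abs=1e-8, rel=1e-8)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_label_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 32
        arm = rng.integers(0, 2, n)
        z = rng.integers(0, 2, n).astype(bool)
        y = rng.normal(0, 1, n) + 0.8 * arm * z
        g1 = g_continuous_two_arm(y, arm, z)
        g2 = g_continuous_two_arm(y, 1 - arm, z)
        assert g2.g == pytest.approx(g1.g, rel=1e-10, abs=1e-12)


class TestContinuousMultiArm:
    def test_no_interaction_noiseless_degenerate_zero(self):
        # identical per-arm shift across z with the pattern repeated twice:
        # zero residual variance, so the fit is flagged degenerate with g=0
        arm = np.tile(np.repeat([0, 1, 2], 2), 2)
        z = np.array([0] * 6 + [1] * 6, dtype=bool)
        y = (arm + 1.0) + 2.0 * z
        cv = g_continuous_multi_arm(y, arm, z)
        assert cv.g == 0.0

    def test_twelve_row_toy_matches_oracle(self):
        rng = np.random.default_rng(7)
        arm = np.tile(np.repeat([0, 1, 2], 2), 2)
        z = np.array([0] * 6 + [1] * 6, dtype=bool)
        y = rng.normal(0, 1, 12) + np.where((arm == 2) & z, -3.0, arm * z * 1.0)
        cv = g_continuous_multi_arm(y, arm, z)
        assert cv.converged and cv.df == 2
        assert cv.g == pytest.approx(ols_wald_oracle(y, arm, z, 3), abs=1e-10)

    def test_missing_arm_is_precondition_error(self):
        y = np.arange(8.0)
        arm = np.array([0, 0, 1, 1, 0, 0, 1, 3])  # arm 2 missing, arm 3 present
        z = np.array([0, 1] * 4, dtype=bool)
        with pytest.raises(ValueError, match="arm"):
            g_continuous_multi_arm(y, arm, z)


# ---------------------------------------------------------------------------
# hazards fitting


class TestFitHazards:
    def test_single_covariate_matches_grid_search(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        delta = np.array([1, 0, 1, 0, 1, 0])
        x = np.array([0.5, -1.0, 1.5, 0.0, -0.5, 1.0])[:, None]
        fit = fit_hazards(times, delta, x)
        grid = np.linspace(-5, 5, 20001)
        lls = [breslow_loglik_oracle(np.array([b]), times, delta, x) for b in grid]
        b_star = grid[int(np.argmax(lls))]
        assert fit.converged
        assert fit.coef[0] == pytest.approx(b_star, abs=1e-3)
        # and the oracle likelihood at our estimate is at least the grid max
        assert breslow_loglik_oracle(fit.coef, times, delta, x) >= max(lls) - 1e-10

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="events"):
            fit_hazards(np.arange(1.0, 5.0), np.zeros(4, int), np.ones((4, 1)))

    def test_constant_covariate_degenerate(self):
        times = np.arange(1.0, 7.0)
        delta = np.array([1, 1, 0, 1, 0, 1])
        fit = fit_hazards(times, delta, np.ones((6, 1)))
        assert fit.coef[0] == 0.0
        assert fit.degenerate

    def test_breslow_ties_match_oracle(self):
        times = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        delta = np.array([1, 1, 1, 0, 1, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.5, -1.0, 0.0, 2.0, -0.5])[:, None]
        fit = fit_hazards(times, delta, x)
        res = minimize(lambda b: -breslow_loglik_oracle(b, times, delta, x),
                       x0=[0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert fit.coef[0] == pytest.approx(res.x[0], abs=1e-4)


class TestSurvivalCriteria:
    def test_duplicated_child_symmetry_zero(self):
        # right child is a relabeled copy of the left: no interaction signal
        rng = np.random.default_rng(3)
        m = 12
        t_half = rng.exponential(1.0, m)
        d_half = rng.integers(0, 2, m)
        d_half[:2] = 1
        arm_half = np.array([0, 1] * (m // 2))
        times = np.concatenate([t_half, t_half])
        delta = np.concatenate([d_half, d_half])
        arm = np.concatenate([arm_half, arm_half])
        z = np.array([True] * m + [False] * m)
        cv = g_survival_two_arm(times, delta, arm, z)
        assert cv.converged
        assert cv.g <= 1e-8

    def test_reversed_effect_toy_matches_optimizer_oracle(self):
        rng = np.random.default_rng(11)
        n = 12
        arm = np.array([0, 1] * 6)
        z = np.array([True] * 6 + [False] * 6)
        rate = np.exp(1.5 * arm * z - 1.5 * arm * ~z)
        times = rng.exponential(1.0 / rate)
        delta = np.ones(n, dtype=int)
        cv = g_survival_two_arm(times, delta, arm, z)
        X = np.column_stack([arm, z, arm * z]).astype(float)
        res = minimize(lambda b: -breslow_loglik_oracle(b, times, delta, X),
                       x0=np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000})
        fit = fit_hazards(times, delta, X)
        assert cv.converged
        assert np.allclose(fit.coef, res.x, atol=1e-3)
        g_oracle = res.x[2] ** 2 / fit.cov[2, 2]
        assert cv.g == pytest.approx(g_oracle, rel=1e-3)

    def test_no_events_in_child_zero(self):
        times = np.arange(1.0, 13.0)
        delta = np.array([0] * 6 + [1] * 6)
        arm = np.array([0, 1] * 6)
        z = np.array([True] * 6 + [False] * 6)  # left child has no events
        cv = g_survival_two_arm(times, delta, arm, z)
        assert cv.g == 0.0 and not cv.converged

    def test_multi_arm_missing_arm_raises(self):
        times = np.arange(1.0, 9.0)
        delta = np.ones(8, int)
        arm = np.array([0, 1, 0, 1, 0, 1, 0, 3])
        z = np.array([0, 1] * 4, dtype=bool)
        with pytest.raises(ValueError, match="arm"):
            g_survival_multi_arm(times, delta, arm, z)

    def test_multi_arm_null_and_alternative_calibration(self):
        from scipy.stats import chi2
        q99 = chi2.ppf(0.99, df=2)
        null_exceed = 0
        alt_exceed = 0
        n_sim = 200
        for s in range(n_sim):
            rng = np.random.default_rng(1000 + s)
            n = 120
            arm = rng.integers(0, 3, n)
            z = rng.integers(0, 2, n).astype(bool)
            t = rng.exponential(1.0, n)
            cv = g_survival_multi_arm(t, np.ones(n, int), arm, z)
            if cv.converged and cv.g > q99:
                null_exceed += 1
            n = 300
            arm = rng.integers(0, 3, n)
            z = rng.integers(0, 2, n).astype(bool)
            rate = np.exp(np.log(3.0) * (arm == 2) * z)
            t = rng.exponential(1.0 / rate)
            cv = g_survival_multi_arm(t, np.ones(n, int), arm, z)
            if cv.converged and cv.g > q99:
                alt_exceed += 1
        assert null_exceed <= 0.05 * n_sim
        assert alt_exceed >= 0.90 * n_sim

    def test_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(21)
        n = 40
        arm = rng.integers(0, 2, n)
        z = rng.integers(0, 2, n).astype(bool)
        times = rng.exponential(np.exp(-(arm * z)))
        delta = rng.integers(0, 2, n)
        delta[z] = np.maximum(delta[z], np.concatenate(([1], np.zeros(z.sum() - 1, int))))
        delta[~z] = np.maximum(delta[~z], np.concatenate(([1], np.zeros((~z).sum() - 1, int))))
        g1 = g_survival_two_arm(times, delta, arm, z)
        g2 = g_survival_two_arm(np.exp(times), delta, arm, z)
        assert g2.g == pytest.approx(g1.g, abs=1e-6, rel=1e-6)


# ---------------------------------------------------------------------------
# dispatch and node labels


class TestCriterionDispatch:
    def test_routes_and_caches(self):
        ds = make_continuous(n=80, K=2, seed=1, interaction=2.0)
        split = Split("X1", "binary", cutpoint=0.5)
        cv = criterion_for(ds, ds.all_rows(), split)
        assert isinstance(cv, CriterionValue)
        assert split.criterion is cv
        assert cv.df == 1

    def test_three_arm_df(self):
        ds = make_continuous(n=120, K=3, seed=2, interaction=2.0)
        split = Split("X1", "binary", cutpoint=0.5)
        assert criterion_for(ds, ds.all_rows(), split).df == 2

    def test_empty_child_zero(self):
        ds = make_continuous(n=40, K=2, seed=3)
        split = Split("X1", "binary", cutpoint=5.0)  # everything goes left
        cv = criterion_for(ds, ds.all_rows(), split)
        assert cv.g == 0.0 and not cv.converged


class TestOptimalTreatment:
    def _ds(self, y, arms):
        df = pd.DataFrame({"Y": y, "t": arms, "x": np.ones(len(y))})
        from dipmtree import parse_types, validate_dataset
        return validate_dataset(df, parse_types(["response", "treatment", "ordinal"],
                                                df.columns))

    def test_largest_mean_wins(self):
        ds = self._ds([1.0, 1.0, 3.0, 3.0], ["A", "A", "B", "B"])
        assert ds.arm_label(optimal_treatment(ds, ds.all_rows())) == "B"

    def test_tie_goes_to_smallest_code(self):
        ds = self._ds([5.0, 5.0, 5.0, 5.0, 2.0, 2.0],
                      ["A", "A", "B", "B", "C", "C"])
        assert ds.arm_label(optimal_treatment(ds, ds.all_rows())) == "A"

    def test_survival_dominant_arm_wins(self):
        df = pd.DataFrame({
            "Y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
            "d": [1, 1, 1, 1, 1, 1, 1, 1],
            "t": [0, 0, 0, 0, 1, 1, 1, 1],
            "x": np.ones(8),
        })
        from dipmtree import parse_types, validate_dataset
        ds = validate_dataset(df, parse_types(
            ["response", "status", "treatment", "ordinal"], df.columns, "survival"))
        assert ds.arm_label(optimal_treatment(ds, ds.all_rows())) == 1

    def test_row_order_invariance(self):
        ds = make_continuous(n=50, K=3, seed=9, interaction=1.0)
        rows = ds.all_rows()
        perm = np.random.default_rng(0).permutation(rows)
        assert optimal_treatment(ds, rows) == optimal_treatment(ds, perm)
        assert node_arm_summary(ds, rows) == pytest.approx(node_arm_summary(ds, perm))


# ---------------------------------------------------------------------------
# Kaplan-Meier / RMST


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        t, s = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert t.tolist() == [0.0, 1.0, 2.0, 3.0]
        assert s == pytest.approx([1.0, 2 / 3, 1 / 3, 0.0])

    def test_all_censored_constant_one(self):
        t, s = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert s.tolist() == [1.0]

    def test_six_subject_hand_table(self):
        # t=1 death (6 at risk), t=2 censor, t=3 death (4 at risk),
        # t=4 death+censor tie: death first, 3 at risk, t=6 censored
        times = [1.0, 2.0, 3.0, 4.0, 4.0, 6.0]
        delta = [1, 0, 1, 1, 0, 0]
        t, s = km_estimate(times, delta)
        assert t.tolist() == [0.0, 1.0, 3.0, 4.0]
        assert s == pytest.approx([1.0, 5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 2 / 3])

    @given(st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_matches_lifelines(self, seed):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(seed)
        n = 25
        times = rng.exponential(1.0, n).round(2) + 0.01
        delta = rng.integers(0, 2, n)
        t, s = km_estimate(times, delta)
        km = KaplanMeierFitter().fit(times, delta)
        for ti, si in zip(t, s):
            assert km.predict(ti) == pytest.approx(si, abs=1e-12)

    def test_rmst_step_integral(self):
        # S = 1 on [0,1), 2/3 on [1,2), 1/3 on [2,3), 0 after
        val = restricted_mean_survival_time([1.0, 2.0, 3.0], [1, 1, 1], tau=2.5)
        assert val == pytest.approx(1.0 + 2 / 3 + 0.5 * 1 / 3)
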