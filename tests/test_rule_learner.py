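"""SCAD derivative, L2-SVM init, weighted-L1 LP and rule fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog, minimize, minimize_scalar

from pseudodtr.contrast import ContrastVector
from pseudodtr.rule_learner import (LinearRule, ScadSpec, default_lambda_grid, fit_rule,
                                    init_rule_l2, scad_derivative, select_lambda,
                                    solve_weighted_l1_svm)


class TestScadDerivative:
    @pytest.mark.parametrize("b,lam,gamma,expected", [
        (0.5, 1.0, 3.7, 1.0),                   # |b| <= lambda branch
        (10.0, 1.0, 3.7, 0.0),                  # beyond gamma*lambda
        (2.0, 1.0, 3.7, (3.7 - 2.0) / 2.7),     # middle branch
    ])
    def test_branches(self, b, lam, gamma, expected):
        assert scad_derivative(b, lam, gamma) == pytest.approx(expected)

    def test_zero_lambda(self):
        assert scad_derivative(0.7, 0.0) == 0.0

    @given(st.floats(0, 50), st.floats(0.01, 5), st.floats(2.01, 10))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_vanishing(self, b, lam, gamma):
        v = scad_derivative(b, lam, gamma)
        assert 0 <= v <= lam + 1e-12
        if b > gamma * lam:
            assert v == 0.0

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            scad_derivative(1.0, 1.0, gamma=1.5)


def _oracle_lp(H, Z, w, pen):
    """Independently assembled dense LP for the weighted-L1 SVM."""
    n, p = H.shape
    cost = np.concatenate([w / n, [0, 0], pen, pen])
    A = np.zeros((n, n + 2 + 2 * p))
    A[:, :n] = -np.eye(n)
    A[:, n] = -Z
    A[:, n + 1] = Z
    A[:, n + 2:n + 2 + p] = -Z[:, None] * H
    A[:, n + 2 + p:] = Z[:, None] * H
    res = linprog(cost, A_ub=A, b_ub=-np.ones(n), bounds=(0, None),
                  method="highs-ipm")
    return res.fun


class TestWeightedL1Lp:
    def test_separable_toy_has_zero_objective(self):
        sol = solve_weighted_l1_svm(np.array([[1.0], [-1.0]]),
                                    np.array([1.0, -1.0]), np.ones(2),
                                    np.array([0.0]))
        assert sol.objective == pytest.approx(0.0, abs=1e-9)
        assert sol.slacks.max() == pytest.approx(0.0, abs=1e-9)

    def test_zero_weights_give_zero_coefficients(self):
        rng = np.random.default_rng(0)
        sol = solve_weighted_l1_svm(rng.normal(size=(10, 3)),
                                    rng.choice([-1.0, 1.0], 10), np.zeros(10),
                                    np.full(3, 0.1))
        np.testing.assert_allclose(sol.rule.coefficients, 0.0)

    def test_matches_generic_lp_oracle(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            n, p = int(r.integers(10, 50)), int(r.integers(2, 8))
            H = r.normal(size=(n, p))
            Z = r.choice([-1.0, 1.0], n)
            w = r.exponential(1, n)
            pen = r.uniform(0, 0.3, p)
            sol = solve_weighted_l1_svm(H, Z, w, pen)
            assert sol.objective == pytest.approx(_oracle_lp(H, Z, w, pen),
                                                  abs=1e-6), f"seed={seed}"

    def test_scale_equivariance(self):
        """Scaling weights and penalty weights jointly by c > 0 leaves the
        decisions unchanged (exact LP homogeneity)."""
        r = np.random.default_rng(5)
        H = r.normal(size=(40, 4))
        Z = r.choice([-1.0, 1.0], 40)
        w = r.exponential(1, 40)
        pen = r.uniform(0.01, 0.2, 4)
        base = solve_weighted_l1_svm(H, Z, w, pen).rule.decide(H)
        for c in (0.1, 7.3):
            scaled = solve_weighted_l1_svm(H, Z, c * w, c * pen).rule.decide(H)
            np.testing.assert_array_equal(base, scaled)


def _dual_l2_svm_objective(H, Z, w, C):
    """Generic convex-solver oracle for the weighted L2-SVM primal value."""
    n = len(Z)
    K = (H @ H.T) * np.outer(Z, Z)
    res = minimize(lambda a: 0.5 * a @ K @ a - a.sum(),
                   np.minimum(C * w, 1e-3), jac=lambda a: K @ a - 1,
                   bounds=[(0, C * wi) for wi in w],
                   constraints=[{"type": "eq", "fun": lambda a: a @ Z,
                                 "jac": lambda a: Z}],
                   method="SLSQP", options={"maxiter": 500, "ftol": 1e-12})
    beta = (res.x * Z) @ H
    prim = lambda b0: (0.5 * beta @ beta
                       + C * np.sum(w * np.maximum(0, 1 - Z * (H @ beta + b0))))
    return minimize_scalar(prim, bounds=(-10, 10), method="bounded",
                           options={"xatol": 1e-10}).fun


class TestInitL2:
    def test_separable_signs_and_antisymmetry(self):
        X = np.array([[1.0], [-1.0]])
        Z = np.array([1.0, -1.0])
        r1 = init_rule_l2(X, Z, np.ones(2))
        r2 = init_rule_l2(X, -Z, np.ones(2))
        assert r1.coefficients[0] > 0
        assert r2.coefficients[0] < 0

    def test_single_class_returns_constant_rule(self):
        with pytest.warns(UserWarning):
            rule = init_rule_l2(np.zeros((3, 2)), np.ones(3), np.ones(3))
        assert np.all(rule.coefficients == 0)
        assert np.all(rule.decide(np.zeros((2, 2))) == 1)

    def test_matches_convex_solver_oracle(self):
        r = np.random.default_rng(7)
        H = r.normal(size=(30, 2))
        Z = r.choice([-1.0, 1.0], 30)
        w = r.exponential(1, 30)
        # compare on the standardized scale the implementation uses internally
        Hs = (H - H.mean(0)) / H.std(0)
        rule = init_rule_l2(H, Z, w, C=1.0, tol=1e-10)
        b0 = rule.intercept + rule.coefficients @ H.mean(0)
        beta_s = rule.coefficients * H.std(0)
        ours = (0.5 * beta_s @ beta_s
                + np.sum(w * np.maximum(0, 1 - Z * (Hs @ beta_s + b0))))
        assert ours == pytest.approx(_dual_l2_svm_objective(Hs, Z, w, 1.0),
                                     abs=1e-4)


class TestFitRule:
    def test_huge_lambda_kills_all_coefficients(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 5))
        cv = ContrastVector(contrast=rng.normal(size=100), scheme="dr")
        rule = fit_rule(X, cv, ScadSpec(lam=100.0))
        assert rule.n_nonzero == 0

    def test_threshold_recovery_single_covariate(self):
        """Stage-2-style recovery: outcome interaction flips sign at x = 0.5;
        the fitted one-covariate rule's threshold lands near 0.5."""
        rng = np.random.default_rng(2)
        n = 1000
        x = rng.uniform(-2, 2, n)
        A = rng.integers(0, 2, n)
        # doubly-robust-style noisy contrast centred on the true interaction
        c = (x - 0.5) + rng.normal(0, 0.8, n)
        cv = ContrastVector(contrast=c, scheme="dr")
        rule = fit_rule(x[:, None], cv, ScadSpec(lam=0.01))
        assert rule.coefficients[0] > 0
        thr = -rule.intercept / rule.coefficients[0]
        assert abs(thr - 0.5) < 0.15

    def test_noise_covariates_zeroed_with_tuned_lambda(self):
        """SCAD-penalized fits drop most pure-noise coefficients."""
        hits = 0
        reps = 8
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n = 600
            X = rng.uniform(-2, 2, size=(n, 10))
            c = 1.0 * X[:, 0] + 1.0 * X[:, 1] + rng.normal(0, 1.0, n)
            cv = ContrastVector(contrast=c, scheme="dr")
            lam = select_lambda(X, cv, ScadSpec(0.0), folds=4, rng=seed)
            rule = fit_rule(X, cv, ScadSpec(lam=lam))
            n_noise_zero = int(np.sum(rule.coefficients[2:] == 0))
            hits += n_noise_zero >= 6
        assert hits >= int(0.8 * reps)

    def test_select_lambda_single_point_grid(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        cv = ContrastVector(contrast=rng.normal(size=60), scheme="dr")
        lam = select_lambda(X, cv, ScadSpec(0.0, lambda_grid=np.array([0.37])),
                            folds=3, rng=0)
        assert lam == 0.37

    def test_pure_noise_contrast_learns_nothing_useful(self):
        """With no signal, the tuned rule's decisions carry no information
        about any covariate direction (held-out plug-in value near zero)."""
        rng = np.random.default_rng(4)
        n = 400
        X = rng.uniform(-2, 2, size=(n, 5))
        c = rng.normal(size=n)
        cv = ContrastVector(contrast=c, scheme="dr")
        lam = select_lambda(X, cv, ScadSpec(0.0), folds=4, rng=0)
        rule = fit_rule(X, cv, ScadSpec(lam=lam))
        Xf = rng.uniform(-2, 2, size=(5000, 5))
        cf = rng.normal(size=5000)
        value = float(np.sum(cf * rule.decide(Xf))) / 5000
        assert abs(value) < 0.05

    def test_strong_signal_beats_intercept_only(self):
        """The selected lambda yields held-out value at least matching the
        all-shrunk (intercept-only) fit in nearly every replicate."""
        wins = 0
        reps = 10
        for seed in range(reps):
            rng = np.random.default_rng(40 + seed)
            n = 500
            X = rng.uniform(-2, 2, size=(n, 5))
            c = 1.5 * X[:, 0] + rng.normal(0, 0.5, n)
            cv = ContrastVector(contrast=c, scheme="dr")
            lam = select_lambda(X, cv, ScadSpec(0.0), folds=4, rng=seed)
            rule = fit_rule(X, cv, ScadSpec(lam=lam))
            flat = fit_rule(X, cv, ScadSpec(lam=1e3))
            Xf = rng.uniform(-2, 2, size=(4000, 5))
            cf = 1.5 * Xf[:, 0]
            v_sel = np.sum(cf * rule.decide(Xf))
            v_flat = np.sum(cf * flat.decide(Xf))
            wins += v_sel >= v_flat
        assert wins >= 9

    def test_decision_invariance_under_coefficient_scaling(self):
        rule = LinearRule(intercept=-0.5, coefficients=np.array([1.0, -2.0]))
        scaled = LinearRule(intercept=-0.5 * 3.7,
                            coefficients=np.array([1.0, -2.0]) * 3.7)
        X = np.random.default_rng(0).normal(size=(50, 2))
        np.testing.assert_array_equal(rule.decide(X), scaled.decide(X))
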