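"""Sparse linear decision rules by SCAD-penalized weighted hinge loss.

The stage-k treatment rule is g(H) = I(b0 + H'b > 0).  It is estimated by
minimizing the weighted hinge surrogate of the misclassification objective

    n^{-1} sum_i w_i [1 - Z_i f(H_i)]_+  +  sum_j P_lambda(|b_j|),

where w_i = |C_i| and Z_i = sign(C_i) come from an estimated treatment
contrast and P_lambda is the SCAD penalty (gamma = 3.7).  One local linear
approximation (LLA) step replaces the SCAD term by a weighted L1 penalty
with weights P'_lambda(|b_j^(0)|) around an initial L2-SVM solution, turning
the problem into a linear program in the split variables b_j = b_j^+ - b_j^-
with slack xi_i >= [1 - Z_i f(H_i)]_+:

    min  sum_i (w_i / n) xi_i + sum_j P'_lambda(|b_j^(0)|)(b_j^+ + b_j^-)
    s.t. Z_i { b0^+ - b0^- + sum_j h_ij (b_j^+ - b_j^-) } >= 1 - xi_i,
         all variables >= 0.

Numerical conventions
---------------------
* The 1/n factor is kept on the loss term, so reported lambdas are
  per-sample and comparable across sample sizes.
* The intercept is unpenalized, as in standard SVM practice.
* Features are standardized (mean 0, sd 1) internally before the LP so that
  a single lambda is comparable across covariates; coefficients are
  back-transformed to the original scale.
* Decisions use the strict indicator I(f > 0): f = 0 maps to action 0.
* The LP has a fixed variable ordering and is solved by HiGHS; degenerate
  optima may differ across solvers, so downstream comparisons are made on
  objectives and decisions, never raw coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

__all__ = [
    "LinearRule",
    "ScadSpec",
    "LpSolution",
    "scad_derivative",
    "init_rule_l2",
    "solve_weighted_l1_svm",
    "fit_rule",
    "select_lambda",
    "default_lambda_grid",
]


@dataclass
class LinearRule:
    """Linear decision rule g(H) = I(intercept + H . coefficients > 0)."""

    intercept: float
    coefficients: np.ndarray
    positive_action: int = 1

    def decision_value(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.coefficients

    def decide(self, X: np.ndarray) -> np.ndarray:
        """0/1 decisions; the boundary f = 0 maps to action 0 (strict >)."""
        return (self.decision_value(X) > 0).astype(int)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))


@dataclass
class ScadSpec:
    """SCAD penalty specification: lambda, gamma (> 2, default 3.7) and an
    optional grid of candidate lambdas for cross-validation."""

    lam: float = 0.0
    gamma: float = 3.7
    lambda_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 2:
            raise ValueError("SCAD requires gamma > 2")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


@dataclass
class LpSolution:
    rule: LinearRule
    slacks: np.ndarray
    objective: float
    solver_status: str


def scad_derivative(beta_abs, lam: float, gamma: float = 3.7):
    """SCAD penalty derivative P'_lambda(|b|).

    Equals lambda on [0, lambda], decays linearly as (gamma*lambda - |b|)_+ /
    (gamma - 1) on (lambda, gamma*lambda], and is 0 beyond.  Vectorised in
    ``beta_abs``; returns 0 identically when lambda = 0.
    """
    b = np.asarray(beta_abs, dtype=float)
    if np.any(b < 0):
        raise ValueError("beta_abs must be nonnegative")
    if gamma <= 2:
        raise ValueError("SCAD requires gamma > 2")
    if lam == 0:
        return np.zeros_like(b) if b.ndim else 0.0
    out = np.where(b <= lam, lam, np.maximum(gamma * lam - b, 0.0) / (gamma - 1.0))
    return out if b.ndim else float(out)


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def _destandardize(b0: float, beta: np.ndarray, mean: np.ndarray, sd: np.ndarray):
    coef = beta / sd
    return float(b0 - np.dot(coef, mean)), coef


def init_rule_l2(features, labels, weights, *, C: float = 1.0,
                 tol: float = 1e-7, max_iter: int = 200_000) -> LinearRule:
    """Weighted soft-margin linear SVM used as the LLA starting point b^(0).

    Solves min 1/2 ||b||^2 + C sum_i w_i [1 - Z_i f(H_i)]_+ (libsvm dual at
    tight tolerance).  Zero-weight subjects are dropped; if only one label
    remains, a constant rule favouring that class is returned with a warning.
    Features are expected raw; standardization happens inside and the rule is
    returned on the original scale.
    """
    from sklearn.svm import SVC

    X = np.asarray(features, dtype=float)
    Z = np.asarray(labels, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    m = w > 0
    if m.sum() == 0 or len(np.unique(Z[m])) < 2:
        only = 1.0 if (m.sum() and np.all(Z[m] > 0)) or not m.sum() else -1.0
        warnings.warn("single-class input to init_rule_l2; returning constant rule")
        return LinearRule(intercept=float(only), coefficients=np.zeros(X.shape[1]))
    Xs, mean, sd = _standardize(X)
    svc = SVC(kernel="linear", C=C, tol=tol, shrinking=True, max_iter=max_iter)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(Xs[m], Z[m], sample_weight=w[m])
    b0, beta = _destandardize(float(svc.intercept_[0]), svc.coef_[0].copy(), mean, sd)
    return LinearRule(intercept=b0, coefficients=beta)


def solve_weighted_l1_svm(features, labels, weights, penalty_weights,
                          *, already_standardized: bool = False) -> LpSolution:
    """Solve the weighted-L1 SVM linear program.

    ``penalty_weights`` are the per-coefficient L1 penalty multipliers
    P'_lambda(|b_j^(0)|) (the LLA weights); the intercept is unpenalized.
    Variable ordering is fixed as [xi (n), b0+, b0-, b+ (p), b- (p)].  The
    LP is always feasible (xi absorbs any violation); a non-optimal solver
    status is raised as an error since it signals a bug, not a data issue.
    """
    H = np.asarray(features, dtype=float)
    Z = np.asarray(labels, dtype=float)
    w = np.asarray(weights, dtype=float)
    pen = np.asarray(penalty_weights, dtype=float)
    n, p = H.shape
    if pen.shape != (p,):
        raise ValueError("penalty_weights must have one entry per feature")

    cost = np.concatenate([w / n, [0.0, 0.0], pen, pen])
    # -xi_i - Z_i(b0+ - b0- + sum_j h_ij (b_j+ - b_j-)) <= -1
    ZH = Z[:, None] * H
    A_ub = sparse.hstack([
        -sparse.identity(n, format="csr"),
        sparse.csr_matrix(-Z[:, None]),
        sparse.csr_matrix(Z[:, None]),
        sparse.csr_matrix(-ZH),
        sparse.csr_matrix(ZH),
    ], format="csr")
    b_ub = -np.ones(n)
    res = linprog(cost, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
    if res.status != 0:
        raise RuntimeError(f"LP solver failed (status={res.status}): {res.message}")
    x = res.x
    xi = x[:n]
    b0 = x[n] - x[n + 1]
    beta = x[n + 2:n + 2 + p] - x[n + 2 + p:]
    # snap split-variable round-off to exact zeros
    beta[np.abs(beta) < 1e-9] = 0.0
    rule = LinearRule(intercept=float(b0), coefficients=beta)
    return LpSolution(rule=rule, slacks=xi, objective=float(res.fun),
                      solver_status="optimal")


def fit_rule(features, contrast, scad: ScadSpec, *, n_lla_steps: int = 1,
             init: LinearRule | None = None) -> LinearRule:
    """SCAD-penalized weighted-SVM rule via LLA around an L2-SVM start.

    Runs ``init_rule_l2`` (unless ``init`` is given), then ``n_lla_steps``
    (default one, a single local linearization) rounds of the weighted-L1 LP
    with penalty weights refreshed from the current coefficients.  Returns
    the rule on the original feature scale.
    """
    X = np.asarray(features, dtype=float)
    if not (hasattr(contrast, "weight") and hasattr(contrast, "label")):
        raise ValueError("contrast must expose .weight and .label")
    w = np.asarray(contrast.weight, dtype=float)
    Z = np.asarray(contrast.label, dtype=float)
    if len(w) != len(X):
        raise ValueError("contrast length must match feature rows")

    Xs, mean, sd = _standardize(X)
    if init is None:
        # weights normalized to mean 1 for the anchor fit only: the L2-SVM is
        # not scale-free in w and the anchor just seeds the LLA penalty weights
        w_bar = w.mean() if w.mean() > 0 else 1.0
        init = init_rule_l2(X, Z, w / w_bar)
    # express the init on the standardized scale for the penalty weights
    beta_std = init.coefficients * sd
    for _ in range(max(1, int(n_lla_steps))):
        pen = scad_derivative(np.abs(beta_std), scad.lam, scad.gamma)
        pen = np.atleast_1d(np.asarray(pen, dtype=float))
        sol = solve_weighted_l1_svm(Xs, Z, w, pen)
        beta_std = sol.rule.coefficients
        b0_std = sol.rule.intercept
    b0, beta = _destandardize(b0_std, beta_std, mean, sd)
    return LinearRule(intercept=b0, coefficients=beta)


def default_lambda_grid(features, contrast, *, n_points: int = 20,
                        span: tuple[float, float] = (1e-4, 1.0)) -> np.ndarray:
    """Log-spaced lambda grid scaled to the weighted margin gradient.

    The scale is max_j |sum_i w_i Z_i h_ij| / n on standardized features --
    the magnitude of the loss gradient at b = 0, above which the L1 penalty
    kills every coefficient.
    """
    X = np.asarray(features, dtype=float)
    Xs, _, _ = _standardize(X)
    wz = np.asarray(contrast.weight) * np.asarray(contrast.label)
    gmax = float(np.max(np.abs(Xs.T @ wz)) / len(Xs))
    if gmax <= 0:
        gmax = 1.0
    return gmax * np.logspace(np.log10(span[0]), np.log10(span[1]), n_points)


def _weighted_value(rule: LinearRule, X, contrast) -> float:
    """Held-out tuning criterion: the estimated value gain sum_i C_i g(H_i).

    This is the plug-in value of the candidate rule relative to never
    treating.  Unlike the weighted label-agreement count sum_i w_i I{Z_i =
    g_i}, the signed form lets the contrast noise cancel, so a constant rule
    cannot win merely because one label class carries more noise mass.
    """
    dec = rule.decide(X)
    return float(np.sum(np.asarray(contrast.contrast) * dec))


def select_lambda(features, contrast, scad: ScadSpec, *, folds: int = 5,
                  rng: np.random.Generator | int | None = None,
                  n_lla_steps: int = 1) -> float:
    """Cross-validated lambda maximizing the held-out weighted decision value.

    Ties are broken toward the larger (sparser) lambda.  The grid defaults to
    ``default_lambda_grid``.
    """
    from .contrast import ContrastVector

    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = np.asarray(features, dtype=float)
    grid = scad.lambda_grid
    if grid is None:
        grid = default_lambda_grid(X, contrast)
    grid = np.sort(np.asarray(grid, dtype=float))
    if len(grid) == 1:
        return float(grid[0])

    rng = np.random.default_rng(rng)
    n = len(X)
    perm = rng.permutation(n)
    fold_id = np.arange(n) % folds
    fold_of = np.empty(n, dtype=int)
    fold_of[perm] = fold_id

    c_arr = np.asarray(contrast.contrast)
    scores = np.zeros(len(grid))
    for f in range(folds):
        tr, te = fold_of != f, fold_of == f
        ctr = ContrastVector(contrast=c_arr[tr], scheme=getattr(contrast, "scheme", "dr"))
        cte = ContrastVector(contrast=c_arr[te], scheme=getattr(contrast, "scheme", "dr"))
        try:
            init = init_rule_l2(X[tr], ctr.label, ctr.weight)
        except ValueError:
            continue
        for g, lam in enumerate(grid):
            rule = fit_rule(X[tr], ctr, ScadSpec(lam=lam, gamma=scad.gamma),
                            n_lla_steps=n_lla_steps, init=init)
            scores[g] += _weighted_value(rule, X[te], cte)
    best = np.max(scores)
    return float(grid[np.flatnonzero(scores >= best - 1e-12)[-1]])
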