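"""Treatment-contrast estimation: IPW and doubly-robust (AIPW) schemes.

The object of interest is the conditional contrast C(H) = mu_1(H) - mu_0(H),
the difference in expected (pseudo-)outcome between the two arms given
history H.  Its sign identifies the better arm and its magnitude the cost of
a wrong assignment, so the pair (|C_i|, sign(C_i)) is exactly the
weight/label decomposition consumed by the weighted-classification rule
learner.

Two estimators are provided:

* IPW:   C_i = { A_i / pi_1(H_i) - (1 - A_i) / (1 - pi_1(H_i)) } Y_i
* AIPW:  mu_a^DR(H_i) = I(A_i = a)/pi_a(H_i) * Y_i
                        + {1 - I(A_i = a)/pi_a(H_i)} * mu_a_hat(H_i)

The AIPW version is doubly robust: it is consistent if either the propensity
model or the outcome (Q) model is correctly specified, and with both correct
it is more efficient than IPW.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from sklearn.linear_model import LinearRegression, LogisticRegression

logger = logging.getLogger(__name__)

#: positivity guard: estimated propensities are clipped to this interval
PROPENSITY_TRUNCATION = (0.01, 0.99)

__all__ = [
    "PropensityModel",
    "OutcomeModel",
    "ContrastVector",
    "fit_propensity",
    "fit_outcome_model",
    "ipw_contrast",
    "dr_mu",
    "dr_contrast",
]


@dataclass
class PropensityModel:
    """Treatment-assignment model pi_a(H).

    ``predict(X)`` returns an (n, L) matrix of per-arm probabilities in arm
    order ``arms``; probabilities are truncated to the positivity interval
    and renormalised.
    """

    kind: Literal["empirical_proportion", "logistic", "multinomial", "known"]
    arms: np.ndarray
    _predict_raw: Callable[[np.ndarray], np.ndarray]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = np.asarray(self._predict_raw(X), dtype=float)
        if p.ndim == 1:
            p = np.column_stack([1.0 - p, p])
        lo, hi = PROPENSITY_TRUNCATION
        n_out = int(np.sum((p < lo) | (p > hi)))
        if n_out:
            logger.info("propensity: truncated %d probabilities to [%.2f, %.2f]",
                        n_out, lo, hi)
        p = np.clip(p, lo, hi)
        return p / p.sum(axis=1, keepdims=True)

    def predict_arm(self, X: np.ndarray, arm) -> np.ndarray:
        j = int(np.flatnonzero(self.arms == arm)[0])
        return self.predict(X)[:, j]


@dataclass
class OutcomeModel:
    """Per-arm outcome regression mu_a(H) (the Q-model).

    The default is one ordinary-least-squares fit within each arm; any
    regressor exposing ``fit(X, y)`` / ``predict(X)`` may be plugged in via
    ``regressor_factory``.
    """

    kind: Literal["linear", "pluggable_regressor"]
    arms: np.ndarray
    models: dict = field(default_factory=dict)

    def predict(self, arm, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.asarray(self.models[arm].predict(X), dtype=float)


@dataclass
class ContrastVector:
    """Estimated contrasts with their weight/label decomposition.

    ``weight = |contrast|`` and ``label = sign(contrast)`` elementwise, with
    the zero-contrast tie broken to label +1 (such subjects carry zero weight
    and do not influence the classifier).
    """

    contrast: np.ndarray
    scheme: Literal["ipw", "dr"]

    @property
    def weight(self) -> np.ndarray:
        return np.abs(self.contrast)

    @property
    def label(self) -> np.ndarray:
        return np.where(self.contrast > 0, 1.0, np.where(self.contrast < 0, -1.0, 1.0))

    def __len__(self) -> int:
        return len(self.contrast)


def fit_propensity(treatments, covariates=None, kind: str = "empirical_proportion",
                   known: Callable[[np.ndarray], np.ndarray] | None = None) -> PropensityModel:
    """Fit the treatment-assignment model.

    ``empirical_proportion`` returns the constant observed arm frequencies
    (appropriate for randomized designs); ``logistic``/``multinomial`` fit
    main-effects generalized linear models on the covariates; ``known`` wraps
    a user-supplied probability function unchanged.
    """
    A = np.asarray(treatments)
    arms = np.unique(A)
    if kind != "known" and len(arms) < 2:
        raise ValueError("at least two observed treatment arms are required")
    counts = np.array([(A == a).sum() for a in arms])
    if np.any(counts == 0):
        missing = arms[counts == 0]
        raise ValueError(f"treatment arm(s) with zero observations: {missing}")

    if kind == "empirical_proportion":
        freq = counts / counts.sum()
        return PropensityModel(kind, arms,
                               lambda X, f=freq: np.tile(f, (len(X), 1)))
    if kind in ("logistic", "multinomial"):
        X = np.asarray(covariates, dtype=float)
        # effectively unpenalized main-effects fit
        clf = LogisticRegression(C=1e10, solver="lbfgs", max_iter=2000)
        clf.fit(X, A)
        return PropensityModel(kind, arms, lambda Xq: clf.predict_proba(np.asarray(Xq, float)))
    if kind == "known":
        if known is None:
            raise ValueError("kind='known' requires the `known` probability function")
        return PropensityModel(kind, arms, known)
    raise ValueError(f"unknown propensity kind: {kind!r}")


class _OLS:
    """Minimal fit/predict OLS used as the default pluggable regressor."""

    def fit(self, X, y):
        self._lr = LinearRegression().fit(X, y)
        return self

    def predict(self, X):
        return self._lr.predict(X)


def fit_outcome_model(pseudo_values, treatments, covariates,
                      kind: str = "linear",
                      regressor_factory: Callable[[], object] | None = None) -> OutcomeModel:
    """Fit per-arm outcome regressions of the pseudo-response on covariates.

    One model per observed arm.  An arm must contain at least p + 1 rows for
    the default linear fit to be identified.
    """
    Y = np.asarray(pseudo_values, dtype=float)
    A = np.asarray(treatments)
    X = np.asarray(covariates, dtype=float)
    if len(Y) != len(A) or len(Y) != len(X):
        raise ValueError("pseudo, treatments and covariates must align")
    arms = np.unique(A)
    factory = regressor_factory if regressor_factory is not None else _OLS
    models = {}
    for a in arms:
        m = A == a
        if kind == "linear" and m.sum() < X.shape[1] + 1:
            raise ValueError(
                f"arm {a!r} has {int(m.sum())} rows, fewer than p+1={X.shape[1] + 1}")
        models[a] = factory().fit(X[m], Y[m])
    return OutcomeModel(kind="linear" if regressor_factory is None else "pluggable_regressor",
                        arms=arms, models=models)


def ipw_contrast(pseudo_values, treatments, prop: PropensityModel,
                 covariates=None) -> ContrastVector:
    """Inverse-probability-weighted contrast {A/pi_1 - (1-A)/(1-pi_1)} Y."""
    Y = np.asarray(pseudo_values, dtype=float)
    A = np.asarray(treatments, dtype=float)
    X = np.zeros((len(Y), 1)) if covariates is None else np.asarray(covariates, float)
    pi1 = prop.predict_arm(X, 1)
    c = (A / pi1 - (1.0 - A) / (1.0 - pi1)) * Y
    return ContrastVector(contrast=c, scheme="ipw")


def dr_mu(pseudo_values, treatments, prop: PropensityModel,
          outcome: OutcomeModel, arm, covariates=None) -> np.ndarray:
    """Elementwise AIPW estimate of mu_arm(H_i).

    I(A=a)/pi_a * Y + {1 - I(A=a)/pi_a} * mu_a_hat(H): the inverse-weighted
    response for subjects observed on the arm, augmented by the outcome-model
    prediction for everyone.
    """
    Y = np.asarray(pseudo_values, dtype=float)
    A = np.asarray(treatments)
    X = np.zeros((len(Y), 1)) if covariates is None else np.asarray(covariates, float)
    ind = (A == arm).astype(float)
    pi_a = prop.predict_arm(X, arm)
    mu_hat = outcome.predict(arm, X)
    w = ind / pi_a
    return w * Y + (1.0 - w) * mu_hat


def dr_contrast(pseudo_values, treatments, prop: PropensityModel,
                outcome: OutcomeModel, covariates=None) -> ContrastVector:
    """Doubly-robust contrast mu_1^DR(H) - mu_0^DR(H)."""
    c = (dr_mu(pseudo_values, treatments, prop, outcome, 1, covariates)
         - dr_mu(pseudo_values, treatments, prop, outcome, 0, covariates))
    return ContrastVector(contrast=c, scheme="dr")
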