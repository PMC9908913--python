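"""Rule learning with three or more treatment arms.

With L >= 3 arms the binary contrast no longer exists; instead the per-arm
mean outcomes mu_a(H) are ordered per subject, mu_(1) <= ... <= mu_(L), and
the rule is learned either by

* a one-versus-one decomposition: all L(L-1)/2 pairwise weighted binary
  rules with weight |mu_a - mu_b| and majority vote, or
* a bounded sub-optimality scheme: a weighted best-arm classification
  whose per-subject weight is the gap between the best arm and the
  runner-up (the lower bound of the loss from a wrong assignment) or
  between the best and the worst arm (the upper bound).  The chain
  0 <= mu_(L) - mu_(L-1) <= mu_(L) - mu_(a) <= mu_(L) - mu_(1) guarantees
  the two weights bracket the true loss of any sub-optimal assignment.

Per-arm Q-values can be supplied from a doubly-robust (AIPW with multinomial
propensities) or plain IPW construction; the ``q_values_*`` helpers build
both.  At L = 2 every scheme collapses to the binary pipeline and produces
decision-identical rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

import numpy as np

from .contrast import ContrastVector, OutcomeModel, PropensityModel
from .rule_learner import LinearRule, ScadSpec, fit_rule, select_lambda

logger = logging.getLogger(__name__)

__all__ = [
    "TreatmentOrdering",
    "MultiArmRule",
    "order_arms",
    "bound_weights",
    "q_values_dr",
    "q_values_ipw",
    "fit_multiclass_rule",
]


@dataclass
class TreatmentOrdering:
    """Per-subject ordering of the estimated per-arm mean outcomes.

    ``sorted_values[i]`` is nondecreasing; ``order_index[i, r]`` is the arm
    code holding rank r (rank L-1 = best).  Ties rank the lower arm code
    lower, so an all-equal row names the highest arm code best.
    """

    arms: np.ndarray               # arm codes, shape (L,)
    sorted_values: np.ndarray      # shape (n, L), nondecreasing rows
    order_index: np.ndarray        # shape (n, L), arm codes by rank

    @property
    def best_arm(self) -> np.ndarray:
        return self.order_index[:, -1]

    @property
    def runner_up_arm(self) -> np.ndarray:
        return self.order_index[:, -2]


def order_arms(q_values: np.ndarray, arms=None) -> TreatmentOrdering:
    """Sort per-subject Q-values with deterministic tie handling."""
    Q = np.atleast_2d(np.asarray(q_values, dtype=float))
    n, L = Q.shape
    if L < 2:
        raise ValueError("at least two arms are required")
    arms = np.arange(L) if arms is None else np.asarray(arms)
    # stable sort on values; ties keep column order, i.e. lower arm code first
    rank = np.argsort(Q, axis=1, kind="stable")
    return TreatmentOrdering(arms=arms,
                             sorted_values=np.take_along_axis(Q, rank, axis=1),
                             order_index=arms[rank])


def bound_weights(ordering: TreatmentOrdering,
                  bound: Literal["lower", "upper"] = "lower") -> np.ndarray:
    """Per-subject classification weight from the ordered Q-values.

    "lower": gap between the best arm and the runner-up; "upper": gap
    between the best and the worst arm.  Always 0 <= lower <= upper.
    """
    sv = ordering.sorted_values
    if bound == "lower":
        return sv[:, -1] - sv[:, -2]
    if bound == "upper":
        return sv[:, -1] - sv[:, 0]
    raise ValueError(f"unknown bound {bound!r}")


def q_values_dr(pseudo_values, treatments, prop: PropensityModel,
                outcome: OutcomeModel, covariates) -> np.ndarray:
    """Per-arm AIPW Q-value matrix (n, L): I(A=a)/pi_a Y + (1 - I/pi_a) mu_a."""
    Y = np.asarray(pseudo_values, dtype=float)
    A = np.asarray(treatments)
    X = np.asarray(covariates, dtype=float)
    cols = []
    for a in prop.arms:
        ind = (A == a).astype(float)
        pi_a = prop.predict_arm(X, a)
        mu = outcome.predict(a, X)
        w = ind / pi_a
        cols.append(w * Y + (1.0 - w) * mu)
    return np.column_stack(cols)


def q_values_ipw(pseudo_values, treatments, prop: PropensityModel,
                 covariates) -> np.ndarray:
    """Per-arm plain IPW Q-value matrix (n, L): I(A=a)/pi_a Y."""
    Y = np.asarray(pseudo_values, dtype=float)
    A = np.asarray(treatments)
    X = np.asarray(covariates, dtype=float)
    cols = []
    for a in prop.arms:
        cols.append((A == a).astype(float) / prop.predict_arm(X, a) * Y)
    return np.column_stack(cols)


@dataclass
class MultiArmRule:
    """Fitted multi-arm decision rule.

    ``scheme`` "ovo_svm": majority vote over pairwise rules (vote ties go to
    the lowest arm code); "bound_lower"/"bound_upper": per-arm best-vs-rest
    scores decided by argmax (score ties to the lowest arm code).
    """

    scheme: str
    arms: np.ndarray
    pairwise: dict = field(default_factory=dict)   # (a, b) -> LinearRule, + action b
    per_arm: dict = field(default_factory=dict)    # a -> LinearRule (best-vs-rest)
    binary: LinearRule | None = None               # L == 2 collapse

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(X)
        if self.binary is not None:
            dec = self.binary.decide(X)
            return np.where(dec == 1, self.arms[1], self.arms[0])
        if self.scheme == "ovo_svm":
            votes = np.zeros((n, len(self.arms)), dtype=int)
            arm_pos = {a: j for j, a in enumerate(self.arms)}
            for (a, b), rule in self.pairwise.items():
                pick_b = rule.decide(X) == 1
                votes[np.arange(n), np.where(pick_b, arm_pos[b], arm_pos[a])] += 1
            # argmax returns the first (lowest-code) arm on vote ties
            return self.arms[np.argmax(votes, axis=1)]
        scores = np.column_stack([self.per_arm[a].decision_value(X) for a in self.arms])
        return self.arms[np.argmax(scores, axis=1)]


def fit_multiclass_rule(features, q_values, scheme: str = "ovo_svm",
                        scad: ScadSpec | None = None, arms=None,
                        folds: int = 0, rng=None) -> MultiArmRule:
    """Fit a multi-arm rule from per-subject Q-values.

    ``scheme`` is "ovo_svm" (one-versus-one on pairwise gaps), "bound_lower"
    or "bound_upper" (best-vs-rest with the bounded sub-optimality weights).
    ``scad`` defaults to an unpenalized fit; with ``folds >= 2`` the penalty
    is tuned per subproblem.  At L = 2 all schemes reduce to a single binary
    fit and are decision-identical to the two-arm pipeline.
    """
    X = np.asarray(features, dtype=float)
    Q = np.atleast_2d(np.asarray(q_values, dtype=float))
    n, L = Q.shape
    arms = np.arange(L) if arms is None else np.asarray(arms)
    if len(arms) != L:
        raise ValueError("arms must match the Q-value columns")
    scad = scad if scad is not None else ScadSpec(lam=0.0)
    rng = np.random.default_rng(rng)

    def _fit_binary(contrast_arr):
        cv = ContrastVector(contrast=np.asarray(contrast_arr, float), scheme="dr")
        spec = scad
        if folds >= 2:
            lam = select_lambda(X, cv, scad, folds=folds, rng=rng)
            spec = ScadSpec(lam=lam, gamma=scad.gamma)
        return fit_rule(X, cv, spec)

    if L == 2:
        rule = _fit_binary(Q[:, 1] - Q[:, 0])
        return MultiArmRule(scheme=scheme, arms=arms, binary=rule)

    if scheme == "ovo_svm":
        pairwise = {}
        for ja, jb in combinations(range(L), 2):
            # positive label and positive action mean "choose the later arm b"
            pairwise[(arms[ja], arms[jb])] = _fit_binary(Q[:, jb] - Q[:, ja])
        return MultiArmRule(scheme=scheme, arms=arms, pairwise=pairwise)

    if scheme in ("bound_lower", "bound_upper"):
        ordering = order_arms(Q, arms)
        w = bound_weights(ordering, bound=scheme.removeprefix("bound_"))
        per_arm = {}
        for j, a in enumerate(arms):
            z = np.where(ordering.best_arm == a, 1.0, -1.0)
            per_arm[a] = _fit_binary(w * z)
        return MultiArmRule(scheme=scheme, arms=arms, per_arm=per_arm)

    raise ValueError(f"unknown scheme {scheme!r}")
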