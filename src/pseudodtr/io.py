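"""Delimited-text readers/writers and rule serialization.

File conventions
----------------
* Subject-level survival table: columns ``id,time,cause,<covariates>``;
  cause 0 means censored.  Comment lines start with ``#``.
* Long-format stage panel: one row per subject with columns
  ``id,time,cause`` followed by per-stage groups ``eta_k,a_k,x_k_*``
  (k = 1..K).  Stage-k history features are assembled as the concatenation
  of all earlier stages' covariates and treatments plus the stage's own
  covariates.
* Fitted regimes: a JSON document with one entry per stage (feature names,
  intercept, coefficients, positive action) plus the objective and the
  configuration echo.

Every writer emits a ``#``-comment header carrying the package version, the
full configuration echo and the seed, so a run can be reproduced
byte-for-byte from its own output.
"""

from __future__ import annotations

import json
import re
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dtr import DtrFit, Stage, StagePanel
from .rule_learner import LinearRule

__all__ = [
    "read_survival_table",
    "write_table",
    "read_panel",
    "write_panel",
    "save_rules",
    "load_rules",
]


def _header_lines(config: dict | None) -> list[str]:
    lines = [f"# pseudodtr version = {__version__}"]
    for key in sorted((config or {})):
        lines.append(f"# {key} = {config[key]}")
    return lines


def write_table(df: pd.DataFrame, path, config: dict | None = None) -> None:
    """Write a delimited table with a reproducibility comment header."""
    with open(path, "w") as fh:
        for line in _header_lines(config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def read_survival_table(path, time_col: str = "time", cause_col: str = "cause",
                        id_col: str = "id"):
    """Read a subject-level survival table.

    Returns ``(df, times, causes, covariate_matrix, covariate_names)``;
    every column other than id/time/cause is treated as a covariate.
    """
    df = pd.read_csv(path, comment="#")
    for col in (time_col, cause_col):
        if col not in df.columns:
            raise KeyError(f"required column {col!r} not found in {path}")
    cov_names = [c for c in df.columns if c not in (id_col, time_col, cause_col)]
    times = df[time_col].to_numpy(dtype=float)
    causes = df[cause_col].to_numpy(dtype=int)
    X = df[cov_names].to_numpy(dtype=float) if cov_names else np.empty((len(df), 0))
    return df, times, causes, X, cov_names


_STAGE_COV = re.compile(r"^x_(\d+)_(.+)$")


def write_panel(time, cause, stage_covariates: Sequence[np.ndarray],
                treatments: Sequence[np.ndarray], at_risk: Sequence[np.ndarray],
                path, config: dict | None = None,
                covariate_names: Sequence[list[str]] | None = None) -> None:
    """Write a long-format stage panel.

    ``stage_covariates[k]`` holds stage k+1's *own* covariates (not the
    accumulated history); the reader reassembles histories.
    """
    n = len(time)
    out = {"id": np.arange(n), "time": time, "cause": cause}
    for k, (X, A, eta) in enumerate(zip(stage_covariates, treatments, at_risk), start=1):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        out[f"eta_{k}"] = np.asarray(eta, dtype=int)
        out[f"a_{k}"] = np.asarray(A, dtype=int)
        names = (covariate_names[k - 1] if covariate_names
                 else [str(j + 1) for j in range(X.shape[1])])
        for j, name in enumerate(names):
            out[f"x_{k}_{name}"] = X[:, j]
    write_table(pd.DataFrame(out), path, config)


def read_panel(path):
    """Read a long-format panel; returns (times, causes, stages, df).

    Stage-k history features are the concatenation of stages 1..k-1's
    covariates and treatments plus stage k's covariates, matching the
    engine's default history layout.
    """
    df = pd.read_csv(path, comment="#")
    times = df["time"].to_numpy(dtype=float)
    causes = df["cause"].to_numpy(dtype=int)
    stage_ids = sorted({int(m.group(1)) for c in df.columns
                        for m in [_STAGE_COV.match(c)] if m})
    if not stage_ids or stage_ids != list(range(1, len(stage_ids) + 1)):
        raise ValueError("panel must contain contiguous stage groups x_1_*, x_2_*, ...")

    stages = []
    hist_blocks: list[np.ndarray] = []
    hist_names: list[str] = []
    for k in stage_ids:
        cov_cols = [c for c in df.columns
                    for m in [_STAGE_COV.match(c)] if m and int(m.group(1)) == k]
        Xk = df[cov_cols].to_numpy(dtype=float)
        eta = (df[f"eta_{k}"].to_numpy(dtype=int) if f"eta_{k}" in df
               else np.ones(len(df), dtype=int))
        A = df[f"a_{k}"].to_numpy(dtype=int)
        features = np.column_stack(hist_blocks + [Xk]) if hist_blocks else Xk
        names = hist_names + cov_cols
        stages.append(Stage(at_risk=eta, treatment=A, features=features,
                            feature_names=list(names)))
        hist_blocks += [Xk, A[:, None].astype(float)]
        hist_names += cov_cols + [f"a_{k}"]
    return times, causes, stages, df


def save_rules(fit: DtrFit, path, feature_names: Sequence[list[str]] | None = None,
               config: dict | None = None) -> None:
    """Serialize a fitted regime to structured text (JSON)."""
    doc = {
        "version": __version__,
        "objective": fit.objective,
        "config": {k: str(v) for k, v in sorted((config or {}).items())},
        "stages": [],
    }
    for k, rule in enumerate(fit.rules, start=1):
        names = (feature_names[k - 1] if feature_names
                 else [f"h{j}" for j in range(len(rule.coefficients))])
        diag = fit.diagnostics[k - 1] if fit.diagnostics else {}
        doc["stages"].append({
            "stage": k,
            "feature_names": list(names),
            "intercept": rule.intercept,
            "coefficients": list(map(float, rule.coefficients)),
            "positive_action": rule.positive_action,
            "lambda": diag.get("lambda"),
            "n_at_risk": diag.get("n_at_risk"),
        })
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_rules(path) -> DtrFit:
    with open(path) as fh:
        doc = json.load(fh)
    rules = [LinearRule(intercept=float(s["intercept"]),
                        coefficients=np.asarray(s["coefficients"], dtype=float),
                        positive_action=int(s["positive_action"]))
             for s in sorted(doc["stages"], key=lambda s: s["stage"])]
    return DtrFit(rules=rules, objective=doc["objective"])
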