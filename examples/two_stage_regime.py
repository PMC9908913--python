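"""Backward induction over two treatment stages (survival endpoint).

Generates the two-stage randomized survival scenario (n = 500, 15%
censoring), fits the full penalized doubly-robust pipeline by backward
induction and evaluates the regime on fresh test data: the fraction of
subjects receiving the truly optimal action at stage 1 (CDR1) and at both
stages (ACDR), and the true 3-year survival the fitted regime attains
(optimum ~0.66; never/always-treat reach only ~0.53/0.34).
"""

from pseudodtr import (ScenarioSpec, attach_pseudo, evaluate_regime, fit_dtr,
                       generate, method_config, objective_for)

spec = ScenarioSpec("s1_survival", n=500, censor_target=0.15, seed=42)
data = generate(spec)
panel = attach_pseudo(data)

config = method_config("pdwl", seed=42, lambda_grid_size=8)
fit = fit_dtr(panel, objective_for(spec), config)

for k, diag in enumerate(fit.diagnostics, start=1):
    print(f"stage {k}: lambda={diag['lambda']:.4f} "
          f"at-risk={diag['n_at_risk']} "
          f"nonzero coefficients={diag['n_nonzero_coefficients']}")

metrics = evaluate_regime(fit, spec, n_test=50_000, rng=0, data=data)
print(f"stage-1 correct decision rate (CDR1): {metrics.cdr1:.3f}")
print(f"both-stage correct decision rate (ACDR): {metrics.acdr:.3f}")
print(f"true 3-year survival under the fitted regime: "
      f"{metrics.value_at_horizon:.3f}")
print(f"IPW estimate of the same value from the training sample: "
      f"{metrics.empirical_value:.3f}")
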