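"""Two-stage regime minimizing a competing-risks cumulative incidence.

The endpoint is the 3-year cumulative incidence of the cause-1 event
(lower is better), so the pipeline uses cause-1 CIF pseudo-observations
and negates the treatment contrasts before classification.  The fitted
regime is evaluated against the true optimal threshold rules; the optimal
3-year cause-1 incidence is ~0.23 while never-treating incurs ~0.43.
"""

from pseudodtr import (ScenarioSpec, attach_pseudo, evaluate_constant_regime,
                       evaluate_regime, fit_dtr, generate, method_config,
                       objective_for)

spec = ScenarioSpec("s1_competing", n=500, censor_target=0.15, seed=7)
panel = attach_pseudo(generate(spec))
fit = fit_dtr(panel, objective_for(spec),
              method_config("pdwl", seed=7, lambda_grid_size=8))

metrics = evaluate_regime(fit, spec, n_test=50_000, rng=0)
never = evaluate_constant_regime(0, spec, n_test=50_000, rng=0)

print(f"objective: {fit.objective} (cause-1 incidence, lower is better)")
print(f"fitted regime:   F1(3) = {metrics.value_at_horizon:.3f}, "
      f"CDR1 = {metrics.cdr1:.3f}, ACDR = {metrics.acdr:.3f}")
print(f"never treat:     F1(3) = {never.value_at_horizon:.3f}")
print("the fitted rules should recover most of the gap between the "
      "never-treat incidence and the ~0.23 optimum")
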