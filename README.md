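# pseudodtr

Optimal (dynamic) treatment regimes for censored time-to-event outcomes.

Clinicians treating chronic disease choose therapies sequentially, and the
best choice at each decision point can depend on a patient's covariates.
Estimating such individualized rules from trial or cohort data is hard when
the outcome is a censored survival time or a competing-risks event: the
response of interest — e.g. the 3-year survival indicator I(T > t) or the
cause-1 incidence indicator I(T ≤ t, D = 1) — is not observed for censored
subjects. `pseudodtr` is a toolkit for biostatisticians that handles the
censoring by **jackknife pseudo-observations** and then learns sparse,
interpretable linear decision rules by **doubly-robust weighted
classification**.

## Method

For a functional θ = E[s(T)] with nonparametric estimator θ̂ (Kaplan–Meier
for survival, Aalen–Johansen for a cause-specific cumulative incidence,
restricted-mean integration), each subject receives the pseudo-response

    Y_i = n·θ̂ − (n−1)·θ̂^(−i),

an (asymptotically) unbiased substitute for s(T_i) that complete-data
machinery can regress on. Given arms A ∈ {0,1}, the conditional contrast
C(H) = μ₁(H) − μ₀(H) is estimated per subject by augmented
inverse-probability weighting,

    μ̂ₐ^DR(H) = I(A=a)/π̂ₐ(H) · Y + {1 − I(A=a)/π̂ₐ(H)} · μ̂ₐ(H),

which is consistent if either the propensity model π̂ₐ or the outcome
(Q-)model μ̂ₐ is correct. The optimal rule g(H) = I(Hᵀβ > 0) minimizes the
weighted misclassification error with weights w_i = |Ĉ_i| and labels
Z_i = sign(Ĉ_i); it is fitted through a weighted hinge loss with a SCAD
penalty (γ = 3.7) for variable selection, linearized once around an
L2-SVM start and solved exactly as a linear program in split variables.
Multi-stage regimes are estimated by backward induction: at each stage the
running value vector Ṽ_{k+1} plays the role of the response, the fitted
stage rule is applied, and the value is propagated as
Ṽ_k = Ṽ_{k+1} ± η_k |μ̂₁k − μ̂₀k| · I{ĝ_k ≠ A_k} (added for survival,
subtracted when minimizing a cumulative incidence). Three or more arms are
handled by ordering per-arm Q-values and one-versus-one (or bounded
sub-optimality) weighted classification.

The package also ships the synthetic study scenarios used to validate all
of this end to end (two-stage survival, two-stage competing risks,
observational propensities, three-arm single stage), with calibrated
censoring, known optimal rules and potential-outcome evaluation.

## Worked example

`examples/two_stage_regime.py` fits the full pipeline (pseudo-observations
→ AIPW contrasts → SCAD-penalized LP classifier → backward induction) on
one simulated two-stage trial (n = 500, 15% censoring) and evaluates it on
fresh data:

```
stage 1: lambda=0.0174 at-risk=500 nonzero coefficients=8
stage 2: lambda=0.0044 at-risk=455 nonzero coefficients=12
stage-1 correct decision rate (CDR1): 0.894
both-stage correct decision rate (ACDR): 0.816
true 3-year survival under the fitted regime: 0.644
IPW estimate of the same value from the training sample: 0.668
```

CDR1/ACDR are the fractions of 50,000 fresh subjects whose stage-1 /
both-stage decisions match the true optimal thresholds; 0.644 is the
3-year survival the fitted regime attains in the generative model, against
an optimum of ~0.66 and ~0.53 for never treating. The other scripts in
`examples/` each exercise one capability (pseudo-observations, single-stage
rules with variable selection, competing risks, three arms, method
comparison) and print a short interpretation with their numbers.

A thin CLI mirrors the library for shell use:

```bash
pseudodtr simulate --scenario s1_survival --n 500 --seed 1 --output panel.csv
pseudodtr fit --input panel.csv --horizon 3 --method pdwl --output-rules rules.json
pseudodtr pseudo --input cohort.csv --horizon 3 --output with_pseudo.csv
```

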