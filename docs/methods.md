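# Methods

This note documents the statistical conventions, tunable parameters and
design decisions behind `pseudodtr`, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pseudo-observations

The package estimates θ = E[s(T)] for three functionals of the event time:
t-year survival s(T) = I(T > t), t-year cause-d cumulative incidence
s(T) = I(T ≤ t, D = d), and the τ-restricted mean s(T) = min(T, τ). Each
subject's pseudo-observation is the jackknife quantity
Y_i = n θ̂ − (n−1) θ̂^(−i), built on the Kaplan–Meier, Aalen–Johansen or
integrated-KM estimator respectively.

Conventions:

- Survival is the right-continuous P(T > t). With continuous simulated
  times the distinction from P(T ≥ t) is measure-zero; on real data with
  ties the choice matters and is documented here once.
- At tied times deaths precede censorings (standard product-limit risk-set
  convention).
- Pseudo-values are **not** clipped to [0, 1]. Values slightly outside the
  unit interval are intrinsic to the jackknife and are what make the
  complete-data identity (pseudo-value = event indicator when there is no
  censoring) exact.
- Two computational routes exist for every functional: a literal O(n²)
  refit (the reference oracle) and a vectorised risk-set-update route used
  by default (prefix-sum corrections of the log-survivor for the survival
  curve; an n×m matrix construction for the cumulative incidence and the
  restricted mean). Their elementwise equality to 1e-10 is a tested
  invariant, and log-factors are floored at −745 so that a survivor curve
  hitting exactly zero stays representable.

IPCW-adjusted variants for covariate-dependent censoring implement both
the normalised ("weighted") and the unnormalised ("direct") form of the
inverse-censoring-weighted survival estimator. The censoring survivor
Ĝ(u|x) comes from a marginal KM with the censoring indicator as the event,
or a Cox model fitted by lifelines (Efron tie handling, Breslow baseline —
lifelines' convention, adopted as ours). Ĝ is fitted once on the full
sample and held fixed across leave-one-out replicates; it is floored at
0.05 before inversion and the number of clipped weights is logged. With no
censoring both variants coincide exactly with the plain jackknife.

## Contrasts and rule learning

Propensities default to the empirical arm proportion (randomized designs)
or a main-effects logistic/multinomial model (observational mode), with
probabilities truncated to [0.01, 0.99] as a positivity guard. Outcome
(Q-)models are ordinary least squares fitted separately within each arm;
any regressor with fit/predict can be plugged in. Zero-contrast subjects
receive label +1 by convention and zero weight, so they cannot influence
the classifier.

The decision rule g(H) = I(β₀ + Hᵀβ > 0) is strict at the boundary (f = 0
maps to action 0). Fitting minimizes n⁻¹ Σ w_i [1 − Z_i f(H_i)]₊ +
Σ_j P_λ(|β_j|) with the SCAD penalty (γ = 3.7, the conventional value; λ
is per-sample because the 1/n factor stays on the loss). One local linear
approximation step around an L2-SVM anchor converts the problem to a
weighted-L1 LP in split variables, solved by HiGHS with a fixed variable
ordering. The intercept is unpenalized. Features are standardized
internally (so one λ is comparable across covariates) and coefficients
back-transformed. Degenerate LP optima can differ between solvers, so all
comparisons downstream are on objectives and decisions, never raw
coefficients. The L2 anchor uses libsvm at tolerance 1e-7 with a 200k
iteration cap and anchor weights normalized to mean one; the anchor only
seeds the LLA penalty weights P′_λ(|β_j⁽⁰⁾|), so these conditioning
choices do not alter the estimand.

**λ selection.** The default grid is 20 log-spaced points (8 in the
replicated benchmarks, for runtime) spanning [1e-4, 1] times the largest
standardized weighted margin gradient at β = 0. Cross-validation scores
each λ by the held-out *plug-in value* Σ_i Ĉ_i g(H_i) of the candidate
rule; ties go to the larger (sparser) λ. We deliberately do not use the
held-out weighted label agreement Σ w_i I{Z_i = g_i}: with noisy contrasts
the label class carrying more |Ĉ| mass wins that criterion regardless of
covariates, so a constant rule is systematically favoured whenever one
action is better on average — which is the typical case at stage 1. The
signed criterion lets the contrast noise cancel and is an unbiased
estimate (up to a constant) of the rule's value.

## Backward induction

At stage k (walking K → 1), the doubly-robust stage contrast uses the
running value Ṽ_{k+1} as the response, with per-arm Q-models fitted on the
at-risk rows (η_k = 1). For the competing-risks objective the contrast is
negated before the weight/label split, so the classifier minimizes the
incidence (justified by the symmetry of the weighted misclassification
objective in the contrast's sign). The value recursion is

    Ṽ_k = Ṽ_{k+1} ± η_k · |μ̂_{1k} − μ̂_{0k}| · I{ĝ_k ≠ A_k},

i.e. the regret magnitude is the **Q-model difference**, not the
subject-level DR contrast. The two candidates coincide in expectation, but
the DR contrast carries the inverse-weighted response noise; propagating
its absolute value injects that noise into every earlier stage's response
and measurably destabilizes stage-1 learning (the weighted hinge then
collapses to a constant rule in a sizable fraction of replicates). The
Q-model difference is smooth and small, keeps the recursion monotone by
construction, and is the form that reproduces the expected benchmark
behaviour. Q-models are fitted at every stage even under the IPW weighting
schemes, because the value recursion needs them regardless of how the
classification weights are built. Off-study subjects (η_k = 0) pass their
value through unchanged and are excluded from stage-k fitting.

The four comparator configurations are degenerations of one code path:
OWL (IPW weights, λ = 0), POWL (IPW + SCAD), DWL (DR, λ = 0), PDWL
(DR + SCAD). Per-stage λ is tuned independently.

With L ≥ 3 arms, per-arm Q-values are the arm-wise AIPW (or plain IPW)
scores with multinomial propensities. The one-versus-one scheme fits all
pairwise rules with weights |μ̂_a − μ̂_b| and votes (ties → lowest arm
code); the bounded schemes weight a best-arm-vs-rest problem by the gap to
the runner-up (lower bound) or to the worst arm (upper bound) and decide
by argmax of the per-arm scores. At L = 2 every scheme reduces to the
binary path and is decision-identical. Multi-stage composition with L ≥ 3
is supported by feeding the bound weights into the stage loop, but only
the single-stage case is exercised by the shipped scenarios.

## Synthetic scenarios

The generators implement the two-stage randomized survival design, its
competing-risks counterpart, the observational variants and the three-arm
single-stage design described in the module docstring of
`pseudodtr.simdata`. Shared conventions:

- Exponential censoring C ~ Exp(c₀) with c₀ calibrated by bisection of the
  Monte Carlo censored fraction (probe size 200,000, fixed probe seed,
  tolerance 0.005, cached per scenario).
- The stage-2 covariate is Uniform on the *realized* per-dataset range of
  the first stage-1 covariate (the literal reading of its definition).
- Identical spec + seed gives byte-identical data.

**Survival scenario.** η₂ = I(T₁ < C) literally, including the printed
adjustment of the terminal time for η₂ = 0 subjects. Under this mechanism
the stage-2 transfer fraction is ≈90% at the 15% censoring calibration and
≈79% at 30%; the documented "about 80%" figure corresponds to the 30%
calibration, and that is where the package's checks test it.

**Regime value.** `evaluate_regime` assigns treatments by the candidate
rules *inside the generative model* (fresh draw; no reweighting). For the
survival scenarios this includes the η₂ transfer dynamics at the
scenario's calibrated censoring rate — the convention under which the true
optimal rules attain S(3) ≈ 0.65 and the non-myopic stage-1 threshold
0.484 (rather than the myopic 0.5) is actually optimal; a static
evaluation that ignores the transfer dynamics gives ≈0.634 under the same
rules and makes 0.5 the stage-1 optimum. A consequence worth knowing: the
never/always-treat reference values under the dynamic evaluation are
≈0.53/0.34, about 0.03 higher than under the static one, and fitted
near-optimal regimes score ≈0.64–0.65 rather than ≈0.61. For the
competing-risks scenario the value is the closed-form subdistribution
incidence E[F₁(3 | x, g₁(x), g₂(x))] averaged over a fresh covariate draw
— the quantity for which the optimal rules attain ≈0.234 and never-treat
≈0.43.

**Competing-risks mechanism.** The printed-recipe transfer rule is
circular (the stage-2 treatment enters the candidate time that decides the
transfer), and the choice matters. We examined four implementations by
simulation: deciding η₂ from the full-model candidate reproduces a ~44.6%
observed cause-1 fraction but makes η₂ depend on A₂, and the induced
selection *exactly cancels* the within-transfer arm contrast — the stage-2
rule becomes unlearnable; shared-uniform couplings zero the contrast on
one side of the true threshold; cause-first redraws of the conditional
time only leave a near-nil timing channel. The adopted mechanism — the
subject realizes a stage-1 (A₂-free) outcome, transfers if that event
falls before the horizon, and transferred subjects redraw cause and time
from the full model with fresh randomness — keeps the transfer decision
causally prior to A₂, yields a strong two-sided stage-2 contrast, and
reproduces observed cause-1 fractions of ≈42% (15% censoring) and ≈40%
(30%) with ≈42% of subjects both transferring and failing from cause 1.
The subdistribution uses the internally consistent exponent convention
P(D=1) = 1 − (1−q)^{1/ψ₁}, F₁(t) = 1 − {1 − q(1−e^{−t})}^{1/ψ₁} (the
`fine_gray_exponent="direct"` flag switches to the ψ convention, under
which the documented optimal-rule directions invert and censoring cannot
be calibrated — retained only for study).

**What the generators do not emulate.** Real registries have
non-exponential, covariate-dependent censoring, measurement error,
missing covariates and staggered entry; passing the shipped checks shows
the estimator recovers the rules of these log-linear/subdistribution
mechanisms under calibrated censoring, not that it is robust to those
features. The IPCW machinery addresses covariate-dependent censoring but
no shipped scenario generates it.

## Problem sizes and runtime choices

The replicated benchmarks run 50 replicates of n = 500 with a reduced
8-point λ grid and 4-fold CV, evaluating each fit on 50,000 fresh
subjects; marginal checks use 200,000 draws. These sizes put every check
within a few minutes on a single core while keeping Monte Carlo error well
inside the asserted tolerances (regime-value MC error ≈0.002 at 50k;
replicate-mean standard errors ≈0.002–0.005 at 50 replicates).

## Known limitations

- Linear decision rules only; no kernelized or neural decision functions.
- Variance estimation for pseudo-value regressions and for the fitted
  value is out of scope; the benchmarks report across-replicate spread.
- The bounded multi-arm schemes are noticeably weaker than one-versus-one
  on the three-arm scenario; they are provided as the cheaper alternative,
  not the recommended default.
- Interval censoring and per-stage time-varying horizons are unsupported.
- The observational variants rely on a correctly specified main-effects
  logistic propensity at the first level of robustness; the "false"
  variant exists precisely to study that misspecification.
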