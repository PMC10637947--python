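# Methods

## The model

Sarcopenia status is treated as a continuous-time Markov process on four
states — 1 no sarcopenia, 2 possible sarcopenia, 3 sarcopenia (severe
sarcopenia merged in), 4 death — governed by a generator matrix Q whose
off-diagonal entries q_rs ≥ 0 are instantaneous per-year transition
intensities and whose diagonal is the negative row sum. Two assumptions are
built in: intensities are constant over follow-up time (time homogeneity),
and the future depends on the present state only (Markov property). Mutual
transitions are allowed among the three transient states, including the
direct 1↔3 pair; death is absorbing. A sensitivity structure adds loss to
follow-up as a second absorbing state 5.

Trajectories are panel-observed: states are seen only at survey waves
(default schedule 0, 2, 4 years), so the path between visits is
interval-censored. Each consecutive pair (t_i, r) → (t_{i+1}, s) contributes
P_rs(Δt) = [exp(ΔtQ)]_rs to the likelihood. Death times come from
registrations rather than visits, so by default an interval ending in death
contributes the event density

    Σ_{s' transient} P_{r s'}(Δt) · q_{s'4},

i.e. the state immediately before death is unknown but the death time is
exact. A flag restores purely panel-observed handling of absorbing events;
both modes are exercised in the tests, and the per-row `death_exact` column
lets a dataset mix the two (e.g. dropout events are never exact).

Covariates act proportionally on intensities,
q_rs(x) = q_rs⁰ · exp(β_rs·x), with hazard ratio exp(β_rs) per covariate
unit. Time-varying covariates enter piecewise-constant at the value observed
at the start of each interval. Continuous covariates are entered uncentered
so a hazard ratio reads "per one unit increase"; binary covariates are 0/1.
In the full covariate model every listed covariate acts on all
transient→transient transitions (spec string `"transient"`); transitions to
death can be given their own coefficient set via an explicit transition
list.

## Estimation

Parameters are the log-intensities (one per allowed transition — the log
scale enforces positivity without constraints) plus the β coefficients.
The likelihood is maximised with L-BFGS-B (a quasi-Newton method) using
finite-difference gradients; convergence tolerances `ftol = 1e−12`,
`gtol = 1e−7`, at most 500 iterations. Starting values are crude
events-per-person-year rates per transition, with 0.1 for transitions never
observed directly; log-intensities are loosely bounded in [−16, 5] and an
estimate at the lower bound is flagged as a boundary solution (the model is
then reported non-converged with partial estimates, not raised).

Standard errors come from the observed information: the Hessian of the
negative log-likelihood at the maximum, computed by numerical
differentiation (`statsmodels.tools.numdiff.approx_hess`), symmetrized and
inverted. Interval estimates:

* intensities — Wald on the log scale, q̂·exp(±1.96·SE(log q̂));
* sojourn times — delta method on the log scale: sojourn_r = 1/Σ_s q_rs with
  ∂ log sojourn / ∂ log q_rs = −q_rs/Σq, propagated through the covariance;
* transition probabilities P(t) — parametric bootstrap: draw parameter
  vectors from N(θ̂, Σ̂) (default 1000 draws, seeded), recompute P(t) per
  draw, take 2.5/97.5 percentiles. Fewer than 100 draws triggers a warning.

### Numerical notes

`transition_probability` uses `scipy.linalg.expm`. Inside the likelihood,
P(t) is needed at many interval lengths per evaluation (every registered
death has its own Δt), so the implementation diagonalises Q once and forms
all P(Δt) with one einsum, falling back to per-time `expm` whenever the
eigenbasis is ill-conditioned (reconstruction checked against row-sum and
non-negativity tolerances of 1e−8). Probabilities are floored at 1e−300
before taking logs so an impossible observed pattern yields a very large
finite penalty rather than a NaN for the optimizer. Duplicate observation
times within a subject are an error, as is any observation after an
absorbing state; subjects with a single visit are dropped with a count.

## Staging

The AWGS-2019 algorithm is applied per visit. Low muscle mass is
ASM/Ht² strictly below the sex cutoff (defaults 6.79 / 4.93 kg/m²; a
cohort-specific alternative takes the sex-specific 20th percentile,
linear-interpolation definition, requiring ≥ 25 values per sex). Low
strength is maximum grip strictly below 28 / 18 kg; grip is missing when
trials lacked full effort or the maximum falls outside the cohort's
[1st, 99th] percentile bounds (computed on baseline visits by default;
pooling across waves is configurable by passing explicit bounds). Low
performance is SPPB ≤ 9.

The published walk and chair-stand scoring bands are exhaustive only on a
discretized scale, so walking speeds are rounded to 2 decimals and chair
times to 1 decimal before band lookup — e.g. 16.65 s falls in the 2-point
chair band. This discretization is this package's choice; recorded-precision
conventions of the source instruments are not public. Balance scoring uses
only the recorded hold durations; a full-tandem hold of 0–2 s scores 2
points only when the semi-tandem stage was completed (held 10 s) or is
unrecorded, reflecting the hierarchical protocol.

Classification: no flags → state 1; low strength or low performance with
normal mass → state 2; low mass plus at least one functional flag → state 3
(all three low is severe sarcopenia, merged into state 3 but recorded in
`pre_merge_severe`). Low mass alone carries no AWGS label: such visits stay
in state 1 with a `low_mass_only` marker, matching the observation that a
sizeable minority of unstaged-healthy older adults have isolated low mass.
A visit missing any component is excluded with a logged reason — no
imputation.

## The synthetic cohort

`SimulationScenario` defaults are the study conditions: 2856 subjects,
waves at 0/2/4 years, initial state mix 52.7/35.7/11.6 %, the published
generator as truth, no dropout. Latent paths are simulated exactly by
competing exponential clocks; waves record the current state; death is
recorded at its exact event time; optional per-wave dropout truncates
observation. Covariates are drawn from the published baseline marginals
(female 48.4 %, rural 69.7 %, age 67.6 (6.1), BMI 22.7 (3.8), cognition
12.6 (5.7)) and act multiplicatively on intensities — deliberately the same
family the estimator assumes, because the recovery suites test estimator
correctness, not robustness to misspecification. The generator does not
emulate survey weights, household clustering, covariate correlation,
measurement error in staging, or informative dropout; passing recovery
tests therefore demonstrates correctness of the likelihood and optimizer
under the stated model, not robustness of the published estimates to
violations of it.

The staging fixture inverts the scoring rules: for each record a target
state is drawn, component flags consistent with it are chosen, and weight,
grip and walk/chair/balance measurements are solved to land on the intended
side of every cutoff with a safety margin larger than the rounding
discretization, so the classifier must recover the planted label exactly on
complete records.

## Validation scales

The test suite fits real sizes kept small enough for routine runs: oracle
equivalence uses 100 random 4-state generators and 100 random toy
trajectories; intensity recovery uses 20 cohorts of 2856 subjects (median
relative error per intensity below 15 %, 95 % Wald coverage ≥ 80 % over
transition × seed cells); hazard-ratio recovery uses 50 cohorts of 4000
subjects with a true hazard ratio of 1.5 on the progression 1→2 (mean β̂
within 0.05 of log 1.5, coverage ≥ 90 %). The closed-form check fits a
two-state chain where the maximum-likelihood intensity is −log(1 − k/n)
analytically.

## Known limitations

* Time-homogeneous intensities only; no semi-Markov or age-as-timescale
  variants, no frailty, no hidden-Markov misclassification layer.
* Finite-difference Hessians can fail to invert at boundary solutions; the
  model is then returned without a covariance matrix and flagged.
* The observed-vs-expected prevalence comparison conditions on subjects
  under observation at each evaluation time; with informative missingness
  it is a diagnostic, not a formal goodness-of-fit test.
* Percentile-based grip quality control is computed on the baseline wave by
  default; per-wave bounds must be supplied explicitly if wanted.
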