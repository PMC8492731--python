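# Methods

## The outcome model

The endpoint is binary pCR. For analyzed patient *i* the model is

    logit p_i = x_iᵀβ + θ_{arm(i)} + δ_{s(i)}(t_i)

where `x_i` holds an intercept and main effects for hormone-receptor status,
HER2 status and the MammaPrint class, `θ` is one additive log-odds effect
per experimental arm (the shared control carries none), `s(i)` is the
patient's HER2 stratum and `t_i` the 90-day calendar bin of their
randomization day, counted backwards from the analysis date (`t = 1` is the
most recent 0–90 days; a patient randomized 750 days back sits in bin 9,
day 0 maps to bin 1 by convention, and bin boundaries are half-open with the
ceiling rule). Patients who switch to non-protocol therapy, forgo surgery or
withdraw are imputed as non-pCR; a missing outcome without any deviation is
unevaluable and excluded with a logged count rather than imputed.

MammaPrint enters as the dichotomized Hi1/Hi2 class (cut at score < −0.573,
strict) rather than the continuous score: the platform defines subtypes and
signatures through the class, so the covariate and the signature predicates
stay on one scale. Optional arm×covariate interaction columns are available
behind a `build_model` flag for sensitivity analyses; the default additive
model is the smallest one that still yields arm-by-signature rates.
Covariate columns that are constant in the data (e.g. HER2 in a
HER2-negative-only trial) are dropped as collinear with the intercept.

## The time machine

Within each HER2 stratum the drift offsets follow a second-order NDLM:
δ(1..4) = 0 (the last year counts fully), δ(5) ~ N(μ₀, τ₀²),
δ(6) − δ(5) ~ N(μ₁, τ₁²), second differences ~ N(0, τ²) for t > 6, and
τ² ~ IG(α, β), with defaults μ₀ = μ₁ = 0, τ₀² = τ₁² = 0.001, α = 1,
β = 0.001. τ₀², τ₁² and τ² are variances, not standard
deviations. The two strata carry independent paths and independent τ². Drift
offsets are arm-agnostic: they apply to control and experimental patients
alike, which is what lets the model bridge eras. Offsets exist only for
bins that actually contain patients beyond the frozen window, so a trial
accruing entirely within the last 360 days collapses exactly to a plain
covariate logistic model.

Note the prior is deliberately tight at the hinge: δ(5) and the first slope
are pinned near zero (SD ≈ 0.032), while the IG(1, 0.001) tail lets τ² grow
when the data demand curvature further back. A "known drift" used in
calibration studies must respect this structure; the coverage study uses a
linear ramp starting at bin 7 (zero through bin 6), whose only nonzero
second difference is the ramp's kink.

## Priors and posterior computation

Non-drift coefficients get independent Normal(0, sd = 2) priors on the logit
scale — weakly informative for probabilities. Sampling is by
Metropolis-within-Gibbs with three ingredients:

* component-wise adaptive random-walk Metropolis on the coefficients (step
  sizes tuned toward 0.44 acceptance during warm-up, Robbins–Monro schedule,
  frozen afterwards);
* the drift path is sampled in its *innovation* parameterization
  e₁ = δ(5), e₂ = δ(6) − δ(5), e_k = second differences — a-priori
  independent coordinates, so single-site updates do not fight the near-unit
  correlation of neighboring δ's (δ = C·e with a fixed lower-triangular
  integration matrix);
* τ² by its conjugate inverse-gamma Gibbs update, followed by a joint
  rescale move of (τ², e₃…) along the funnel axis, whose acceptance ratio
  reduces to the likelihood change plus −α·Δlog τ² − β·Δ(1/τ²) because the
  innovation-prior terms cancel against the Jacobian.

Chains are seeded through `numpy.random.SeedSequence` spawning: the same
`SamplerConfig.seed` reproduces draws bit-for-bit. Default 4 chains, 500
warm-up and 1000 retained draws per chain; split-R̂ is computed for every
coefficient and log τ², and a warning (never a silent return) is raised when
any exceeds 1.05. Degenerate outcomes (all non-pCR) are handled by the
priors without numerical failure.

## Derived quantities and decision rules

Signature pCR rates are evaluated at current time (δ = 0) and averaged over
the covariate-profile mixture observed among patients in the signature —
a rate is a mixture of probabilities, not of logits. Superiority is the
fraction of joint posterior draws in which the arm's signature rate exceeds
control's. The predictive probability of phase-3 success treats each
posterior draw as the truth of a 300-patient 1:1 trial and computes the
success probability exactly by enumerating the joint binomial distribution
of pCR counts (151×151 grid at 150/arm); "success" is a one-sided
two-proportion pooled z-test at α = 0.025 — a conventional confirmatory
standard, configurable, since no specific test is mandated by the design
thresholds themselves. Graduation requires any signature's predictive
probability ≥ 0.85; futility requires all < 0.10; an accrual cap yields its
own stop state.

Adaptive randomization gives control exactly the 20% allocation; the
experimental share is split proportionally to the posterior probability of
being the best arm in the patient's subtype (per-draw argmax, ties split
equally), with an optional tempering exponent. This "probability best"
weighting is one concrete choice among the published descriptions of
response-adaptive allocation in this platform family.

## Signature scores

*IGF-1 ligand score*: gene-wise mean centering across the analyzed
population (configurable to median), per-gene Pearson correlation with IGF1,
ternary signs gated at a two-sided p ≤ 0.01 from the exact t transform with
n−2 df, then per-patient Pearson correlation between the sign vector and
centered expression over the signature genes — values lie in [−1, 1].
Zero-variance genes get sign 0 with a warning. *Creighton IGF-1R score*:
gene-wise median centering, per-patient slope t-statistic of expression
regressed on the published ±1 sign vector (computed through the correlation
identity t = r·√((m−2)/(1−r²))), negated, then z-scored to mean 0 / SD 1
over the population. Duplicate probes are collapsed by per-gene mean at
read time; the IGFBP5/IGFBP4 ratio is a difference on the log scale since
array data are log-scale. Tertile classification cuts at the empirical 1/3
and 2/3 quantiles with boundary ties absorbed into the lower group.

## Qualifying biomarker evaluation

Markers are standardized (mean 0, SD 1) before fitting for comparability
across the panel. M1/M2 test `pCR ~ marker` within each arm against the
intercept-only model; M3 tests `pCR ~ marker + Tx + marker×Tx` against the
model without the interaction; M1-2b/M3b add HR status. All tests are
likelihood-ratio chi-square on nested binomial GLMs; log-likelihoods are
computed from clipped fitted probabilities so (quasi-)separation degrades to
a flagged warning instead of a NaN, faithful to reporting the stated models
rather than switching to a penalized fit. No multiplicity adjustment is
applied, by design. The Fisher test uses the two-sided probability-mass
rule (sum of tables no more probable than observed), with an empty margin
returning p = 1 under a warning.

## HbA1c analysis

"Elevated" is strictly > 5.7% and the diabetic range strictly > 6.5% (a
subset of elevated); exactly 5.7 is normal. The analysis cohort requires a
baseline and at least one on-treatment measurement. A baseline-normal
patient "became elevated" if *any* on-treatment value exceeds 5.7; a
baseline-elevated patient "stayed elevated" only if *all* on-treatment
values do — the asymmetric any/all convention matches how the two
transitions are clinically read (incident vs persistent hyperglycemia).

## Synthetic-data generators

The trial generator draws covariates at HR-positive prevalence 0.535 and
MammaPrint-Hi2 prevalence 0.505 (the two arms' observed prevalences
averaged), HER2-negative-only by default (the eligibility rule), accrual
uniform over per-arm calendar windows (control 0–1800 days, experimental
850–1800, emulating a late-joining arm against a platform-lifetime control
pool), and outcomes from the logistic model with intercept −1.6, HR effect
−0.7, Hi2 effect +0.6 and experimental log-OR 0.4 — placing marginal pCR
rates near 22% (experimental) and 16–17% (control). About 3% of patients
carry a protocol deviation with a missing outcome. True drift is supplied
as per-bin offset arrays per stratum; `linear_ramp` builds the
prior-compatible ramp used in calibration.

The expression generator drives a signed ligand block (anchored by IGF1)
and a signed Creighton-like block (+364/−438 sign proportions) from one
latent factor; because the Creighton score negates the regression
t-statistic, the two recomputed scores come out negatively correlated, as
on real arrays. The HbA1c generator draws baselines Normal(5.4, 0.49)
truncated positive — median 5.4% with roughly a quarter above 5.7% — takes
the first on-treatment measurement at Normal(56, 16) days, and adds a
0.25-point treatment elevation with 0.15-point measurement noise; pCR is
drawn independently of glycemia at 22%.

What the generators do *not* emulate: microarray noise structure (probe
effects, batch, heteroscedasticity), correlated covariates, informative
dropout, non-uniform accrual, or era effects beyond the additive per-bin
offsets. Passing tests therefore show the algorithms are correct under the
assumed data-generating mechanisms, not that the clinical conclusions of
any real trial are reproduced.

## Problem sizes and numerical choices

Default fits use 4 chains × (500 warm-up + 1000–1500 draws), which this
sampler completes in seconds at n ≈ 230–400. The equivalence check compares
10,000-draw posteriors (KS distance bound 0.05 sized to Monte-Carlo error at
that effective sample size); the coverage study uses 50 replicates of
n = 400 with 2 × (400 + 800) draws; the interaction calibration uses 1000
simulations at 120/arm; the Fisher sweep enumerates all 132,470
nondegenerate 2×2 tables with total ≤ 40. Tolerances: brute-force score
oracles at 1e-10; exact enumerations at ~1e-12 (floating-point accumulation
only). Ties in the per-draw best-arm count are split equally; quantiles use
numpy's default linear interpolation.

## Known limitations

* The sampler is random-walk based; for much larger trials or many arms a
  gradient-based sampler would mix faster per draw.
* The phase-3 success test is a fixed-sample z-test; group-sequential
  phase-3 designs are not modeled.
* The drift model assumes additive, arm-agnostic era effects per HER2
  stratum; arm-specific drift is out of scope.
* Signature scores assume the published gene lists are given; re-deriving
  them from training data, and probe-level preprocessing, are out of scope.
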