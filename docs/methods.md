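# Methods

## The problem

Epidemiological dose–response studies of radiation-exposed cohorts
assign each person to a dose group with a central dose estimate, but
the true dose is uncertain. Two error types behave very differently:
*Berkson* error (true dose scatters around the assigned value) and
*classical* error (the observed surrogate scatters around the true
value, producing regression dilution). Either component can be
*shared* — identical for everyone in a given dose realisation, as with
a dosimetry-system bias — or *unshared* (independent per person).
`doserr` simulates grouped cohort data under a composite
shared/unshared Berkson–classical lognormal error model and measures
how well five correction strategies recover a known dose–response.

## Dose-error model

Individuals sit in dose groups `k` with central doses `D_cent,k`.
Within one *meta-simulation*, `m` *sub-simulations* draw for every
individual `i`:

    D_true,i,j = D_cent,k(i) · exp[−(σ²_sB + σ²_uB)/2] · exp[σ_sB ε_j + σ_uB δ_ij]
    D_surr,i,j = D_cent,k(i) · exp[−(σ²_sC + σ²_uC)/2] · exp[σ_sC μ_j + σ_uC ν_ij]

with `ε_j, μ_j, δ_ij, ν_ij` iid N(0,1). The shared draws `ε_j, μ_j`
are common to all individuals within sub-simulation `j`; the unshared
draws are independent per individual. The deterministic factors make
every dose's expectation equal its central dose. A log-scale SD of 0.2
is conventionally labelled "20%" error (geometric SD `e^0.2`). Setting
the Berkson SDs to zero leaves a purely classical model and vice
versa. Two individuals' true doses then have Pearson correlation
`(e^{σ²_sB} − 1)/(e^{σ²_sB + σ²_uB} − 1)` across sub-simulations —
exactly 1 when the unshared component vanishes.

## Case generation and collapse

Cancer cases (default N = 250) are drawn once per meta-simulation from
a multinomial over individuals with probabilities proportional to the
excess-relative-risk model `RR = 1 + αD + βD²` evaluated on each
individual's true dose and averaged over the `m` sub-simulations; the
same case vector applies to all sub-simulations of the meta-simulation.
Data are collapsed to the dose groups (cases summed, doses averaged).
Three per-group dose summaries feed the estimators:

- the group mean of **true** doses over individuals and sub-simulations
  (the regression-calibration dose, i.e. the conditional expectation
  of true dose given the group);
- the group mean of **surrogate** doses from one designated
  sub-simulation (the unadjusted-regression dose — averaging
  surrogates over sub-simulations would cancel exactly the classical
  error whose effect the unadjusted method is meant to exhibit);
- all `m` per-sub-simulation group-mean **true**-dose vectors (input
  to the averaging estimators).

## Fitting engine

The Poisson linear relative-risk model for group `g`,

    μ_g = e^κ · PY_g · (1 + α d_g [+ β d_g²]),

is fitted by maximum likelihood under the positivity constraint
`1 + αd + βd² > 0` at every observed dose. The intercept `κ` is a pure
scale and is profiled out analytically, leaving a 1-D (linear) or 2-D
(linear-quadratic) numerical maximisation (coarse scan plus bounded
Brent, or Nelder–Mead with rejection outside the admissible region).
95% intervals are profile-likelihood sets (`Δ logL ≤ χ²₁(0.95)/2 =
1.921`), located by geometric bracket expansion and root bisection; a
side whose likelihood never drops below the threshold inside the
admissible region is flagged unbounded rather than silently truncated.
AIC is `−2 logL + 2p` with `p` counting `κ`.

## The five estimators

- **Unadjusted**: plain fit at the surrogate-dose group means. The
  shared classical factor `c` multiplies all doses, so `α̂ ≈ α̂₀/c`
  with `E[1/c] = e^{σ²_sC}` — an upward bias (≈ 4% at 20% error) and
  undercoverage that no amount of data removes.
- **Regression calibration**: fit at the group-mean true dose.
- **MCML** (Monte Carlo maximum likelihood): maximises the arithmetic
  mean of the per-dose-vector likelihoods, `L(θ) = (1/m) Σ_j L_j(θ)`,
  over the `m` dose vectors; profile intervals on this averaged
  likelihood. With one vector — or identical vectors — it degenerates
  to the plain fit.
- **Quasi-2DMC with BMA**: Bayesian model averaging over the dose
  vectors. Mixture weights are softmax-parameterised,
  `p_j = e^{λ_j}/(1 + Σ_k e^{λ_k})` with the last vector as reference
  category, and the posterior is `∝ [Σ_k p_k L_k(θ)] π(θ) π(λ)` with
  N(0, 1000²) priors on all of `κ, α, β, λ`. A Metropolis–Hastings
  sampler alternates single-parameter updates of the risk parameters
  (proposal SDs 0.2 for κ, 1 for α and β) with block updates of λ
  (blocks of 10, proposal SD 2). Two chains of 1000 burn-in + 1000
  kept iterations start from the plain-fit MLE (jittered); the
  split-half Brooks–Gelman–Rubin factor above 1.05 flags a run
  non-converged. Intervals are equal-tailed 2.5/97.5 posterior
  quantiles of the pooled chains.
- **FMA** (frequentist model averaging): each dose vector gets its own
  ML fit; coefficient SDs are recovered from profile CIs as
  `min(MLE − lower, upper − MLE)/1.96`; each fit contributes `k = 100`
  normal draws per coefficient, pooled with AIC weights
  `e^{−AIC_j/2}/Σ_k e^{−AIC_k/2}` (max-AIC subtracted before
  exponentiation; the sign is the corrected one — the flipped sign
  demonstrably up-weights worse-fitting vectors). The weighted mean is
  the central estimate and weighted 2.5/97.5 centiles the interval. An
  asymmetric-SD variant (separate SDs above/below the MLE) exists but
  is off by default: occasional very wide one-sided CIs make it badly
  biased.

An `extended_regression_calibration` slot in the estimator registry is
an explicit extension point; the method itself is defined elsewhere and
out of scope here.

## Default study conditions

- 5 dose groups (0–0.07, 0.08–0.19, 0.20–0.99, 1.00–2.49, ≥2.5 Gy)
  with central doses 0.02, 0.13, 0.45, 1.5, 2 Gy (the open top group is
  assigned 2 Gy) and person-years 2.5e6, 3.6e5, 4.5e5, 1.6e5, 5.0e4 —
  proportional to the published bone-marrow-dose person-year structure
  of the Life Span Study cohort that motivates the grid.
- Individuals per group are exactly proportional to person-years
  (50000, 7200, 9000, 3200, 1000). Proportionality is required for the
  per-individual multinomial case draw to be consistent with
  person-year Poisson offsets; the absolute scale is large enough that
  unshared error averages out in group means, emulating the
  person-year-scale populations behind real grouped data. With much
  smaller groups the group-mean doses would inherit artificial shape
  noise.
- True models: linear-quadratic α = 0.25/Gy, β = 2/Gy²; linear
  α = 3/Gy. Error SDs per scenario from {0, 0.2, 0.5}; classical error
  fixed at 20%/20% in the standard scenarios.
- Study scale is 500 meta-simulations × 1000 sub-simulations. The
  bundled test ensembles run 60–200 × 100 (and 200 × 10 where Berkson
  error is zero and sub-simulations are degenerate); the steering
  templates expose both scales.

## What the generator does and does not emulate

The simulator reproduces the error *structure* of dosimetry systems —
shared versus unshared, Berkson versus classical, multiplicative
lognormal — on a realistic cohort skeleton. It does not emulate
covariate stratification (age, sex, city), secular person-year
accumulation, dose-dependent follow-up, or non-multiplicative error.
Passing tests therefore demonstrate the estimators' behaviour under
the assumed error model, not their performance on any real cohort.

## Numerical choices

- Profile-CI root location: `brentq` to 1e-6 (1e-3 inside the
  per-vector FMA loop, where the bound only feeds an SD recovery);
  bracket expansion doubles a step of 0.25·scale up to 60 times before
  declaring a side unbounded.
- Inner profiling over a second coefficient uses a warm-started 1-D
  pattern search with parabolic refinement (tolerance 1e-6·scale);
  the MCML profile, with two free parameters, uses warm-started
  Nelder–Mead.
- Degenerate inputs: all-equal doses raise (slope unidentifiable);
  all-cases-in-one-group returns a finite flagged optimum; proposals
  or parameter values violating RR positivity are rejected/raise by
  contract.
- Seeds form a `SeedSequence` tree (scenario → meta-simulation →
  {doses, cases, MCMC, FMA draws}), so runs are bit-reproducible and
  independent of parallel scheduling.

## Known limitations

- The Bayesian-model-averaging posterior under large *shared* Berkson
  error concentrates where the mixture components have the largest
  posterior volume. Because a shared lognormal factor `c` rescales a
  dose vector and a linear-quadratic fit absorbs rescaling exactly
  (`α → α/c`, `β → β/c²`), the stationary posterior favours small-`c`
  vectors and biases *both* coefficients upward (β more strongly), and
  mixture intervals are wide. Published accounts of this estimator
  family report a different failure signature (α inflated, β deflated,
  with collapsed coverage) that cannot arise from any weighting over
  rescaled vectors (Jensen's inequality forbids
  `E[1/c²] < (E[1/c])²`); reproducing it would require a dose-vector
  construction other than per-sub-simulation group means of the true
  doses. The estimator here is the faithful softmax-mixture sampler,
  verified against dense quadrature on a small fixture; its
  qualitative conclusion — order-of-magnitude coefficient bias and
  unreliable inference under large shared Berkson error — stands, with
  the sign split differing.
- Group-level collapse discards within-group dose variation beyond its
  mean; fits are 5-point regressions, so the quadratic coefficient is
  weakly identified whenever high-dose information is diluted.
- Sample Pearson correlations of lognormal doses converge slowly
  (heavy tails); desk-scale estimates at m = 100 scatter noticeably
  around the closed form.
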