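# Methods

`rrmeta` studies meta-analysis of the risk ratio (RR), the ratio of event
probabilities π_T/π_C between a treatment and a control arm, analysed
throughout on the log scale. The package implements three modelling
frameworks side by side, together with the data generators and diagnostics
needed to compare them.

## Effect estimators

For a 2×2 table (y_C, n_C, y_T, n_T) two conventions are implemented:

* **conventional**: θ̂ = log[(y_T/n_T)/(y_C/n_C)] with variance
  s² = 1/y_T − 1/n_T + 1/y_C − 1/n_C; when the table has a zero cell, 0.5
  is added to all four cells (so arm totals become n + 1) before both
  formulas.
* **half-corrected** (bias-corrected): θ̂ = log[(y_T+½)/(n_T+½)] −
  log[(y_C+½)/(n_C+½)], applied to *every* table. It is unbiased to
  O(n⁻²), finite even for double-zero tables, and its variance analogue
  replaces each count by count + ½.

The classic inverse-variance pathway (`fit_rem`) defaults to the
conventional estimator, which is what reproduces the reference analyses of
the two packaged examples; the beta-binomial inverse-variance pathway uses
the half-corrected estimator, whose bias properties the multiplicative
variance inflation is derived for. Both are selectable everywhere via the
`estimator` argument.

## Conventional random-effects model

Study effects are modelled as θ̂_j ~ N(θ, v_j + τ²) and pooled with
weights w_j = 1/(v_j + τ̂²). τ² is estimated by

* **DerSimonian–Laird**: τ̂² = max(0, (Q − (K−1)) / (Σw − Σw²/Σw)),
  w = 1/v;
* **Mandel–Paule**: the unique root of the generalized Q statistic
  Σ (θ̂_j − θ̄(τ²))²/(v_j + τ²) = K − 1 (the statistic is strictly
  decreasing in τ², so bisection with a geometrically grown bracket is
  guaranteed; tolerance 1e−10);
* **REML**: Fisher scoring on the restricted likelihood of the
  normal-normal marginal model, truncated at zero, tolerance 1e−10 on τ²,
  at most 100 iterations, DL start.

Wald intervals use z = 1.959964 so that 3-decimal limits are reproducible;
a Q-profile interval for τ² is available as a descriptive companion.
Studies with y_T + y_C equal to 0 or n carry no information about the RR
and are dropped before pooling, as is customary.

## The log-binomial mixed model and its repairs

With a log link, log π_jT = log π_jC + θ + b_j and b_j ~ N(0, τ²). The
constraint π_jT < 1 requires b_j < A_j = −log π_jC − θ, which a normal
random effect violates with probability 1 − Φ(A_j/τ): the model is
improper. Two repairs are implemented, matching the two practical options
for simulating such data:

* **point mass (censoring)**: b_j is capped at the boundary, equivalently
  π_jT is set just below 1 (offset 1e−12, chosen to keep
  Binomial(n, π_T) non-degenerate while being measure-zero for every
  computed quantity). The realized effect is min(X, c*) for
  X ~ N(θ, τ²), and its mean and variance follow from the censored-normal
  closed forms
  E = θΦ(β) − τφ(β) + c*(1 − Φ(β)),
  E[X²∧c*²] = (θ² + τ²)Φ(β) − τ(θ + c*)φ(β) + c*²(1 − Φ(β)),
  β = (c* − θ)/τ. These are validated against a 10⁶-draw Monte-Carlo
  oracle in the tests.
* **truncation (rejection)**: offending b_j are redrawn per study, giving
  a right-truncated normal with the standard closed-form moments
  E = θ − τφ(β)/Φ(β),
  Var = τ²[1 − βφ(β)/Φ(β) − (φ(β)/Φ(β))²],
  validated against quadrature and against `scipy.stats.truncnorm`.
  When Φ(β) underflows (below 1e−12) the moment routines raise instead of
  returning garbage, and the rejection sampler refuses designs whose
  acceptance probability is below 1e−8.

Both repairs pull E(θ_j) below θ and Var(θ_j) below τ², and make them
depend on π_jC — the theoretical bias curves that the simulator overlays
on its empirical output come from exactly these closed forms.

## Beta-binomial model

Arm counts follow BetaBinom(n, π, ρ): a binomial whose success
probability is Beta-distributed with mean π and variance π(1−π)ρ, giving
Var(Y) = nπ(1−π)(1 + (n−1)ρ). The intra-cluster correlation ρ plays the
heterogeneity role multiplicatively that τ² plays additively.

**Likelihood route.** The joint likelihood over both arms of all studies
(common π_T, π_C, ρ) is maximized in unconstrained coordinates —
(logit π_T, logit π_C, logit ρ) for the direct parametrization, or
(α, θ, log σ) with σ = ρ/(1−ρ) for the logit-link parametrization — by
Nelder–Mead with multi-start (ρ₀ ∈ {0.01, 0.1, 0.3}; the BB likelihood is
not an exponential family and can be multimodal for small K), tolerance
1e−9. The two parametrizations reach the same maximum; they differ in the
covariance (inverse observed information, central-difference Hessian) and
hence in the delta-method variance of log RR:

* direct: Var(log RR) ≈ Var(π̂_T)/π̂_T² + Var(π̂_C)/π̂_C²;
* logit: Var(log RR) ≈ g′ Σ_η g′ᵀ with η = (α+θ, α) and
  g′ = (1/(1+e^{η_T}), −1/(1+e^{η_C})) — the full form including the
  covariance of the two linear predictors.

**Inverse-variance route.** Half-corrected effects are pooled with
weights from the ρ-inflated plug-in variances. Four estimators of ρ are
provided, all truncated at 0:

* **MoM** — DL-analogue: Q at ρ = 0 matched to its first moment, which is
  linear in ρ because the plug-in variance is v_j(ρ) = v_j(0) + d_j ρ;
* **MP** — the root of Q(ρ) = K − 1 with fully ρ-dependent weights;
* **REML** — restricted likelihood of the normal approximation
  θ̂_j ~ N(θ, v_j(ρ));
* **BD** — inversion of a Breslow–Day-type homogeneity statistic: for a
  candidate ρ, the common RR is the inverse-variance pooled estimate, each
  study's control probability is re-fitted by constrained ML under that
  common RR (a closed-form quadratic), and the two-arm Pearson statistic
  with BB-inflated variances is solved for T(ρ) = K − 1. The confidence
  interval inverts the χ²_{K−1} quantiles and is reported untruncated.
  This statistic is a reconstruction: on the pre-eclampsia example it
  reproduces the reference point estimate (0.019) and interval
  (≈0.003–0.103 vs 0.003–0.106), but on the antidepressant example it
  gives 0.038 where the reference analysis reports 0.006, and the exact
  form of the original statistic is not recoverable from the published
  description. Treat BD results as method-specific.

## Simulators

Both simulators use equal arm sizes n/2, a common π_C across studies, and
the customary discard rule; each (seed, replicate) pair gets an
independent counter-based RNG stream (`numpy` SeedSequence spawn keys), so
any single replicate is reproducible in isolation. Default replication is
1000; the test suite and the directional checks run 200 (and smaller
smoke sizes), chosen so the full suite completes in a few minutes while
keeping Monte-Carlo error well inside the asserted margins.

* `logbin`: θ_j from N(θ, τ²) with the point-mass or truncation repair,
  then binomial arms. The driver reports bias of τ̂² (DL/MP/REML), bias of
  θ̂, and CI coverage.
* `betabin`: beta draw then binomial per arm (exact BB sampling); the
  driver compares the IV estimators with the two likelihood fits.

What the generators emulate is the *model side* of each framework: they
produce counts whose study-level effects follow the stated mixing
distributions exactly. They do not emulate features of real collections
of trials — unequal and correlated arm sizes, baseline-risk/effect
correlation, selective publication, or mixtures of effect clusters (both
packaged examples visibly suggest such mixtures). Passing simulation
tests therefore demonstrates internal consistency of estimator and
generator, not robustness to those real-data departures.

## Residual screen

For collections of meta-analyses the screen computes half-corrected
effects, ρ=0 plug-in variances, DL heterogeneity, FE or RE weights, the
studentized residuals r_mj = (θ̂_mj − θ̂_m)/s_mj with
s²_mj = 1/w_mj − 1/Σw_mj, and the estimated truncation probability
1 − Φ((−log p̂_mjC − θ̂_m)/τ̂_m), binned into ten half-open intervals
(<0.05, [0.05–0.15), …, ≥0.85). Default filters — arm sizes ≥ 5, K ≥ 3,
τ̂² > 0, applied before residual computation — are all configurable.
τ̂_m = 0 defines the truncation probability as 0 (no random effect to
truncate). Residuals are not exactly centered; a study whose weight
dominates the pool can make s²_mj ≤ 0, and such records carry NaN
residuals rather than failing. The synthetic-collection generator simply
cycles a list of simulator designs, so benign and heavily truncated
regimes can be screened together; it stands in for literature-wide
collections, which are out of scope.

## Numerical choices and degenerate inputs

* Normal cdf/pdf, log-beta and log-gamma come from `scipy.special`; the
  BB log-pmf is computed via `betaln` (stable up to the n ≈ 1000 arms in
  the packaged data) and cross-checked against `scipy.stats.betabinom`.
* ρ = 0 inside likelihoods falls back to the exact binomial log-pmf
  (the g = 1/ρ − 1 parametrization loses precision below ρ ≈ 1e−8).
* Root-finding uses Brent's method on guaranteed brackets; monotonicity
  of every inverted statistic in its parameter is what guarantees
  uniqueness, and is property-tested.
* Double-zero / all-event studies: finite under the half-corrected
  estimator, dropped by pooling layers; a dataset that is entirely
  degenerate raises.
* A single-study dataset pools to its own estimate; heterogeneity
  estimation and residuals require K ≥ 2 and say so.

## Known limitations

* The BD statistic is a reconstruction (see above).
* The inverse-variance BB pathway inherits the transformation bias of the
  log-RR scale: the simulators show it attenuating |θ̂| substantially at
  K = 20, so its pooled estimates should be read with that in mind — this
  is a finding the package reproduces, not a defect it removes.
* CIs for ρ from MoM/MP/REML are not implemented (only BD inversion
  provides one); τ² intervals are Q-profile only.
* No small-sample CI adjustments (Knapp–Hartung), prediction intervals,
  covariates, or odds-ratio/risk-difference measures.
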