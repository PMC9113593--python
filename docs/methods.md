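# Methods

## The model

Axial observations are angles identified modulo π, so a distribution for them
lives on the half circle [0, π). `hcmb3` builds one from the **modified
Burr-III** law on the positive half line, F(x) = [1 + γx^(−β)]^(−α/γ)
(shapes α, β, γ > 0), via the inverse stereographic projection x = tan(θ/2).
If m(θ) = tan(θ/2), the projected density is g(θ) = |m′(θ)| f(m(θ)), giving

    g(θ) = (αβ/2) sec²(θ/2) tan(θ/2)^(−β−1) [1 + γ tan(θ/2)^(−β)]^(−α/γ−1)
    G(θ) = [1 + γ tan(θ/2)^(−β)]^(−α/γ)

with closed-form quantile θ(u) = 2 arctan{[(u^(−γ/α) − 1)/γ]^(−1/β)}.
Random generation is plain inverse-transform sampling of a seeded uniform
generator — exact, fast, and reproducible.

All three parameters are shapes; none is a location or scale on the circle.
β controls tail decay on the projected line (hence the behaviour at both
ends of the half circle), while α and γ jointly steer skewness and modality.
The family nests the half-circular Burr III (γ = 1), the half-circular
log-logistic (α = γ, with the log-logistic scale α^(1/β)), and reaches the
half-circular generalized inverse Weibull in the γ → 0 limit
(G → exp(−α tan(θ/2)^(−β))). The projected gamma and Burr XII laws (standard
linear cdfs pushed through x = tan(θ/2)) are carried as non-nested
competitors for model comparison; their parameterizations are the textbook
ones — gamma(shape, rate) and 1 − (1 + x^c)^(−k).

### Boundary and numerical conventions

* Angles live in the half-open interval [0, π). At θ = 0 the density takes
  its analytic limit: 0 when αβ > γ, the finite value (αβ/2)γ^(−α/γ−1) when
  αβ = γ, and +∞ (an integrable singularity) when αβ < γ. A second
  integrable singularity appears at θ → π when β < 1.
* All log-density and cdf evaluations route through
  `log1p`/`logaddexp`-style expressions, so extreme shape values and angles
  within 1e−8 of the boundaries do not overflow.
* Quadrature (trigonometric moments, normalization checks) uses adaptive
  Gauss–Kronrod with absolute tolerance 1e−12 and up to 400–1000
  subdivisions; the returned error estimate is checked and a failure raised
  rather than silently accepting a bad integral.
* The mode search scans the analytic derivative of the log-density on a
  4096-point grid over (1e−8, π − 1e−8) and refines each maximum-type sign
  change by Brent's method. The derivative was re-derived from the
  log-density and is verified against finite differences in the tests;
  modality has no closed form in this family.

## Circular characteristics

The p-th trigonometric moment is (α_p, β_p) = (E cos pθ, E sin pθ), computed
by quadrature; φ_p = α_p + iβ_p is the characteristic function at integer p.
Derived quantities: mean resultant length ρ = |φ₁|, circular variance
v = 1 − ρ, circular SD σ = √(−log ρ²), and skewness/kurtosis

    γ₁ = β₂* / (1 − ρ)^{3/2},     γ₂ = (α₂* − ρ⁴) / (1 − ρ)²,

where (α₂*, β₂*) are the second moments rotated through twice the mean
direction (α₂* = α₂cos2μ + β₂sin2μ, β₂* = β₂cos2μ − α₂sin2μ — the standard
directional-statistics central moments).

**Mean-direction convention.** The default reported μ is the *literal*
single-argument arctan(β₁/α₁), which lands in (−π/2, π/2) and is negative
whenever the moment vector points into the second quadrant — this is the
convention used by the published tables this package reproduces. The
statistically standard two-argument atan2(β₁, α₁) is available via
`convention="quadrant"` and is always the one used internally for the
central-moment rotation, where the literal form would rotate through the
wrong quadrant. γ₁/γ₂ under the published tables' exact convention could not
be established (their printed skewness values are not reproducible from
their own printed first and second moments), so the standard definition
above is used and documented as such.

## Estimation

All eight objectives are optimised over z = (log α, log β, log γ), which
keeps every iterate strictly inside the positive orthant without
constraints. The search runs a Nelder–Mead simplex from up to eight spread
starting points — seven fixed shape triples plus a quartile-matching
heuristic (γ = 1, β from the interquartile ratio of tan(θ/2), α from the
median) — and keeps the best optimum (objective tolerance 1e−9, parameter
tolerance 1e−7, deterministic start order). The MLE is additionally polished
by L-BFGS-B with the analytic score mapped to z-space.

* The log-likelihood's final term is Σ log[1 + γ tan(θᵢ/2)^(−β)]; the
  analytic score components were derived from it and are verified against
  finite differences to 1e−5 relative error in the tests.
* MLE standard errors use the **observed information** (numerically
  differenced analytic score; the expected information is intractable), and
  100(1−λ)% intervals are ψ̂ ± z_{λ/2}√(J⁻¹)ᵢᵢ with λ = 0.05 by default.
* The percentile objective matches the *projected* order statistics
  t₍ᵢ₎ = tan(θ₍ᵢ₎/2) to the linear modified Burr-III quantile at plotting
  positions pᵢ = i/(n+1); an angle-scale variant (residuals in θ) is
  available via `pce_scale="angle"`.
* Spacings in the MPS objective use G(θ₍₀₎) = 0 and G(θ₍ₙ₊₁₎) = 1; a zero
  spacing caused by tied observations is replaced by the density at the tied
  point (the standard repair), with a warning.
* cdf values inside log-based objectives are clamped to [1e−300, 1−1e−16].
* **Divergence flagging.** The α–γ ridge of this family lets small-sample
  fits escape toward infinity with an essentially flat objective. A fit
  whose optimum leaves [1e−5, 1e5] on any parameter is reported with
  `converged=False`; the Monte Carlo harness counts such replicates as
  failures and excludes them from the moment summaries. At n = 25 this
  affects roughly 10–25% of replicates depending on the method; at n = 100
  almost none.

## Monte Carlo harness

`SimDesign` defaults mirror the reference study design: 10,000 replicates,
n ∈ (25, 50, 75, 100), truth (2, 3, 4) (with (1, 3.5, 1) and (4, 3, 4) as
companion settings). Per-cell seeds derive from
`SeedSequence(base_seed, spawn_key=(size_index, rep))`, so every cell is
independent, order-insensitive, and bitwise reproducible. Bias and MSE are
the plain empirical mean of (t̂ − t) and (t̂ − t)² over converged
replicates; the failure count is reported alongside. Harness fits use four
simplex starts (the heuristic plus three spread triples): multistart breadth
exists to protect isolated data analyses, whereas Monte Carlo summaries
average over replicates, so the harness trades the remaining starts for
replicates. The packaged acceptance run uses 500 replicates at
n ∈ {25, 100}; the full design remains available through `SimDesign` or the
CLI config.

## Goodness of fit

AIC = −2ℓ + 2k, BIC = −2ℓ + k log n, and CAIC is the finite-sample
*corrected* AIC, AIC + 2k(k+1)/(n−k−1) (this is the convention the published
comparison table uses, verified by its own arithmetic). A² and W² follow the
standard order-statistic formulas on the fitted probability integral
transforms, with the small-sample modifications A* = A²(1 + 0.75/n +
2.25/n²) and W* = W²(1 + 0.5/n) applied by default (`modified=False` gives
the raw statistics). The K-S p-value uses the asymptotic Kolmogorov series,
documented as approximate for n in the tens. The TTT transform reports the
scaled total-time-on-test curve and flags a concave (above-diagonal) curve
as increasing-hazard.

## What the synthetic data does and does not show

The generator draws exactly from the model law by inverse transform, so
estimator tests on synthetic samples validate *statistical* behaviour
(consistency, bias decay, ranking of methods) under a correctly specified
model. Real axial data adds measurement rounding, ties, possible
contamination and model misspecification — none of which the synthetic
fixtures emulate. Passing recovery tests therefore demonstrates that the
estimators and their implementation are sound, not that hcMB-III fits any
particular data set; the model-comparison battery (`gof`) is the tool for
the latter question.

## Known limitations

* The observed-information SEs assume an interior optimum; on the α–γ ridge
  at small n the information matrix is near-singular and SEs are omitted
  when inversion fails.
* The K-S p-value is asymptotic; exact small-sample enumeration is not
  implemented.
* Wrapped (full-circle) variants, Bayesian estimation, censored likelihoods
  and profile-likelihood intervals are out of scope.
* The published study's full 10,000-replicate tables were produced with an
  unstated optimizer, seeds and failure policy; agreement at Monte Carlo
  scale is statistical, not digit-for-digit.
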