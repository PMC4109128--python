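# Methods

## Model and distributional machinery

The package centres on the interval-screened (weighted) normal
distribution WN_(a,b)(m, Ω): the law of X₂ when (X₁, X₂) is bivariate
normal N₂(m, Ω) and we condition on the screening event a ≤ X₁ ≤ b. Its
density, sampler and moments are implemented generically in
`hsgm.screened` for any 2-vector m, SPD Ω and interval, and the two-stage
prior / posterior objects are special cases:

* prior: m = (μ, μ), Ω = σ²[[δ, δ], [δ, 1]];
* single-observation posterior: m = ((1−δ)μ + δμ*, μ*),
  Ω = [[δ(1−δ)σ² + δ²σ*², δσ*²], [δσ*², σ*²]] with
  μ* = (σ²y + τ²μ)/(σ² + τ²), σ*² = σ²τ²/(σ² + τ²);
* full conditional for n observations: the same with ȳ in place of y and
  τ²/n in place of τ².

Moments use the truncated-normal factors β₁ = (φ(g_b) − φ(g_a))/Z,
β₂ = (g_b φ(g_b) − g_a φ(g_a))/Z + β₁², so that the screened outcome has
mean m₂ − β₁κ and variance Ω₂₂ − β₂κ², where κ = Cov(X₁,X₂)/sd(X₁) and
g_a, g_b standardize the interval under the screening coordinate. The
identities mean + β₁κ = m₂ and variance + β₂κ² = Ω₂₂ are exact and define
the *constraining effect* reported by the inference layer.

**Square-root convention.** All standardizations under the prior
covariance use sd(X₁) = σ√δ: v*(·) = (·−μ)/(σ√δ), η* = ξ*√δ/σ, and the
standardized correlation of the pair is √δ. This is the unique convention
consistent with Var(X₁) = δσ² and with the stochastic representation
θ = μ + σ√δ·T + σ√(1−δ)·Z (T truncated standard normal on
[v*(a), v*(b)], Z standard normal, independent), which is also how the
sampler draws θ.

## Numerical choices

* **Truncated-normal sampling** is inverse-CDF. Intervals straddling the
  mode use the direct form Φ⁻¹(Φ(g_a) + u·ΔΦ); intervals lying in one
  tail are mapped to the upper tail and handled entirely in log space via
  `log_ndtr`/`ndtri_exp`, so intervals whose normal mass underflows
  double precision (e.g. [40, 41]) still yield exact in-range draws.
  Uniforms are clipped to [1e−16, 1−1e−16] so quantile endpoints cannot
  return ±∞.
* **Φ differences** are computed as Φ(hi) − Φ(lo) when the interval
  straddles 0 and as Φ(−lo) − Φ(−hi) when both arguments are positive,
  avoiding cancellation; a log-space variant backs the entropy
  integrand.
* **Bivariate-normal rectangle probabilities** are computed by adaptive
  1-D quadrature of φ(x)·[Φ((u₂−ρx)/s) − Φ((l₂−ρx)/s)], s = √(1−ρ²),
  with absolute tolerance 1e−13. The integration range on the first
  coordinate is clipped to ±8.5 (discarded tail < 2e−17) because an
  enormous finite range starves the adaptive rule of the central mass;
  rectangles lying entirely beyond 8.5 sd fall back to a bounded tail
  strip. scipy's bivariate CDF serves as an independent cross-check in
  the tests, not as the implementation.
* **δ boundaries.** δ = 0 is handled exactly as the normal special case
  (in the posterior objects the screening coordinate is carried with
  zero covariance, so the screened density degenerates to the
  unconstrained normal and the constraining effect is identically zero);
  δ ≥ 1 − 1e−6 is clipped with a warning since the screening covariance
  is singular at δ = 1.
* **Inverse gamma** is parameterized as (shape, rate) with density
  ∝ t^(−shape−1) e^(−rate/t); the τ² full conditional is
  (c + n/2, d + ½Σ(y_i − θ)²), the unique pair consistent with n normal
  likelihood factors and an IG(c, d) prior in this parameterization.
* **Degree inversion** uses bisection on the monotone map δ ↦ (1−α)·100%
  with a 200-iteration cap, stopping only when both the degree (1e−6
  percentage points) and the δ-bracket (1e−9) are resolved — the map
  flattens near its limits, so a degree-only stop would leave δ poorly
  determined.

## Entropy estimation

Ent(π₁) and Ent(π₂) are closed-form. Ent(π₃) has one intractable term,
−E[ln W(θ)] with W the screening weight; everything else reduces in
closed form to ½(1 + ln 2πσ² + δ[v*(a)φ(v*(a)) − v*(b)φ(v*(b))]/Z*) +
ln Z*. The expectation is averaged over draws of θ from π₃ itself
(n_draws defaults to 10⁵) and its standard error — sample SD of ln W over
√n_draws — is reported in the `EntropyEstimate`. At tiny δ with a wide
interval the weight can be numerically 1 for every draw, giving a
legitimately zero SE from a genuine MC run. At δ = 0 the weight is
identically 1 and the exact normal entropy is returned.

The δ → 1 comparison between Ent(π₃) and Ent(π₂) carries a residual
distributional bias of order √(1−δ) that dominates the MC error; at
δ = 0.9999 the measured gap is ≈ 6e−3 nats, and the tests assert the
1e−2 band that also governs the density-limit checks.

## Gibbs sampler

The sampler alternates θ | τ² (screened-normal via the stochastic
representation) and τ² | θ (inverse gamma, drawn as rate/Gamma(shape)).
Defaults: 11,000 iterations with 1,000 burn-in, no thinning;
effective sample sizes by non-overlapping batch means (batch size ⌊√n⌋).
Initialization: θ₀ = ȳ, replaced by the interval midpoint when ȳ falls
outside a finite [a, b]; τ²₀ = the sample variance (1 when n = 1). All
randomness flows from one integer seed through `numpy`'s `SeedSequence`;
replicated studies spawn independent child streams per replicate.

## Synthetic-data generator and what the tests show

`generate_dataset` emulates exactly the assumed data layer: i.i.d.
N(θ_true, τ²_true) responses. The calibration study uses θ_true = 0.3
inside [a, b] = [−1, 1], τ²_true = 1, n = 100, δ = 0.5, μ = 0, σ² = 1 and
c = 2, d = 1 (prior mean of τ² equal to the truth), with 200 replicates
of 11,000 iterations — sizes chosen so a full study completes in well
under a minute on one core while leaving the binomial SE of a 95%
coverage estimate at ≈ 1.5 percentage points. Because the generator
matches the model exactly, passing coverage/bias checks demonstrate
internal consistency of the sampler and the conjugate algebra; they say
nothing about robustness to model misspecification (non-normal noise,
drifting means, dependent errors), which real data may exhibit.

## Independent oracles used in testing

* a rejection sampler that draws the bivariate pair and keeps X₂ when X₁
  lands in the interval — exact screened-normal draws by construction;
* adaptive quadrature of the densities for normalization, moments and
  −∫ p ln p;
* direct conditional-probability simulation for α;
* scipy's `truncnorm` and bivariate CDF for the truncated-normal and
  rectangle-probability layers;
* an independently coded textbook semi-conjugate Gibbs sampler for the
  δ = 0 subcase.

## Known limitations

* Single interval constraint on a scalar mean only; no multivariate
  screening and no constraint families beyond one interval.
* Hyperparameters μ, σ², a, b, c, d are taken as known; no
  empirical-Bayes estimation.
* The behaviour of α when μ lies outside [a, b] follows the formulas as
  implemented (the δ = 0 limit is defined as the plain prior interval
  mass); the δ → 0 conditional limit is genuinely discontinuous there.
* Ent(π₃) is Monte Carlo only; no deterministic quadrature path is
  exposed for the integral term.
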