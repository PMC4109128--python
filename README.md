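# hsgm — normal-mean inference under an uncertain interval constraint

`hsgm` implements Bayesian estimation of a normal mean θ when prior
knowledge says θ *probably* lies in an interval [a, b], but the analyst is
not certain the constraint holds. It is aimed at biostatisticians and
epidemiological modellers who would otherwise have to choose between a
plain normal prior (ignoring the constraint) and a hard-truncated prior
(over-committing to it).

## The model

Data are `y_i = θ + ε_i`, `ε_i ~ N(0, τ²)`, with `τ² ~ IG(c, d)` and a
**two-stage prior** on θ:

```
θ | θ₀ ~ N(θ₀, (1−δ)σ²)
θ₀     ~ N(μ, δσ²) truncated to [a, b],      δ ∈ [0, 1)
```

Marginally, θ follows an *interval-screened (weighted) normal*
distribution: the law of the second coordinate X₂ of a bivariate normal
with covariance σ²[[δ, δ], [δ, 1]], conditioned on the first coordinate
falling in [a, b]. Its density is

```
π₃(θ) = φ(θ; μ, σ²) · [Φ(ξ*v*(b) − η*(θ−μ)) − Φ(ξ*v*(a) − η*(θ−μ))] / [Φ(v*(b)) − Φ(v*(a))]
```

with `v*(·) = (·−μ)/(σ√δ)`, `ξ* = (1−δ)^(−1/2)`, `η* = ξ*√δ/σ`. This
family interpolates between the unconstrained normal prior π₁ (δ = 0) and
the hard-truncated prior π₂ (δ → 1), and each member is the
maximum-entropy prior given the moment constraints `E[θ] = μ`,
`Var(θ) = σ²` and interval-probability constraint `P(a ≤ θ ≤ b) = α`.

Three things follow, all implemented here:

* **An objective uncertainty measure.** The prior probability the model
  assigns to the constraint is `α = Φ̄₂/(Φ(v*(b)) − Φ(v*(a)))`, a
  bivariate-normal rectangle probability divided by a univariate interval
  probability; the **degree of uncertainty** is `(1−α)×100%`. The map
  δ ↦ (1−α) is monotone, so a target degree can be inverted to a unique δ
  (and hence to the variance split σ₀² = (1−δ)σ², σ₁² = δσ²).
* **Entropy ordering.** `Ent(π₁) > Ent(π₃) > Ent(π₂)` in nats; the gap
  `Ent(π₃) − Ent(π₂)` shrinks as δ grows and widens with σ². π₁/π₂
  entropies are closed-form; π₃'s is estimated by Monte Carlo with a
  reported standard error.
* **Conjugate posterior inference.** At known τ² the screened-normal
  prior is conjugate (the posterior is again screened normal); with
  unknown τ² a Gibbs sampler alternates a screened-normal draw for θ and
  an inverse-gamma draw for τ². The posterior mean and variance decompose
  as `θ* − β₁κ` and `ω*² − β₂κ²`, where θ*, ω*² are the unconstrained
  conjugate posterior moments and the second terms are the **constraining
  effect** of the interval.

## Worked example

How uncertain is a prior with μ = 0, σ² = 1, δ = 0.5 about the constraint
θ ∈ [−1, 0]?

```bash
$ hsgm uncertainty --mu 0 --sigma2 1 --a -1 --b 0 --delta 0.5
{
  "alpha": 0.487205697896163,
  "degree_percent": 51.2794302103837,
  ...
}
```

So this prior places only 48.7% of its mass behind the constraint — a
51.3% degree of uncertainty. Conversely, ask for the δ that yields a 30%
degree:

```bash
$ hsgm uncertainty --mu 0 --sigma2 1 --a -1 --b 0 --target-degree 30
{
  "delta": 0.8548383588190556,
  "sigma0_sq": 0.14516164118094443,
  "sigma1_sq": 0.8548383588190556,
  ...
}
```

Fit the model to simulated data (true θ = 0.3, τ² = 1, n = 100):

```bash
$ hsgm simulate --theta 0.3 --tau2 1 --n 100 --seed 11 --out y.csv
$ hsgm fit --data y.csv --mu 0 --sigma2 1 --delta 0.5 --a -1 --b 1 --seed 11
{
  "theta_mean": 0.3210396675684612,
  "theta_sd": 0.0914842380579647,
  "theta_ci95": [0.14113450360328236, 0.5009366345731336],
  "tau2_mean": 0.8533338587165972,
  "constraining_effect": {
    "mean_shift": -0.0006367702305445946,
    "variance_reduction": -1.7636581089124205e-05
  },
  ...
}
```

The posterior mean 0.321 recovers the truth; the constraining effect is
tiny here because n = 100 observations dominate a symmetric interval.
`hsgm figures` exports the entropy-gap and uncertainty curves as CSV
tables, and `hsgm calibrate` runs a replicated synthetic coverage study
from a YAML config.

The same functionality is available as a library:

```python
from hsgm import Interval, alpha_of_delta
alpha_of_delta(0.0, 1.0, 0.5, Interval(-1.0, 0.0)).degree_percent  # 51.279
```

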