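"""Posterior inference for the normal mean under the two-stage interval prior.

Model: y_i = theta + e_i, e_i ~ N(0, tau2), i = 1..n, with
tau2 ~ IG(c, d) and the two-stage prior on theta

    theta | theta0 ~ N(theta0, (1 - delta) sigma2),
    theta0 ~ N(mu, delta sigma2) truncated to [a, b],

whose marginal is the interval-screened normal WN_(a,b) with covariance
sigma2 [[delta, delta], [delta, 1]].  The prior is conjugate for theta at
known tau2 (the posterior is again a screened normal), and the two full
conditionals — screened normal for theta, inverse gamma for tau2 — drive
a routine Gibbs sampler.

Inverse-gamma convention throughout: IG(shape, rate) has density
proportional to t^(-shape-1) exp(-rate/t), mean rate/(shape-1) for
shape > 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .screened import (
    Interval,
    TruncatedNormalParams,
    WeightedNormalParams,
    _trunc_std_ppf,
    truncated_normal_moments,
)

__all__ = [
    "HsgmModel",
    "Dataset",
    "ConditionalPosterior",
    "PosteriorDraws",
    "conjugate_update_single",
    "theta_full_conditional",
    "tau2_full_conditional",
    "gibbs_sample",
    "constraining_effect",
]


@dataclass(frozen=True)
class HsgmModel:
    """Hyperparameters of the hierarchical screened Gaussian model.

    delta in [0, 1) splits the total prior variance sigma2 of theta into
    the truncated-stage part sigma1^2 = delta sigma2 and the smoothing
    part sigma0^2 = (1 - delta) sigma2; delta = 0 recovers the plain
    N(mu, sigma2) prior.
    """

    mu: float
    sigma2: float
    delta: float
    interval: Interval
    c: float
    d: float

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")
        if not (self.c > 0 and self.d > 0):
            raise ValueError("inverse-gamma parameters c, d must be positive")

    @property
    def sigma0_sq(self) -> float:
        return (1.0 - self.delta) * self.sigma2

    @property
    def sigma1_sq(self) -> float:
        return self.delta * self.sigma2


@dataclass(frozen=True)
class Dataset:
    """Observed responses y_1..y_n."""

    y: np.ndarray

    def __post_init__(self) -> None:
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if y.ndim != 1 or y.size < 1:
            raise ValueError("y must be a nonempty 1-D vector")
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def ybar(self) -> float:
        return float(self.y.mean())


@dataclass(frozen=True)
class ConditionalPosterior:
    """The screened-normal full conditional of theta at fixed tau2.

    theta_star / omega_star2 are the unconstrained conjugate posterior
    mean and variance; the screening shifts them by the constraining
    effect: mean = theta_star - beta1 kappa, variance = omega_star2 -
    beta2 kappa^2.
    """

    theta_star: float
    omega_star2: float
    theta1_star: float
    omega11_star2: float
    kappa: float
    beta1: float
    beta2: float
    mean: float
    variance: float
    wn: WeightedNormalParams


@dataclass(frozen=True)
class PosteriorDraws:
    """Post-burn-in paired Gibbs chains for (theta, tau2)."""

    theta: np.ndarray
    tau2: np.ndarray
    n_iter: int
    burn_in: int
    seed: int
    ess_theta: float
    ess_tau2: float

    def summary(self) -> dict:
        q_th = np.quantile(self.theta, [0.025, 0.975])
        q_t2 = np.quantile(self.tau2, [0.025, 0.975])
        return {
            "theta_mean": float(self.theta.mean()),
            "theta_sd": float(self.theta.std(ddof=1)),
            "theta_ci95": [float(q_th[0]), float(q_th[1])],
            "tau2_mean": float(self.tau2.mean()),
            "tau2_sd": float(self.tau2.std(ddof=1)),
            "tau2_ci95": [float(q_t2[0]), float(q_t2[1])],
            "ess_theta": self.ess_theta,
            "ess_tau2": self.ess_tau2,
            "n_iter": self.n_iter,
            "burn_in": self.burn_in,
            "seed": self.seed,
        }


def _posterior_scalars(
    ybar: float, n: int, tau2: float, model: HsgmModel
) -> tuple[float, float]:
    """Unconstrained conjugate posterior (theta_star, omega_star2) from ybar."""
    s2, mu = model.sigma2, model.mu
    theta_star = (ybar * s2 + mu * tau2 / n) / (s2 + tau2 / n)
    omega_star2 = s2 * tau2 / (n * s2 + tau2)
    return theta_star, omega_star2


def conjugate_update_single(
    y: float, tau2: float, model: HsgmModel
) -> WeightedNormalParams:
    """Screened-normal posterior of theta for a single observation at known tau2.

    With mu_post = (sigma2 y + tau2 mu)/(sigma2 + tau2) and s_post2 =
    sigma2 tau2/(sigma2 + tau2), the posterior is WN_(a,b)(m*, S*) with
    m* = ((1-delta) mu + delta mu_post, mu_post) and
    S* = [[delta(1-delta) sigma2 + delta^2 s_post2, delta s_post2],
          [delta s_post2, s_post2]].

    At delta = 0 the screening covariance vanishes and the posterior is
    exactly N(mu_post, s_post2); the returned parameters then carry a
    decoupled screening coordinate (zero covariance, prior-scale variance)
    so the screened density degenerates to that normal.
    """
    if not tau2 > 0:
        raise ValueError("tau2 must be positive")
    s2, mu, delta = model.sigma2, model.mu, model.delta
    mu_post = (s2 * y + tau2 * mu) / (s2 + tau2)
    s_post2 = s2 * tau2 / (s2 + tau2)
    if delta == 0.0:
        m = np.array([mu, mu_post])
        Om = np.array([[s2, 0.0], [0.0, s_post2]])
    else:
        m = np.array([(1.0 - delta) * mu + delta * mu_post, mu_post])
        o11 = delta * (1.0 - delta) * s2 + delta**2 * s_post2
        Om = np.array([[o11, delta * s_post2], [delta * s_post2, s_post2]])
    return WeightedNormalParams(m, Om, model.interval)


def theta_full_conditional(
    data: Dataset, tau2: float, model: HsgmModel
) -> ConditionalPosterior:
    """Full conditional of theta given tau2 and the data.

    Reduces to the single-observation conjugate update applied to the
    sample mean with variance tau2/n, since the likelihood in theta is
    proportional to phi(ybar; theta, tau2/n).
    """
    if not tau2 > 0:
        raise ValueError("tau2 must be positive")
    wn = conjugate_update_single(data.ybar, tau2 / data.n, model)
    theta_star, omega_star2 = _posterior_scalars(data.ybar, data.n, tau2, model)
    theta1_star = float(wn.m[0])
    omega11_star2 = float(wn.Omega[0, 0])
    kappa = float(wn.kappa)  # = delta omega_star2 / omega11_star for delta > 0
    tm = truncated_normal_moments(
        TruncatedNormalParams(theta1_star, omega11_star2, model.interval)
    )
    beta1 = 0.0 if model.delta == 0.0 else tm.beta1
    beta2 = 0.0 if model.delta == 0.0 else tm.beta2
    return ConditionalPosterior(
        theta_star=theta_star,
        omega_star2=omega_star2,
        theta1_star=theta1_star,
        omega11_star2=omega11_star2,
        kappa=kappa,
        beta1=beta1,
        beta2=beta2,
        mean=theta_star - beta1 * kappa,
        variance=omega_star2 - beta2 * kappa**2,
        wn=wn,
    )


def tau2_full_conditional(
    data: Dataset, theta: float, model: HsgmModel
) -> tuple[float, float]:
    """Inverse-gamma (shape, rate) of the noise-variance full conditional.

    shape = c + n/2, rate = d + sum((y_i - theta)^2)/2 — the unique pair
    consistent with n normal likelihood factors and the IG(c, d) prior.
    """
    rss = float(np.sum((data.y - theta) ** 2))
    return model.c + data.n / 2.0, model.d + 0.5 * rss


def constraining_effect(cp: ConditionalPosterior) -> tuple[float, float]:
    """Signed screening contributions (mean_shift, variance_reduction).

    mean_shift = -beta1 kappa and variance_reduction = -beta2 kappa^2, the
    exact differences between the screened posterior moments and the
    unconstrained conjugate posterior N(theta_star, omega_star2).
    """
    return -cp.beta1 * cp.kappa, -cp.beta2 * cp.kappa**2


def _ess_batch_means(x: np.ndarray) -> float:
    """Effective sample size via non-overlapping batch means."""
    n = x.size
    if n < 16:
        return float(n)
    m = int(math.floor(math.sqrt(n)))
    k = n // m
    means = x[: k * m].reshape(k, m).mean(axis=1)
    var_bm = means.var(ddof=1) * m  # long-run variance estimate
    var_x = x.var(ddof=1)
    if var_bm <= 0:
        return float(n)
    return float(min(n, n * var_x / var_bm))


def gibbs_sample(
    data: Dataset,
    model: HsgmModel,
    n_iter: int = 11_000,
    burn_in: int = 1_000,
    seed: int = 0,
    init: Optional[tuple[float, float]] = None,
    fix_tau2: Optional[float] = None,
) -> PosteriorDraws:
    """Gibbs sampler alternating theta | tau2 and tau2 | theta.

    theta is drawn from its screened-normal full conditional via the
    stochastic representation (truncated-normal plus independent normal
    component); tau2 from its inverse gamma.  ``fix_tau2`` freezes the
    noise variance at a known value (its update is skipped).  Deterministic
    given ``seed``.
    """
    if not n_iter > burn_in >= 0:
        raise ValueError("require n_iter > burn_in >= 0")
    rng = np.random.default_rng(seed)
    y = data.y
    n = data.n
    ybar = data.ybar
    a, b = model.interval.a, model.interval.b
    mu, s2, delta = model.mu, model.sigma2, model.delta
    shape = model.c + n / 2.0

    if init is not None:
        theta, tau2 = float(init[0]), float(init[1])
    else:
        theta = ybar
        if not (a <= theta <= b):
            if math.isfinite(a) and math.isfinite(b):
                theta = 0.5 * (a + b)
        tau2 = float(y.var(ddof=1)) if n > 1 else 1.0
        if tau2 <= 0:
            tau2 = 1.0
    if fix_tau2 is not None:
        tau2 = float(fix_tau2)
    if not tau2 > 0:
        raise ValueError("initial tau2 must be positive")

    # pre-draw the uniforms/normals consumed per iteration
    u_trunc = rng.uniform(size=n_iter)
    z_norm = rng.standard_normal(n_iter)

    thetas = np.empty(n_iter)
    tau2s = np.empty(n_iter)
    for it in range(n_iter):
        # --- theta | tau2: screened-normal full conditional -------------
        t2n = tau2 / n
        theta_star = (ybar * s2 + mu * t2n) / (s2 + t2n)
        omega_star2 = s2 * tau2 / (n * s2 + tau2)
        if delta == 0.0:
            theta = theta_star + math.sqrt(omega_star2) * z_norm[it]
        else:
            theta1 = (1.0 - delta) * mu + delta * theta_star
            o11 = delta * (1.0 - delta) * s2 + delta**2 * omega_star2
            o11_sd = math.sqrt(o11)
            kappa = delta * omega_star2 / o11_sd
            resid_sd = math.sqrt(omega_star2 - kappa**2)
            ga = -math.inf if math.isinf(a) else (a - theta1) / o11_sd
            gb = math.inf if math.isinf(b) else (b - theta1) / o11_sd
            t = float(_trunc_std_ppf(np.float64(u_trunc[it]), ga, gb))
            theta = theta_star + kappa * t + resid_sd * z_norm[it]
        # --- tau2 | theta: inverse gamma --------------------------------
        if fix_tau2 is None:
            rate = model.d + 0.5 * float(np.sum((y - theta) ** 2))
            g = rng.standard_gamma(shape)
            tau2 = rate / g
        if not (math.isfinite(theta) and math.isfinite(tau2) and tau2 > 0):
            raise FloatingPointError(
                f"non-finite Gibbs draw at iteration {it}: theta={theta}, tau2={tau2}"
            )
        thetas[it] = theta
        tau2s[it] = tau2

    th = thetas[burn_in:]
    t2 = tau2s[burn_in:]
    return PosteriorDraws(
        theta=th,
        tau2=t2,
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
        ess_theta=_ess_batch_means(th),
        ess_tau2=_ess_batch_means(t2),
    )
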