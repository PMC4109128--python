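"""Truncated-normal and interval-screened (weighted) normal distributions.

The weighted normal WN_(a,b)(m, Omega) is the law of the second coordinate
X2 of a bivariate normal (X1, X2) ~ N2(m, Omega), conditioned on the
screening event a <= X1 <= b.  It is the marginal prior of the normal mean
under a two-stage prior hierarchy in which the hyper-mean is truncated
normal on [a, b], and it interpolates between the unconstrained normal
prior and the hard-truncated prior.

All samplers take explicit integer seeds; there is no hidden global RNG
state.  Truncated-normal draws use an inverse-CDF scheme with log-space
complementary forms, so intervals carrying arbitrarily small normal mass
deep in a tail are handled without catastrophic cancellation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri, ndtri_exp

__all__ = [
    "Interval",
    "TruncatedNormalParams",
    "TruncatedMoments",
    "WeightedNormalParams",
    "truncated_normal_moments",
    "truncated_normal_sample",
    "wn_pdf",
    "wn_sample",
    "wn_moments",
    "wn_rejection_oracle",
]

_MASS_FLOOR = 1e-300
# standardized endpoints beyond this magnitude in a common tail switch the
# sampler to log-space complementary forms
_TAIL_SWITCH = 0.0

_SQRT_2PI = math.sqrt(2.0 * math.pi)


class EmptyTruncationError(ValueError):
    """The normal mass on the truncation interval underflows to zero."""


@dataclass(frozen=True)
class Interval:
    """A constraint interval [a, b]; either endpoint may be infinite."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.a < self.b:
            raise ValueError(f"require a < b strictly, got [{self.a}, {self.b}]")

    @property
    def is_unbounded(self) -> bool:
        """True when both endpoints are infinite (screening is vacuous)."""
        return math.isinf(self.a) and math.isinf(self.b)

    def standardize(self, loc: float, scale: float) -> tuple[float, float]:
        """Return ((a - loc)/scale, (b - loc)/scale) with infinite endpoints preserved."""
        ga = -math.inf if math.isinf(self.a) else (self.a - loc) / scale
        gb = math.inf if math.isinf(self.b) else (self.b - loc) / scale
        return ga, gb


@dataclass(frozen=True)
class TruncatedNormalParams:
    """N(mu, sigma2) doubly truncated to ``interval``."""

    mu: float
    sigma2: float
    interval: Interval

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)

    def standardized_endpoints(self) -> tuple[float, float]:
        return self.interval.standardize(self.mu, self.sigma)


@dataclass(frozen=True)
class TruncatedMoments:
    """Moment factors of a doubly truncated normal.

    ``-beta1`` and ``1 - beta2`` are the mean and variance of the standard
    normal truncated to the standardized interval; ``mean``/``variance``
    are the moments on the original scale.
    """

    beta1: float
    beta2: float
    mean: float
    variance: float


@dataclass(frozen=True)
class WeightedNormalParams:
    """Parameters of WN_(a,b)(m, Omega): bivariate normal screened on X1.

    ``m`` holds the locations of the screening coordinate X1 and the
    outcome coordinate X2; ``Omega`` is their 2x2 covariance; ``interval``
    applies to X1.  Derived scalars (screening sd, regression coefficient
    kappa = Cov(X1,X2)/sd(X1), residual sd) are computed on demand.
    """

    m: np.ndarray
    Omega: np.ndarray
    interval: Interval

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float).reshape(2)
        O = np.asarray(self.Omega, dtype=float).reshape(2, 2)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "Omega", O)
        if not np.allclose(O, O.T):
            raise ValueError("Omega must be symmetric")
        if O[0, 0] <= 0 or O[1, 1] <= 0:
            raise ValueError("Omega diagonal entries must be positive")
        if np.linalg.det(O) <= 0:
            raise ValueError("Omega must be positive definite")

    @classmethod
    def from_prior(
        cls, mu: float, sigma2: float, delta: float, interval: Interval
    ) -> "WeightedNormalParams":
        """WN parameters of the two-stage prior with mixing weight delta.

        The hierarchy theta | theta0 ~ N(theta0, (1-delta) sigma2),
        theta0 ~ truncated N(mu, delta sigma2) on [a, b] marginalizes to
        WN_(a,b)((mu, mu), sigma2 [[delta, delta], [delta, 1]]); the
        correlation of the standardized pair is sqrt(delta).
        """
        if not 0 < delta < 1:
            raise ValueError("from_prior requires 0 < delta < 1")
        m = np.array([mu, mu])
        O = sigma2 * np.array([[delta, delta], [delta, 1.0]])
        return cls(m, O, interval)

    # -- derived scalars -------------------------------------------------
    @property
    def screening_sd(self) -> float:
        return math.sqrt(self.Omega[0, 0])

    @property
    def outcome_sd(self) -> float:
        return math.sqrt(self.Omega[1, 1])

    @property
    def kappa(self) -> float:
        """Regression scale Cov(X1, X2)/sd(X1) of the screening on the outcome."""
        return self.Omega[0, 1] / self.screening_sd

    @property
    def residual_sd(self) -> float:
        """sd of X2 given X1 (the non-screened component of the outcome)."""
        return math.sqrt(self.Omega[1, 1] - self.Omega[0, 1] ** 2 / self.Omega[0, 0])

    @property
    def cond_screen_sd(self) -> float:
        """sd of X1 given X2."""
        return math.sqrt(self.Omega[0, 0] - self.Omega[0, 1] ** 2 / self.Omega[1, 1])

    def standardized_screen_interval(self) -> tuple[float, float]:
        return self.interval.standardize(self.m[0], self.screening_sd)

    def screening_probability(self) -> float:
        """P(a <= X1 <= b), the normalizer of the screened density."""
        za, zb = self.standardized_screen_interval()
        return _phi_diff(za, zb)


# ---------------------------------------------------------------------------
# stable normal-CDF helpers


def _phi_diff(lo, hi):
    """Phi(hi) - Phi(lo), via complementary CDFs when both arguments are positive."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    both_pos = (lo > 0) & (hi > 0)
    direct = ndtr(hi) - ndtr(lo)
    comp = ndtr(-lo) - ndtr(-hi)
    out = np.where(both_pos, comp, direct)
    return out if out.ndim else float(out)


def _log_phi_diff(lo, hi):
    """log(Phi(hi) - Phi(lo)), stable deep in either tail.

    Both-positive arguments go through log of complementary CDFs with
    log1p/expm1; both-negative mirror; straddling intervals take the log
    of the direct difference.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    out = np.empty(np.broadcast(lo, hi).shape)
    lo_b, hi_b = np.broadcast_arrays(lo, hi)
    pos = (lo_b > 0) & (hi_b > 0)
    neg = (lo_b < 0) & (hi_b < 0)
    mid = ~(pos | neg)
    if np.any(pos):
        la = log_ndtr(-lo_b[pos])  # log P(Z > lo), the larger tail mass
        lb = log_ndtr(-hi_b[pos])
        out[pos] = la + np.log1p(-np.exp(lb - la))
    if np.any(neg):
        la = log_ndtr(hi_b[neg])
        lb = log_ndtr(lo_b[neg])
        out[neg] = la + np.log1p(-np.exp(lb - la))
    if np.any(mid):
        out[mid] = np.log(ndtr(hi_b[mid]) - ndtr(lo_b[mid]))
    return out if out.ndim else float(out)


def _std_normal_pdf(x):
    x = np.asarray(x, dtype=float)
    out = np.where(np.isinf(x), 0.0, np.exp(-0.5 * np.minimum(x, 3e2) ** 2) / _SQRT_2PI)
    return out if out.ndim else float(out)


def _trunc_std_ppf(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Quantiles of the standard normal truncated to [lo, hi].

    Straddling intervals use the direct inverse CDF; intervals lying in a
    single tail use log-space complementary forms (log_ndtr / ndtri_exp),
    which remain exact for tail masses far below the double underflow of
    Phi differences.
    """
    if lo >= hi:
        raise EmptyTruncationError(f"empty truncation region [{lo}, {hi}]")
    # keep u strictly inside (0, 1): the endpoints would map to the interval
    # bounds, which may be infinite
    u = np.clip(u, 1e-16, 1.0 - 1e-16)
    if hi <= -_TAIL_SWITCH:  # left tail: mirror into the right tail
        return -_trunc_std_ppf(u, -hi, -lo)
    if lo >= _TAIL_SWITCH:  # right tail, log-space
        la = log_ndtr(-lo)  # log P(Z > lo)
        lb = -np.inf if np.isinf(hi) else log_ndtr(-hi)
        w = np.exp(lb - la)  # in [0, 1)
        # target upper-tail mass, uniform between exp(lb) and exp(la)
        log_t = la + np.log(w + u * (1.0 - w))
        return -ndtri_exp(log_t)
    fa = ndtr(lo)
    fb = ndtr(hi)
    if fb - fa < _MASS_FLOOR:
        raise EmptyTruncationError(
            f"normal mass on [{lo}, {hi}] underflows; truncation region is empty"
        )
    return ndtri(fa + u * (fb - fa))


# ---------------------------------------------------------------------------
# truncated normal


def truncated_normal_moments(p: TruncatedNormalParams) -> TruncatedMoments:
    """Mean/variance of the doubly truncated normal via the factors beta1, beta2.

    With standardized endpoints g_a, g_b and Z = Phi(g_b) - Phi(g_a):
    beta1 = (phi(g_b) - phi(g_a))/Z and
    beta2 = (g_b phi(g_b) - g_a phi(g_a))/Z + beta1^2, so the truncated
    standard normal has mean -beta1 and variance 1 - beta2; on the
    original scale mean = mu - sigma beta1, variance = sigma2 (1 - beta2).
    """
    ga, gb = p.standardized_endpoints()
    z = _phi_diff(ga, gb)
    if z < _MASS_FLOOR:
        raise EmptyTruncationError(
            f"normal mass on [{p.interval.a}, {p.interval.b}] underflows"
        )
    pa, pb = _std_normal_pdf(ga), _std_normal_pdf(gb)
    beta1 = (pb - pa) / z
    ta = 0.0 if math.isinf(ga) else ga * pa
    tb = 0.0 if math.isinf(gb) else gb * pb
    beta2 = (tb - ta) / z + beta1**2
    return TruncatedMoments(
        beta1=beta1,
        beta2=beta2,
        mean=p.mu - p.sigma * beta1,
        variance=p.sigma2 * (1.0 - beta2),
    )


def truncated_normal_sample(
    p: TruncatedNormalParams, n: int, seed: int
) -> np.ndarray:
    """n i.i.d. draws from the doubly truncated normal, reproducible under seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ga, gb = p.standardized_endpoints()
    u = rng.uniform(size=n)
    return p.mu + p.sigma * _trunc_std_ppf(u, ga, gb)


# ---------------------------------------------------------------------------
# weighted (interval-screened) normal


def wn_pdf(theta, p: WeightedNormalParams):
    """Density of the screened outcome [X2 | a <= X1 <= b] at theta.

    phi(theta; m2, Omega22) * [Phi(u_b) - Phi(u_a)] / P(a <= X1 <= b),
    where u_a, u_b standardize the interval under the conditional law of
    X1 given X2 = theta.  Accepts scalars or arrays.
    """
    theta = np.asarray(theta, dtype=float)
    m1, m2 = p.m
    sd2 = p.outcome_sd
    z = _std_normal_pdf((theta - m2) / sd2) / sd2
    if p.interval.is_unbounded:
        out = z if theta.ndim else float(z)
        return out
    slope = p.Omega[0, 1] / p.Omega[1, 1]
    csd = p.cond_screen_sd
    cond_mean = m1 + slope * (theta - m2)
    a, b = p.interval.a, p.interval.b
    ua = -np.inf if math.isinf(a) else (a - cond_mean) / csd
    ub = np.inf if math.isinf(b) else (b - cond_mean) / csd
    weight = _phi_diff(ua, ub) / p.screening_probability()
    out = z * weight
    return out if theta.ndim else float(out)


def wn_sample(p: WeightedNormalParams, n: int, seed: int) -> np.ndarray:
    """Draws via the stochastic representation of the screened normal.

    theta = m2 + kappa * T + residual_sd * Z with T standard truncated
    normal on the standardized screening interval and Z standard normal,
    independent.  For the two-stage prior parameterization this is exactly
    mu + sigma sqrt(delta) T + sigma sqrt(1 - delta) Z.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    za, zb = p.standardized_screen_interval()
    t = _trunc_std_ppf(rng.uniform(size=n), za, zb)
    z = rng.standard_normal(n)
    return p.m[1] + p.kappa * t + p.residual_sd * z


def wn_moments(p: WeightedNormalParams) -> tuple[float, float]:
    """Closed-form mean and variance of the screened outcome.

    mean = m2 - beta1 kappa, variance = Omega22 - beta2 kappa^2, with
    beta1, beta2 the truncated-normal factors of the screening coordinate.
    """
    tm = truncated_normal_moments(
        TruncatedNormalParams(p.m[0], p.Omega[0, 0], p.interval)
    )
    k = p.kappa
    return p.m[1] - tm.beta1 * k, p.Omega[1, 1] - tm.beta2 * k**2


def wn_rejection_oracle(
    p: WeightedNormalParams,
    n: int,
    seed: int,
    min_acceptance: float = 1e-6,
    max_batch: int = 2_000_000,
) -> np.ndarray:
    """Brute-force screened-normal draws by rejection.

    Samples (X1, X2) from the bivariate normal and keeps X2 whenever X1
    falls in the screening interval, until n draws are accepted.  Exact by
    construction; intended as an independent oracle for the direct sampler
    and the closed-form moments, not for production use.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    acc_prob = p.screening_probability()
    if acc_prob < min_acceptance:
        raise EmptyTruncationError(
            f"screening acceptance rate {acc_prob:.2e} below {min_acceptance:.0e}; "
            "use wn_sample instead"
        )
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(p.Omega)
    a, b = p.interval.a, p.interval.b
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        batch = min(max_batch, max(1000, int(1.2 * (n - got) / acc_prob)))
        z = rng.standard_normal((2, batch))
        x = (chol @ z) + p.m[:, None]
        keep = x[1, (x[0] >= a) & (x[0] <= b)]
        out.append(keep)
        got += keep.size
    return np.concatenate(out)[:n]
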