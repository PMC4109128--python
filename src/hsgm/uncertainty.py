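"""Objective degree of uncertainty carried by the two-stage interval prior.

The two-stage prior assigns the constraint event {a <= theta <= b} prior
probability alpha = P(a <= X2 <= b | a <= X1 <= b) under the screened
bivariate normal with covariance sigma2 [[delta, delta], [delta, 1]]; the
degree of uncertainty about the constraint is (1 - alpha) x 100%.  alpha
is a ratio of a bivariate-normal rectangle probability to a univariate
interval probability, is increasing in delta, and tends to 1 as delta -> 1
(hard truncation) and to the plain prior interval mass as delta -> 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .screened import Interval, _phi_diff, _std_normal_pdf

__all__ = [
    "UncertaintyReport",
    "DeltaSolution",
    "bvn_rect_prob",
    "alpha_of_delta",
    "delta_for_uncertainty",
    "uncertainty_curve",
]

_DELTA_CLIP = 1.0 - 1e-6


@dataclass(frozen=True)
class UncertaintyReport:
    """alpha and the degree of uncertainty (1 - alpha) x 100% for one prior."""

    alpha: float
    degree_percent: float
    delta: float
    mu: float
    sigma2: float
    interval: Interval

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "degree_percent": self.degree_percent,
            "delta": self.delta,
            "mu": self.mu,
            "sigma2": self.sigma2,
            "a": self.interval.a,
            "b": self.interval.b,
        }


@dataclass(frozen=True)
class DeltaSolution:
    """Mixing weight solving degree(delta) = target, with the variance split."""

    delta: float
    sigma0_sq: float  # first-stage variance (1 - delta) sigma2
    sigma1_sq: float  # truncated-stage variance delta sigma2
    report: UncertaintyReport


def bvn_rect_prob(
    lower1: float,
    upper1: float,
    lower2: float,
    upper2: float,
    rho: float,
) -> float:
    """P(lower1 <= X1 <= upper1, lower2 <= X2 <= upper2) for standardized
    bivariate normal with correlation rho.

    Computed by adaptive quadrature of phi(x) [Phi((u2 - rho x)/s) -
    Phi((l2 - rho x)/s)] over the first coordinate (s = sqrt(1 - rho^2)),
    to absolute accuracy ~1e-12.  Infinite endpoints are allowed.
    """
    if not lower1 < upper1 or not lower2 < upper2:
        raise ValueError("require lower < upper on each coordinate")
    if not abs(rho) < 1:
        raise ValueError("require |rho| < 1")
    if rho == 0.0:
        return float(_phi_diff(lower1, upper1) * _phi_diff(lower2, upper2))
    if math.isinf(lower1) and math.isinf(upper1):
        return float(_phi_diff(lower2, upper2))
    if math.isinf(lower2) and math.isinf(upper2):
        return float(_phi_diff(lower1, upper1))
    s = math.sqrt(1.0 - rho * rho)

    def integrand(x: float) -> float:
        lo = -np.inf if math.isinf(lower2) else (lower2 - rho * x) / s
        hi = np.inf if math.isinf(upper2) else (upper2 - rho * x) / s
        return _std_normal_pdf(x) * _phi_diff(lo, hi)

    # clip to the region carrying normal mass above the accuracy target:
    # beyond 8.5 sd the discarded tail is < 2e-17, but a huge finite range
    # would starve the adaptive rule of the central mass
    lo_c, hi_c = max(lower1, -8.5), min(upper1, 8.5)
    if lo_c >= hi_c:  # rectangle entirely beyond ~8.5 sd on coordinate 1
        lo_c, hi_c = max(lower1, -45.0), min(upper1, 45.0)
    val, _ = integrate.quad(
        integrand, lo_c, hi_c, epsabs=1e-13, epsrel=1e-13, limit=200
    )
    return float(min(max(val, 0.0), 1.0))


def alpha_of_delta(
    mu: float, sigma2: float, delta: float, interval: Interval
) -> UncertaintyReport:
    """Prior probability alpha of the constraint event under the two-stage prior.

    alpha = Phi2bar((a,b); m, Sigma) / (Phi(v*(b)) - Phi(v*(a))) with
    Sigma = sigma2 [[delta, delta], [delta, 1]], standardized correlation
    sqrt(delta) and v*(.) = (. - mu)/(sigma sqrt(delta)).  delta = 0 is the
    continuous limit alpha = Phi((b - mu)/sigma) - Phi((a - mu)/sigma).
    """
    if not 0 <= delta < 1:
        raise ValueError("delta must lie in [0, 1)")
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    sigma = math.sqrt(sigma2)
    va, vb = interval.standardize(mu, sigma)
    if delta == 0.0 or interval.is_unbounded:
        alpha = 1.0 if interval.is_unbounded else float(_phi_diff(va, vb))
    else:
        sd1 = sigma * math.sqrt(delta)
        sa, sb = interval.standardize(mu, sd1)
        denom = float(_phi_diff(sa, sb))
        if denom <= 0.0:
            raise ValueError(
                "screening interval carries no normal mass; alpha undefined"
            )
        num = bvn_rect_prob(sa, sb, va, vb, math.sqrt(delta))
        alpha = min(num / denom, 1.0)
    return UncertaintyReport(
        alpha=alpha,
        degree_percent=(1.0 - alpha) * 100.0,
        delta=delta,
        mu=mu,
        sigma2=sigma2,
        interval=interval,
    )


def delta_for_uncertainty(
    target_degree_percent: float,
    mu: float,
    sigma2: float,
    interval: Interval,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> DeltaSolution:
    """Invert the monotone map delta -> degree of uncertainty by bisection.

    The attainable range is (0%, (1 - [Phi(v(b)) - Phi(v(a))]) x 100%):
    degree decreases from the plain-prior exterior mass at delta -> 0 to
    0% at delta -> 1.  Raises ValueError with the attainable range when the
    target falls outside it.
    """
    lo_d, hi_d = 1e-12, _DELTA_CLIP
    deg = lambda d: alpha_of_delta(mu, sigma2, d, interval).degree_percent
    deg_lo, deg_hi = deg(lo_d), deg(hi_d)
    # degree is decreasing in delta
    if not deg_hi < target_degree_percent < deg_lo:
        raise ValueError(
            f"target degree {target_degree_percent:g}% outside the attainable "
            f"range ({deg_hi:.6g}%, {deg_lo:.6g}%) for this (mu, sigma2, interval)"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo_d + hi_d)
        d_mid = deg(mid)
        # stop only when both the degree and the bracket are resolved: the
        # degree map flattens near its limits, so a degree-only stop would
        # leave delta poorly determined
        if abs(d_mid - target_degree_percent) < tol and hi_d - lo_d < 1e-9:
            lo_d = hi_d = mid
            break
        if d_mid > target_degree_percent:
            lo_d = mid
        else:
            hi_d = mid
    delta = 0.5 * (lo_d + hi_d)
    report = alpha_of_delta(mu, sigma2, delta, interval)
    return DeltaSolution(
        delta=delta,
        sigma0_sq=(1.0 - delta) * sigma2,
        sigma1_sq=delta * sigma2,
        report=report,
    )


def uncertainty_curve(
    mu: float,
    sigma2_list: list[float],
    interval: Interval,
    delta_grid: list[float],
):
    """Table of (sigma2, delta, alpha, degree_percent) over a parameter grid."""
    import pandas as pd

    rows = []
    for s2 in sigma2_list:
        for d in delta_grid:
            rep = alpha_of_delta(mu, s2, d, interval)
            rows.append(
                {
                    "sigma2": s2,
                    "delta": d,
                    "alpha": rep.alpha,
                    "degree_percent": rep.degree_percent,
                }
            )
    return pd.DataFrame(rows)
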