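"""Maximum-entropy priors for a normal mean under an interval constraint.

Three levels of certainty about theta in [a, b] give three maximum-entropy
priors with matched first two moments:

* ``unconstrained`` — no constraint: the N(mu, sigma2) density pi1.
* ``certain``       — the constraint holds with probability 1: the doubly
  truncated normal pi2 on [a, b].
* ``uncertain``     — the constraint holds with prior probability alpha
  < 1: the interval-screened (weighted) normal pi3, which places reduced
  but positive density outside [a, b].

Differential entropies (in nats) are closed-form for pi1 and pi2; the
entropy of pi3 contains one intractable integral, estimated here by Monte
Carlo over draws from pi3 itself, with a reported standard error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .screened import (
    Interval,
    WeightedNormalParams,
    _log_phi_diff,
    _phi_diff,
    _std_normal_pdf,
    wn_pdf,
    wn_sample,
)

__all__ = [
    "PriorSpec",
    "EntropyEstimate",
    "prior_pdf",
    "entropy_closed_form",
    "entropy_mc",
    "diff_ent_curve",
]

_LN_2PI = math.log(2.0 * math.pi)
_DELTA_CLIP = 1.0 - 1e-6

Case = Literal["unconstrained", "certain", "uncertain"]


@dataclass(frozen=True)
class PriorSpec:
    """One of the three interval-constraint priors for the normal mean."""

    mu: float
    sigma2: float
    interval: Interval
    case: Case
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")
        if self.case not in ("unconstrained", "certain", "uncertain"):
            raise ValueError(f"unknown case {self.case!r}")
        if self.case == "uncertain":
            if not 0.0 <= self.delta < 1.0:
                if self.delta >= 1.0:
                    warnings.warn(
                        f"delta={self.delta} clipped to {_DELTA_CLIP} "
                        "(screening covariance is singular at delta=1)",
                        stacklevel=2,
                    )
                    object.__setattr__(self, "delta", _DELTA_CLIP)
                else:
                    raise ValueError("delta must lie in [0, 1)")
            elif self.delta > _DELTA_CLIP:
                warnings.warn(
                    f"delta={self.delta} clipped to {_DELTA_CLIP}", stacklevel=2
                )
                object.__setattr__(self, "delta", _DELTA_CLIP)
        if self.case == "certain":
            sigma = math.sqrt(self.sigma2)
            va, vb = self.interval.standardize(self.mu, sigma)
            if _phi_diff(va, vb) <= 0:
                raise ValueError("truncation interval carries no normal mass")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)

    def wn_params(self) -> WeightedNormalParams:
        if self.case != "uncertain" or self.delta == 0.0:
            raise ValueError("wn_params applies to the uncertain case with delta > 0")
        return WeightedNormalParams.from_prior(
            self.mu, self.sigma2, self.delta, self.interval
        )


@dataclass(frozen=True)
class EntropyEstimate:
    """A differential entropy in nats, with MC error when simulated."""

    value: float
    mc_se: float = 0.0
    n_draws: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        # mc_se = 0 with n_draws > 0 is possible when the integrand is
        # numerically constant over the draws (e.g. screening weight
        # indistinguishable from 1 at tiny delta)
        if self.mc_se < 0 or (self.mc_se > 0.0 and self.n_draws == 0):
            raise ValueError("positive mc_se requires n_draws > 0")


def prior_pdf(theta, spec: PriorSpec):
    """Density of the selected prior at theta (scalar or array)."""
    theta = np.asarray(theta, dtype=float)
    sigma = spec.sigma
    z = (theta - spec.mu) / sigma
    normal = _std_normal_pdf(z) / sigma
    if spec.case == "unconstrained" or (
        spec.case == "uncertain" and spec.delta == 0.0
    ):
        out = normal
    elif spec.case == "certain":
        va, vb = spec.interval.standardize(spec.mu, sigma)
        mass = _phi_diff(va, vb)
        inside = (theta >= spec.interval.a) & (theta <= spec.interval.b)
        out = np.where(inside, normal / mass, 0.0)
    else:
        out = wn_pdf(theta, spec.wn_params())
        out = np.asarray(out)
    return out if theta.ndim else float(out)


def entropy_closed_form(spec: PriorSpec) -> EntropyEstimate:
    """Exact differential entropy of the unconstrained or certain prior.

    Normal: (1 + ln 2 pi sigma2)/2.  Truncated normal on [a, b] with
    standardized endpoints v(a), v(b) and mass Z = Phi(v(b)) - Phi(v(a)):
    (1 + ln 2 pi sigma2 + [v(a) phi(v(a)) - v(b) phi(v(b))]/Z)/2 + ln Z.
    """
    if spec.case == "uncertain":
        raise ValueError(
            "no closed form for the uncertain-constraint prior; use entropy_mc"
        )
    if spec.case == "unconstrained":
        return EntropyEstimate(0.5 * (1.0 + _LN_2PI + math.log(spec.sigma2)))
    va, vb = spec.interval.standardize(spec.mu, spec.sigma)
    zmass = float(_phi_diff(va, vb))
    ta = 0.0 if math.isinf(va) else va * _std_normal_pdf(va)
    tb = 0.0 if math.isinf(vb) else vb * _std_normal_pdf(vb)
    value = 0.5 * (1.0 + _LN_2PI + math.log(spec.sigma2) + (ta - tb) / zmass) + math.log(
        zmass
    )
    return EntropyEstimate(value)


def entropy_mc(spec: PriorSpec, n_draws: int, seed: int) -> EntropyEstimate:
    """Entropy of the uncertain-constraint prior pi3 by Monte Carlo.

    All terms are closed-form except the expected log screening weight
    E[ln{Phi(xi* v*(b) - eta*(theta - mu)) - Phi(xi* v*(a) - eta*(theta -
    mu))}], which is averaged over draws of theta from pi3 via its
    stochastic representation; mc_se is the standard error of that term.

    Writing v*(.) = (. - mu)/(sigma sqrt(delta)) and Z* = Phi(v*(b)) -
    Phi(v*(a)), the closed part is
    (1 + ln 2 pi sigma2 + delta [v*(a) phi(v*(a)) - v*(b) phi(v*(b))]/Z*)/2
    + ln Z*.
    """
    if spec.case != "uncertain":
        raise ValueError("entropy_mc applies to the uncertain case")
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    if spec.delta == 0.0:
        # exact normal special case: the screening weight is identically 1
        return EntropyEstimate(
            0.5 * (1.0 + _LN_2PI + math.log(spec.sigma2))
        )
    sigma = spec.sigma
    delta = spec.delta
    sd1 = sigma * math.sqrt(delta)
    va, vb = spec.interval.standardize(spec.mu, sd1)
    zmass = float(_phi_diff(va, vb))
    ta = 0.0 if math.isinf(va) else va * _std_normal_pdf(va)
    tb = 0.0 if math.isinf(vb) else vb * _std_normal_pdf(vb)
    closed = 0.5 * (
        1.0 + _LN_2PI + math.log(spec.sigma2) + delta * (ta - tb) / zmass
    ) + math.log(zmass)

    p = spec.wn_params()
    theta = wn_sample(p, n_draws, seed)
    # conditional-screening arguments xi* v*(.) - eta*(theta - mu)
    xi = 1.0 / math.sqrt(1.0 - delta)
    eta = xi * math.sqrt(delta) / sigma
    lo = -np.inf if math.isinf(spec.interval.a) else xi * va - eta * (theta - spec.mu)
    hi = np.inf if math.isinf(spec.interval.b) else xi * vb - eta * (theta - spec.mu)
    logw = _log_phi_diff(lo, hi)
    term = float(np.mean(logw))
    se = float(np.std(logw, ddof=1) / math.sqrt(n_draws))
    return EntropyEstimate(closed - term, mc_se=se, n_draws=n_draws, seed=seed)


def diff_ent_curve(
    mu: float,
    sigma2_list: list[float],
    interval: Interval,
    delta_grid: list[float],
    n_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Entropy gap Ent(pi3) - Ent(pi2) over a (sigma2, delta) grid.

    One row per combination, with all three entropies and the MC standard
    error of Ent(pi3).  The gap is positive and decreases in delta (the
    uncertain prior interpolates from pi1 at delta=0 to pi2 at delta=1)
    and increases with sigma2 at fixed delta.
    """
    dg = list(delta_grid)
    if any(not 0 < d < 1 for d in dg) or any(
        d2 <= d1 for d1, d2 in zip(dg, dg[1:])
    ):
        raise ValueError("delta_grid must be strictly increasing inside (0, 1)")
    children = np.random.SeedSequence(seed).spawn(len(sigma2_list) * len(dg))
    rows = []
    k = 0
    for s2 in sigma2_list:
        ent1 = entropy_closed_form(
            PriorSpec(mu, s2, interval, "unconstrained")
        ).value
        ent2 = entropy_closed_form(PriorSpec(mu, s2, interval, "certain")).value
        for d in dg:
            sub_seed = int(children[k].generate_state(1)[0] % 2**31)
            k += 1
            est = entropy_mc(
                PriorSpec(mu, s2, interval, "uncertain", delta=d), n_draws, sub_seed
            )
            rows.append(
                {
                    "sigma2": s2,
                    "delta": d,
                    "ent_pi1": ent1,
                    "ent_pi2": ent2,
                    "ent_pi3": est.value,
                    "ent_pi3_se": est.mc_se,
                    "diff_ent": est.value - ent2,
                }
            )
    return pd.DataFrame(rows)
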