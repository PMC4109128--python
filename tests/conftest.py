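import numpy as np
import pytest
from hypothesis import settings

from hsgm import Interval, WeightedNormalParams

# derandomized hypothesis runs: the suite must be reproducible
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def reference_wn() -> WeightedNormalParams:
    """The screened-normal prior used as a running example: mu=0, sigma2=1,
    delta=0.5, constraint [-1, 1]."""
    return WeightedNormalParams.from_prior(0.0, 1.0, 0.5, Interval(-1.0, 1.0))


@pytest.fixture(scope="session")
def paper_intervals() -> list[Interval]:
    """The two constraint intervals used in the curve panels."""
    return [Interval(-1.0, 0.0), Interval(-1.0, 1.5)]


def quad_moments(pdf, lo=-np.inf, hi=np.inf):
    """Mean/variance of a density by adaptive quadrature (test oracle)."""
    from scipy import integrate

    mean, _ = integrate.quad(lambda t: t * pdf(t), lo, hi, limit=300)
    var, _ = integrate.quad(lambda t: (t - mean) ** 2 * pdf(t), lo, hi, limit=300)
    return mean, var
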