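"""Conjugate updates, full conditionals, and the Gibbs sampler."""

import math

import numpy as np
import pytest
from scipy import stats

from hsgm import (
    Dataset,
    HsgmModel,
    Interval,
    conjugate_update_single,
    constraining_effect,
    gibbs_sample,
    generate_dataset,
    tau2_full_conditional,
    theta_full_conditional,
    wn_pdf,
    wn_rejection_oracle,
)


def make_model(delta=0.5, interval=(-1.0, 1.0), mu=0.0, sigma2=1.0, c=2.0, d=1.0):
    return HsgmModel(mu=mu, sigma2=sigma2, delta=delta, interval=Interval(*interval), c=c, d=d)


class TestConjugateUpdate:
    def test_delta_zero_is_textbook_normal_update(self):
        model = make_model(delta=0.0)
        y, tau2 = 0.8, 1.0
        wn = conjugate_update_single(y, tau2, model)
        mu_post = (1.0 * y + tau2 * 0.0) / (1.0 + tau2)
        s_post2 = 1.0 * tau2 / (1.0 + tau2)
        grid = np.linspace(-4, 4, 81)
        np.testing.assert_allclose(
            wn_pdf(grid, wn),
            stats.norm.pdf(grid, mu_post, math.sqrt(s_post2)),
            rtol=1e-12,
        )

    def test_uninformative_data_limit_recovers_prior(self):
        model = make_model(delta=0.5)
        wn = conjugate_update_single(0.8, 1e12, model)
        prior = model  # posterior location/scale approach mu, sigma2
        assert wn.m[1] == pytest.approx(prior.mu, abs=1e-9)
        assert wn.Omega[1, 1] == pytest.approx(prior.sigma2, rel=1e-9)
        assert wn.Omega[0, 0] == pytest.approx(prior.delta * prior.sigma2, rel=1e-9)

    @pytest.mark.parametrize("delta,y,tau2", [(0.5, 0.8, 1.0), (0.25, -0.4, 2.0), (0.9, 1.6, 0.5)])
    def test_posterior_proportional_to_likelihood_times_prior(self, delta, y, tau2):
        from hsgm import PriorSpec, prior_pdf

        model = make_model(delta=delta)
        wn = conjugate_update_single(y, tau2, model)
        spec = PriorSpec(model.mu, model.sigma2, model.interval, "uncertain", delta=delta)
        grid = np.linspace(model.mu - 8, model.mu + 8, 161)
        numer = stats.norm.pdf(y, grid, math.sqrt(tau2)) * prior_pdf(grid, spec)
        denom = wn_pdf(grid, wn)
        ratio = numer / denom
        assert np.max(np.abs(ratio / ratio[80] - 1)) < 1e-8

    def test_rejects_nonpositive_tau2(self):
        with pytest.raises(ValueError):
            conjugate_update_single(0.0, 0.0, make_model())


class TestThetaFullConditional:
    def test_single_observation_reduction(self):
        model = make_model()
        data = Dataset(np.array([0.8]))
        cp = theta_full_conditional(data, 1.0, model)
        wn = conjugate_update_single(0.8, 1.0, model)
        np.testing.assert_allclose(cp.wn.m, wn.m)
        np.testing.assert_allclose(cp.wn.Omega, wn.Omega)

    def test_delta_zero_moments_are_unconstrained(self):
        model = make_model(delta=0.0)
        data = generate_dataset(0.3, 1.0, 50, seed=50)
        cp = theta_full_conditional(data, 1.0, model)
        assert cp.mean == cp.theta_star
        assert cp.variance == cp.omega_star2
        assert constraining_effect(cp) == (0.0, 0.0)

    def test_closed_form_scalars(self):
        model = make_model(delta=0.5)
        data = generate_dataset(0.3, 1.0, 50, seed=51)
        tau2 = 0.8
        cp = theta_full_conditional(data, tau2, model)
        n, ybar = data.n, data.ybar
        assert cp.theta_star == pytest.approx(
            (ybar * 1.0 + 0.0 * tau2 / n) / (1.0 + tau2 / n), rel=1e-12
        )
        assert cp.omega_star2 == pytest.approx(tau2 / (n + tau2), rel=1e-12)
        assert cp.theta1_star == pytest.approx(0.5 * cp.theta_star, rel=1e-12)
        assert cp.omega11_star2 == pytest.approx(
            0.25 + 0.25 * cp.omega_star2, rel=1e-12
        )
        assert cp.kappa == pytest.approx(
            0.5 * cp.omega_star2 / math.sqrt(cp.omega11_star2), rel=1e-12
        )

    def test_moments_match_rejection_oracle(self):
        model = make_model(delta=0.5)
        data = generate_dataset(0.3, 1.0, 50, seed=52)
        cp = theta_full_conditional(data, 1.0, model)
        draws = wn_rejection_oracle(cp.wn, 1_000_000, seed=53)
        se = math.sqrt(cp.variance / draws.size)
        assert abs(draws.mean() - cp.mean) < 4 * se
        var_se = cp.variance * math.sqrt(2.0 / draws.size)
        assert abs(draws.var(ddof=1) - cp.variance) < 4 * var_se


class TestTau2FullConditional:
    def test_zero_residual(self):
        model = make_model(c=2.0, d=1.0)
        data = Dataset(np.full(6, 0.3))
        assert tau2_full_conditional(data, 0.3, model) == (2.0 + 3.0, 1.0)

    def test_arithmetic(self):
        # c=2, d=1, n=4, RSS=6 -> shape 4, rate 4
        model = make_model(c=2.0, d=1.0)
        r = math.sqrt(1.5)
        data = Dataset(np.array([r, r, -r, -r]) + 0.5)
        theta = 0.5
        shape, rate = tau2_full_conditional(data, theta, model)
        assert shape == 4.0
        assert rate == pytest.approx(4.0, rel=1e-15)

    def test_inverse_gamma_moment_identity(self):
        model = make_model(c=3.0, d=2.0)
        data = generate_dataset(0.0, 1.0, 20, seed=60)
        shape, rate = tau2_full_conditional(data, 0.0, model)
        rng = np.random.default_rng(61)
        draws = rate / rng.standard_gamma(shape, size=100_000)
        expected = rate / (shape - 1)
        sd = expected / math.sqrt(shape - 2) if shape > 2 else expected
        assert abs(draws.mean() - expected) < 4 * sd / math.sqrt(draws.size)


class TestConstrainingEffect:
    def test_algebraic_identity(self):
        model = make_model(delta=0.7, interval=(-1.0, 0.5))
        data = generate_dataset(0.0, 1.0, 30, seed=70)
        cp = theta_full_conditional(data, 1.2, model)
        shift, vred = constraining_effect(cp)
        assert cp.mean - shift == pytest.approx(cp.theta_star, abs=1e-14)
        assert cp.variance - vred == pytest.approx(cp.omega_star2, abs=1e-14)

    def test_symmetric_interval_gives_zero_shift(self):
        model = make_model(delta=0.5)
        data = generate_dataset(0.0, 1.0, 200, seed=71)
        cp = theta_full_conditional(data, 1.0, model)
        # recentre the interval on theta1_star to force symmetry
        sym = HsgmModel(
            mu=model.mu, sigma2=model.sigma2, delta=model.delta,
            interval=Interval(cp.theta1_star - 0.7, cp.theta1_star + 0.7),
            c=model.c, d=model.d,
        )
        cp_sym = theta_full_conditional(data, 1.0, sym)
        shift, vred = constraining_effect(cp_sym)
        assert shift == pytest.approx(0.0, abs=1e-12)
        assert vred < 0  # screening always tightens the variance


class TestGibbs:
    def test_fixed_tau2_matches_full_conditional(self):
        model = make_model(delta=0.5)
        data = generate_dataset(0.3, 1.0, 100, seed=80)
        cp = theta_full_conditional(data, 1.0, model)
        draws = gibbs_sample(data, model, n_iter=30_000, burn_in=1_000, seed=81,
                             fix_tau2=1.0)
        assert np.all(draws.tau2 == 1.0)
        se = math.sqrt(cp.variance / draws.theta.size)
        assert abs(draws.theta.mean() - cp.mean) < 4 * se
        assert draws.theta.var(ddof=1) == pytest.approx(cp.variance, rel=0.05)

    def test_delta_zero_matches_reference_sampler(self):
        # independent textbook semi-conjugate normal-inverse-gamma Gibbs
        model = make_model(delta=0.0, c=2.0, d=1.0)
        data = generate_dataset(0.3, 1.0, 60, seed=82)
        draws = gibbs_sample(data, model, n_iter=41_000, burn_in=1_000, seed=83)

        rng = np.random.default_rng(84)
        y, n = data.y, data.n
        theta, tau2 = data.ybar, 1.0
        ref_th, ref_t2 = [], []
        for it in range(41_000):
            v = 1.0 / (n / tau2 + 1.0 / model.sigma2)
            m = v * (y.sum() / tau2 + model.mu / model.sigma2)
            theta = m + math.sqrt(v) * rng.standard_normal()
            rate = model.d + 0.5 * np.sum((y - theta) ** 2)
            tau2 = rate / rng.standard_gamma(model.c + n / 2)
            if it >= 1_000:
                ref_th.append(theta)
                ref_t2.append(tau2)
        ref_th, ref_t2 = np.array(ref_th), np.array(ref_t2)
        for ours, ref in ((draws.theta, ref_th), (draws.tau2, ref_t2)):
            se = math.hypot(ours.std() / math.sqrt(ours.size),
                            ref.std() / math.sqrt(ref.size))
            assert abs(ours.mean() - ref.mean()) < 5 * se
            assert ours.std() == pytest.approx(ref.std(), rel=0.05)

    def test_deterministic_under_seed(self):
        model = make_model()
        data = generate_dataset(0.3, 1.0, 30, seed=85)
        a = gibbs_sample(data, model, n_iter=500, burn_in=100, seed=86)
        b = gibbs_sample(data, model, n_iter=500, burn_in=100, seed=86)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.tau2, b.tau2)

    def test_posterior_concentrates_with_n(self):
        model = make_model(delta=0.5)
        sds = []
        for n in (100, 10_000):
            data = generate_dataset(0.3, 1.0, n, seed=87)
            d = gibbs_sample(data, model, n_iter=4_000, burn_in=500, seed=88)
            sds.append(d.summary()["theta_sd"])
        assert sds[1] < sds[0] / 5  # ~ n^(-1/2) shrinkage
        data = generate_dataset(0.3, 1.0, 10_000, seed=87)
        d = gibbs_sample(data, model, n_iter=4_000, burn_in=500, seed=88)
        assert d.summary()["theta_mean"] == pytest.approx(data.ybar, abs=0.02)

    def test_invalid_iteration_counts(self):
        model = make_model()
        data = generate_dataset(0.3, 1.0, 10, seed=89)
        with pytest.raises(ValueError):
            gibbs_sample(data, model, n_iter=100, burn_in=100, seed=0)
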