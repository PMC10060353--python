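"""MSD/higher-order estimators, conjugate updates and sampling distributions."""

import math

import numpy as np
import pytest
from scipy import optimize, stats

from crowddiff import (
    GammaPosterior,
    ObservationSet,
    fit_all,
    hom_loglik,
    mle_sigma_hom,
    msd_estimate,
    msd_lag,
    pooled_posterior,
    posterior_update,
)
from crowddiff.infer import IMPROPER_PRIOR, sigma2_to_diffusion
from conftest import MORSE, NO_INTERACTION


def make_obs(positions, dt=1.0):
    positions = np.asarray(positions, dtype=float)
    times = np.arange(positions.shape[1], dtype=float) * dt
    return ObservationSet(times=times, positions=positions)


def brownian_increment_obs(rng, n, k, sigma, dt):
    inc = sigma * np.sqrt(dt) * rng.standard_normal((n, k, 2))
    pos = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(inc, axis=1)], axis=1)
    return make_obs(pos, dt=dt)


class TestMsdLag:
    def test_zero_at_first_observation(self):
        obs = make_obs([[[0.0, 0.0], [3.0, 4.0]]])
        assert msd_lag(obs, 0, 0.0) == 0.0

    def test_straight_line_displacement(self):
        obs = make_obs([[[1.0, 1.0], [4.0, 5.0]]])
        assert msd_lag(obs, 0, 1.0) == 25.0

    def test_unobserved_time_rejected(self):
        obs = make_obs([[[0.0, 0.0], [1.0, 0.0]]])
        with pytest.raises(ValueError):
            msd_lag(obs, 0, 0.5)

    def test_population_average_matches_brownian_theory(self, brownian_obs):
        T = float(brownian_obs.times[-1])
        msd = np.mean([msd_lag(brownian_obs, i, T) for i in range(brownian_obs.n_particles)])
        expected = 2.0 * 0.01**2 * T
        se = expected / np.sqrt(brownian_obs.n_particles)
        assert abs(msd - expected) < 3 * se


class TestMsdEstimate:
    def test_zero_for_static_particle(self):
        obs = make_obs([[[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]])
        assert msd_estimate(obs, 0) == 0.0

    def test_single_increment_hand_value(self):
        obs = make_obs([[[0.0, 0.0], [3.0, 4.0]]])
        assert msd_estimate(obs, 0) == pytest.approx(12.5, rel=1e-15)

    def test_unbiased_on_brownian_data(self):
        rng = np.random.default_rng(40)
        sigma = 0.02
        ratios = []
        for _ in range(200):
            obs = brownian_increment_obs(rng, 1, 100, sigma, 60.0)
            ratios.append(msd_estimate(obs, 0) / sigma**2)
        assert 0.97 < np.mean(ratios) < 1.03


class TestZeroInteractionEquivalence:
    def test_hom_mle_reduces_to_msd(self, brownian_obs):
        for i in range(0, brownian_obs.n_particles, 7):
            hom = mle_sigma_hom(brownian_obs, i, NO_INTERACTION)
            msd = msd_estimate(brownian_obs, i)
            assert hom == pytest.approx(msd, rel=1e-13)

    def test_posteriors_coincide(self, brownian_obs):
        a = posterior_update(brownian_obs, 0, interaction=NO_INTERACTION, method="hom")
        b = posterior_update(brownian_obs, 0, method="msd")
        assert a.alpha == b.alpha
        assert a.beta == pytest.approx(b.beta, rel=1e-13)


class TestConjugacy:
    def test_shape_grows_by_one_per_observation(self, brownian_obs):
        post = posterior_update(brownian_obs, 3, method="msd")
        assert post.alpha == brownian_obs.n_intervals

    def test_single_increment_hand_beta(self):
        # residual (1, 1) against Sbar = I: beta = (1 + 1) / 2
        obs = make_obs([[[0.0, 0.0], [1.0, 1.0]]], dt=1.0)
        post = posterior_update(obs, 0, method="msd")
        assert post.beta == pytest.approx(1.0, rel=1e-15)

    def test_prior_passes_through(self):
        obs = make_obs([[[0.0, 0.0], [1.0, 1.0]]], dt=1.0)
        prior = GammaPosterior(2.0, 5.0)
        post = posterior_update(obs, 0, prior=prior, method="msd")
        assert post.alpha == 3.0 and post.beta == pytest.approx(6.0)

    def test_sequential_equals_batch(self, crowded_obs):
        obs, cfg = crowded_obs
        sub = ObservationSet(times=obs.times[:7], positions=obs.positions[:, :7, :])
        batch = posterior_update(sub, 2, interaction=cfg.interaction, method="hom")
        running = IMPROPER_PRIOR
        for k in range(6):
            step = ObservationSet(
                times=obs.times[k : k + 2], positions=obs.positions[:, k : k + 2, :]
            )
            running = posterior_update(step, 2, prior=running,
                                       interaction=cfg.interaction, method="hom")
        assert running.alpha == batch.alpha
        # identical quadratic forms, summed in different association orders
        assert running.beta == pytest.approx(batch.beta, rel=1e-14)

    def test_mle_equals_beta_over_k(self, crowded_obs):
        obs, cfg = crowded_obs
        for i in (0, 5, 17):
            post = posterior_update(obs, i, interaction=cfg.interaction, method="hom")
            mle = mle_sigma_hom(obs, i, cfg.interaction)
            assert mle == pytest.approx(post.beta / obs.n_intervals, rel=1e-12)

    def test_pooled_posterior_sums_increments(self, brownian_obs):
        pooled = pooled_posterior(brownian_obs, method="msd")
        singles = [
            posterior_update(brownian_obs, i, method="msd")
            for i in range(brownian_obs.n_particles)
        ]
        assert pooled.alpha == sum(p.alpha for p in singles)
        assert pooled.beta == pytest.approx(sum(p.beta for p in singles), rel=1e-12)


class TestHomLoglik:
    def test_matches_iid_gaussian_when_interactions_off(self, brownian_obs):
        i, sigma = 4, 0.012
        ll = hom_loglik(brownian_obs, i, sigma, NO_INTERACTION)
        inc = np.diff(brownian_obs.positions[i], axis=0)
        var = sigma**2 * brownian_obs.dt
        direct = float(
            stats.norm.logpdf(inc, scale=np.sqrt(var)).sum()
        )
        assert ll == pytest.approx(direct, rel=1e-12)

    def test_maximizer_equals_mle(self, crowded_obs):
        obs, cfg = crowded_obs
        i = 9
        mle = mle_sigma_hom(obs, i, cfg.interaction)
        res = optimize.minimize_scalar(
            lambda s: -hom_loglik(obs, i, s, cfg.interaction),
            bounds=(1e-4, 1.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert res.x**2 == pytest.approx(mle, rel=1e-6)

    def test_concave_in_precision(self, crowded_obs):
        # as a function of tau = sigma^-2: K log(tau) - beta tau + const
        obs, cfg = crowded_obs
        taus = np.linspace(1e3, 5e4, 40)
        lls = [hom_loglik(obs, 1, t**-0.5, cfg.interaction) for t in taus]
        second = np.diff(lls, n=2)
        assert np.all(second < 0)

    def test_rejects_nonpositive_sigma(self, crowded_obs):
        obs, cfg = crowded_obs
        with pytest.raises(ValueError):
            hom_loglik(obs, 0, 0.0, cfg.interaction)


class TestSamplingDistribution:
    def test_rescaled_beta_is_chi_squared(self):
        # 2 beta_K / sigma^2 ~ chi^2 with 2K dof on Brownian data
        rng = np.random.default_rng(12345)
        sigma, k, dt, reps = 0.01, 20, 300.0, 500
        obs = brownian_increment_obs(rng, reps, k, sigma, dt)
        stat = np.array(
            [2.0 * posterior_update(obs, i, method="msd").beta / sigma**2
             for i in range(reps)]
        )
        _, p = stats.kstest(stat, stats.chi2(2 * k).cdf)
        assert p > 0.01


class TestRecordsAndHelpers:
    def test_fit_all_matches_per_particle(self, crowded_obs):
        obs, cfg = crowded_obs
        records = fit_all(obs, interaction=cfg.interaction)
        assert len(records) == 2 * obs.n_particles
        rec = next(r for r in records if r.method == "hom" and r.particle_id == 3)
        assert rec.sigma2_mle == pytest.approx(
            mle_sigma_hom(obs, 3, cfg.interaction), rel=1e-12
        )
        assert rec.posterior.alpha == obs.n_intervals

    def test_diffusion_conversion_is_half_sigma2(self):
        assert sigma2_to_diffusion(0.02) == 0.01

    def test_hom_requires_interaction(self, brownian_obs):
        with pytest.raises(ValueError):
            posterior_update(brownian_obs, 0, method="hom")
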