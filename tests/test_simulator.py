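"""Integration kernel and the full run protocol."""

import numpy as np
import pytest

import webstab
from webstab.bioenergetics import build_params, rhs
from webstab.config import RunConfig
from webstab.niche import body_masses, trophic_levels
from webstab.noise import NoiseGenerator
from webstab.simulator import (
    disconnected_species,
    enforce_extinctions,
    integrate,
    run_protocol,
    simulate_community,
)

from conftest import make_web


def lone_producer_params(config=None):
    web = make_web(1, [])
    config = config or RunConfig()
    return build_params(web, np.array([1.0]), np.array([1.0]), 0.0, config)


class TestIntegrate:
    def test_producer_without_mortality_stays_at_capacity(self):
        config = RunConfig()
        params = lone_producer_params(config)
        params.d = np.zeros(1)  # switch mortality off for the closed form
        noise = NoiseGenerator(1, 0.0, 0.0, 0.1, seed=0)
        status, B, Brec, _, _ = integrate(params, noise, 100.0, 0.1, config,
                                          B0=np.array([params.K]))
        assert status == 0
        assert np.allclose(Brec, params.K, atol=1e-9)

    def test_producer_with_mortality_reaches_logistic_equilibrium(self):
        config = RunConfig()
        params = lone_producer_params(config)
        # dB = rB(1 - B/K) - dB has equilibrium K (1 - d/r)
        expected = params.K * (1.0 - params.d[0] / params.r)
        noise = NoiseGenerator(1, 0.0, 0.0, 0.1, seed=0)
        _, B, Brec, _, _ = integrate(params, noise, 200.0, 0.1, config,
                                     B0=np.array([1.0]))
        assert Brec[-1, 0] == pytest.approx(expected, rel=1e-6)

    def test_deterministic_run_reaches_steady_state(self, sample_web):
        # with a type III response and no noise the community settles with no
        # visible oscillations
        config = RunConfig()
        tl = trophic_levels(sample_web)
        params = build_params(sample_web, tl, body_masses(tl, 10.0), 0.5, config)
        noise = NoiseGenerator(sample_web.n_species, 0.0, 0.0, 0.1, seed=0)
        _, _, Brec, _, _ = integrate(params, noise, 2000.0, 0.1, config, seed=3)
        total = Brec[-100:].sum(axis=1)
        assert total.std() / total.mean() < 1e-3

    def test_step_halving_changes_little_when_deterministic(self, sample_web):
        config = RunConfig()
        tl = trophic_levels(sample_web)
        params = build_params(sample_web, tl, body_masses(tl, 10.0), 0.5, config)
        means = []
        for dt in (0.1, 0.05):
            noise = NoiseGenerator(sample_web.n_species, 0.0, 0.0, dt, seed=0)
            _, _, Brec, _, _ = integrate(params, noise, 2000.0, dt, config,
                                         seed=3)
            means.append(Brec[-500:].sum(axis=1).mean())
        assert abs(means[0] - means[1]) / means[1] < 0.01

    def test_kernel_matches_numpy_rhs_stepwise(self, sample_web):
        # one Euler step of the compiled kernel equals the reference rhs
        config = RunConfig()
        tl = trophic_levels(sample_web)
        params = build_params(sample_web, tl, body_masses(tl, 5.0), 0.3, config)
        rng = np.random.default_rng(1)
        B0 = rng.uniform(0.5, 1.0, sample_web.n_species)
        eps_row = rng.normal(0, 0.3, sample_web.n_species)

        class OneStep:
            def steps(self, n):
                return np.tile(eps_row, (n, 1))

        status, B, _, _, _ = integrate(params, OneStep(), 0.1, 0.1, config,
                                       B0=B0)
        d_t = params.d * np.exp(eps_row)
        expected = B0 + 0.1 * rhs(B0, d_t, params)
        expected[expected < config.extinction_threshold] = 0.0
        assert status == 0
        assert np.allclose(B, expected, rtol=1e-12, atol=1e-14)


class TestExtinctions:
    def test_threshold_rule(self):
        B, extinct = enforce_extinctions(np.array([9e-7, 1.1e-6, 0.0, 2.0]))
        assert B[0] == 0.0 and list(extinct) == [0]
        assert B[1] == pytest.approx(1.1e-6)
        assert B[3] == 2.0

    def test_extinct_species_stay_extinct(self, sample_web):
        res = simulate_community(sample_web, Z=10.0, c=0.1, sigma_e=0.6,
                                 rho=1.0, seed=5)
        B = res.recorded_biomass
        for i in range(B.shape[1]):
            zeros = np.nonzero(B[:, i] == 0.0)[0]
            if zeros.size:
                assert (B[zeros[0]:, i] == 0.0).all()


class TestDisconnection:
    def test_consumer_without_prey_is_removed(self):
        web = make_web(3, [(1, 0), (2, 1)])
        alive = np.array([True, False, True])
        out = dict(disconnected_species(web, alive))
        assert out[2] == "consumer_without_prey"

    def test_producer_without_consumer_follows_flag(self):
        web = make_web(2, [(1, 0)])
        alive = np.array([True, False])
        assert dict(disconnected_species(web, alive))[0] == \
            "producer_without_consumer"
        assert disconnected_species(web, alive,
                                    remove_unconsumed_producers=False) == []

    def test_intact_web_has_no_removals(self):
        web = make_web(3, [(1, 0), (2, 1)])
        assert disconnected_species(web, np.ones(3, dtype=bool)) == []


class TestRunProtocol:
    def test_recorded_window_is_clean(self, sample_result):
        res = sample_result
        assert res.converged
        assert res.recorded_biomass.shape[0] == 500
        assert res.noise.shape == res.recorded_biomass.shape
        window_start = res.total_time - 500.0
        assert all(t <= window_start for t in res.extinction_times.values())
        assert (res.recorded_biomass >= 0).all()

    def test_replay_is_bit_identical(self, sample_web):
        a = simulate_community(sample_web, 10.0, 0.5, 0.3, 0.5, seed=42)
        b = simulate_community(sample_web, 10.0, 0.5, 0.3, 0.5, seed=42)
        assert np.array_equal(a.recorded_biomass, b.recorded_biomass)
        assert np.array_equal(a.noise, b.noise)
        assert a.extinct == b.extinct
        assert a.n_extensions == b.n_extensions

    def test_extension_after_disconnection(self):
        # a consumer whose only prey is driven extinct must be zeroed and the
        # run extended; strong noise on a fragile chain makes this likely
        rng = np.random.default_rng(0)
        seen_removal = False
        for seed in range(12):
            web = webstab.generate_niche_web(10, 0.1, rng)
            res = simulate_community(web, 10.0, 0.0, 0.6, 1.0, seed=seed)
            if res.removed:
                seen_removal = True
                assert res.n_extensions >= 1
                for i, _reason in res.removed:
                    assert res.recorded_biomass[-1, i] == 0.0
                break
        assert seen_removal

    def test_no_survivor_marks_degenerate(self, sample_web):
        # absurdly violent noise wipes the community out
        res = simulate_community(sample_web, 10.0, 0.5, sigma_e=0.6,
                                 rho=1.0, seed=1)
        if res.n_survivors == 0:
            assert res.degenerate
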