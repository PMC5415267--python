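"""Mesoscopic integrator: elementary operations, oracles, and invariants."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import mesopop as mp
from mesopop.meso import (
    _kernel_arrays,
    effective_probability,
    expected_spike_count,
    integrate_input_step,
    sample_activity,
    update_moments,
)
from mesopop.model import PopulationParams, SimSettings, StimulusStep
from conftest import single_population_spec


class TestInputIntegration:
    def test_fixed_point_at_rest(self):
        h, y, htot = integrate_input_step(
            h=0.0, y=[0.0], a_del=[0.0], ri_ext=0.0, u_rest=0.0,
            tau_m=0.02, tau_s=[0.003], J=[5.0], dt=0.0005,
        )
        assert h == 0.0 and htot == 0.0 and y[0] == 0.0

    def test_relaxation_to_drive(self):
        """Constant external drive: h -> u_rest + RI exponentially with tau_m."""
        h = 0.0
        for _ in range(2000):
            h, _, _ = integrate_input_step(
                h, [0.0], [0.0], ri_ext=24.0, u_rest=0.0,
                tau_m=0.02, tau_s=[0.003], J=[0.0], dt=0.0005,
            )
        assert h == pytest.approx(24.0, rel=1e-9)
        # half-way check against the closed form after 20 ms
        h2 = 0.0
        for _ in range(40):
            h2, _, _ = integrate_input_step(
                h2, [0.0], [0.0], 24.0, 0.0, 0.02, [0.003], [0.0], 0.0005,
            )
        assert h2 == pytest.approx(24.0 * (1 - math.exp(-1.0)), rel=1e-9)

    @pytest.mark.parametrize("tau_s", [0.003, 0.02, 0.006])
    def test_one_step_matches_dense_ode_solution(self, tau_s, rng):
        """Exact one-step update vs a high-accuracy ODE solve.

        Inputs are genuinely piecewise-constant over the step, so the
        update should agree with the integrated ODE to ~1e-8, including
        the tau_s = tau_m degenerate case.
        """
        tau_m, dt = 0.02, 0.0005
        J = np.array([300.0, -150.0])
        tau_sv = np.array([tau_s, 0.006])
        h0 = rng.normal(10, 3)
        y0 = rng.uniform(0, 20, 2)
        a = rng.uniform(0, 30, 2)
        ri = rng.normal(5, 3)
        u_rest = 1.5

        def rhs(t, s):
            h, y1, y2 = s
            dy = (-np.array([y1, y2]) + a) / tau_sv
            dh = (-h + u_rest + ri) / tau_m + float(J @ np.array([y1, y2]))
            return [dh, dy[0], dy[1]]

        sol = solve_ivp(rhs, (0, dt), [h0, *y0], rtol=1e-12, atol=1e-12)
        h1, y1, _ = integrate_input_step(
            h0, y0, a, ri, u_rest, tau_m, tau_sv, J, dt
        )
        assert h1 == pytest.approx(sol.y[0, -1], rel=1e-8)
        assert np.allclose(y1, sol.y[1:, -1], rtol=1e-8)


class TestEffectiveProbability:
    def test_single_pool_average(self):
        assert effective_probability([0.5, 0.9], 0.2, [0.0, 0.0], 3.0) == \
            pytest.approx(0.2, rel=1e-12)

    def test_constant_probability_recovered(self):
        p = 0.123
        out = effective_probability([p, p, p], p, [1.0, 2.0, 0.5], 4.0)
        assert out == pytest.approx(p, rel=1e-12)

    def test_degenerate_variances_fall_back_to_free(self):
        assert effective_probability([0.5], 0.07, [0.0], 0.0) == 0.07

    def test_weighted_average_bounds(self, rng):
        p = rng.uniform(0, 1, 20)
        v = rng.uniform(0, 5, 20)
        pf = rng.uniform(0, 1)
        z = rng.uniform(0, 5)
        out = effective_probability(p, pf, v, z)
        assert min(p.min(), pf) - 1e-12 <= out <= max(p.max(), pf) + 1e-12

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            effective_probability([0.5], 0.2, [-1.0], 0.0)


class TestExpectedSpikeCount:
    def test_normalized_state_has_no_correction(self):
        # sum(m) + x = N: the deficit term vanishes regardless of p_eff
        m = np.array([30.0, 50.0])
        p = np.array([0.1, 0.2])
        a = expected_spike_count(p, m, 0.05, 20.0, 0.99, 100)
        b = expected_spike_count(p, m, 0.05, 20.0, 0.01, 100)
        assert a == pytest.approx(b) == pytest.approx(0.1 * 30 + 0.2 * 50 + 1.0)

    def test_clipped_to_population_size(self):
        out = expected_spike_count([1.0], [90.0], 1.0, 90.0, 1.0, 100)
        assert out == 100.0

    def test_never_negative(self):
        out = expected_spike_count([0.0], [200.0], 0.0, 0.0, 0.5, 100)
        assert out == 0.0


class TestSampleActivity:
    def test_zero_mean_always_zero(self, rng):
        for mode in ("binomial", "poisson", "gaussian"):
            assert sample_activity(0.0, 100, mode, rng) == 0.0

    def test_saturated_binomial_is_N(self, rng):
        assert all(
            sample_activity(50.0, 50, "binomial", rng) == 50.0 for _ in range(20)
        )

    def test_moments(self, rng):
        """nbar = 5, N = 1000: mean ~5; binomial var ~4.975, poisson ~5."""
        n = 40_000
        bino = np.array([sample_activity(5.0, 1000, "binomial", rng) for _ in range(n)])
        pois = np.array([sample_activity(5.0, 1000, "poisson", rng) for _ in range(n)])
        assert bino.mean() == pytest.approx(5.0, abs=0.05)
        assert pois.mean() == pytest.approx(5.0, abs=0.05)
        assert bino.var() == pytest.approx(4.975, rel=0.05)
        assert pois.var() == pytest.approx(5.0, rel=0.05)

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_activity(120.0, 100, "binomial", rng)


class TestMomentUpdates:
    def test_frozen_when_probability_zero(self):
        m, v = update_moments([5.0, 3.0], [1.0, 0.5], [0.0, 0.0])
        assert np.all(m == [5.0, 3.0]) and np.all(v == [1.0, 0.5])

    def test_survival_matches_exponential_exactly(self):
        """With P = 1 - e^{-lam dt}, the mean recursion IS e^{-lam tau}."""
        lam, dt, a0 = 10.0, 1e-4, 40.0
        p = -math.expm1(-lam * dt)
        m = a0
        for n in range(1, 2001):
            (m,), _ = update_moments([m], [0.0], [p])
            assert m == pytest.approx(a0 * math.exp(-lam * n * dt), rel=1e-10)

    def test_variance_closed_form(self):
        """v(tau) = A0 (e^{-lam tau} - e^{-2 lam tau}) for constant hazard.

        The discrete recursion solves the variance equation exactly up
        to a factor e^{lam dt}, so with lam*dt = 1e-8 the continuum
        closed form is reproduced to ~1e-8 relative error.
        """
        lam, a0 = 10.0, 25.0
        dt = 1e-9
        p = -math.expm1(-lam * dt)
        m, v = a0, 0.0
        n_steps = 20_000
        for n in range(1, n_steps + 1):
            (m_new,), (v,) = update_moments([m], [v], [p])
            m = m_new
        tau = n_steps * dt
        expect = a0 * (math.exp(-lam * tau) - math.exp(-2 * lam * tau))
        assert v == pytest.approx(expect, rel=1e-7)

    def test_variance_shape_and_maximum(self):
        """Coarser dt: the whole curve follows the closed form to O(lam dt)
        and peaks at tau = ln2 / lam."""
        lam, a0, dt = 10.0, 25.0, 1e-5
        p = -math.expm1(-lam * dt)
        m, v = a0, 0.0
        taus, vs = [], []
        for n in range(1, 20_001):
            (m,), (v,) = update_moments([m], [v], [p])
            taus.append(n * dt)
            vs.append(v)
        taus, vs = np.array(taus), np.array(vs)
        expect = a0 * (np.exp(-lam * taus) - np.exp(-2 * lam * taus))
        assert np.max(np.abs(vs - expect) / expect.max()) < 3 * lam * dt
        assert taus[np.argmax(vs)] == pytest.approx(math.log(2) / lam, rel=2e-3)

    def test_first_update_after_reset_seeds_variance(self):
        # a freshly fired cohort starts at m = dn, v = 0; one thinning
        # step leaves v = p * m (binomial decrement variance)
        m, v = update_moments([10.0], [0.0], [0.3])
        assert m[0] == pytest.approx(7.0)
        assert v[0] == pytest.approx(3.0)


class TestFreeThresholdFixedPoint:
    def test_stationary_adaptation_level(self):
        """g -> A* under constant activity; the free threshold offset is
        sum_l J_l e^{-T/tau_l} A*."""
        theta = mp.AdaptationKernel(((0.1, 1.0),), t_ref=0.004)
        pop = PopulationParams(N=100, delta_u=2.5, theta=theta)
        dt = 0.0005
        T = 1.386
        K = np.array([int(round(T / dt))], dtype=np.int64)
        spec = single_population_spec(pop, mu=20.0)
        _, eg, wfree, *_ = _kernel_arrays(spec, K, dt)
        a_star = 10.0
        g = 0.0
        for _ in range(200_000):  # 100 s >> tau_theta
            g = g * eg[0, 0] + a_star * (1 - eg[0, 0])
        offset = wfree[0, 0] * g
        assert offset == pytest.approx(0.1 * math.exp(-K[0] * dt) * 10.0, rel=1e-6)
        assert offset == pytest.approx(0.25, rel=5e-3)


class TestRunMeso:
    def test_zero_duration_empty_trace(self, lif_pop):
        spec = single_population_spec(lif_pop, mu=20.0)
        tr = mp.run_meso(spec, SimSettings(dt=0.0005, duration=0.0))
        assert tr.n_steps == 0

    def test_deterministic_mode_is_reproducible_without_rng(self, lif_pop):
        spec = single_population_spec(lif_pop, mu=25.0)
        st1 = SimSettings(dt=0.0005, duration=0.5, seed=1, sampling="deterministic")
        st2 = SimSettings(dt=0.0005, duration=0.5, seed=999, sampling="deterministic")
        a = mp.run_meso(spec, st1)
        b = mp.run_meso(spec, st2)
        assert np.array_equal(a.counts, b.counts)

    def test_seed_determinism(self, lif_pop):
        spec = single_population_spec(lif_pop, mu=25.0)
        st = SimSettings(dt=0.0005, duration=0.5, seed=42)
        a = mp.run_meso(spec, st)
        b = mp.run_meso(spec, st)
        assert np.array_equal(a.counts, b.counts)

    def test_counts_bounded_by_population_size(self, lif_pop):
        spec = single_population_spec(lif_pop, mu=35.0)
        tr = mp.run_meso(spec, SimSettings(dt=0.0005, duration=1.0, seed=3))
        assert np.all(tr.counts >= 0) and np.all(tr.counts <= lif_pop.N)

    def test_engine_matches_bruteforce_reference(self):
        """Fast circular-buffer engine vs direct-summation reference.

        Adapting, self-coupled population in deterministic mode: the two
        independent implementations must produce the same expected
        activity trajectory.
        """
        theta = mp.AdaptationKernel(((1.5, 0.01), (0.3, 0.2)), t_ref=0.004)
        pop = PopulationParams(N=80, u_th=10.0, u_r=5.0, theta=theta)
        spec = single_population_spec(pop, mu=22.0, J_w=0.02)
        st = SimSettings(dt=0.0005, duration=0.4, seed=4,
                         sampling="deterministic", record_expected=True,
                         history_T=0.15)
        a = mp.run_meso(spec, st)
        b = mp.run_meso_reference(spec, st)
        rel = np.abs(a.expected - b.expected) / (np.abs(b.expected) + 1e-9)
        assert rel.max() < 1e-6

    def test_stationary_rate_matches_renewal_theory(self, lif_pop):
        spec = single_population_spec(lif_pop, mu=30.0)
        st = SimSettings(dt=0.0002, duration=12.0, seed=5,
                         burn_in_deterministic=1.0)
        tr = mp.run_meso(spec, st)
        r_th = mp.renewal_theory(lif_pop, 30.0).rate
        assert tr.mean_rate(2.0)[0] == pytest.approx(r_th, rel=0.03)


class TestExactRefractoryPoissonReduction:
    def test_general_integrator_reduces_to_wilson_cowan_form(self):
        """For dead-time Poisson neurons the population equation is exact:
        the general integrator's expected activity equals the direct
        two-factor form f(h) * (fraction non-refractory) at every step."""
        pop = PopulationParams(N=200, model_variant="GLM")
        spec = single_population_spec(pop, mu=16.5, J_w=0.01)
        st = SimSettings(dt=0.0005, duration=2.0, seed=7, record_expected=True)
        tr = mp.run_meso(spec, st)
        nbar = mp.expected_activity_refractory_poisson(
            pop, tr.counts[:, 0], st.dt, J=spec.coupling[0, 0],
            tau_s=0.003, delay_steps=2, ri_ext=16.5,
        )
        abar = nbar / (pop.N * st.dt)
        rel = np.abs(tr.expected[:, 0] - abar) / np.maximum(np.abs(abar), 1e-12)
        assert rel.max() < 1e-10

    def test_fully_refractory_population_is_silent(self):
        """If every neuron fired within the last dead time, the expected
        activity is zero (the availability bracket vanishes)."""
        pop = PopulationParams(N=100, model_variant="GLM", t_ref=0.004)
        dn = np.zeros(4)  # synchronized start: all fired at t = -dt
        nbar = mp.expected_activity_refractory_poisson(pop, dn, 0.001, ri_ext=20.0)
        assert np.all(nbar[:3] == 0.0)


class TestGlmGifNearEquivalence:
    def test_stationary_rates_agree_at_low_rates(self):
        """eta(t) = (u_r - u_th) e^{-(t - t_ref)/tau_m} approximates the
        voltage reset; stationary rates agree within 10% below 5 Hz."""
        gif = PopulationParams(N=1)
        mu = 14.0  # low-rate regime
        r_gif = mp.renewal_theory(gif, mu).rate
        assert r_gif < 5.0
        amp = (gif.u_r - gif.u_th) * math.exp(gif.t_ref / gif.tau_m)
        eta = mp.AdaptationKernel(((amp * gif.tau_m, gif.tau_m),), t_ref=gif.t_ref)
        glm = PopulationParams(N=1, model_variant="GLM", eta=eta)
        r_glm = mp.renewal_theory(glm, mu).rate
        assert r_glm == pytest.approx(r_gif, rel=0.10)
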