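"""Microscopic network simulator and connectivity."""

import math

import numpy as np
import pytest

import mesopop as mp
from mesopop.model import NetworkSpec, PopulationParams, SimSettings, StimulusStep
from conftest import single_population_spec


def two_pop_spec(n_e=1000, n_i=250, p=0.2, w_e=0.3, w_i=-1.5, mu=24.0):
    pops = [PopulationParams(N=n_e, delta_u=2.5),
            PopulationParams(N=n_i, delta_u=2.5)]
    stim = [[StimulusStep(0.0, float("inf"), mu)] for _ in range(2)]
    return NetworkSpec(
        pops, p=np.full((2, 2), p), w=[[w_e, w_i], [w_e, w_i]],
        delay=np.full((2, 2), 0.001), tau_s=[0.003, 0.006], stimulus=stim,
    )


class TestConnectivity:
    def test_fixed_in_degree(self):
        spec = two_pop_spec(n_e=1000, n_i=250, p=0.2)
        conn = mp.build_connectivity(spec, seed=0)
        assert conn.in_degree[0, 0] == 200  # p*N_E = 0.2*1000
        assert conn.in_degree[0, 1] == 50
        for per_src in conn.presyn[::137]:
            assert len(per_src[0]) == 200
            assert len(per_src[1]) == 50

    def test_no_multapses_no_autapses(self):
        spec = two_pop_spec(n_e=50, n_i=10, p=0.5)
        conn = mp.build_connectivity(spec, seed=1)
        for i, per_src in enumerate(conn.presyn):
            for b, idx in enumerate(per_src):
                assert len(np.unique(idx)) == len(idx)  # no repeats
                if conn.pop_of[i] == b:
                    assert i not in idx

    def test_full_connectivity_cross_population(self):
        spec = two_pop_spec(n_e=20, n_i=8, p=1.0)
        conn = mp.build_connectivity(spec, seed=2)
        # cross-population at p=1: all source neurons present
        assert np.array_equal(conn.presyn[0][1], np.arange(20, 28))
        # within-population at p=1: in-degree N including self (the
        # mean-field limit where the approximation becomes exact)
        assert len(conn.presyn[0][0]) == 20

    def test_p_zero_is_uncoupled(self):
        spec = two_pop_spec(p=0.0, n_e=30, n_i=10)
        conn = mp.build_connectivity(spec, seed=3)
        assert all(len(idx) == 0 for per in conn.presyn for idx in per)

    def test_excessive_in_degree_rejected(self):
        pops = [PopulationParams(N=10), PopulationParams(N=100)]
        spec = NetworkSpec(
            pops, p=[[0.95, 0.0], [0.0, 0.0]], w=[[0.1, 0.0], [0.0, 0.0]],
            delay=np.full((2, 2), 0.001), tau_s=[0.003, 0.006],
        )
        # round(0.95*10) = 10 > 9 available after self-exclusion
        with pytest.raises(ValueError, match="in-degree"):
            mp.build_connectivity(spec, seed=4)

    def test_seed_determinism(self):
        spec = two_pop_spec(n_e=40, n_i=10, p=0.5)
        a = mp.build_connectivity(spec, seed=9)
        b = mp.build_connectivity(spec, seed=9)
        for pa, pb in zip(a.presyn, b.presyn):
            for ia, ib in zip(pa, pb):
                assert np.array_equal(ia, ib)


class TestRunMicro:
    def test_zero_escape_rate_never_spikes(self):
        pop = PopulationParams(N=50, c=0.0)
        spec = single_population_spec(pop, mu=40.0)
        tr = mp.run_micro(spec, SimSettings(dt=0.0005, duration=0.5, seed=1))
        assert tr.counts.sum() == 0

    def test_empty_trace_for_zero_duration(self, lif_pop):
        spec = single_population_spec(lif_pop, mu=20.0)
        tr = mp.run_micro(spec, SimSettings(dt=0.0005, duration=0.0))
        assert tr.n_steps == 0

    def test_seed_determinism(self, lif_pop):
        spec = single_population_spec(lif_pop, mu=25.0)
        st = SimSettings(dt=0.0005, duration=0.5, seed=77)
        a = mp.run_micro(spec, st)
        b = mp.run_micro(spec, st)
        assert np.array_equal(a.counts, b.counts)

    def test_counts_bounded_by_N(self, lif_pop):
        spec = single_population_spec(lif_pop, mu=35.0)
        tr = mp.run_micro(spec, SimSettings(dt=0.0005, duration=1.0, seed=2))
        assert np.all(tr.counts <= lif_pop.N)

    def test_stationary_rate_matches_renewal_theory(self, lif_pop):
        """Uncoupled neurons under constant drive are renewal processes."""
        spec = single_population_spec(lif_pop, mu=30.0)
        tr = mp.run_micro(spec, SimSettings(dt=0.0002, duration=12.0, seed=6))
        r_th = mp.renewal_theory(lif_pop, 30.0).rate
        assert tr.mean_rate(2.0)[0] == pytest.approx(r_th, rel=0.03)

    def test_hard_threshold_limit_matches_deterministic_lif(self):
        """delta_u -> 0: spikes lock to the deterministic threshold
        crossings, so the ISI equals t_ref + tau_m ln((mu-u_r)/(mu-u_th))
        up to one time step."""
        pop = PopulationParams(N=20, delta_u=0.01, c=1e4)
        mu = 30.0
        spec = single_population_spec(pop, mu=mu)
        dt = 0.0002
        tr = mp.run_micro(
            spec, SimSettings(dt=dt, duration=2.0, seed=3, record_raster=True)
        )
        isi_det = pop.t_ref + pop.tau_m * math.log(
            (mu - pop.u_r) / (mu - pop.u_th)
        )
        isis = np.concatenate(
            [np.diff(s) for s in tr.spike_times_by_neuron(0) if len(s) > 1]
        )
        assert np.all(np.abs(isis - isi_det) <= 2 * dt + 1e-12)

    def test_isi_distribution_matches_renewal_theory(self, lif_pop):
        """Kolmogorov-Smirnov check of the empirical ISI distribution
        against the analytic renewal ISI law at >= 10^4 intervals.

        The tolerance 0.03 covers the KS noise floor at this sample
        size (~0.014) plus the time-discretization of spike times."""
        import scipy.stats

        spec = single_population_spec(lif_pop, mu=30.0)
        tr = mp.run_micro(
            spec, SimSettings(dt=0.0002, duration=3.0, seed=19, record_raster=True)
        )
        isis = np.concatenate([
            np.diff(s) for s in tr.spike_times_by_neuron(0) if len(s) > 1
        ])
        assert len(isis) >= 10_000
        th = mp.renewal_theory(lif_pop, 30.0)
        # analytic CDF: 1 - S(t), with S from the hazard integral
        t_grid = th.isi_times
        lam = mp.analysis.renewal_hazard(lif_pop, 30.0, t_grid)
        cum = np.concatenate([[0.0], np.cumsum(
            0.5 * (lam[1:] + lam[:-1]) * np.diff(t_grid))])
        cdf_grid = 1.0 - np.exp(-cum)

        def cdf(x):
            return np.interp(x, t_grid, cdf_grid)

        ks = scipy.stats.kstest(isis, cdf).statistic
        assert ks < 0.03

    def test_raster_consistent_with_counts(self, lif_pop):
        spec = single_population_spec(lif_pop, mu=25.0)
        tr = mp.run_micro(
            spec, SimSettings(dt=0.0005, duration=0.5, seed=8, record_raster=True)
        )
        assert tr.raster is not None
        assert len(tr.raster) == int(tr.counts.sum())


class TestDensityProcess:
    def test_neuron_count_conserved_long_run(self, lif_pop):
        """sum_k m(t_l, t_k) = N exactly at every step (checked inside
        the loop; a violation raises)."""
        spec = single_population_spec(lif_pop, mu=25.0)
        tr = mp.run_density_micro(
            spec, SimSettings(dt=0.0005, duration=5.0, seed=11)
        )
        assert tr.n_steps == 10_000
        assert np.all(tr.counts >= 0) and np.all(tr.counts <= lif_pop.N)

    def test_silent_population_stays_synchronized(self):
        pop = PopulationParams(N=100, c=0.0)
        spec = single_population_spec(pop, mu=30.0)
        tr = mp.run_density_micro(spec, SimSettings(dt=0.0005, duration=0.2))
        assert tr.counts.sum() == 0

    def test_multi_population_rejected(self):
        spec = two_pop_spec(n_e=20, n_i=8, p=0.5)
        with pytest.raises(ValueError, match="one population"):
            mp.run_density_micro(spec, SimSettings(duration=0.1))

    def test_constant_hazard_survival_decay(self):
        """Dead-time Poisson cohort: the mean survival fraction of the
        synchronized cohort decays as e^{-lam (t - t_ref)} once the dead
        time has passed.  Measured via the complement: the cumulative
        activity equals N times (1 - survival) while no neuron has fired
        twice."""
        lam = 27.18  # f(mu - u_th) for mu = 17, delta_u = 2, c = 10
        # constant drive enters via u_rest so the free potential starts
        # at its stationary value (no membrane charging transient)
        pop = PopulationParams(N=4000, model_variant="GLM", u_rest=17.0)
        spec = single_population_spec(pop, mu=0.0)
        dt = 0.0005
        tr = mp.run_density_micro(spec, SimSettings(dt=dt, duration=0.02, seed=13))
        # all neurons synchronized at t = -dt; dead time ends at t_ref - dt
        cum = np.cumsum(tr.counts[:, 0])
        t_edges = (np.arange(tr.n_steps) + 1) * dt  # end of each bin
        surv = 1.0 - cum / pop.N
        expect = np.exp(-lam * np.maximum(t_edges - (pop.t_ref - dt), 0.0))
        # second spikes require first-spike + dead time; before ~9.5 ms
        # the cumulative count is purely first spikes of the cohort
        sel = t_edges < 0.0095
        assert np.allclose(surv[sel], expect[sel], atol=0.02)

    def test_rate_agrees_with_neuron_level_simulation(self, lif_pop):
        """Cross-simulator equivalence on the same uncoupled population."""
        spec = single_population_spec(lif_pop, mu=30.0)
        trd = mp.run_density_micro(spec, SimSettings(dt=0.0002, duration=12.0, seed=14))
        trm = mp.run_micro(spec, SimSettings(dt=0.0002, duration=12.0, seed=15))
        rd, rm = trd.mean_rate(2.0)[0], trm.mean_rate(2.0)[0]
        assert rd == pytest.approx(rm, rel=0.03)
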