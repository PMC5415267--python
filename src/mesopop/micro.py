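"""Microscopic reference simulators.

Two levels below the mesoscopic equations are provided:

* :func:`run_micro` -- the full spiking network: every GIF/GLM neuron is
  integrated individually, with fixed in-degree random connectivity
  (each neuron receives exactly ``round(p[a, b] * N[b])`` synapses from
  population ``b``, drawn without replacement, no self-connections).
* :func:`run_density_micro` -- the intermediate survival-number process
  for a single population: the distribution of last spike times
  ``m(t_l, t_k)`` is evolved with one binomial decrement per occupied
  bin, conserving the neuron count exactly.  This is the stochastic
  process whose moment closure yields the mesoscopic equations.

Both share the numerics of the mesoscopic integrator (exact exponential
one-step updates, trapezoidal hazard average) so that cross-level
comparisons probe the population-level approximations only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _engine
from .meso import _coupling_arrays, _pop_scalars, _round_steps
from .model import NetworkSpec, SimSettings, quasi_renewal_kernel, validate_dt
from .trace import ActivityTrace

__all__ = ["Connectivity", "build_connectivity", "run_micro", "run_density_micro"]


@dataclass
class Connectivity:
    """Fixed in-degree random connectivity.

    ``presyn[i][b]`` lists the global indices of the neurons in source
    population ``b`` projecting onto target neuron ``i``.  ``offsets``
    maps population index to the first global neuron index.
    """

    presyn: list[list[np.ndarray]]
    offsets: np.ndarray
    pop_of: np.ndarray
    in_degree: np.ndarray  # (M, M) realized in-degree per (target pop, source pop)

    @property
    def n_neurons(self) -> int:
        return len(self.presyn)

    def reverse_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style (targets, pointers) over source neurons."""
        n = self.n_neurons
        counts = np.zeros(n, dtype=np.int64)
        for i, per_src in enumerate(self.presyn):
            for idx in per_src:
                np.add.at(counts, idx, 1)
        ptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=ptr[1:])
        fill = ptr[:-1].copy()
        out = np.zeros(int(ptr[-1]), dtype=np.int64)
        for i, per_src in enumerate(self.presyn):
            for idx in per_src:
                for j in idx:
                    out[fill[j]] = i
                    fill[j] += 1
        return out, ptr


def build_connectivity(spec: NetworkSpec, seed: int) -> Connectivity:
    """Draw a fixed in-degree wiring for the network.

    In-degrees ``round(p[a, b] * N[b])`` are sampled without replacement
    (no multapses); a neuron never connects to itself (no autapses), so
    for within-population wiring at most ``N - 1`` partners exist.  The
    one exception is full connectivity (in-degree exactly ``N`` from the
    own population): there the self-connection is included, which is
    precisely what the mesoscopic mean field assumes in the ``p = 1``
    limit where it becomes exact.
    """
    rng = np.random.default_rng(seed)
    N = spec.N
    M = spec.M
    offsets = np.concatenate([[0], np.cumsum(N)])
    pop_of = np.repeat(np.arange(M), N).astype(np.int64)
    indeg = np.zeros((M, M), dtype=np.int64)
    for a in range(M):
        for b in range(M):
            want = spec.p[a, b] * N[b]
            indeg[a, b] = int(round(want))
            if abs(want - indeg[a, b]) > 1e-9:
                warnings.warn(
                    f"in-degree p*N = {want:g} for ({a} <- {b}) rounded to "
                    f"{indeg[a, b]}",
                    RuntimeWarning,
                    stacklevel=2,
                )
            avail = N[b] if (a == b and spec.p[a, b] >= 1.0) else (
                N[b] - (1 if a == b else 0)
            )
            if indeg[a, b] > avail:
                raise ValueError(
                    f"required in-degree {indeg[a, b]} from population {b} "
                    f"exceeds the {avail} available neurons"
                )
    presyn: list[list[np.ndarray]] = []
    for a in range(M):
        for i_local in range(N[a]):
            i_global = offsets[a] + i_local
            per_src: list[np.ndarray] = []
            for b in range(M):
                k = indeg[a, b]
                if k == 0:
                    per_src.append(np.empty(0, dtype=np.int64))
                    continue
                pool = N[b]
                if a == b and k < pool:
                    # sample from N-1 candidates, skipping self
                    pick = rng.choice(pool - 1, size=k, replace=False)
                    pick = pick + (pick >= i_local)
                else:
                    pick = rng.choice(pool, size=k, replace=False)
                per_src.append(np.sort(pick).astype(np.int64) + offsets[b])
            presyn.append(per_src)
    return Connectivity(presyn=presyn, offsets=offsets, pop_of=pop_of, in_degree=indeg)


def _micro_kernel_arrays(spec: NetworkSpec, dt: float):
    M = spec.M
    Lt = max(1, max(len(p.theta.components) for p in spec.populations))
    Le = max(1, max(len(p.eta.components) for p in spec.populations))
    n_comp = np.zeros(M, dtype=np.int64)
    n_eta = np.zeros(M, dtype=np.int64)
    eg = np.zeros((M, Lt))
    jump_th = np.zeros((M, Lt))
    ee = np.zeros((M, Le))
    jump_eta = np.zeros((M, Le))
    for a, pop in enumerate(spec.populations):
        n_comp[a] = len(pop.theta.components)
        for li, (j, tau) in enumerate(pop.theta.components):
            eg[a, li] = math.exp(-dt / tau)
            jump_th[a, li] = (j / tau) * math.exp(-dt / tau)
        n_eta[a] = len(pop.eta.components)
        for li, (j, tau) in enumerate(pop.eta.components):
            ee[a, li] = math.exp(-dt / tau)
            jump_eta[a, li] = (j / tau) * math.exp(-dt / tau)
    return n_comp, eg, jump_th, n_eta, ee, jump_eta


def run_micro(
    spec: NetworkSpec,
    settings: SimSettings,
    conn: Connectivity | None = None,
) -> ActivityTrace:
    """Simulate the full spiking network neuron by neuron.

    All neurons start synchronized at t = -dt (reset, refractory, one
    kernel load), mirroring the initialization of the mesoscopic
    integrator.  If ``conn`` is not given it is built deterministically
    from ``settings.seed``.
    """
    dt = settings.dt
    validate_dt(spec, dt)
    n_steps = settings.n_steps
    if conn is None:
        conn = build_connectivity(spec, seed=settings.seed + 1_000_003)
    M = spec.M
    Ntot = int(spec.N.sum())
    kref, u_rest, u_r, u_th, c_, delta_u, is_glm = _pop_scalars(spec, dt)
    cAw, cYw, em, es, dly = _coupling_arrays(spec, dt, per_synapse=True)
    n_comp, eg, jump_th, n_eta, ee, jump_eta = _micro_kernel_arrays(spec, dt)
    ext = spec.external_drive(n_steps, dt)
    radj_idx, radj_ptr = conn.reverse_adjacency()

    dn = np.zeros((n_steps, M))
    cap = int(min(Ntot * n_steps, 20_000_000)) if settings.record_raster else 0
    raster_t = np.zeros(cap, dtype=np.int64)
    raster_i = np.zeros(cap, dtype=np.int64)
    n_raster = _engine.micro_loop(
        n_steps, dt, M, Ntot,
        conn.pop_of,
        kref, em, es,
        u_rest, u_r, u_th, c_, delta_u, is_glm,
        cAw, cYw, dly, ext,
        n_comp, eg, jump_th, n_eta, ee, jump_eta,
        radj_idx, radj_ptr,
        settings.seed, settings.record_raster,
        dn, raster_t, raster_i,
    )
    raster = None
    if settings.record_raster:
        gi = raster_i[:n_raster]
        pops = conn.pop_of[gi]
        raster = np.column_stack([
            raster_t[:n_raster] * dt,
            pops.astype(float),
            (gi - conn.offsets[pops]).astype(float),
        ])
    return ActivityTrace(
        dt=dt, counts=dn, N=spec.N, raster=raster,
        meta={"level": "micro", "seed": settings.seed},
    )


def run_density_micro(spec: NetworkSpec, settings: SimSettings) -> ActivityTrace:
    """Binomial survival-number process for a single population.

    Tracks the number of survivors ``m(t_l, t_k)`` of every past
    last-spike bin; per step, each occupied bin loses a binomial number
    of neurons with its firing probability, and the bin losses sum to
    the spike count of the step.  The neuron count is conserved exactly
    at every step (an assertion failure indicates a bug).
    """
    if spec.M != 1:
        raise ValueError("the survival-number process is defined for one population")
    dt = settings.dt
    validate_dt(spec, dt)
    n_steps = settings.n_steps
    pop = spec.populations[0]
    kref, u_rest, u_r, u_th, c_, delta_u, is_glm = _pop_scalars(spec, dt)
    cA, cY, em, es, dly = _coupling_arrays(spec, dt)
    ext = spec.external_drive(n_steps, dt)[:, 0]

    ages = np.arange(n_steps + 2) * dt
    theta_tab = np.zeros(n_steps + 2)
    qr_tab = np.zeros(n_steps + 2)
    eta_tab = np.zeros(n_steps + 2)
    theta_tab[1:] = pop.theta.exp_sum(ages[1:])
    qr_tab[1:] = quasi_renewal_kernel(pop.theta, ages[1:], pop.delta_u) / pop.N
    if not pop.eta.is_empty:
        eta_tab[1:] = pop.eta.exp_sum(ages[1:])
    nonzero = np.nonzero(qr_tab > 1e-14 * pop.delta_u / pop.N)[0]
    j_qr_cut = int(max(nonzero.max() if len(nonzero) else 0, kref[0] + 1))

    dn = np.zeros(n_steps, dtype=np.int64)
    status = _engine.density_loop(
        n_steps, dt,
        pop.N, int(kref[0]), float(em[0]),
        float(u_rest[0]), float(u_r[0]), float(u_th[0]), float(c_[0]),
        float(delta_u[0]), bool(is_glm[0]),
        float(cA[0, 0]), float(cY[0, 0]), float(es[0]), int(dly[0, 0]),
        ext, theta_tab, qr_tab, eta_tab, j_qr_cut,
        settings.seed, dn,
    )
    if status != 0:
        raise AssertionError(
            f"neuron-count conservation violated at step {-status - 1}"
        )
    return ActivityTrace(
        dt=dt, counts=dn[:, None].astype(float), N=spec.N,
        meta={"level": "density", "seed": settings.seed},
    )
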