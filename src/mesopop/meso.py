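"""Stochastic mesoscopic population integrator.

Instead of simulating individual neurons, each population is represented
by the distribution of last spike times over a finite history of length
``T = K*dt``: expected survival numbers ``m_k`` and their variances
``v_k`` per last-spike bin, plus a lumped "free" pool ``(x, z)`` for
neurons whose last spike is older than ``T``.  Each time step computes
per-bin firing probabilities from the quasi-renewal hazard, forms the
variance-weighted effective firing probability ``P_Lambda``, the
expected spike count, and draws a single random number per population.

``run_meso`` drives the compiled loop in :mod:`mesopop._engine`;
``run_meso_reference`` is an independent, slow re-implementation (direct
threshold summation, no circular buffers) used to validate the fast
path; ``expected_activity_refractory_poisson`` is the closed-form
special case of non-leaky refractoriness (Poisson neurons with dead
time) for which the population equation is exact.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from . import _engine
from .model import (
    NetworkSpec,
    PopulationParams,
    SimSettings,
    choose_history_length,
    escape_rate,
    quasi_renewal_kernel,
    validate_dt,
)
from .trace import ActivityTrace

__all__ = [
    "run_meso",
    "run_meso_reference",
    "effective_probability",
    "expected_spike_count",
    "sample_activity",
    "update_moments",
    "integrate_input_step",
    "expected_activity_refractory_poisson",
]

_SAMPLING_CODE = {"binomial": 0, "poisson": 1, "gaussian": 2, "deterministic": 3}


# ---------------------------------------------------------------------------
# elementary update operations (also used by the reference integrator)
# ---------------------------------------------------------------------------

def integrate_input_step(h, y, a_del, ri_ext, u_rest, tau_m, tau_s, J, dt):
    """Exact one-step update of the coupled (h, y) input system.

    ``y`` holds the synaptic filter states (1/s) driven by the delayed
    activities ``a_del`` (1/s) of the source populations, which together
    with the external drive ``ri_ext`` (mV) are treated as constant over
    the step.  ``J`` is the row of effective couplings (mV) seen by this
    population.  Returns ``(h_new, y_new, h_tot)`` where ``h_tot`` is
    the integrated input increment in mV.
    """
    y = np.asarray(y, dtype=float)
    a_del = np.asarray(a_del, dtype=float)
    tau_s = np.asarray(tau_s, dtype=float)
    J = np.asarray(J, dtype=float)
    em = math.exp(-dt / tau_m)
    es = np.exp(-dt / tau_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_y = np.where(
            np.abs(tau_s - tau_m) < 1e-9,
            dt * em,
            tau_m * tau_s * (es - em) / (tau_s - tau_m),
        )
    h_tot = ri_ext * (1.0 - em) + float(
        np.sum(J * (tau_m * (1.0 - em) * a_del + c_y * (y - a_del)))
    )
    y_new = a_del + (y - a_del) * es
    h_new = u_rest + (h - u_rest) * em + h_tot
    return h_new, y_new, h_tot


def effective_probability(p_lam, p_free, v, z):
    """Variance-weighted effective firing probability P_Lambda.

    The weights are the survival-number variances: bins whose survival
    count fluctuates most are where the "holes and overshoots" of the
    pseudo-density live, so their hazard dominates the correction rate.
    Falls back to ``p_free`` when all variances vanish (e.g. right after
    full synchronization), where the correction term is multiplied by a
    vanishing bracket anyway.
    """
    p_lam = np.asarray(p_lam, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v < 0) or z < 0:
        raise ValueError("variances must be non-negative")
    denom = v.sum() + z
    if denom <= 0.0:
        return float(p_free)
    return float((np.dot(p_lam, v) + p_free * z) / denom)


def expected_spike_count(p_lam, m_bar, p_free, x, p_eff, N):
    """Expected spike count with the normalization-deficit correction.

    ``sum_k P_k m_k + P_free x`` is the contribution of the tracked
    pseudo-density; the deficit ``N - sum_k m_k - x`` is assigned the
    effective probability ``p_eff``.  Clipped to [0, N].
    """
    p_lam = np.asarray(p_lam, dtype=float)
    m_bar = np.asarray(m_bar, dtype=float)
    nbar = float(np.dot(p_lam, m_bar) + p_free * x + p_eff * (N - m_bar.sum() - x))
    return min(max(nbar, 0.0), float(N))


def sample_activity(nbar, N, mode, rng):
    """Draw the spike count for one step from the expected count.

    binomial (default): Delta_n ~ B(N, nbar/N); poisson: truncated at N;
    gaussian: round(nbar + sqrt(nbar)*xi) clipped to [0, N];
    deterministic: the expected count itself (infinite-N proxy).
    """
    if not (0.0 <= nbar <= N):
        raise ValueError(f"expected count {nbar} outside [0, {N}]")
    if mode == "deterministic":
        return float(nbar)
    if mode == "binomial":
        return float(rng.binomial(int(N), min(nbar / N, 1.0)))
    if mode == "poisson":
        return float(min(rng.poisson(nbar), int(N)))
    if mode == "gaussian":
        d = round(nbar + math.sqrt(nbar) * rng.standard_normal())
        return float(min(max(d, 0), int(N)))
    raise ValueError(f"unknown sampling mode {mode!r}")


def update_moments(m_bar, v, p_lam):
    """One-step update of survival means and variances.

    m_k <- (1 - P_k) m_k;  v_k <- (1 - P_k)^2 v_k + P_k m_k  (with the
    pre-update m_k), reflecting binomial thinning of each cohort.
    """
    m_bar = np.asarray(m_bar, dtype=float)
    v = np.asarray(v, dtype=float)
    p_lam = np.asarray(p_lam, dtype=float)
    m_new = (1.0 - p_lam) * m_bar
    v_new = (1.0 - p_lam) ** 2 * v + p_lam * m_bar
    return m_new, v_new


# ---------------------------------------------------------------------------
# preparation of compiled-loop inputs
# ---------------------------------------------------------------------------

def _history_lengths(spec: NetworkSpec, settings: SimSettings) -> np.ndarray:
    dt = settings.dt
    if settings.history_T == "auto":
        T = [choose_history_length(pop, dt=dt) for pop in spec.populations]
    else:
        T = [float(settings.history_T)] * spec.M
    K = np.array([max(int(round(t / dt)), 2) for t in T], dtype=np.int64)
    return K


def _round_steps(value: float, dt: float, what: str) -> int:
    steps = max(int(round(value / dt)), 1)
    if abs(steps * dt - value) > 1e-9:
        warnings.warn(
            f"{what} = {value:g} s is not a multiple of dt = {dt:g} s; "
            f"rounded to {steps * dt:g} s",
            RuntimeWarning,
            stacklevel=3,
        )
    return steps


def _kernel_arrays(spec: NetworkSpec, K: np.ndarray, dt: float):
    """Precompute per-population kernel tables for the compiled loops."""
    M = spec.M
    Kmax = int(K.max())
    n_comp = np.zeros(M, dtype=np.int64)
    Lmax = max(1, max(len(p.theta.components) for p in spec.populations))
    eg = np.zeros((M, Lmax))
    wfree = np.zeros((M, Lmax))
    theta_tab = np.zeros((M, Kmax + 2))
    qr_tab = np.zeros((M, Kmax + 2))
    eta_tab = np.zeros((M, Kmax + 2))
    ages = np.arange(Kmax + 2) * dt
    for a, pop in enumerate(spec.populations):
        n_comp[a] = len(pop.theta.components)
        for li, (j, tau) in enumerate(pop.theta.components):
            eg[a, li] = math.exp(-dt / tau)
            wfree[a, li] = j * math.exp(-K[a] * dt / tau)
        theta_tab[a, 1:] = pop.theta.exp_sum(ages[1:])
        qr_tab[a, 1:] = quasi_renewal_kernel(pop.theta, ages[1:], pop.delta_u) / pop.N
        if not pop.eta.is_empty:
            eta_tab[a, 1:] = pop.eta.exp_sum(ages[1:])
    return n_comp, eg, wfree, theta_tab, qr_tab, eta_tab


def _coupling_arrays(spec: NetworkSpec, dt: float, per_synapse: bool = False):
    """Input-integration coefficients cA, cY and decay factors."""
    M = spec.M
    tau_m = np.array([p.tau_m for p in spec.populations])
    em = np.exp(-dt / tau_m)
    es = np.exp(-dt / spec.tau_s)
    weight = spec.w if per_synapse else spec.coupling
    cA = np.zeros((M, M))
    cY = np.zeros((M, M))
    for a in range(M):
        for b in range(M):
            if weight[a, b] == 0.0 or spec.p[a, b] == 0.0:
                continue
            ts, tm = spec.tau_s[b], tau_m[a]
            cA[a, b] = weight[a, b] * tm * (1.0 - em[a])
            if abs(ts - tm) < 1e-9:
                cY[a, b] = weight[a, b] * dt * em[a]
            else:
                cY[a, b] = weight[a, b] * tm * ts * (es[b] - em[a]) / (ts - tm)
    dly = np.zeros((M, M), dtype=np.int64)
    for a in range(M):
        for b in range(M):
            dly[a, b] = _round_steps(spec.delay[a, b], dt, f"delay[{a},{b}]")
    return cA, cY, em, es, dly


def _pop_scalars(spec: NetworkSpec, dt: float):
    pops = spec.populations
    kref = np.array([_round_steps(p.t_ref, dt, "t_ref") for p in pops], dtype=np.int64)
    return (
        kref,
        np.array([p.u_rest for p in pops]),
        np.array([p.u_r for p in pops]),
        np.array([p.u_th for p in pops]),
        np.array([p.c for p in pops]),
        np.array([p.delta_u for p in pops]),
        np.array([p.model_variant == "GLM" for p in pops]),
    )


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def run_meso(spec: NetworkSpec, settings: SimSettings) -> ActivityTrace:
    """Integrate the stochastic mesoscopic population equations.

    The network starts fully synchronized at t = -dt (all neurons
    refractory, no adaptation history).  A deterministic warm-up of
    ``settings.burn_in_deterministic`` seconds (expected counts fed back
    without sampling) can be used to relax this transient before
    stochastic sampling starts.
    """
    dt = settings.dt
    validate_dt(spec, dt)
    n_steps = settings.n_steps
    M = spec.M
    K = _history_lengths(spec, settings)
    kref, u_rest, u_r, u_th, c_, delta_u, is_glm = _pop_scalars(spec, dt)
    K = np.maximum(K, kref + 2)
    cA, cY, em, es, dly = _coupling_arrays(spec, dt)
    n_comp, eg, wfree, theta_tab, qr_tab, eta_tab = _kernel_arrays(spec, K, dt)
    ext = spec.external_drive(n_steps, dt)

    dn = np.zeros((n_steps, M))
    abar = np.zeros((n_steps, M))
    free_dist = np.zeros((n_steps, M))
    det_steps = int(round(settings.burn_in_deterministic / dt))
    status = _engine.meso_loop(
        n_steps, dt, M,
        spec.N, K, kref, em,
        u_rest, u_r, u_th, c_, delta_u, is_glm,
        cA, cY, es, dly, ext,
        n_comp, eg, wfree, theta_tab, qr_tab, eta_tab,
        _SAMPLING_CODE[settings.sampling], det_steps, settings.seed,
        dn, abar, free_dist,
    )
    if status != 0:
        raise FloatingPointError(
            f"non-finite expected activity at step {status - 1} "
            f"(t = {(status - 1) * dt:g} s)"
        )
    expected = abar / (spec.N[None, :] * dt) if settings.record_expected else None
    return ActivityTrace(
        dt=dt, counts=dn, N=spec.N, expected=expected,
        meta={
            "level": "meso", "seed": settings.seed, "K": K.tolist(),
            "free_distance": free_dist,
        },
    )


# ---------------------------------------------------------------------------
# independent reference implementations (oracles)
# ---------------------------------------------------------------------------

def run_meso_reference(spec: NetworkSpec, settings: SimSettings) -> ActivityTrace:
    """Slow, direct implementation of the mesoscopic update step.

    Written against the population equations themselves: thresholds are
    obtained by explicit summation of the quasi-renewal kernel over the
    whole explicit history each step (no incremental sweep, no circular
    buffers).  Intended for validating :func:`run_meso` on small
    problems; the per-step cost is O(K^2).
    """
    dt = settings.dt
    validate_dt(spec, dt)
    n_steps = settings.n_steps
    M = spec.M
    K = _history_lengths(spec, settings)
    kref, u_rest, u_r, u_th, c_, delta_u, is_glm = _pop_scalars(spec, dt)
    K = np.maximum(K, kref + 2)
    dly = np.array(
        [[_round_steps(spec.delay[a, b], dt, "delay") for b in range(M)] for a in range(M)],
        dtype=int,
    )
    ext = spec.external_drive(n_steps, dt)
    J = spec.coupling
    rng = np.random.default_rng(settings.seed)
    det_steps = int(round(settings.burn_in_deterministic / dt))

    N = spec.N.astype(float)
    H0 = int(K.max()) + int(dly.max()) + 2
    dnfull = np.zeros((n_steps + H0, M))
    dnfull[H0 - 1, :] = N  # synchronized at t = -dt
    # per population, arrays indexed by absolute bin k (offset by H0)
    m = [np.zeros(n_steps + H0) for _ in range(M)]
    v = [np.zeros(n_steps + H0) for _ in range(M)]
    ub = [np.full(n_steps + H0, spec.populations[a].u_r) for a in range(M)]
    lam = [np.zeros(n_steps + H0) for _ in range(M)]
    for a in range(M):
        m[a][H0 - 1] = N[a]
    h = u_rest.copy()
    x = np.zeros(M)
    z = np.zeros(M)
    y = np.zeros((M, M))
    g = [np.zeros(max(1, len(p.theta.components))) for p in spec.populations]
    lam_free = np.array(
        [escape_rate(h[a], u_th[a], c_[a], delta_u[a]) for a in range(M)]
    )
    abar_out = np.zeros((n_steps, M))

    for l in range(n_steps):
        for a in range(M):
            pop = spec.populations[a]
            Ka = int(K[a])
            a_del = np.array(
                [dnfull[H0 + l - dly[a, b], b] / (N[b] * dt) for b in range(M)]
            )
            h_new, y[a], h_tot = integrate_input_step(
                h[a], y[a], a_del, ext[l, a], u_rest[a],
                pop.tau_m, spec.tau_s, J[a], dt,
            )
            # free threshold via the g variables
            th_free = u_th[a]
            for li, (jcomp, tau) in enumerate(pop.theta.components):
                egl = math.exp(-dt / tau)
                g[a][li] = g[a][li] * egl + (
                    dnfull[H0 + l - Ka, a] / (N[a] * dt)
                ) * (1.0 - egl)
                th_free += jcomp * math.exp(-Ka * dt / tau) * g[a][li]
            lf_new = escape_rate(h_new, th_free, c_[a], delta_u[a])
            p_free = -math.expm1(-0.5 * (lam_free[a] + lf_new) * dt)

            ks = np.arange(l - Ka, l)  # absolute bin indices in the window
            ages = (l + 1) - ks
            idx = H0 + ks
            # membrane potentials of refractory cohorts
            if pop.model_variant == "GLM":
                u_new = h_new + pop.eta.exp_sum(ages * dt)
            else:
                u_new = u_rest[a] + (ub[a][idx] - u_rest[a]) * math.exp(
                    -dt / pop.tau_m
                ) + h_tot
                u_new[ages <= kref[a]] = u_r[a]
            ub[a][idx] = u_new
            # thresholds by direct summation of the quasi-renewal kernel
            qr = quasi_renewal_kernel(pop.theta, ages * dt, pop.delta_u) / N[a]
            qr_oldest = (
                quasi_renewal_kernel(pop.theta, (Ka + 1) * dt, pop.delta_u) / N[a]
            )
            contrib = qr * dnfull[idx, a]
            th = np.empty(Ka)
            for i in range(Ka):
                th[i] = (
                    th_free
                    + pop.theta.exp_sum(ages[i] * dt)
                    + contrib[:i].sum()
                    - qr_oldest * dnfull[H0 + l - Ka, a]
                )
            lam_new = np.where(
                ages <= kref[a],
                0.0,
                escape_rate(u_new, th, c_[a], delta_u[a]),
            )
            p_k = -np.expm1(-0.5 * (lam[a][idx] + lam_new) * dt)
            lam[a][idx] = lam_new

            p_eff = effective_probability(p_k, p_free, v[a][idx], z[a])
            nbar = expected_spike_count(
                p_k, m[a][idx], p_free, x[a], p_eff, N[a]
            )
            if l < det_steps:
                dn_l = nbar
            else:
                dn_l = sample_activity(nbar, N[a], settings.sampling, rng)

            m[a][idx], v[a][idx] = update_moments(m[a][idx], v[a][idx], p_k)
            z[a] = (1 - p_free) ** 2 * z[a] + p_free * x[a] + v[a][H0 + l - Ka]
            x[a] = (1 - p_free) * x[a] + m[a][H0 + l - Ka]
            m[a][H0 + l] = dn_l
            v[a][H0 + l] = 0.0
            ub[a][H0 + l] = u_r[a]
            lam[a][H0 + l] = 0.0
            dnfull[H0 + l, a] = dn_l
            abar_out[l, a] = nbar
            h[a] = h_new
            lam_free[a] = lf_new

    counts = dnfull[H0:, :].copy()
    expected = abar_out / (N[None, :] * dt)
    return ActivityTrace(
        dt=dt, counts=counts, N=spec.N, expected=expected,
        meta={"level": "meso-reference", "seed": settings.seed},
    )


def expected_activity_refractory_poisson(
    pop: PopulationParams,
    dn: np.ndarray,
    dt: float,
    J: float = 0.0,
    tau_s: float = 0.003,
    delay_steps: int = 1,
    ri_ext: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Expected activity of absolute-refractory Poisson neurons (exact case).

    For neurons whose hazard is f(h(t)) once the dead time has passed
    (no reset, no adaptation), the population equation collapses to the
    Wilson-Cowan-type form

        Abar(t) = f(h(t)) * (1 - integral of A_N over the last t_ref),

    which is exact at finite N.  This routine replays a given realized
    spike-count sequence ``dn`` (with the standard synchronized start at
    t = -dt) through that equation, using the same exact exponential
    one-step input integration and trapezoidal hazard average as the
    simulators, and returns the expected counts per bin.

    Discretization of the refractory integral: cohorts whose dead time
    has not yet expired at the end of the step contribute fully to the
    refractory fraction; the single boundary cohort whose dead time
    expires during the current step fires with the half-trapezoid
    probability 1 - exp(-lambda(t_{l+1}) dt / 2), matching the per-bin
    hazard averaging of the integrators.
    """
    n_steps = len(dn)
    N = float(pop.N)
    kref = max(int(round(pop.t_ref / dt)), 1)
    ri = np.broadcast_to(np.asarray(ri_ext, dtype=float), (n_steps,))
    dnfull = np.concatenate([[N], np.asarray(dn, dtype=float)])  # bin -1 first
    h = pop.u_rest
    y = np.zeros(1)
    lam_prev = escape_rate(h, pop.u_th, pop.c, pop.delta_u)
    nbar = np.zeros(n_steps)
    for l in range(n_steps):
        a_del = np.array([dnfull[l - delay_steps + 1] / (N * dt)
                          if l - delay_steps + 1 >= 0 else 0.0])
        h, y, _ = integrate_input_step(
            h, y, a_del, ri[l], pop.u_rest, pop.tau_m,
            np.array([tau_s]), np.array([J]), dt,
        )
        lam_new = escape_rate(h, pop.u_th, pop.c, pop.delta_u)
        p_free = -math.expm1(-0.5 * (lam_prev + lam_new) * dt)
        p_boundary = -math.expm1(-0.5 * lam_new * dt)
        recent = dnfull[max(l - kref + 1, 0): l + 1].sum()
        idx_b = l - kref + 1  # cohort whose dead time expires within this step
        boundary = dnfull[idx_b] if idx_b >= 0 else 0.0
        nbar[l] = min(max(p_free * (N - recent) + p_boundary * boundary, 0.0), N)
        lam_prev = lam_new
    return nbar
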