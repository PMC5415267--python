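"""Core model objects shared by the microscopic and mesoscopic simulators.

A network consists of M homogeneous populations of generalized
integrate-and-fire (GIF) neurons.  Each neuron has a leaky membrane with
time constant ``tau_m``, is reset to ``u_r`` after a spike and clamped
there for an absolute refractory period ``t_ref``.  Spikes are emitted
stochastically with conditional intensity ("escape rate")

    lambda(t) = c * exp((u(t) - theta(t)) / delta_u),

where the dynamic threshold ``theta(t)`` accumulates a spike-triggered
kernel over past spikes.  The GLM (spike-response) variant replaces the
voltage reset by an additive spike-after-potential kernel ``eta``.

This module holds the parameter containers, the elementary model
functions (escape rate, quasi-renewal kernel) and the time-step /
history-length validation logic used by both simulation back ends.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "AdaptationKernel",
    "PopulationParams",
    "NetworkSpec",
    "SimSettings",
    "StimulusStep",
    "escape_rate",
    "quasi_renewal_kernel",
    "choose_history_length",
    "validate_dt",
    "EXP_CLAMP",
]

# Clamp on the escape-rate exponent (u - theta)/delta_u.  Firing
# probabilities saturate at 1 via 1 - exp(-lambda*dt) long before this,
# so the clamp only guards against float overflow.
EXP_CLAMP = 20.0


@dataclass(frozen=True)
class AdaptationKernel:
    """Spike-triggered kernel as a sum of exponentials.

    The kernel evaluates to ``sum_l (J_l / tau_l) * exp(-t / tau_l)`` for
    ``t >= t_ref`` (strengths ``J_l`` in mV*s, timescales ``tau_l`` in s).
    On ``(0, t_ref)`` the kernel is infinite, encoding absolute
    refractoriness; for ``t <= 0`` it is zero.  The same structure is
    used for the threshold kernel ``theta`` and, in the GLM variant, for
    the spike-after-potential ``eta`` (for which the refractory sentinel
    is irrelevant because the hazard is forced to zero there anyway).
    """

    components: tuple[tuple[float, float], ...] = ()
    t_ref: float = 0.004

    def __post_init__(self) -> None:
        if self.t_ref <= 0:
            raise ValueError("t_ref must be positive")
        comps = tuple((float(j), float(tau)) for j, tau in self.components)
        for _, tau in comps:
            if tau <= 0:
                raise ValueError("kernel timescales must be positive")
        object.__setattr__(self, "components", comps)

    @property
    def is_empty(self) -> bool:
        return len(self.components) == 0

    def exp_sum(self, t):
        """The exponential part sum_l (J_l/tau_l) e^{-t/tau_l} (mV)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for j, tau in self.components:
            out = out + (j / tau) * np.exp(-t / tau)
        return out

    def __call__(self, t):
        """Evaluate the kernel; +inf inside the absolute refractory period."""
        t = np.asarray(t, dtype=float)
        out = np.where(t > 0, self.exp_sum(t), 0.0)
        out = np.where((t > 0) & (t < self.t_ref), np.inf, out)
        if out.ndim == 0:
            return float(out)
        return out

    def envelope(self, t):
        """Upper bound sum_l |J_l/tau_l| e^{-t/tau_l}, used for tail bounds."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for j, tau in self.components:
            out = out + abs(j / tau) * np.exp(-t / tau)
        return out


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of one homogeneous population.

    Voltage-like quantities are in mV, times in seconds, ``c`` (the
    escape rate at threshold) in 1/s.  ``model_variant`` selects between
    the reset-based GIF neuron and the kernel-based GLM neuron; the GIF
    variant must not carry an ``eta`` kernel (the reset takes its role).
    """

    N: int = 500
    tau_m: float = 0.02
    t_ref: float = 0.004
    u_th: float = 15.0
    u_r: float = 0.0
    u_rest: float = 0.0
    c: float = 10.0
    delta_u: float = 2.0
    theta: AdaptationKernel | None = None
    eta: AdaptationKernel | None = None
    model_variant: Literal["GIF", "GLM"] = "GIF"

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.tau_m <= 0 or self.t_ref <= 0:
            raise ValueError("tau_m and t_ref must be positive")
        if self.delta_u <= 0:
            raise ValueError("delta_u must be positive")
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.model_variant not in ("GIF", "GLM"):
            raise ValueError("model_variant must be 'GIF' or 'GLM'")
        theta = self.theta or AdaptationKernel((), self.t_ref)
        eta = self.eta or AdaptationKernel((), self.t_ref)
        if self.model_variant == "GIF" and not eta.is_empty:
            raise ValueError("GIF variant uses the voltage reset; eta must be empty")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "eta", eta)


@dataclass(frozen=True)
class StimulusStep:
    """One piecewise-constant external-drive segment RI_ext (mV).

    Active on [start, stop): closed on the left, open on the right.
    """

    start: float
    stop: float
    amplitude: float


@dataclass
class NetworkSpec:
    """M populations plus connectivity and stimulus protocol.

    ``p``, ``w`` and ``delay`` are MxM matrices with row index = target
    population, column index = source population.  ``tau_s`` is the
    per-source synaptic decay time.  The effective mesoscopic coupling is
    ``J[a, b] = p[a, b] * N[b] * w[a, b]`` (mV).  ``stimulus[a]`` is a
    list of :class:`StimulusStep`; the total drive of population ``a`` is
    ``mu(t) = u_rest + RI_ext(t)``.
    """

    populations: list[PopulationParams]
    p: np.ndarray
    w: np.ndarray
    delay: np.ndarray
    tau_s: np.ndarray
    stimulus: list[list[StimulusStep]] = field(default_factory=list)

    def __post_init__(self) -> None:
        M = len(self.populations)
        self.p = np.asarray(self.p, dtype=float).reshape(M, M)
        self.w = np.asarray(self.w, dtype=float).reshape(M, M)
        self.delay = np.asarray(self.delay, dtype=float).reshape(M, M)
        self.tau_s = np.asarray(self.tau_s, dtype=float).reshape(M)
        if not self.stimulus:
            self.stimulus = [[] for _ in range(M)]
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("connection probabilities must lie in [0, 1]")
        if np.any(self.delay <= 0):
            raise ValueError("transmission delays must be positive")
        if np.any(self.tau_s <= 0):
            raise ValueError("synaptic time constants must be positive")
        if not np.all(np.isfinite(self.coupling)):
            raise ValueError("effective coupling J = p*N*w must be finite")

    @property
    def M(self) -> int:
        return len(self.populations)

    @property
    def N(self) -> np.ndarray:
        return np.array([pop.N for pop in self.populations], dtype=np.int64)

    @property
    def coupling(self) -> np.ndarray:
        """Effective coupling J[a, b] = p[a, b] * N[b] * w[a, b] (mV)."""
        return self.p * self.N[None, :] * self.w

    def external_drive(self, n_steps: int, dt: float) -> np.ndarray:
        """RI_ext(t_l) per step and population, shape (n_steps, M) in mV.

        Step boundaries are aligned to the dt grid, closed on the left.
        """
        out = np.zeros((n_steps, self.M))
        t = np.arange(n_steps) * dt
        for a, segs in enumerate(self.stimulus):
            for seg in segs:
                out[(t >= seg.start - 1e-12) & (t < seg.stop - 1e-12), a] += seg.amplitude
        return out


@dataclass(frozen=True)
class SimSettings:
    """Simulation settings shared by both levels of description."""

    dt: float = 0.0002
    duration: float = 1.0
    seed: int = 0
    history_T: float | Literal["auto"] = "auto"
    sampling: Literal["binomial", "poisson", "gaussian", "deterministic"] = "binomial"
    record_expected: bool = False
    record_raster: bool = False
    burn_in_deterministic: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.sampling not in ("binomial", "poisson", "gaussian", "deterministic"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


def escape_rate(u, theta_total, c: float, delta_u: float):
    """Exponential escape rate c * exp((u - theta_total)/delta_u) in 1/s.

    ``theta_total`` may be +inf (absolute-refractory sentinel), in which
    case the rate is exactly zero.  The exponent is clamped at
    ``EXP_CLAMP`` to avoid overflow.
    """
    if delta_u <= 0:
        raise ValueError("delta_u must be positive")
    u = np.asarray(u, dtype=float)
    th = np.asarray(theta_total, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("membrane potential must be finite")
    x = np.where(np.isposinf(th), -np.inf, np.minimum((u - th) / delta_u, EXP_CLAMP))
    out = c * np.exp(x)
    if out.ndim == 0:
        return float(out)
    return out


def quasi_renewal_kernel(theta: AdaptationKernel, t, delta_u: float):
    """Quasi-renewal kernel theta_tilde(t) = delta_u * (1 - e^{-theta(t)/delta_u}).

    Saturates at ``delta_u`` where ``theta`` is infinite (absolute
    refractoriness) and reduces to ``theta`` itself where the kernel is
    small compared to ``delta_u``.
    """
    th = np.asarray(theta(t), dtype=float)
    out = delta_u * -np.expm1(-th / delta_u)
    if out.ndim == 0:
        return float(out)
    return out


def choose_history_length(
    pop: PopulationParams,
    tol_theta: float = 0.01,
    dt: float | None = None,
    n_rel: float = 5.0,
    max_T: float | None = None,
) -> float:
    """Length T of the explicit refractory history for one population.

    T must (i) cover several relative-refractory timescales,
    ``T >= n_rel * max(t_ref, tau_m)``, and (ii) be long enough that the
    spike-triggered kernels have decayed to ``tol_theta * delta_u``, so
    that beyond T the quasi-renewal kernel is indistinguishable from the
    raw kernel and a neuron's hazard no longer depends on its exact last
    spike time.  The kernel-tail condition is checked on the envelope
    ``sum_l |J_l/tau_l| e^{-t/tau_l}`` which is monotone, so the first
    grid point satisfying it bounds the whole tail.
    """
    if not (0.0 < tol_theta < 1.0):
        raise ValueError("tol_theta must lie in (0, 1)")
    T = n_rel * max(pop.t_ref, pop.tau_m)
    if dt is not None:
        T = math.ceil(T / dt - 1e-9) * dt
    kernels = [k for k in (pop.theta, pop.eta) if k is not None and not k.is_empty]
    if not kernels:
        return T
    bound = tol_theta * pop.delta_u
    if max_T is None:
        max_T = T + 25.0 * max(tau for k in kernels for _, tau in k.components)
    step = dt if dt is not None else min(
        tau for k in kernels for _, tau in k.components) / 10.0

    def tail(t: float) -> float:
        return float(sum(k.envelope(t) for k in kernels))

    while tail(T) > bound:
        T += step
        if T > max_T:
            raise ValueError(
                f"kernel tail does not fall below {bound:g} mV within the "
                f"cap T = {max_T:g} s; increase tol_theta or the cap"
            )
    return T


def validate_dt(spec: NetworkSpec, dt: float, probe=None) -> dict:
    """Check the time-step conditions for a network.

    Hard requirements (raise on failure): ``dt <= t_ref`` for every
    population (at most one spike per neuron per bin) and ``dt`` not
    larger than any transmission delay.  Additionally, if ``probe`` is
    given as a pair of arrays ``(u_minus_theta, dt_probe)`` sampled on a
    trajectory, the accuracy condition of the trapezoidal hazard average,

        ((d/dt (u - theta))^2 + delta_u |d2/dt2 (u - theta)|) * dt^2 << 12 delta_u^2,

    is evaluated by finite differences and a warning is emitted when the
    left side exceeds 10% of the right side.  Returns a diagnostics dict.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    diags: dict = {"dt": dt}
    min_tref = min(pop.t_ref for pop in spec.populations)
    diags["refractory_ok"] = dt <= min_tref + 1e-12
    if not diags["refractory_ok"]:
        raise ValueError(f"dt = {dt:g} s exceeds the shortest t_ref = {min_tref:g} s")
    coupled = (spec.p * np.abs(spec.w)) > 0
    if np.any(coupled):
        min_delay = float(spec.delay[coupled].min())
        diags["delay_ok"] = dt <= min_delay + 1e-12
        if not diags["delay_ok"]:
            raise ValueError(f"dt = {dt:g} s exceeds the shortest delay = {min_delay:g} s")
    else:
        diags["delay_ok"] = True
    if probe is not None:
        x, dtp = np.asarray(probe[0], dtype=float), float(probe[1])
        if x.size >= 3:
            d1 = np.gradient(x, dtp)
            d2 = np.gradient(d1, dtp)
            delta_u = min(pop.delta_u for pop in spec.populations)
            lhs = (d1**2 + delta_u * np.abs(d2)) * dt**2
            ratio = float(np.max(lhs) / (12.0 * delta_u**2))
            diags["trapezoid_ratio"] = ratio
            diags["trapezoid_ok"] = ratio < 0.1
            if not diags["trapezoid_ok"]:
                warnings.warn(
                    f"trapezoidal-hazard accuracy condition is strained "
                    f"(ratio {ratio:.3g} >= 0.1); consider a smaller dt",
                    RuntimeWarning,
                    stacklevel=2,
                )
    return diags
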