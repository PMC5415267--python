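"""Statistics of population activities.

Power spectra (empirical segment-averaged periodograms and the analytic
renewal-theory spectrum), interspike-interval statistics, trial-averaged
PSTH, and residence-time ("dominance time") analysis of bistable
competition traces.

Conventions: the power spectrum is the two-sided spectral density
``C(f) = lim <|A~(f; T)|^2>/T`` evaluated on positive frequencies,
with ``A~`` the Fourier transform of the mean-subtracted activity on a
window of length ``T``.  With this normalization a Poisson population of
rate ``r`` and size ``N`` has the flat spectrum ``r/N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from .model import PopulationParams, escape_rate
from .trace import ActivityTrace

__all__ = [
    "SpectrumEstimate",
    "RenewalStats",
    "DominanceStats",
    "power_spectrum",
    "renewal_hazard",
    "renewal_theory",
    "renewal_spectrum",
    "isi_stats",
    "psth_and_std",
    "dominance_times",
]


@dataclass
class SpectrumEstimate:
    frequencies: np.ndarray    # Hz
    power: np.ndarray          # (1/s)^2 per Hz
    n_segments: int
    segment_length: float      # s

    def at(self, f: float) -> float:
        """Power at the frequency-grid point closest to ``f``."""
        return float(self.power[np.argmin(np.abs(self.frequencies - f))])

    def band_mean(self, f_lo: float, f_hi: float) -> float:
        sel = (self.frequencies >= f_lo) & (self.frequencies <= f_hi)
        return float(self.power[sel].mean())


@dataclass
class RenewalStats:
    rate: float                # 1/s
    cv: float
    isi_times: np.ndarray | None = None
    isi_density: np.ndarray | None = None


@dataclass
class DominanceStats:
    durations: np.ndarray      # s
    mean: float
    cv: float
    serial_correlation: float


def _as_series(trace, pop: int, dt: float | None):
    if isinstance(trace, ActivityTrace):
        return trace.activity[:, pop], trace.dt
    if dt is None:
        raise ValueError("dt is required when passing a bare array")
    return np.asarray(trace, dtype=float), dt


def power_spectrum(
    trace,
    segment_length: float,
    pop: int = 0,
    dt: float | None = None,
) -> SpectrumEstimate:
    """Segment-averaged periodogram of a stationary activity trace.

    Non-overlapping rectangular windows of ``segment_length`` seconds,
    per-segment mean removal; the caller is responsible for discarding
    non-stationary transients first.
    """
    x, dt = _as_series(trace, pop, dt)
    nper = int(round(segment_length / dt))
    n_seg = len(x) // nper
    if n_seg < 1:
        raise ValueError("trace is shorter than one segment")
    segs = x[: n_seg * nper].reshape(n_seg, nper)
    segs = segs - segs.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(segs, axis=1) * dt) ** 2 / (nper * dt)
    freqs = np.fft.rfftfreq(nper, dt)
    return SpectrumEstimate(
        frequencies=freqs[1:],
        power=spec.mean(axis=0)[1:],
        n_segments=n_seg,
        segment_length=nper * dt,
    )


def renewal_hazard(pop: PopulationParams, mu: float, t: np.ndarray) -> np.ndarray:
    """Hazard lambda(t|0) of a non-adapting neuron under constant drive mu.

    Zero during the dead time.  For the GIF variant the membrane relaxes
    from the reset towards mu, u(t) = mu + (u_r - mu) exp(-(t -
    t_ref)/tau_m); for the GLM variant there is no reset and the
    membrane sits at mu plus the spike-after-potential eta(t).  The
    hazard is the escape rate at u(t) - u_th.
    """
    if pop.theta is not None and not pop.theta.is_empty:
        raise ValueError("renewal theory requires a non-adapting population")
    t = np.asarray(t, dtype=float)
    if pop.model_variant == "GLM":
        u = mu + pop.eta.exp_sum(t)
    else:
        u = mu + (pop.u_r - mu) * np.exp(-np.maximum(t - pop.t_ref, 0.0) / pop.tau_m)
    lam = escape_rate(u, pop.u_th, pop.c, pop.delta_u)
    return np.where(t > pop.t_ref, lam, 0.0)


def _renewal_grid(pop: PopulationParams, mu: float, grid: float | None):
    """Hazard, survival and ISI density on a fine grid.

    The hazard is identically zero on [0, t_ref) and jumps to its
    right-limit value at t_ref; a grid point is placed exactly at t_ref
    and all quadrature is restricted to the support [t_ref, inf), so the
    discontinuity introduces no integration error.  Returns the index
    ``n_ref`` of the t_ref grid point and the asymptotic hazard used for
    the analytic exponential tail beyond the grid.
    """
    h = grid if grid is not None else pop.tau_m / 100.0
    lam_inf = escape_rate(mu, pop.u_th, pop.c, pop.delta_u)
    if lam_inf <= 1e-12:
        raise ValueError("hazard is numerically zero; no stationary rate exists")
    t_max = pop.t_ref + 10.0 * pop.tau_m + 40.0 / lam_inf
    n_ref = max(int(round(pop.t_ref / h)), 1)
    h = pop.t_ref / n_ref
    n = int(math.ceil(t_max / h))
    t = np.arange(n + 1) * h
    # right-limit hazard on the support (the value at exactly t_ref)
    lam = renewal_hazard(pop, mu, np.maximum(t, pop.t_ref * (1 + 1e-12)))
    lam[:n_ref] = 0.0
    cum = np.zeros(n + 1)
    cum[n_ref:] = np.concatenate(
        [[0.0], np.cumsum((lam[n_ref + 1:] + lam[n_ref:-1]) * 0.5 * h)]
    )
    S = np.exp(-cum)
    keep = S > 1e-14
    if not keep.all():
        last = int(np.argmin(keep))
        t, lam, S = t[: last + 1], lam[: last + 1], S[: last + 1]
    p_isi = lam * S
    return t, lam, S, p_isi, lam_inf, h, n_ref


def renewal_theory(
    pop: PopulationParams, mu: float, grid: float | None = None
) -> RenewalStats:
    """Stationary rate, CV and ISI density of a renewal GIF neuron.

    The rate is 1 / integral of the survival function; moments are
    computed by Simpson quadrature on a fine grid with the analytic
    exponential tail (hazard -> f(mu - u_th)) appended.  The dead-time
    part [0, t_ref], where S = 1 exactly, is integrated in closed form.
    """
    t, lam, S, p_isi, lam_inf, h, n_ref = _renewal_grid(pop, mu, grid)
    T_end, S_end = t[-1], S[-1]
    tr = pop.t_ref
    m1 = tr + simpson(S[n_ref:], x=t[n_ref:]) + S_end / lam_inf
    m2 = 2.0 * (
        tr**2 / 2.0
        + simpson(t[n_ref:] * S[n_ref:], x=t[n_ref:])
        + S_end * (T_end / lam_inf + 1.0 / lam_inf**2)
    )
    rate = 1.0 / m1
    var = m2 - m1**2
    cv = math.sqrt(max(var, 0.0)) / m1
    return RenewalStats(rate=rate, cv=cv, isi_times=t, isi_density=p_isi)


def renewal_spectrum(
    pop: PopulationParams,
    mu: float,
    freqs: np.ndarray,
    grid: float | None = None,
) -> SpectrumEstimate:
    """Analytic power spectrum of N independent renewal spike trains.

    C(f) = (r/N) * (1 - |P~(f)|^2) / |1 - P~(f)|^2 with P~ the Fourier
    transform of the ISI density (convention e^{+2 pi i f t}).  To avoid
    catastrophic cancellation at low frequencies, the deficit
    D(f) = 1 - P~(f) = integral of p(t) (1 - e^{i w t}) dt is computed
    directly, and the spectrum evaluated as (2 Re D - |D|^2)/|D|^2.
    The density is integrated on a grid fine enough for the highest
    requested frequency; the exponential tail beyond the grid is added
    in closed form.
    """
    freqs = np.asarray(freqs, dtype=float)
    f_max = float(freqs.max())
    h_req = grid if grid is not None else pop.tau_m / 100.0
    h_req = min(h_req, 1.0 / (50.0 * f_max))
    t, lam, S, p_isi, lam_inf, h, n_ref = _renewal_grid(pop, mu, h_req)
    T_end, S_end = t[-1], S[-1]
    rate = 1.0 / (
        pop.t_ref + simpson(S[n_ref:], x=t[n_ref:]) + S_end / lam_inf
    )
    # trapezoidal quadrature of p(t) (1 - e^{iwt}) over the support,
    # chunked over frequencies to keep the phase matrix small
    ts = t[n_ref:]
    weights = np.full(len(ts), h)
    weights[0] = weights[-1] = h / 2.0
    pw = p_isi[n_ref:] * weights
    # normalize the density (gridded part + analytic tail mass S_end) so
    # the numerical ISI distribution is a proper one and D(0) = 0
    norm = pw.sum() + S_end
    pw /= norm
    s_tail = S_end / norm
    mass = pw.sum()
    D = np.empty(len(freqs), dtype=complex)
    chunk = max(1, 4_000_000 // max(len(ts), 1))
    for i in range(0, len(freqs), chunk):
        w = 2.0j * math.pi * freqs[i: i + chunk, None]
        D[i: i + chunk] = mass - np.exp(w * ts[None, :]) @ pw
    # analytic tail: p(t) = lam_inf * s_tail * exp(-lam_inf (t - T_end))
    wf = 2.0j * math.pi * freqs
    D += s_tail - lam_inf * s_tail * np.exp(wf * T_end) / (lam_inf - wf)
    frac = (2.0 * D.real - np.abs(D) ** 2) / np.abs(D) ** 2
    return SpectrumEstimate(
        frequencies=freqs,
        power=(rate / pop.N) * frac,
        n_segments=0,
        segment_length=math.inf,
    )


def isi_stats(spike_trains, min_isis: int = 100, n_bins: int = 100) -> RenewalStats:
    """Empirical rate, CV and ISI histogram from per-neuron spike times.

    ``spike_trains`` is an iterable of 1-D arrays of spike times (one
    per neuron), e.g. from :meth:`ActivityTrace.spike_times_by_neuron`.
    """
    isis = []
    total_spikes = 0
    t_span = 0.0
    for st in spike_trains:
        st = np.asarray(st, dtype=float)
        total_spikes += len(st)
        if len(st) >= 2:
            isis.append(np.diff(st))
            t_span = max(t_span, st[-1] - st[0])
    if not isis:
        raise ValueError("no interspike intervals found")
    isis = np.concatenate(isis)
    if len(isis) < min_isis:
        raise ValueError(f"only {len(isis)} ISIs; need at least {min_isis}")
    mean = isis.mean()
    cv = isis.std(ddof=1) / mean
    hist, edges = np.histogram(isis, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RenewalStats(rate=1.0 / mean, cv=float(cv),
                        isi_times=centers, isi_density=hist)


def psth_and_std(traces: list) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean and standard deviation of A_N across aligned trials.

    Accepts a list of :class:`ActivityTrace` (or activity arrays of
    identical shape); returns arrays shaped like one trial.
    """
    arrs = [
        t.activity if isinstance(t, ActivityTrace) else np.asarray(t, dtype=float)
        for t in traces
    ]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("trials must have identical length and population count")
    stack = np.stack(arrs)
    return stack.mean(axis=0), stack.std(axis=0, ddof=1)


def _two_means(x: np.ndarray, n_iter: int = 200) -> tuple[float, float]:
    """1-D two-means split used to locate the low/high activity levels."""
    lo, hi = float(np.percentile(x, 10)), float(np.percentile(x, 90))
    if hi <= lo:
        return lo, hi
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        low_mask = x < mid
        if not low_mask.any() or low_mask.all():
            break
        lo_new, hi_new = float(x[low_mask].mean()), float(x[~low_mask].mean())
        if abs(lo_new - lo) < 1e-12 and abs(hi_new - hi) < 1e-12:
            break
        lo, hi = lo_new, hi_new
    return lo, hi


def dominance_times(
    trace,
    smooth_window: float = 0.1,
    thresholds: tuple[float, float] | None = None,
    pop: int = 0,
    dt: float | None = None,
    min_switches: int = 10,
) -> DominanceStats:
    """Residence durations in the high-activity state of a bistable trace.

    The activity is low-pass filtered by a moving average (default
    100 ms), the low/high activity levels are located by a two-means
    split of the smoothed histogram, and state changes are detected with
    hysteresis at 40% / 60% of the distance between the two levels
    (overridable via ``thresholds`` in absolute activity units).
    Returns completed high-state durations with mean, CV and the lag-1
    serial correlation.
    """
    x, dt = _as_series(trace, pop, dt)
    win = max(int(round(smooth_window / dt)), 1)
    kernel = np.ones(win) / win
    xs = np.convolve(x, kernel, mode="valid")
    if thresholds is None:
        lo, hi = _two_means(xs)
        if hi - lo <= 0:
            raise ValueError("no separation between activity levels")
        thr_lo = lo + 0.4 * (hi - lo)
        thr_hi = lo + 0.6 * (hi - lo)
    else:
        thr_lo, thr_hi = thresholds
    state = 1 if xs[0] > thr_hi else 0
    entry = None
    durations = []
    for i in range(1, len(xs)):
        if state == 0 and xs[i] > thr_hi:
            state = 1
            entry = i
        elif state == 1 and xs[i] < thr_lo:
            if entry is not None:
                durations.append((i - entry) * dt)
            state = 0
    durations = np.asarray(durations)
    if len(durations) < min_switches:
        raise ValueError(
            f"only {len(durations)} completed high states; "
            f"need at least {min_switches}"
        )
    mean = durations.mean()
    cv = durations.std(ddof=1) / mean
    if len(durations) >= 3 and durations.std() > 0:
        a, b = durations[:-1], durations[1:]
        with np.errstate(invalid="ignore"):
            sc = float(np.corrcoef(a, b)[0, 1])
    else:
        sc = float("nan")
    return DominanceStats(
        durations=durations, mean=float(mean), cv=float(cv), serial_correlation=sc
    )
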