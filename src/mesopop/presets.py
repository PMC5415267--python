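"""Turn-key network configurations for the standard benchmark setups.

Each preset bundles a :class:`NetworkSpec` and default
:class:`SimSettings`: a population of uncoupled LIF neurons under step
drive, adapting and bursty single populations, a two-population E-I
network with scalable size/connectivity, a winner-take-all bistable
circuit of two excitatory populations competing through shared
inhibition, and the eight-population layered cortical microcircuit
(modified Potjans-Diesmann column with constant drive, enlarged escape
noise, and optional spike-frequency adaptation on excitatory cells).

Single-neuron defaults (unless a preset overrides them): tau_m = 20 ms,
t_ref = 4 ms, u_th = 15 mV, u_r = 0 mV, c = 10 Hz, delta_u = 2 mV,
delay 1 ms, tau_s = 3 ms (excitatory) / 6 ms (inhibitory).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    AdaptationKernel,
    NetworkSpec,
    PopulationParams,
    SimSettings,
    StimulusStep,
)
from .trace import ActivityTrace

__all__ = [
    "Preset",
    "preset_uncoupled_lif",
    "preset_adapting",
    "preset_ei_network",
    "preset_bistable",
    "preset_cortical_column",
    "fixture_generator",
    "COLUMN_POPULATIONS",
    "COLUMN_RATES",
]

DEFAULTS = dict(tau_m=0.02, t_ref=0.004, u_th=15.0, u_r=0.0, c=10.0, delta_u=2.0)
DEFAULT_DELAY = 0.001
TAU_S_E = 0.003
TAU_S_I = 0.006


@dataclass
class Preset:
    name: str
    spec: NetworkSpec
    settings: SimSettings
    description: str = ""
    notes: dict = field(default_factory=dict)


def _uncoupled(M: int, tau_s: list[float]) -> tuple[np.ndarray, ...]:
    z = np.zeros((M, M))
    return z, z.copy(), np.full((M, M), DEFAULT_DELAY), np.asarray(tau_s)


def preset_uncoupled_lif(
    mu: float = 30.0,
    N: int = 500,
    mu_baseline: float = 15.0,
    t_step: float = 0.0,
    duration: float = 2.0,
    dt: float = 0.0002,
) -> Preset:
    """Uncoupled LIF population (no adaptation) under a step drive.

    The drive mu = u_rest + RI_ext steps from ``mu_baseline`` to ``mu``
    at ``t_step`` (with the default ``t_step = 0`` the drive is simply
    constant at ``mu``).  With u_rest = 0 the stimulus amplitude equals
    the drive itself.
    """
    pop = PopulationParams(N=N, **DEFAULTS)
    p, w, delay, tau_s = _uncoupled(1, [TAU_S_E])
    stim = []
    if t_step > 0:
        stim.append(StimulusStep(0.0, t_step, mu_baseline))
    stim.append(StimulusStep(t_step, float("inf"), mu))
    spec = NetworkSpec([pop], p, w, delay, tau_s, [stim])
    return Preset(
        name="uncoupled_lif",
        spec=spec,
        settings=SimSettings(dt=dt, duration=duration),
        description="independent leaky integrate-and-fire neurons, constant "
                    "threshold; renewal statistics apply in the stationary state",
    )


def preset_adapting(
    kind: str = "adapting",
    N: int = 500,
    duration: float = 2.0,
    dt: float = 0.0002,
    t_step: float = 0.0,
) -> Preset:
    """Adapting or bursty single population with a dynamic threshold.

    'adapting': two-timescale accumulating threshold (10 ms and 1 s,
    1.5 mV*s each), elevated reset u_r = 25 mV, drive step 12 -> 27 mV.
    'bursty': biphasic kernel with a facilitating part (-0.45 mV*s,
    50 ms) and an adapting part (2.5 mV*s, 1 s), tau_m = 10 ms, constant
    drive 20 mV.
    """
    if kind == "adapting":
        theta = AdaptationKernel(((1.5, 0.01), (1.5, 1.0)), t_ref=DEFAULTS["t_ref"])
        pop = PopulationParams(
            N=N, **{**DEFAULTS, "u_th": 10.0, "u_r": 25.0}, theta=theta
        )
        stim = []
        if t_step > 0:
            stim.append(StimulusStep(0.0, t_step, 12.0))
        stim.append(StimulusStep(t_step, float("inf"), 27.0))
    elif kind == "bursty":
        theta = AdaptationKernel(((-0.45, 0.05), (2.5, 1.0)), t_ref=DEFAULTS["t_ref"])
        pop = PopulationParams(
            N=N, **{**DEFAULTS, "u_th": 10.0, "u_r": 0.0, "tau_m": 0.01}, theta=theta
        )
        stim = [StimulusStep(0.0, float("inf"), 20.0)]
    else:
        raise ValueError("kind must be 'adapting' or 'bursty'")
    p, w, delay, tau_s = _uncoupled(1, [TAU_S_E])
    spec = NetworkSpec([pop], p, w, delay, tau_s, [stim])
    return Preset(
        name=f"{kind}_population",
        spec=spec,
        settings=SimSettings(dt=dt, duration=duration),
        description=f"{kind} single population with spike-triggered threshold kernel",
    )


def preset_ei_network(
    N: int = 250,
    p: float = 1.0,
    mu: float = 24.0,
    duration: float = 10.0,
    dt: float = 0.0002,
) -> Preset:
    """Two-population excitatory-inhibitory network.

    ``N`` is the total size, split 4:1 into N_E excitatory and
    N_I = N_E/4 inhibitory neurons (``N`` must be divisible by 5).  Each
    neuron receives C = p*N synapses in total.  Synaptic strengths
    follow the reference point w = 0.3 mV (inhibitory -5w) at C = 200
    and are rescaled so that C*w stays constant, keeping the mesoscopic
    coupling J = p*N*w independent of the network size.
    """
    if N % 5:
        raise ValueError("total size N must be divisible by 5")
    n_e, n_i = 4 * N // 5, N // 5
    w_e = 0.3 * 200.0 / (p * N)
    w_i = -5.0 * w_e
    pops = [
        PopulationParams(N=n_e, **{**DEFAULTS, "delta_u": 2.5}),
        PopulationParams(N=n_i, **{**DEFAULTS, "delta_u": 2.5}),
    ]
    pmat = np.full((2, 2), p)
    wmat = np.array([[w_e, w_i], [w_e, w_i]])
    delay = np.full((2, 2), DEFAULT_DELAY)
    tau_s = np.array([TAU_S_E, TAU_S_I])
    stim = [[StimulusStep(0.0, float("inf"), mu)] for _ in range(2)]
    spec = NetworkSpec(pops, pmat, wmat, delay, tau_s, stim)
    return Preset(
        name="ei_network",
        spec=spec,
        settings=SimSettings(dt=dt, duration=duration),
        description="balanced E-I network with fixed in-degree C = p*N",
        notes={"C": p * N, "w_e": w_e, "w_i": w_i},
    )


def preset_bistable(
    adaptation: bool = False,
    duration: float = 100.0,
    dt: float = 0.0002,
) -> Preset:
    """Winner-take-all circuit: two excitatory populations, shared inhibition.

    N_E1 = N_E2 = 400, N_I = 200, full connectivity.  Each excitatory
    population excites itself and the inhibitory population; the
    inhibitory population inhibits everyone (including itself).  There
    is no direct E1-E2 coupling, so the competition is purely
    disynaptic.  Without adaptation (w_E = 0.0624 mV, w_I = -0.2496 mV,
    mu = 36 mV) the switching between the two attractors is driven by
    finite-size fluctuations alone; with weak slow adaptation on the
    excitatory cells (J_theta = 0.1 mV*s, tau_theta = 1 s, w_E = 0.096,
    w_I = -0.384, mu_E = 36.5 mV) the switching becomes more regular.
    """
    delta_u = 2.5
    if adaptation:
        w_e, w_i = 0.096, -0.384
        mu_e, mu_i = 36.5, 36.0
        theta = AdaptationKernel(((0.1, 1.0),), t_ref=DEFAULTS["t_ref"])
    else:
        w_e, w_i = 0.0624, -0.2496
        mu_e, mu_i = 36.0, 36.0
        theta = None
    e_kwargs = {**DEFAULTS, "delta_u": delta_u}
    pops = [
        PopulationParams(N=400, **e_kwargs, theta=theta),
        PopulationParams(N=400, **e_kwargs, theta=theta),
        PopulationParams(N=200, **e_kwargs),
    ]
    wmat = np.array([
        [w_e, 0.0, w_i],
        [0.0, w_e, w_i],
        [w_e, w_e, w_i],
    ])
    pmat = np.where(wmat != 0.0, 1.0, 0.0)
    delay = np.full((3, 3), DEFAULT_DELAY)
    tau_s = np.array([TAU_S_E, TAU_S_E, TAU_S_I])
    stim = [
        [StimulusStep(0.0, float("inf"), mu_e)],
        [StimulusStep(0.0, float("inf"), mu_e)],
        [StimulusStep(0.0, float("inf"), mu_i)],
    ]
    spec = NetworkSpec(pops, pmat, wmat, delay, tau_s, stim)
    return Preset(
        name="bistable_wta" + ("_adapting" if adaptation else ""),
        spec=spec,
        settings=SimSettings(dt=dt, duration=duration),
        description="bistable winner-take-all network; finite-size noise "
                    "drives switching between the two attractors",
    )


# --- modified layered cortical column (8 populations) ---------------------

COLUMN_POPULATIONS = ["L2/3e", "L2/3i", "L4e", "L4i", "L5e", "L5i", "L6e", "L6i"]
_COLUMN_N = [20683, 5834, 21915, 5479, 4850, 1065, 14395, 2948]
_COLUMN_MU_HAT = [19.149, 20.362, 30.805, 28.069, 29.437, 29.33, 34.932, 32.081]
COLUMN_RATES = [0.974, 2.861, 4.673, 5.65, 8.141, 9.013, 0.988, 7.53]
_COLUMN_U_REST_ADAPT = [20.123, 20.362, 35.478, 28.069, 37.578, 29.33, 35.92, 32.081]
_COLUMN_P = [
    [0.1009, 0.1689, 0.0437, 0.0818, 0.0323, 0.0, 0.0076, 0.0],
    [0.1346, 0.1371, 0.0316, 0.0515, 0.0755, 0.0, 0.0042, 0.0],
    [0.0077, 0.0059, 0.0497, 0.135, 0.0067, 0.0003, 0.0453, 0.0],
    [0.0691, 0.0029, 0.0794, 0.1597, 0.0033, 0.0, 0.1057, 0.0],
    [0.1004, 0.0622, 0.0505, 0.0057, 0.0831, 0.3726, 0.0204, 0.0],
    [0.0548, 0.0269, 0.0257, 0.0022, 0.06, 0.3158, 0.0086, 0.0],
    [0.0156, 0.0066, 0.0211, 0.0166, 0.0572, 0.0197, 0.0396, 0.2252],
    [0.0364, 0.001, 0.0034, 0.0005, 0.0277, 0.008, 0.0658, 0.1443],
]
_COLUMN_STIM = [0.0, 0.0, 19.0, 11.964, 0.0, 0.0, 9.896, 3.788]
_COLUMN_W_EXC = 0.176
_COLUMN_W_INH = -0.702
# The projection L4e -> L2/3e carries twice the excitatory weight, as in
# the original layered-column model.  (Self-consistency check: with this
# placement, plugging the printed stationary rates into the mean synaptic
# input reproduces those same rates from renewal theory for all eight
# populations; with the doubled weight placed on L4e -> L4e it does not.)
_COLUMN_W_L23E_L4E = 0.351


def preset_cortical_column(
    with_adaptation: bool = True,
    with_stimulus: bool = False,
    duration: float = 10.0,
    dt: float = 0.0005,
) -> Preset:
    """Eight-population layered cortical microcircuit.

    Constant drive and enlarged escape noise (delta_u = 5 mV) replace
    the external Poisson input of the original model.  Without
    adaptation the resting potentials are the fitted values that
    reproduce the target stationary rates; with adaptation (J_theta =
    1 mV*s, tau_theta = 1 s on excitatory populations) the resting
    potentials are shifted by J_theta * r so the same rates result.
    The optional stimulus is a 30 ms step to layers 4 and 6 on
    [0.06 s, 0.09 s), mimicking thalamic input.
    """
    M = 8
    pops = []
    for a in range(M):
        excitatory = a % 2 == 0
        theta = None
        if with_adaptation and excitatory:
            theta = AdaptationKernel(((1.0, 1.0),), t_ref=0.002)
        u_rest = _COLUMN_U_REST_ADAPT[a] if with_adaptation else _COLUMN_MU_HAT[a]
        pops.append(
            PopulationParams(
                N=_COLUMN_N[a], tau_m=0.01, t_ref=0.002, u_th=15.0, u_r=0.0,
                u_rest=u_rest, c=10.0, delta_u=5.0, theta=theta,
            )
        )
    w = np.empty((M, M))
    for a in range(M):
        for b in range(M):
            w[a, b] = _COLUMN_W_EXC if b % 2 == 0 else _COLUMN_W_INH
    w[0, 2] = _COLUMN_W_L23E_L4E
    p = np.array(_COLUMN_P)
    delay = np.full((M, M), 0.0015)
    tau_s = np.full(M, 0.0005)
    stim = []
    for a in range(M):
        segs = []
        if with_stimulus and _COLUMN_STIM[a] != 0.0:
            segs.append(StimulusStep(0.06, 0.09, _COLUMN_STIM[a]))
        stim.append(segs)
    spec = NetworkSpec(pops, p, w, delay, tau_s, stim)
    return Preset(
        name="cortical_column",
        spec=spec,
        settings=SimSettings(dt=dt, duration=duration),
        description="modified 8-population layered cortical column with "
                    "constant drive and escape noise",
        notes={
            "populations": COLUMN_POPULATIONS,
            "target_rates_hz": COLUMN_RATES,
        },
    )


# --- synthetic fixtures for unit-testing the analysis operations ----------

def fixture_generator(kind: str, seed: int = 0, **kwargs) -> ActivityTrace:
    """Synthetic activity traces with known statistics.

    kinds: 'poisson' (independent Poisson spikers binned into counts),
    'square' (deterministic two-level square wave), 'telegraph'
    (memoryless two-state process with exponential residence times).
    """
    rng = np.random.default_rng(seed)
    dt = kwargs.get("dt", 0.001)
    duration = kwargs.get("duration", 10.0)
    n = int(round(duration / dt))
    if kind == "poisson":
        N = kwargs.get("N", 100)
        rate = kwargs.get("rate", 10.0)
        counts = rng.poisson(N * rate * dt, size=n).astype(float)
        counts = np.minimum(counts, N)
        return ActivityTrace(dt=dt, counts=counts[:, None], N=np.array([N]),
                             meta={"fixture": kind, "rate": rate})
    if kind == "square":
        N = kwargs.get("N", 100)
        period = kwargs.get("period", 2.0)
        lo, hi = kwargs.get("levels", (0.0, 20.0))
        t = np.arange(n) * dt
        level = np.where((t % period) < period / 2, hi, lo)
        counts = level * N * dt
        return ActivityTrace(dt=dt, counts=counts[:, None], N=np.array([N]),
                             meta={"fixture": kind, "period": period})
    if kind == "telegraph":
        N = kwargs.get("N", 100)
        rate_up = kwargs.get("rate_up", 1.0)     # leaving the low state
        rate_down = kwargs.get("rate_down", 1.0)  # leaving the high state
        lo, hi = kwargs.get("levels", (0.0, 20.0))
        level = np.empty(n)
        state, t_next, i = 0, 0.0, 0
        while i < n:
            rate = rate_up if state == 0 else rate_down
            stay = rng.exponential(1.0 / rate)
            j = min(n, i + max(int(round(stay / dt)), 1))
            level[i:j] = hi if state else lo
            state, i = 1 - state, j
        counts = level * N * dt
        return ActivityTrace(dt=dt, counts=counts[:, None], N=np.array([N]),
                             meta={"fixture": kind})
    raise ValueError(f"unknown fixture kind {kind!r}")
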