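"""Time-binned population activity traces."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ActivityTrace"]


@dataclass
class ActivityTrace:
    """Population activities binned at resolution ``dt``.

    ``counts[l, a]`` is the number of neurons of population ``a`` that
    fired in the bin ``[l*dt, (l+1)*dt)``; the activity is
    ``A_N = counts / (N * dt)`` in 1/s.  Counts are stored as floats
    because the deterministic (infinite-N) sampling mode produces
    non-integer expected counts.  ``expected`` optionally stores the
    expected activity Abar(t) and ``raster`` individual spikes as rows
    ``(time_s, population_index, neuron_index)``.
    """

    dt: float
    counts: np.ndarray            # (n_steps, M)
    N: np.ndarray                 # (M,)
    expected: np.ndarray | None = None
    raster: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        self.N = np.atleast_1d(np.asarray(self.N, dtype=np.int64))
        if self.counts.shape[1] != self.N.shape[0]:
            raise ValueError("counts and N disagree on the number of populations")

    @property
    def n_steps(self) -> int:
        return self.counts.shape[0]

    @property
    def M(self) -> int:
        return self.counts.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    @property
    def activity(self) -> np.ndarray:
        """A_N(t) = counts / (N * dt), shape (n_steps, M), units 1/s."""
        return self.counts / (self.N[None, :] * self.dt)

    def mean_rate(self, t_min: float = 0.0, t_max: float | None = None) -> np.ndarray:
        """Time-averaged activity per population over [t_min, t_max)."""
        sel = self.times >= t_min
        if t_max is not None:
            sel &= self.times < t_max
        if not np.any(sel):
            raise ValueError("empty averaging window")
        return self.activity[sel].mean(axis=0)

    def slice(self, t_min: float, t_max: float | None = None) -> "ActivityTrace":
        sel = self.times >= t_min
        if t_max is not None:
            sel &= self.times < t_max
        return ActivityTrace(
            dt=self.dt,
            counts=self.counts[sel],
            N=self.N,
            expected=None if self.expected is None else self.expected[sel],
            raster=self.raster,
            meta=dict(self.meta),
        )

    def spike_times_by_neuron(self, pop: int = 0) -> list[np.ndarray]:
        """Per-neuron spike time arrays extracted from the raster."""
        if self.raster is None:
            raise ValueError("trace carries no raster")
        r = self.raster
        sel = r[:, 1].astype(int) == pop
        out = []
        for i in range(self.N[pop]):
            out.append(r[sel & (r[:, 2].astype(int) == i), 0])
        return out

    def to_file(self, path: str | Path) -> None:
        """Write the trace as delimited text: time, A_N per population."""
        path = Path(path)
        header = (
            f"mesopop activity trace\ndt = {self.dt!r}\n"
            f"N = {' '.join(str(int(n)) for n in self.N)}\n"
            "columns: time_s " + " ".join(f"A_N[{a}]" for a in range(self.M))
        )
        np.savetxt(path, np.column_stack([self.times, self.activity]), header=header)

    @classmethod
    def from_file(cls, path: str | Path) -> "ActivityTrace":
        path = Path(path)
        dt = None
        N = None
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if body.startswith("dt ="):
                    dt = float(body.split("=", 1)[1])
                elif body.startswith("N ="):
                    N = np.array([int(tok) for tok in body.split("=", 1)[1].split()])
        data = np.loadtxt(path)
        data = np.atleast_2d(data)
        if dt is None or N is None:
            raise ValueError(f"{path} is not a mesopop trace file")
        activity = data[:, 1:]
        counts = activity * N[None, :] * dt
        return cls(dt=dt, counts=counts, N=N)
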