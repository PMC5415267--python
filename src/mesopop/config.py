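"""Configuration (de)serialization.

Network specifications and simulation settings round-trip through a
plain nested-dict representation, stored as JSON or YAML.  Kernel
components are stored as ``[J, tau]`` pairs (mV*s, s), matrices as
nested lists, stimuli as ``[start, stop, amplitude]`` triples.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .model import (
    AdaptationKernel,
    NetworkSpec,
    PopulationParams,
    SimSettings,
    StimulusStep,
)
from .presets import Preset

__all__ = [
    "spec_to_dict", "spec_from_dict",
    "settings_to_dict", "settings_from_dict",
    "preset_to_dict", "preset_from_dict",
    "save_config", "load_config",
]


def _kernel_to_list(k: AdaptationKernel | None):
    if k is None or k.is_empty:
        return []
    return [[j, tau] for j, tau in k.components]


def _pop_to_dict(pop: PopulationParams) -> dict:
    return {
        "N": pop.N, "tau_m": pop.tau_m, "t_ref": pop.t_ref,
        "u_th": pop.u_th, "u_r": pop.u_r, "u_rest": pop.u_rest,
        "c": pop.c, "delta_u": pop.delta_u,
        "theta": _kernel_to_list(pop.theta),
        "eta": _kernel_to_list(pop.eta),
        "model_variant": pop.model_variant,
    }


def _pop_from_dict(d: dict) -> PopulationParams:
    t_ref = d["t_ref"]
    theta = AdaptationKernel(tuple(map(tuple, d.get("theta", []))), t_ref)
    eta = AdaptationKernel(tuple(map(tuple, d.get("eta", []))), t_ref)
    return PopulationParams(
        N=d["N"], tau_m=d["tau_m"], t_ref=t_ref, u_th=d["u_th"], u_r=d["u_r"],
        u_rest=d["u_rest"], c=d["c"], delta_u=d["delta_u"],
        theta=theta, eta=eta, model_variant=d.get("model_variant", "GIF"),
    )


def spec_to_dict(spec: NetworkSpec) -> dict:
    return {
        "populations": [_pop_to_dict(p) for p in spec.populations],
        "p": spec.p.tolist(),
        "w": spec.w.tolist(),
        "delay": spec.delay.tolist(),
        "tau_s": spec.tau_s.tolist(),
        "stimulus": [
            [[s.start, s.stop, s.amplitude] for s in segs] for segs in spec.stimulus
        ],
    }


def spec_from_dict(d: dict) -> NetworkSpec:
    return NetworkSpec(
        populations=[_pop_from_dict(pd) for pd in d["populations"]],
        p=np.asarray(d["p"], dtype=float),
        w=np.asarray(d["w"], dtype=float),
        delay=np.asarray(d["delay"], dtype=float),
        tau_s=np.asarray(d["tau_s"], dtype=float),
        stimulus=[
            [StimulusStep(*seg) for seg in segs] for segs in d.get("stimulus", [])
        ],
    )


def settings_to_dict(s: SimSettings) -> dict:
    return {
        "dt": s.dt, "duration": s.duration, "seed": s.seed,
        "history_T": s.history_T, "sampling": s.sampling,
        "record_expected": s.record_expected, "record_raster": s.record_raster,
        "burn_in_deterministic": s.burn_in_deterministic,
    }


def settings_from_dict(d: dict) -> SimSettings:
    return SimSettings(**d)


def preset_to_dict(preset: Preset) -> dict:
    return {
        "name": preset.name,
        "description": preset.description,
        "spec": spec_to_dict(preset.spec),
        "settings": settings_to_dict(preset.settings),
        "notes": preset.notes,
    }


def preset_from_dict(d: dict) -> Preset:
    return Preset(
        name=d["name"],
        spec=spec_from_dict(d["spec"]),
        settings=settings_from_dict(d["settings"]),
        description=d.get("description", ""),
        notes=d.get("notes", {}),
    )


def save_config(obj, path: str | Path) -> None:
    """Write a Preset, NetworkSpec or SimSettings as JSON or YAML."""
    path = Path(path)
    if isinstance(obj, Preset):
        d = preset_to_dict(obj)
    elif isinstance(obj, NetworkSpec):
        d = spec_to_dict(obj)
    elif isinstance(obj, SimSettings):
        d = settings_to_dict(obj)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_config(path: str | Path):
    """Load a configuration file written by :func:`save_config`."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    if "name" in d and "spec" in d:
        return preset_from_dict(d)
    if "populations" in d:
        return spec_from_dict(d)
    return settings_from_dict(d)
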