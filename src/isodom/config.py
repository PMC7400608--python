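"""YAML configuration loading for the assignment engine and the simulator.

A config file has up to three top-level sections, all optional; anything
omitted falls back to the package defaults::

    assignment:
      tolerance_ppm: 0.3
      isotope_mode: c12_only
      bounds: {c_max: 40, n_max: 5, o_max: 30, p_max: 2, s_max: 2}
    pipeline:
      min_labeling_percent: 50
      mass_window: [90, 391]
    simulation:
      seed: 0
      n_substrate: 60
      dropout: 0.1
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .assignment import AssignmentConstraints, ElementBounds
from .simulate import SimConfig

__all__ = ["PipelineOptions", "load_config", "constraints_from_dict",
           "sim_config_from_dict"]


@dataclasses.dataclass(frozen=True)
class PipelineOptions:
    min_labeling_percent: float = 50.0
    mass_window: tuple[float, float] = (90.0, 391.0)


def _only_known(cls, data: dict, where: str) -> dict:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")
    return data


def constraints_from_dict(data: dict) -> AssignmentConstraints:
    data = dict(data or {})
    bounds = ElementBounds(**_only_known(ElementBounds, data.pop("bounds", {}),
                                         "assignment.bounds"))
    return AssignmentConstraints(bounds=bounds,
                                 **_only_known(AssignmentConstraints, data,
                                               "assignment"))


def sim_config_from_dict(data: dict,
                         constraints: AssignmentConstraints | None = None
                         ) -> SimConfig:
    data = dict(data or {})
    data.pop("constraints", None)
    for key in ("timepoints", "control_timepoints", "substrate_mz_range",
                "precursor_mz_range", "mass_window"):
        if key in data:
            data[key] = tuple(data[key])
    if "windows" in data:
        data["windows"] = tuple((str(w[0]), float(w[1]), float(w[2]))
                                for w in data["windows"])
    if "substrate_class_mix" in data:
        mix = data["substrate_class_mix"]
        if isinstance(mix, dict):
            mix = tuple(mix.items())
        data["substrate_class_mix"] = tuple(mix)
    kwargs = _only_known(SimConfig, data, "simulation")
    if constraints is not None:
        kwargs["constraints"] = constraints
    return SimConfig(**kwargs)


def load_config(path=None) -> tuple[AssignmentConstraints, PipelineOptions, SimConfig]:
    """Load (constraints, pipeline options, sim config) from a YAML file."""
    raw = {}
    if path is not None:
        with open(Path(path)) as fh:
            raw = yaml.safe_load(fh) or {}
    constraints = constraints_from_dict(raw.get("assignment", {}))
    pipe = raw.get("pipeline", {}) or {}
    options = PipelineOptions(
        min_labeling_percent=float(pipe.get("min_labeling_percent", 50.0)),
        mass_window=tuple(pipe.get("mass_window", (90.0, 391.0))))
    sim = sim_config_from_dict(raw.get("simulation", {}), constraints)
    return constraints, options, sim
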