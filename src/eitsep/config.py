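"""YAML configuration loading for the simulation and training stages.

The top-level file may contain ``phantom:``, ``simulation:`` and
``training:`` sections; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .data import SimulationConfig
from .phantoms import PhantomSamplingConfig
from .training import TrainingConfig


def _build(cls, d: dict, what: str):
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {what} config keys: {sorted(unknown)}")
    tupled = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return cls(**tupled)


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    phantom = _build(PhantomSamplingConfig, raw.get("phantom", {}), "phantom")
    sim_raw = dict(raw.get("simulation", {}))
    sim_raw["phantom"] = phantom
    simulation = _build(SimulationConfig, sim_raw, "simulation")
    training = _build(TrainingConfig, raw.get("training", {}), "training")
    return {"simulation": simulation, "training": training}
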