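"""YAML-backed run configuration: nested stage blocks, strictly validated.

Unknown keys are rejected with their full path so typos never silently
fall back to defaults.  All randomness in a run flows from the single
global ``seed`` through per-stage derived streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

from .config import (CardFanoutSpec, InterventionEffect, LabelingConfig,
                     LognormalSpec, SimulationConfig)
from .errors import ConfigurationError
from .intervention import EvalConfig, InterventionPolicy, ModelConfig


def _coerce(name: str, target_type, value):
    if target_type is LognormalSpec:
        return LognormalSpec(*value) if not isinstance(value, LognormalSpec) else value
    if target_type is CardFanoutSpec and isinstance(value, dict):
        return CardFanoutSpec(**value)
    if target_type is InterventionEffect and isinstance(value, dict):
        return InterventionEffect(**value)
    if target_type is date and isinstance(value, str):
        return date.fromisoformat(value)
    if target_type in (tuple, "tuple") and isinstance(value, list):
        return tuple(value)
    return value


def _build(cls, block: dict, path: str):
    block = dict(block or {})
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(block) - set(fields)
    if unknown:
        raise ConfigurationError(path, f"unknown keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in block.items():
        f = fields[key]
        t = f.type if isinstance(f.type, type) else None
        # resolve common annotated types by default-value inspection
        default = getattr(cls(), key, None) if cls is not SimulationConfig else \
            getattr(SimulationConfig(n_accounts=10), key, None)
        for candidate in (LognormalSpec, CardFanoutSpec, InterventionEffect, date):
            if isinstance(default, candidate):
                value = _coerce(key, candidate, value)
                break
        else:
            if isinstance(default, tuple) and isinstance(value, list):
                value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as e:
        raise ConfigurationError(path, str(e)) from e


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    policy: InterventionPolicy = field(default_factory=InterventionPolicy)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0
    out_dir: str = "scalpguard_out"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        known = {"simulation", "labeling", "model", "policy", "evaluation",
                 "seed", "out_dir"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError("<root>", f"unknown keys: {sorted(unknown)}")
        return cls(
            simulation=_build(SimulationConfig, raw.get("simulation", {}), "simulation"),
            labeling=_build(LabelingConfig, raw.get("labeling", {}), "labeling"),
            model=_build(ModelConfig, raw.get("model", {}), "model"),
            policy=_build(InterventionPolicy, raw.get("policy", {}), "policy"),
            evaluation=_build(EvalConfig, raw.get("evaluation", {}), "evaluation"),
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "scalpguard_out")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)


def effective_sim_config(rc: RunConfig, seed: int | None = None) -> SimulationConfig:
    return rc.simulation.replace(seed=rc.seed if seed is None else seed)
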