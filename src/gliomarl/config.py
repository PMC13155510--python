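"""Configuration: one YAML/JSON file maps onto the parameter dataclasses of
every scale, with unknown keys rejected and all defaults declared in code.

Layout (all blocks optional; missing keys take defaults)::

    profile: scaled            # or "full"
    seed: 1
    lattice:   {nx: 50, ny: 50, dt: 1.0, ...}
    cells:     {pTC: 0.5, div: 24.0, ...}
    signaling: {alpha_ERK: 1.0, ...}
    fields:    {D_cytokine: 2.0, ...}
    engine:    {vasc_p0: 0.25, initial_density: 0.58, ...}
    surrogate: {r_tc: 0.4, sigma: 0.08, ...}
    reward:    {w_dose: 0.1, ...}
    policy:    {lstm_hidden: 16, ...}
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

from .agents import CellParams
from .engine import EngineParams, FieldParams
from .lattice import LatticeConfig
from .rl import PolicySpec, RewardParams
from .signaling import SignalingParams
from .surrogate import SurrogateParams

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    profile: str = "scaled"
    seed: int = 1
    engine: EngineParams = dc_field(default_factory=EngineParams.scaled)
    surrogate: SurrogateParams = dc_field(default_factory=SurrogateParams)
    reward: RewardParams = dc_field(default_factory=RewardParams)
    policy: PolicySpec = dc_field(default_factory=PolicySpec)


_BLOCKS = {
    "lattice": LatticeConfig,
    "cells": CellParams,
    "signaling": SignalingParams,
    "fields": FieldParams,
    "engine": EngineParams,
    "surrogate": SurrogateParams,
    "reward": RewardParams,
    "policy": PolicySpec,
}


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{path}: {e}") from e


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = set(_BLOCKS) | {"profile", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")

    profile = raw.get("profile", "scaled")
    if profile not in ("scaled", "full"):
        raise ConfigError("profile must be 'scaled' or 'full'")
    engine = EngineParams.scaled() if profile == "scaled" else EngineParams()

    if "lattice" in raw:
        engine.lattice = _build(LatticeConfig, raw["lattice"], "lattice")
    if "cells" in raw:
        engine.cells = _build(CellParams, raw["cells"], "cells")
    if "signaling" in raw:
        engine.signaling = _build(SignalingParams, raw["signaling"], "signaling")
    if "fields" in raw:
        engine.fields = _build(FieldParams, raw["fields"], "fields")
    if "engine" in raw:
        eng_keys = raw["engine"]
        allowed = {"vasc_p0", "vasc_band", "initial_density",
                   "burnin_cap_days", "tc_capacity_frac"}
        unknown = set(eng_keys) - allowed
        if unknown:
            raise ConfigError(f"engine: unknown key(s) {sorted(unknown)}")
        for k, v in eng_keys.items():
            setattr(engine, k, v)

    cfg = RunConfig(
        profile=profile,
        seed=int(raw.get("seed", 1)),
        engine=engine,
        surrogate=_build(SurrogateParams, raw.get("surrogate", {}), "surrogate"),
        reward=_build(RewardParams, raw.get("reward", {}), "reward"),
        policy=_build(PolicySpec, raw.get("policy", {}), "policy"),
    )
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    """Serialize a RunConfig back to YAML (round-trips through load)."""
    out = {
        "profile": cfg.profile,
        "seed": cfg.seed,
        "lattice": dataclasses.asdict(cfg.engine.lattice),
        "cells": dataclasses.asdict(cfg.engine.cells),
        "signaling": dataclasses.asdict(cfg.engine.signaling),
        "fields": dataclasses.asdict(cfg.engine.fields),
        "engine": {k: getattr(cfg.engine, k)
                   for k in ("vasc_p0", "vasc_band", "initial_density",
                             "burnin_cap_days", "tc_capacity_frac")},
        "surrogate": dataclasses.asdict(cfg.surrogate),
        "reward": dataclasses.asdict(cfg.reward),
        "policy": dataclasses.asdict(cfg.policy),
    }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
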