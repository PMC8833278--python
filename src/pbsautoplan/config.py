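"""Layered run configuration: built-in defaults < YAML file < explicit overrides.

Every pipeline run resolves a single :class:`RunConfig`, writes it next to the
outputs, and stamps its hash into the plan provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .beamspot import MachineModel
from .core import config_hash
from .robust_opt import DEFAULT_OBJECTIVE_PARAMS, OptimizerConfig, ScenarioFamily

__all__ = ["RunConfig", "load_config"]


@dataclass
class StructgenConfig:
    ant_avoid_margin_mm: float | None = None  # None: half the machine spot FWHM
    subtract_target_from_ant_avoid: bool = True
    postneck_lateral_mm: float = 10.0
    postneck_posterior_mm: float = 10.0
    skin_rind_mm: float = 5.0


@dataclass
class EvaluationConfig:
    shift_mm: float = 3.0
    range_pct: float = 3.5
    rotation_deg: float = 3.0
    dvh_bin_cge: float = 0.1


@dataclass
class RunConfig:
    machine: MachineModel = field(default_factory=MachineModel)
    structgen: StructgenConfig = field(default_factory=StructgenConfig)
    optimization_family: ScenarioFamily = field(default_factory=ScenarioFamily)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    objective_params: dict = field(default_factory=lambda: dict(DEFAULT_OBJECTIVE_PARAMS))
    # stride used to subsample non-target external voxels in robust scenario
    # matrices (keeps 15 scenario matrices desk-scale)
    robust_external_stride: int = 13
    anterior_gap_cm: float = 5.0
    posterior_gap_cm: float = 10.0
    range_shifter_wet_cm: float = 7.5
    target_name: str = "CTV50"
    seed: int = 0

    def ant_avoid_margin(self) -> float:
        if self.structgen.ant_avoid_margin_mm is not None:
            return self.structgen.ant_avoid_margin_mm
        return self.machine.spot_fwhm_mm / 2.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return config_hash(self.to_dict())

    def dump_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _merge_dataclass(obj, overrides: dict):
    for k, v in overrides.items():
        if not hasattr(obj, k):
            raise KeyError(f"unknown config key '{k}' for {type(obj).__name__}")
        cur = getattr(obj, k)
        if dataclasses.is_dataclass(cur) and isinstance(v, dict):
            _merge_dataclass(cur, v)
        elif isinstance(cur, dict) and isinstance(v, dict):
            cur.update(v)
        elif isinstance(cur, tuple) and isinstance(v, list):
            setattr(obj, k, tuple(v))
        else:
            setattr(obj, k, v)
    return obj


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Resolve a run configuration from defaults, an optional YAML file, and
    explicit overrides (in increasing precedence)."""
    cfg = RunConfig()
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        _merge_dataclass(cfg, data)
    if overrides:
        _merge_dataclass(cfg, overrides)
    return cfg
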