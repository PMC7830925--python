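"""Pipeline configuration: YAML-backed parameters with validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

ALL_STAGES = ("simulate", "de", "enrich", "compare", "gem")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    outdir: str = "fibroprog_out"
    seed: int = 0
    alpha: float = 0.05
    min_set_size: int = 5
    objective_fraction: float = 0.3   # MADE functionality fraction f
    capacity_eps: float = 1e-6        # FVA up/down tolerance
    w_max: float = 10.0               # confidence weight cap
    min_models: int = 3               # "significant in >= k models" summary
    stages: tuple[str, ...] = ALL_STAGES
    # external inputs; None means "use the simulated panel in outdir"
    expression: list[str] | None = None
    sample_sheets: list[str] | None = None
    gene_sets: str | None = None
    gem_model: str | None = None
    reference_table: str | None = None
    # synthetic-panel knobs forwarded to SimulationConfig
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_set_size < 2:
            raise ConfigError("min_set_size must be at least 2")
        if not 0 <= self.objective_fraction <= 1:
            raise ConfigError("objective_fraction must be in [0, 1]")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)
        if not self.stages:
            raise ConfigError("no stages requested")

    def validate_inputs(self) -> None:
        """Check that files required by the requested stages exist (before
        any compute)."""
        needed: list[str] = []
        if "simulate" not in self.stages:
            if "de" in self.stages or "enrich" in self.stages:
                needed += self.expression or []
                needed += self.sample_sheets or []
            if "enrich" in self.stages and self.gene_sets:
                needed.append(self.gene_sets)
            if "gem" in self.stages:
                if not self.gem_model:
                    raise ConfigError(
                        "gem stage requested but no metabolic model configured"
                    )
                needed.append(self.gem_model)
        if self.reference_table:
            needed.append(self.reference_table)
        missing = [p for p in needed if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input file(s): {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigError("config YAML must be a mapping")
        payload.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in payload and payload["stages"] is not None:
            payload["stages"] = tuple(payload["stages"])
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["stages"] = list(self.stages)
        return out
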