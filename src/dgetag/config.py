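"""Validated pipeline configuration.

A run is fully specified by one JSON document: screening thresholds,
tag dialect, and the simulation block.  Unknown keys are rejected and
out-of-range values raise errors naming the offending key, so a run
manifest echoing the resolved config is a complete provenance record.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .simulate import CONDITIONS, BASELINE, PLANTED_CLASSES

__all__ = ["PipelineConfig", "Thresholds", "TagDialect", "SimulationConfig", "load_config"]


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha_fdr: float = Field(default=0.001, gt=0.0, lt=1.0)
    lfc_min: float = Field(default=1.0, ge=0.0)
    q_enrich: float = Field(default=0.05, gt=0.0, le=1.0)
    min_expressed_count: int = Field(default=1, ge=1)
    min_copies: int = Field(default=2, ge=1)
    zero_floor: int = Field(default=1, ge=1)


class TagDialect(BaseModel):
    model_config = ConfigDict(extra="forbid")

    anchor: str = "CATG"
    body_length: int = Field(default=17, ge=1)
    max_mismatch: int = Field(default=0, ge=0, le=1)

    @field_validator("anchor")
    @classmethod
    def _acgt_anchor(cls, v: str) -> str:
        if not v or not set(v) <= set("ACGT"):
            raise ValueError(f"anchor must be a non-empty ACGT motif, got {v!r}")
        return v


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_genes: int = Field(default=3000, ge=1)
    length_min: int = Field(default=200, ge=1)
    length_max: int = Field(default=1200, ge=1)
    class_sizes: dict[str, int] = Field(
        default_factory=lambda: {
            "normal_up": 50,
            "microcycle_up": 100,
            "sucrose_specific": 30,
            "nitrate_specific": 30,
            "phosphate_specific": 30,
        }
    )
    fold_change: float = Field(default=8.0, gt=1.0)
    abundance_location: float = 1.0
    abundance_scale: float = Field(default=1.5, gt=0.0)
    planted_abundance_floor: float = Field(default=1.25e-4, ge=0.0)
    # nutrient-specific planted genes are expressed only on their own
    # nutrient medium: zero abundance everywhere else, including SYA
    nutrient_sya_factor: float | None = Field(default=0.0, ge=0.0)
    depth: int = Field(default=300_000, ge=0)
    depths: dict[str, int] | None = None
    error_rate: float = Field(default=0.001, ge=0.0, lt=1.0)
    adaptor_rate: float = Field(default=0.005, ge=0.0, lt=1.0)
    annotation_terms: int = Field(default=40, ge=0)
    annotation_mean_term_size: float = Field(default=15.0, gt=0.0)
    planted_enriched_class: str | None = "microcycle_up"
    planted_term_size: int = Field(default=20, ge=1)

    @field_validator("class_sizes")
    @classmethod
    def _known_classes(cls, v: dict[str, int]) -> dict[str, int]:
        unknown = set(v) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"class_sizes has unknown classes {sorted(unknown)}")
        if any(size < 0 for size in v.values()):
            raise ValueError("class_sizes must be non-negative")
        return v

    @field_validator("depths")
    @classmethod
    def _known_conditions(cls, v):
        if v is not None:
            unknown = set(v) - set(CONDITIONS)
            if unknown:
                raise ValueError(f"depths has unknown conditions {sorted(unknown)}")
            if any(d < 0 for d in v.values()):
                raise ValueError("depths must be non-negative")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        if self.length_min > self.length_max:
            raise ValueError("length_min must not exceed length_max")
        if sum(self.class_sizes.values()) > self.n_genes:
            raise ValueError("class_sizes sum exceeds n_genes")
        if (
            self.planted_enriched_class is not None
            and self.planted_enriched_class not in PLANTED_CLASSES
        ):
            raise ValueError(
                f"planted_enriched_class {self.planted_enriched_class!r} unknown"
            )
        return self

    def condition_depths(self) -> dict[str, int]:
        base = {c: self.depth for c in CONDITIONS}
        if self.depths:
            base.update(self.depths)
        return base


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = Field(default=1, ge=0)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    tag: TagDialect = Field(default_factory=TagDialect)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)

    @property
    def conditions(self) -> tuple[str, ...]:
        return CONDITIONS

    @property
    def baseline(self) -> str:
        return BASELINE

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, indent=1)


def load_config(path: str | Path | None = None, data: dict | None = None) -> PipelineConfig:
    """Load and validate a config from JSON (or a pre-parsed dict)."""
    if data is None:
        if path is None:
            raise ValueError("either path or data must be given")
        with open(path) as fh:
            data = json.load(fh)
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        raise ValueError(f"invalid pipeline config: {exc}") from exc
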