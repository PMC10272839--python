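"""Run configuration: schema-validated YAML for reproducible experiments.

A RunConfig fully determines an experiment together with its seed;
identical (config, seed) pairs produce identical outputs. Unknown keys are
rejected rather than ignored so typos fail fast.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .cell_lines import PRESET_LINES, VirtualCellLine
from .receptors import MUTATIONS


class PopulationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_cells: int = Field(25, ge=1)
    cv: float = Field(0.11, ge=0.0, lt=1.0)
    sampled_classes: tuple[str, ...] = ("expression", "degradation")


class StimulusSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["basal", "TME_step", "CpG_pulse"] = "TME_step"
    amplitude: float = Field(1.0, ge=0.0)
    level: float = Field(0.05, ge=0.0)
    t_end: float = Field(8.0, gt=0.0)


class SolverSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rtol: float = Field(1e-6, gt=0)
    atol: float = Field(1e-8, gt=0)


class ModelTablesSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    species: str
    parameters: str
    reactions: str


class LineSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    subunit_scalings: dict[str, float] = Field(default_factory=dict)
    mutations: tuple[str, ...] = ()

    def to_line(self) -> VirtualCellLine:
        return VirtualCellLine(self.name, self.subunit_scalings, tuple(self.mutations))


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    recipe: Literal["tenfold_expression", "basal_fingerprints", "mutation_response", "custom"] = "custom"
    seed: int = 0
    outdir: str = "results/run"
    population: PopulationSection = PopulationSection()
    stimulus: StimulusSection = StimulusSection()
    solver: SolverSection = SolverSection()
    model_tables: ModelTablesSection | None = None
    lines: tuple[str | LineSection, ...] = ()
    mutations: tuple[str, ...] = ()

    @field_validator("mutations")
    @classmethod
    def _known_mutations(cls, v):
        unknown = [m for m in v if m not in MUTATIONS]
        if unknown:
            raise ValueError(f"unknown mutation name(s): {unknown}; known: {sorted(MUTATIONS)}")
        return v

    @model_validator(mode="after")
    def _known_lines(self):
        for entry in self.lines:
            if isinstance(entry, str) and entry not in PRESET_LINES:
                raise ValueError(
                    f"unknown preset line {entry!r}; known: {sorted(PRESET_LINES)}"
                )
            if isinstance(entry, LineSection):
                entry.to_line()  # validates subunits and mutation names
        return self

    def resolve_lines(self) -> list[VirtualCellLine]:
        out = []
        for entry in self.lines:
            out.append(PRESET_LINES[entry] if isinstance(entry, str) else entry.to_line())
        return out

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def validate_config(path: str | Path) -> list[str]:
    """Full schema and cross-reference check without running anything.

    Returns a list of error strings (empty when valid) instead of raising
    one error at a time.
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as e:
        return [f"cannot read config: {e}"]
    try:
        RunConfig.model_validate(raw)
    except Exception as e:  # pydantic collects all field errors in one raise
        return [line.strip() for line in str(e).splitlines() if line.strip()]
    return []
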