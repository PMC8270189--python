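"""Experiment configuration: schema-validated YAML/JSON documents and
figure-level presets."""

from __future__ import annotations

from pathlib import Path
from typing import List, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .neuron import DT_DEFAULT

__all__ = ["ScenarioConfig", "GridConfig", "ExperimentConfig", "load_config", "preset"]


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    m_inh: int = Field(ge=0, le=16)
    mode: Literal["uncompensated", "compensated", "overcompensated"] = "uncompensated"


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    start: float
    stop: float
    step: float

    @field_validator("step")
    @classmethod
    def _positive_step(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("grid step must be > 0")
        return v

    def values(self) -> List[float]:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return [self.start + i * self.step for i in range(n)]


_DEFAULT_GRIDS = {
    "ild": GridConfig(start=-45.0, stop=15.0, step=2.0),
    "phase": GridConfig(start=-180.0, stop=180.0, step=10.0),
    "population": GridConfig(start=-45.0, stop=45.0, step=2.0),
}


class ExperimentConfig(BaseModel):
    """One experiment: a task, a stimulus grid, and a scenario sweep."""

    model_config = ConfigDict(extra="forbid")

    task: Literal["ild", "phase", "population"]
    model: Literal["active", "passive"] = "active"
    f_m: float = 300.0
    grid: Optional[GridConfig] = None
    n_trials: int = Field(default=500, ge=2)
    duration_ms: float = Field(default=500.0, gt=0)
    dt_ms: float = Field(default=DT_DEFAULT, gt=0)
    seed: int = Field(default=0, ge=0)
    scenarios: List[ScenarioConfig] = Field(min_length=1)
    average_range: Optional[Tuple[float, float]] = None
    out_dir: str = "results"

    def effective_grid(self) -> GridConfig:
        return self.grid or _DEFAULT_GRIDS[self.task]

    def effective_average_range(self) -> Tuple[float, float]:
        if self.average_range is not None:
            return self.average_range
        if self.task == "ild":
            return (-45.0, 15.0)
        if self.task == "phase":
            return (-180.0, 180.0)
        return (-35.0, 35.0)


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML/JSON config file; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return ExperimentConfig.model_validate(data)


_SWEEP_FULL = [0, 1, 2, 4, 6, 8, 12, 16]


def preset(name: str, scale: float = 1.0, seed: int = 0, out_dir: str = "results") -> ExperimentConfig:
    """Figure-level presets; ``scale`` multiplies the trial count of 4000."""
    n = max(2, int(round(4000 * scale)))
    common = dict(n_trials=n, seed=seed, out_dir=out_dir)
    presets = {
        "fig1": dict(task="ild", scenarios=[{"m_inh": 8}], **common),
        "fig2": dict(
            task="ild",
            scenarios=[{"m_inh": m} for m in _SWEEP_FULL],
            **common,
        ),
        "fig3": dict(
            task="ild",
            scenarios=[{"m_inh": m, "mode": "compensated"} for m in _SWEEP_FULL if m > 0],
            **common,
        ),
        "fig4": dict(
            task="ild",
            scenarios=[{"m_inh": m, "mode": "overcompensated"} for m in _SWEEP_FULL if m > 0],
            **common,
        ),
        "fig5": dict(
            task="phase",
            f_m=150.0,
            scenarios=[{"m_inh": m, "mode": "compensated"} for m in _SWEEP_FULL if m > 0],
            **common,
        ),
        "fig6": dict(
            task="ild",
            model="passive",
            scenarios=[{"m_inh": m} for m in _SWEEP_FULL],
            **common,
        ),
        "fig7": dict(
            task="population",
            scenarios=[{"m_inh": m} for m in (4, 6, 8)],
            **common,
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return ExperimentConfig.model_validate(presets[name])
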