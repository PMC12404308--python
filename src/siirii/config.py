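"""Run configuration: YAML in, validated pydantic models out.

One configuration fully determines a pipeline run (reproducibility):
either a ``simulate`` block describing a synthetic survey, or an
``input`` block pointing at microdata plus a variable map, together with
the outcomes, SES dimensions and significance level to analyze.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .simulate import DEFAULT_SES_PROPORTIONS, OutcomeSpec, SimulationConfig

__all__ = ["PipelineConfig", "load_config", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Configuration file fails schema validation."""


class OutcomeBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str = "outcome"
    p0: float = 0.3
    beta: float | dict[str, float] = math.log(2.0)
    dimension: str = "schooling"

    def to_spec(self) -> OutcomeSpec:
        beta = self.beta if isinstance(self.beta, float) else dict(self.beta)
        return OutcomeSpec(self.name, self.p0, beta, self.dimension)


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_strata: int = 10
    psus_per_stratum: int = 8
    respondents_per_psu: int = 25
    years: list[str] = ["2013", "2019"]
    ses_proportions: Optional[dict[str, list[float]]] = None
    outcomes: list[OutcomeBlock] = Field(default_factory=lambda: [OutcomeBlock()])
    sex_effect: float = -0.10
    age_effects: tuple[float, float] = (-0.10, -0.30)
    prop_male: float = 0.471
    age_proportions: tuple[float, float, float] = (0.261, 0.558, 0.181)
    psu_effect_sd: float = 0.05
    weight_cv: float = 0.5

    def to_config(self, seed: int | None = None) -> SimulationConfig:
        return SimulationConfig(
            n_strata=self.n_strata,
            psus_per_stratum=self.psus_per_stratum,
            respondents_per_psu=self.respondents_per_psu,
            years=tuple(self.years),
            ses_proportions=(
                {k: tuple(v) for k, v in self.ses_proportions.items()}
                if self.ses_proportions
                else dict(DEFAULT_SES_PROPORTIONS)
            ),
            outcomes=tuple(o.to_spec() for o in self.outcomes),
            sex_effect=self.sex_effect,
            age_effects=self.age_effects,
            prop_male=self.prop_male,
            age_proportions=self.age_proportions,
            psu_effect_sd=self.psu_effect_sd,
            weight_cv=self.weight_cv,
            seed=self.seed if seed is None else seed,
        )


class InputBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    path: str
    variable_map: str | dict = Field(default_factory=dict)

    def load_mapping(self, base: Path) -> Mapping:
        if isinstance(self.variable_map, dict):
            return self.variable_map
        p = Path(self.variable_map)
        if not p.is_absolute():
            p = base / p
        return yaml.safe_load(p.read_text()) or {}


class PipelineConfig(BaseModel):
    """Top-level run configuration (exactly one of simulate / input)."""

    model_config = ConfigDict(extra="forbid")

    simulate: Optional[SimulateBlock] = None
    input: Optional[InputBlock] = None
    outcomes: Optional[list[str]] = None
    dimensions: list[str] = ["schooling", "income"]
    covariates: list[str] = ["sex", "age_group"]
    alpha: float = 0.05
    per_year_ridit: bool = True

    @model_validator(mode="after")
    def _one_source(self) -> "PipelineConfig":
        if (self.simulate is None) == (self.input is None):
            raise ValueError(
                "exactly one of 'simulate' or 'input' must be given"
            )
        if self.input is not None and not self.outcomes:
            raise ValueError("'outcomes' is required with an 'input' block")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        return self

    def outcome_names(self) -> list[str]:
        if self.outcomes:
            return list(self.outcomes)
        return [o.name for o in self.simulate.outcomes]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a YAML mapping")
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigurationError(f"invalid config {path}:\n{exc}") from exc
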