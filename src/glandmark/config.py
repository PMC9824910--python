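"""Run configuration: one YAML/JSON document shared by all CLI subcommands.

Validated with pydantic; schema violations are reported with the path into
the document (e.g. ``model.span``).  CLI flags override config scalars.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ConfigError


class SimulateSection(BaseModel):
    n_subjects: int = Field(500, ge=1)
    scenario: Literal["default", "drifted", "homogeneous"] = "default"
    visit_interval: float = Field(1.0, gt=0)
    visit_jitter: float = Field(0.15, ge=0)
    max_visits: int = Field(10, ge=1)
    censoring_rate: float = Field(0.04, ge=0)
    admin_cutoff: float = Field(12.0, gt=0)


class DataSection(BaseModel):
    visits: Optional[str] = None
    outcomes: Optional[str] = None
    delimiter: Optional[str] = None
    covariates: Optional[list[str]] = None


class ModelSection(BaseModel):
    strategy: Literal["SPM", "GLA"] = "GLA"
    landmark_variables: list[str] = Field(default_factory=lambda: ["time"])
    kernel: Literal["epanechnikov", "uniform"] = "epanechnikov"
    span: Optional[float] = 0.5
    bandwidth: Optional[float] = None
    standardize: bool = True
    covariates: Optional[list[str]] = None
    adjust_landmark_linear: Optional[bool] = None
    min_events: float = Field(10, gt=0)
    grid_size: Optional[int] = Field(None, ge=2)

    @model_validator(mode="after")
    def _check_localization(self):
        if self.strategy == "GLA":
            if (self.span is None) == (self.bandwidth is None):
                raise ValueError(
                    "exactly one of span / bandwidth must be set")
            if self.span is not None and not 0 < self.span <= 1:
                raise ValueError(f"span must lie in (0, 1], got {self.span}")
            if self.bandwidth is not None and self.bandwidth <= 0:
                raise ValueError("bandwidth must be positive")
            if not 1 <= len(self.landmark_variables) <= 2:
                raise ValueError("landmark_variables must name 1 or 2 "
                                 "variables")
        return self


class EvaluateSection(BaseModel):
    methods: dict[str, ModelSection] = Field(default_factory=dict)
    benchmark: str = "SPM"
    horizons: list[float] = Field(default_factory=lambda: [3.0])
    n_splits: int = Field(5, ge=1)
    n_boot: int = Field(2000, ge=0)
    bootstrap: Literal["refit", "predictions"] = "refit"
    spm_covariate_mode: Literal["current", "baseline"] = "current"


class SpanSection(BaseModel):
    grid: list[float] = Field(default_factory=lambda: [0.2, 0.4, 0.6, 0.8,
                                                       1.0])
    n_splits: int = Field(2, ge=1)
    n_boot: int = Field(100, ge=0)


class RunConfig(BaseModel):
    seed: int = 0
    horizon: float = Field(3.0, gt=0)
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    data: DataSection = Field(default_factory=DataSection)
    model: ModelSection = Field(default_factory=ModelSection)
    evaluate: EvaluateSection = Field(default_factory=EvaluateSection)
    span_selection: SpanSection = Field(default_factory=SpanSection)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(payload)
    except ValidationError as err:
        lines = []
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"])
            lines.append(f"  {loc}: {e['msg']}")
        raise ConfigError("invalid run configuration:\n" +
                          "\n".join(lines)) from None
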