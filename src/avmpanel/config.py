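"""Pipeline configuration: a single validated YAML/JSON document.

Unknown keys are rejected and every numeric parameter is range-checked, so
a typo in a config file fails fast with the offending field named.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "load_config"]


class QCParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lcr_threshold: float = Field(default=98.0, ge=0.0, le=100.0)
    maf_threshold: float = Field(default=0.05, ge=0.0, le=1.0)


class StatsParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: str = Field(default="student", pattern="^(student|welch)$")
    q_threshold: float = Field(default=1e-6, gt=0.0, le=1.0)
    sigma_ratio_threshold: float = Field(default=0.4, ge=0.0, lt=1.0)


class PanelParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fraction: float = Field(default=0.10, gt=0.0, le=1.0)
    allowed_regions: list[str] = Field(
        default_factory=lambda: ["TSS200", "5UTR", "1stExon", "Body", "3UTR"]
    )
    exclusions_path: str | None = None


class ClassifierParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    rule: str = Field(default="midpoint", pattern="^(midpoint|centroid)$")


class PyroParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    slope: float = 0.9
    intercept: float = 5.0
    noise_sd_pct: float = Field(default=3.0, ge=0.0)


class HipscParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    attenuation: float = Field(default=0.6, gt=0.0, le=1.0)
    n_inverse_loci: int = Field(default=2, ge=0)
    n_atrial_like: int = Field(default=4, ge=2)
    n_ventricular_like: int = Field(default=8, ge=2)
    noise_sd: float = Field(default=0.05, ge=0.0)


class PipelineConfig(BaseModel):
    """Full pipeline configuration with per-stage parameter blocks."""

    model_config = ConfigDict(extra="forbid")

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    qc: QCParams = Field(default_factory=QCParams)
    stats: StatsParams = Field(default_factory=StatsParams)
    panel: PanelParams = Field(default_factory=PanelParams)
    classifier: ClassifierParams = Field(default_factory=ClassifierParams)
    pyro: PyroParams = Field(default_factory=PyroParams)
    hipsc: HipscParams = Field(default_factory=HipscParams)
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = self.model_copy(deep=True)
        cfg.seed = seed
        cfg.simulation.seed = seed
        return cfg


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML (or JSON) config file; defaults when path is None."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(doc)
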