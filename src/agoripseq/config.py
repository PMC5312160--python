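"""Pipeline configuration with a strict schema (unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NormalizationSettings(_Strict):
    trim_m: float = Field(0.30, ge=0, lt=0.5)
    trim_a: float = Field(0.05, ge=0, lt=0.5)
    ref_library: Optional[str] = None
    min_avg_cpm: float = Field(1.0, ge=0)


class ModelSettings(_Strict):
    dispersion: Literal["shrunk", "common", "genewise"] = "shrunk"
    prior_weight: float = Field(10.0, gt=0)
    tol: float = Field(1e-8, gt=0)
    max_iter: int = Field(50, ge=1)


class CallingSettings(_Strict):
    min_ago_fold: float = Field(4.0, gt=0)
    min_lysate_fold: float = Field(1.5, gt=0)
    min_cpm: float = Field(8.0, ge=0)
    fdr_cutoff: Optional[float] = Field(None, ge=0, le=1)
    ago_rule: Literal["both", "any"] = "both"


class SimulationSettings(_Strict):
    n_genes: int = Field(2000, ge=1)
    n_replicates: int = Field(3, ge=1)
    library_size_mean: float = Field(2.37e7, gt=0)
    library_size_cv: float = Field(0.10, ge=0)
    dispersion: float = Field(0.1, ge=0)
    baseline_logmean_range: tuple[float, float] = (0.0, 9.0)
    frac_targets: float = Field(0.05, ge=0, le=1)
    ago_enrichment_log2fc: float = 2.0
    lysate_log2fc: float = -0.585
    igg_background_frac: float = Field(0.10, ge=0, le=1)
    igg_floor_cpm: float = Field(0.0, ge=0)


class IntegrationSettings(_Strict):
    down_fold_cutoff: float = Field(1.5, gt=0)
    p_cutoff: float = Field(0.05, gt=0, le=1)


class PipelineConfig(_Strict):
    """Top-level configuration for ``agorip run``."""

    counts: Optional[Path] = None
    sample_sheet: Optional[Path] = None
    tissue_table: Optional[Path] = None
    output_dir: Path = Path("agorip_results")
    seed: int = 0
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"
    normalization: NormalizationSettings = NormalizationSettings()
    model: ModelSettings = ModelSettings()
    calling: CallingSettings = CallingSettings()
    simulation: Optional[SimulationSettings] = None
    integration: IntegrationSettings = IntegrationSettings()

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v):
        if not 0 <= v < 2**31:
            raise ValueError("seed must lie in [0, 2^31)")
        return v


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)
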