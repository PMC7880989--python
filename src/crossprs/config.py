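"""Declarative pipeline configuration with range validation.

Loaded from YAML; unknown keys are rejected and every threshold is
range-checked with defaults matching the published analysis.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator


class Thresholds(BaseModel):
    model_config = {"extra": "forbid"}

    gw_significance: float = Field(default=5e-8, gt=0.0, lt=1.0)
    proxy_r2: float = Field(default=0.8, ge=0.0, le=1.0)
    prune_r2: float = Field(default=0.3, gt=0.0, le=1.0)
    maf_min: float = Field(default=0.01, ge=0.0, le=0.5)
    maf_diff_max: float = Field(default=0.10, ge=0.0, le=1.0)
    ambiguous_maf: float = Field(default=0.45, ge=0.0, le=0.5)
    min_eur_fraction: float = Field(default=0.70, ge=0.0, le=1.0)
    min_cases: int = Field(default=650, ge=1)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    proxy_window_bp: int = Field(default=500_000, ge=0)


class CohortInput(BaseModel):
    model_config = {"extra": "forbid"}

    label: str
    dir: str  # directory with dosages.tsv / manifest.tsv / phenotypes.tsv / diagnoses.tsv
    specimen_date: str = "2010-01-01"


class CancerOutcome(BaseModel):
    model_config = {"extra": "forbid"}

    site_code: str
    sex: Optional[str] = None  # restrict to one sex (sex-specific cancers)


class SecondaryTrait(BaseModel):
    model_config = {"extra": "forbid"}

    name: str
    family: str = "linear"  # linear | logistic
    extra_covariates: list[str] = []

    @field_validator("family")
    @classmethod
    def _family_ok(cls, v):
        if v not in ("linear", "logistic"):
            raise ValueError(f"family must be linear|logistic, got {v!r}")
        return v


class SensitivityConfig(BaseModel):
    model_config = {"extra": "forbid"}

    ld_overlap: bool = False
    exclude: dict[str, list[str]] = {}           # cancer -> variant ids to drop
    restrict_discovery: dict[str, str] = {}      # cancer -> subphenotype label
    incident_prevalent: bool = False


class PipelineConfig(BaseModel):
    model_config = {"extra": "forbid"}

    seed: int = 0
    out_dir: str = "run"
    catalog: str = ""
    cohorts: list[CohortInput] = []
    cancers: list[CancerOutcome] = []
    ld_table: Optional[str] = None
    regions_bed: Optional[str] = None
    thresholds: Thresholds = Thresholds()
    variant_scan: bool = True
    secondary_traits: list[SecondaryTrait] = []
    secondary_cohort: Optional[str] = None  # defaults to the last cohort
    sensitivity: SensitivityConfig = SensitivityConfig()
    covariates: list[str] = ["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5",
                             "pc6", "pc7", "pc8", "pc9", "pc10", "batch"]

    def config_hash(self) -> str:
        # out_dir excluded so reruns into different directories stay comparable
        payload = self.model_dump(mode="json")
        payload.pop("out_dir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def validate_config(raw: str | dict) -> PipelineConfig:
    """Parse structured config text into a validated PipelineConfig."""
    data = yaml.safe_load(raw) if isinstance(raw, str) else raw
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return PipelineConfig.model_validate(data)


def load_config(path) -> PipelineConfig:
    return validate_config(Path(path).read_text())
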