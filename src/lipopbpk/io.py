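"""File I/O and pipeline configuration.

Concentration-time CSVs are comma-separated UTF-8 with a header row:
``subject, species, dose_mg_per_kg, matrix, time_h, conc_ug_per_ml``
(an optional ``blq`` column marks below-LLOQ samples; an empty
``conc_ug_per_ml`` cell means BLQ/missing).  Times are hours, concentrations
ug/ml, decimal point.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .nca import ConcTimeProfile

REQUIRED_COLUMNS = ("subject", "species", "dose_mg_per_kg", "matrix",
                    "time_h", "conc_ug_per_ml")


class SchemaError(ValueError):
    pass


class RowErrors(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def read_profiles(path) -> list[ConcTimeProfile]:
    """Read a profiles CSV into typed per-subject/matrix profiles.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    if df.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return []
    errors = []
    times = np.empty(len(df))
    concs = np.empty(len(df))
    doses = np.empty(len(df))
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            times[i - 2] = float(row.time_h)
            doses[i - 2] = float(row.dose_mg_per_kg)
        except ValueError:
            errors.append(f"line {i}: non-numeric time_h/dose ({row.time_h!r})")
            times[i - 2] = np.nan
            doses[i - 2] = np.nan
            continue
        c = row.conc_ug_per_ml.strip()
        if c == "" or c.upper() in ("BLQ", "NA", "NAN"):
            concs[i - 2] = np.nan
        else:
            try:
                concs[i - 2] = float(c)
            except ValueError:
                errors.append(f"line {i}: non-numeric conc_ug_per_ml ({c!r})")
                concs[i - 2] = np.nan
    if errors:
        raise RowErrors(errors)
    df = df.assign(_t=times, _c=concs, _d=doses)
    profiles = []
    for (subject, matrix, dose), sub in df.groupby(
            ["subject", "matrix", "_d"], sort=False):
        sub = sub.sort_values("_t")
        profiles.append(ConcTimeProfile(
            subject=subject, species=sub["species"].iloc[0],
            dose=dose * 1000.0,                     # mg/kg -> ug/kg
            matrix=matrix,
            times=sub["_t"].to_numpy(),
            concentrations=sub["_c"].to_numpy()))
    return profiles


def write_profiles(df: pd.DataFrame, path) -> None:
    cols = [c for c in df.columns if c != "id_pct_per_g"]
    df[cols].to_csv(path, index=False)


# --------------------------------------------------------------------------
# pipeline configuration


class DrugConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    molecular_weight: float = 6044.4
    ionization_class: str = "polyanion"
    pka_list: list[float] = Field(default_factory=list)
    logp: float = -2.0
    fup: float = 0.04                   # fraction unbound in plasma
    blood_plasma_ratio: float = 1.0


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    species: str = "monkey"
    dose_levels_mg_per_kg: list[float] = Field(default=[11.5, 23.0, 46.0])
    subjects_per_dose: int = 3
    sampling_times_h: list[float] = Field(
        default=[0.08, 0.17, 0.33, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 6.0])
    lloq_ug_per_ml: float = 0.18

    @field_validator("dose_levels_mg_per_kg")
    @classmethod
    def _positive_doses(cls, v):
        if any(d <= 0 for d in v):
            raise ValueError("dose levels must be > 0")
        return v


class VariabilityConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cv_cl: float = 0.15
    cv_kp: float = 0.15
    residual_cv: float = 0.10


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.10
    rdnm_bounds: tuple[float, float] = (0.80, 1.25)
    kp_method: str = "lukacova"


class TranslationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    km_animal: float = 12.0
    km_human: float = 37.0
    human_bw_kg: float = 60.0
    safety_factor: float = 10.0
    allometric_exponent: float = 0.8


class PipelineConfig(BaseModel):
    """Validated configuration for a full pipeline run; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 20211103
    output_dir: str = "pipeline_output"
    drug: DrugConfig = Field(default_factory=DrugConfig)
    design: DesignConfig = Field(default_factory=DesignConfig)
    variability: VariabilityConfig = Field(default_factory=VariabilityConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    translation: TranslationConfig = Field(default_factory=TranslationConfig)
    monkey_cl_ml_per_kg_h: float = 100.0
    human_dose_mg: float = 90.0
    physiology_overrides: dict[str, dict[str, dict[str, float]]] = Field(
        default_factory=dict)        # species -> tissue -> {volume, blood_flow}
    kp_overrides: dict[str, float] = Field(default_factory=dict)


def load_config(path: Optional[str] = None) -> PipelineConfig:
    """Load a YAML pipeline config; defaults when ``path`` is None."""
    if path is None:
        return PipelineConfig()
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)
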