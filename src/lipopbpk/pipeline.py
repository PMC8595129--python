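"""End-to-end pipeline: synthetic study -> NCA -> dose proportionality ->
PBPK predictions -> human translation, with table-style reports on disk.

Everything is deterministic given the config (including its seed); the run
log records the resolved configuration, package version and seed so every
report cell can be recomputed from it.
"""
from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .doseprop import PowerModelFit, fit_power_model
from .io import PipelineConfig, write_profiles
from .nca import ConcTimeProfile, NCAResult, run_nca, summarize_by_dose
from .partition import PhyschemProfile, predict_kps, vss_from_kps
from .pbpk import DoseEvent, build_model, exposure_metrics, simulate
from .physiology import load_physiology
from .synthetic import (StudyDesign, VariabilityModel, generate_plasma_study,
                        species_truth_model)
from .translation import ScalingInput, allometric_cl, hed_dose


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class ReportBundle:
    nca_results: pd.DataFrame
    nca_summary: pd.DataFrame
    doseprop: pd.DataFrame
    pbpk_predictions: pd.DataFrame
    translation: dict
    output_dir: Path


def _drug_from_config(cfg: PipelineConfig) -> PhyschemProfile:
    d = cfg.drug
    return PhyschemProfile(
        molecular_weight=d.molecular_weight,
        ionization_class=d.ionization_class, pka_list=tuple(d.pka_list),
        logp=d.logp, fup=d.fup, blood_plasma_ratio=d.blood_plasma_ratio)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the whole analysis chain and write its report files.

    Writes ``profiles.csv``, ``nca_results.csv``, ``nca_summary.csv``,
    ``doseprop.csv``, ``pbpk_predictions.csv``, ``translation_summary.json``
    and ``run_log.json`` under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- synthetic monkey study ------------------------------------------
    stage = "generate"
    try:
        design = StudyDesign(
            species=config.design.species,
            dose_levels=tuple(config.design.dose_levels_mg_per_kg),
            subjects_per_dose=config.design.subjects_per_dose,
            sampling_times=tuple(config.design.sampling_times_h),
            lloq=config.design.lloq_ug_per_ml)
        phys = load_physiology(config.design.species)
        if config.design.species in config.physiology_overrides:
            phys = phys.with_overrides(
                config.physiology_overrides[config.design.species])
        cl_truth = config.monkey_cl_ml_per_kg_h * phys.body_weight / 1000.0
        truth = species_truth_model(config.design.species, cl_truth,
                                    kp_overrides=config.kp_overrides,
                                    physiology=phys)
        var = VariabilityModel(cv_cl=config.variability.cv_cl,
                               cv_kp=config.variability.cv_kp,
                               residual_cv=config.variability.residual_cv,
                               seed=config.seed)
        data = generate_plasma_study(design, truth, var)
        write_profiles(data, out / "profiles.csv")
    except Exception as e:                      # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- per-subject NCA --------------------------------------------------
    stage = "nca"
    try:
        results: list[NCAResult] = []
        for (subject, dose), sub in data[data.matrix == "plasma"].groupby(
                ["subject", "dose_mg_per_kg"], sort=False):
            prof = ConcTimeProfile(
                subject=subject, species=design.species,
                dose=dose * 1000.0, matrix="plasma",
                times=sub.time_h.to_numpy(),
                concentrations=sub.conc_ug_per_ml.to_numpy())
            r = run_nca(prof)
            r.dose = dose               # report in mg/kg for tables
            results.append(r)
        nca_df = pd.DataFrame([r.as_dict() for r in results])
        nca_df.to_csv(out / "nca_results.csv", index=False)
        summary = summarize_by_dose(results)
        summary.to_csv(out / "nca_summary.csv", index=False)
    except Exception as e:                      # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- dose proportionality --------------------------------------------
    stage = "doseprop"
    try:
        rows = []
        fits: dict[str, PowerModelFit] = {}
        for param, col in (("AUCinf", "AUC_inf"), ("Cmax", "Cmax")):
            d = pd.DataFrame({"dose": nca_df["dose"], "value": nca_df[col]}).dropna()
            fit = fit_power_model(d, alpha=config.analysis.alpha,
                                  parameter=param,
                                  bounds=config.analysis.rdnm_bounds)
            fits[param] = fit
            rows.append({
                "parameter": param,
                "gm_low": fit.predicted_gm[0], "gm_high": fit.predicted_gm[1],
                "slope": fit.slope, "slope_ci_low": fit.slope_ci[0],
                "slope_ci_high": fit.slope_ci[1], "rdnm": fit.rdnm,
                "rdnm_ci_low": fit.rdnm_ci[0], "rdnm_ci_high": fit.rdnm_ci[1],
                "conclusion": fit.classification,
            })
        dp_df = pd.DataFrame(rows)
        dp_df.to_csv(out / "doseprop.csv", index=False)
    except Exception as e:                      # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- PBPK predictions (per-dose animal + human) ----------------------
    stage = "pbpk"
    try:
        pred_rows = []
        bw = truth.physiology.body_weight
        for dose in design.dose_levels:
            m = truth.with_dosing([DoseEvent("iv_bolus", dose * bw, 0.0)])
            sim = simulate(m, t_end=_t_end_for(m))
            met = exposure_metrics(sim)
            pred_rows.append({
                "species": design.species, "dose": f"{dose:g} mg/kg",
                "Cmax_ug_per_ml": met["Cmax"],
                "AUCinf_ug_h_per_ml": met["AUC_inf"]})
        # human prediction with allometrically scaled clearance
        tr = config.translation
        cl_mean = float(nca_df["CL"].mean())            # ml/kg/h
        cl_human = allometric_cl(ScalingInput(
            cl_mean * bw / 1000.0, bw, tr.human_bw_kg, tr.allometric_exponent))
        hphys = load_physiology("human_chinese_male")
        drug_h = _drug_from_config(config)
        kps_h = predict_kps(drug_h, [t.name for t in hphys.perfused_tissues],
                            method=config.analysis.kp_method,
                            overrides=config.kp_overrides)
        human = build_model(hphys, kps_h, cl_human, drug_h.blood_plasma_ratio,
                            [DoseEvent("iv_bolus", config.human_dose_mg, 0.0)])
        sim_h = simulate(human, t_end=_t_end_for(human))
        met_h = exposure_metrics(sim_h)
        pred_rows.append({
            "species": "human", "dose": f"{config.human_dose_mg:g} mg",
            "Cmax_ug_per_ml": met_h["Cmax"],
            "AUCinf_ug_h_per_ml": met_h["AUC_inf"]})
        pred_df = pd.DataFrame(pred_rows)
        pred_df.to_csv(out / "pbpk_predictions.csv", index=False)
    except Exception as e:                      # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- translation summary ---------------------------------------------
    stage = "translation"
    try:
        hed = hed_dose(max(design.dose_levels), tr.km_animal, tr.km_human,
                       tr.human_bw_kg, tr.safety_factor)
        translation = {
            "mean_monkey_CL_ml_per_kg_h": cl_mean,
            "human_CL_L_per_h": cl_human,
            "human_Vss_L": vss_from_kps(kps_h, hphys),
            "hed_mg_per_kg": hed.hed_mg_per_kg,
            "fih_dose_raw_mg": hed.raw_dose_mg,
            "fih_dose_reported_mg": hed.reported_dose_mg,
        }
        with open(out / "translation_summary.json", "w") as fh:
            json.dump(translation, fh, indent=2)
    except Exception as e:                      # noqa: BLE001
        raise PipelineError(stage, e) from e

    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.model_dump(),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)

    return ReportBundle(nca_results=nca_df, nca_summary=summary, doseprop=dp_df,
                        pbpk_predictions=pred_df, translation=translation,
                        output_dir=out)


def _t_end_for(model) -> float:
    """Horizon capturing >= 99.9% elimination: ~10 effective half-lives."""
    if model.clearance <= 0:
        return 24.0
    t = 10.0 * np.log(2.0) * model.vss / model.clearance
    return float(np.clip(t, 12.0, 400.0))
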