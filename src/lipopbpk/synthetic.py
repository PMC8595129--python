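"""Synthetic study datasets with the designs of the animal experiments.

Three generators mirror the three experiments the pipeline analyses:

* a monkey single-IV-dose plasma PK study (3 dose levels x 3 animals,
  sampling 0.08-6 h),
* a rat tissue-distribution study (serial-sacrifice design, 9 tissues +
  plasma at 4 kill times, tissue homogenised 1 g + 10 ml saline),
* an ultrafiltration plasma-protein-binding experiment (QC levels 0.25,
  2.5, 25 ug/ml).

Between-subject variability is lognormal on clearance and on the common
Kp scale; residual error is proportional lognormal; concentrations below
the assay LLOQ (0.18 ug/ml) are flagged BLQ.  Identical seeds give
identical datasets.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .partition import PhyschemProfile, predict_kps
from .pbpk import DoseEvent, PBPKModel, build_model, simulate
from .physiology import PhysiologySpec, TissueSpec, load_physiology

DEFAULT_SEED = 20211103
DEFAULT_LLOQ = 0.18                     # ug/ml, assay lower quantification limit

MONKEY_SAMPLING_H = (0.08, 0.17, 0.33, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 6.0)
MONKEY_DOSES_MG_KG = (11.5, 23.0, 46.0)
RAT_KILL_TIMES_H = (0.17, 0.5, 2.0, 6.0)
RAT_TISSUES = ("heart", "lung", "kidney", "jejunum", "stomach", "fat",
               "liver", "spleen", "muscle")
HOMOGENATE_DILUTION = 11.0              # 1 g tissue + 10 ml saline

#: rat truth Kps for the tissue-distribution fixture.  These are config
#: values chosen so that the finite-window tissue AUCs honor the observed
#: exposure ranking (plasma < muscle < heart < lung < stomach < jejunum <
#: fat < liver < spleen < kidney) under perfusion-limited kinetics; they are
#: not estimates of real partition coefficients.
DEFAULT_RAT_TISSUE_KPS: dict[str, float] = {
    "muscle": 1.5, "heart": 3.0, "lung": 5.0, "stomach": 8.0,
    "jejunum": 12.0, "fat": 25.0, "liver": 150.0, "spleen": 300.0,
    "kidney": 500.0,
}


@dataclass(frozen=True)
class StudyDesign:
    species: str
    dose_levels: tuple[float, ...]            # mg/kg
    subjects_per_dose: int
    sampling_times: tuple[float, ...]         # h
    matrices: tuple[str, ...] = ("plasma",)
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self):
        if any(d <= 0 for d in self.dose_levels):
            raise ValueError("doses must be > 0")
        if np.any(np.diff(self.sampling_times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.subjects_per_dose < 1:
            raise ValueError("subjects_per_dose must be >= 1")


@dataclass(frozen=True)
class VariabilityModel:
    cv_cl: float = 0.15          # between-subject CV on clearance
    cv_kp: float = 0.15          # between-subject CV on the common Kp scale
    residual_cv: float = 0.10    # proportional lognormal residual
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if min(self.cv_cl, self.cv_kp, self.residual_cv) < 0:
            raise ValueError("CVs must be >= 0")


def monkey_plasma_design(lloq: float = DEFAULT_LLOQ) -> StudyDesign:
    """The monkey IV study design: 3 doses x 3 animals, 0.08-6 h sampling."""
    return StudyDesign("monkey", MONKEY_DOSES_MG_KG, 3, MONKEY_SAMPLING_H,
                       ("plasma",), lloq)


def rat_tissue_design(lloq: float = DEFAULT_LLOQ) -> StudyDesign:
    """The rat serial-sacrifice tissue study: 25 mg/kg, 4 kill times."""
    return StudyDesign("rat", (25.0,), 5, RAT_KILL_TIMES_H,
                       ("plasma",) + RAT_TISSUES, lloq)


def default_drug(species: str = "monkey") -> PhyschemProfile:
    """The bundled nanoliposomal-ASODN drug profile for one species."""
    cfg = _constants()["drug"]
    return PhyschemProfile(
        molecular_weight=cfg["molecular_weight"],
        ionization_class=cfg["ionization_class"],
        pka_list=tuple(cfg["pka_list"]),
        logp=cfg["logp"],
        fup=cfg["fup"]["human" if species.startswith("human") else species],
        blood_plasma_ratio=cfg["blood_plasma_ratio"],
    )


def _constants() -> dict:
    from .translation import load_constants
    return load_constants()


def species_truth_model(species: str, cl_L_per_h: float,
                        kp_overrides: Mapping[str, float] | None = None,
                        physiology: PhysiologySpec | None = None) -> PBPKModel:
    """Build a truth PBPK model from bundled physiology and predicted Kps."""
    phys = physiology if physiology is not None else load_physiology(species)
    drug = default_drug(species)
    tissues = [t.name for t in phys.perfused_tissues]
    kps = predict_kps(drug, tissues, overrides=kp_overrides)
    return build_model(phys, kps, cl_L_per_h, drug.blood_plasma_ratio)


def monkey_truth_model(cl_ml_per_kg_h: float = 100.0) -> PBPKModel:
    """Monkey truth model; clearance given per kg (default 100 ml/kg/h)."""
    phys = load_physiology("monkey")
    return species_truth_model("monkey", cl_ml_per_kg_h * phys.body_weight / 1000.0)


def generate_plasma_study(design: StudyDesign, truth: PBPKModel,
                          variability: VariabilityModel | None = None,
                          seed: int | None = None) -> pd.DataFrame:
    """Simulate one plasma PK study subject-by-subject.

    Each subject's clearance and Kp scale are drawn lognormally around the
    truth model, the whole-body model is integrated, concentrations are
    sampled at the design times, proportional residual error is applied and
    values below the LLOQ are blanked and flagged.
    """
    var = variability if variability is not None else VariabilityModel()
    rng = np.random.default_rng(var.seed if seed is None else seed)
    bw = truth.physiology.body_weight
    times = np.asarray(design.sampling_times, float)
    rows = []
    for dose in design.dose_levels:
        for j in range(design.subjects_per_dose):
            subject = f"{design.species}-{dose:g}-{j + 1}"
            cl_i = truth.clearance * _lognormal(rng, var.cv_cl)
            kp_scale = _lognormal(rng, var.cv_kp)
            kps_i = {t: k * kp_scale for t, k in truth.kps.items()}
            model = build_model(truth.physiology, kps_i, cl_i,
                                truth.blood_plasma_ratio,
                                [DoseEvent("iv_bolus", dose * bw, 0.0)])
            sim = simulate(model, t_end=float(times[-1]))
            conc = np.interp(times, sim.time, sim.plasma_conc)
            eps = _lognormal(rng, var.residual_cv, size=times.size)
            conc = conc * eps
            for t, c in zip(times, conc):
                blq = c < design.lloq
                rows.append(dict(subject=subject, species=design.species,
                                 dose_mg_per_kg=dose, matrix="plasma",
                                 time_h=t, conc_ug_per_ml=(np.nan if blq else c),
                                 blq=blq))
            for m in design.matrices:
                if m in ("urine", "feces"):
                    # no prototype drug is recoverable in excreta: all BLQ
                    for t in times:
                        rows.append(dict(subject=subject, species=design.species,
                                         dose_mg_per_kg=dose, matrix=m,
                                         time_h=t, conc_ug_per_ml=np.nan,
                                         blq=True))
    return pd.DataFrame(rows)


def _lognormal(rng: np.random.Generator, cv: float, size=None):
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    return np.exp(rng.normal(0.0, sigma, size=size))


def _rat_tissue_physiology() -> PhysiologySpec:
    """Rat physiology with the gut split into jejunum/stomach and adipose
    relabelled 'fat', so the sampled organs are explicit compartments."""
    phys = load_physiology("rat")
    tissues = []
    for t in phys.tissues:
        if t.name == "gut":
            tissues.append(TissueSpec("jejunum", 0.6 * t.volume, 0.6 * t.blood_flow))
            tissues.append(TissueSpec("stomach", 0.4 * t.volume, 0.4 * t.blood_flow))
        elif t.name == "adipose":
            tissues.append(TissueSpec("fat", t.volume, t.blood_flow))
        else:
            tissues.append(t)
    return replace(phys, tissues=tuple(tissues))


def generate_tissue_study(design: StudyDesign | None = None,
                          truth_kps: Mapping[str, float] | None = None,
                          dose_mg_per_kg: float = 25.0,
                          cl_L_per_h: float = 0.025,
                          residual_cv: float = 0.0,
                          seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Simulate the rat serial-sacrifice tissue-distribution study.

    Tissue concentrations come from the whole-body solution.  The assay
    measures an 11-fold diluted homogenate (1 g tissue + 10 ml saline):
    noise and the LLOQ apply at homogenate level, and the reported tissue
    concentration is the homogenate value multiplied back by 11.
    ID%/g = concentration per gram / total dose x 100.
    """
    design = design if design is not None else rat_tissue_design()
    kps_truth = dict(DEFAULT_RAT_TISSUE_KPS)
    if truth_kps:
        kps_truth.update(truth_kps)
    phys = _rat_tissue_physiology()
    sampled = [m for m in design.matrices if m != "plasma"]
    missing = [m for m in sampled if m not in kps_truth]
    if missing:
        raise KeyError(f"missing truth Kp for designed tissue(s): {missing}")
    model = species_truth_model("rat", cl_L_per_h, kp_overrides=kps_truth,
                                physiology=phys)
    bw = phys.body_weight
    dose_mg = dose_mg_per_kg * bw
    model = model.with_dosing([DoseEvent("iv_bolus", dose_mg, 0.0)])
    sim = simulate(model, t_end=float(design.sampling_times[-1]))
    rng = np.random.default_rng(seed)
    vols = {t.name: t.volume for t in phys.tissues}
    rows = []
    times = np.asarray(design.sampling_times, float)
    for it, t in enumerate(times):
        for j in range(design.subjects_per_dose):
            animal = f"rat-t{t:g}-{j + 1}"
            for m in design.matrices:
                if m == "plasma":
                    c_meas = float(np.interp(t, sim.time, sim.plasma_conc))
                    dilution = 1.0
                else:
                    i = sim.compartments.index(m)
                    amt = float(np.interp(t, sim.time, sim.amounts[i]))
                    c_meas = amt / vols[m]          # ug per g at unit density
                    dilution = HOMOGENATE_DILUTION
                c_assay = (c_meas / dilution) * _lognormal(rng, residual_cv)
                blq = c_assay < design.lloq
                c_rep = np.nan if blq else c_assay * dilution
                rows.append(dict(
                    subject=animal, species="rat", dose_mg_per_kg=dose_mg_per_kg,
                    matrix=m, time_h=t,
                    conc_ug_per_ml=c_rep,
                    id_pct_per_g=(np.nan if blq else 100.0 * c_rep / (dose_mg * 1000.0)),
                    blq=blq))
    return pd.DataFrame(rows)


def tissue_auc_ranking(df: pd.DataFrame) -> list[str]:
    """Matrices ordered by trapezoidal AUC of the mean profile, ascending."""
    aucs = {}
    for m, sub in df.groupby("matrix"):
        prof = sub.groupby("time_h")["conc_ug_per_ml"].mean().dropna()
        if len(prof) >= 2:
            aucs[m] = float(np.trapezoid(prof.values, prof.index.values))
        else:
            aucs[m] = 0.0
    return sorted(aucs, key=aucs.get)


def generate_binding_study(fu_truth: Mapping[str, float],
                           nominal_concs: Sequence[float] = (0.25, 2.5, 25.0),
                           noise_cv: float = 0.0, replicates: int = 3,
                           seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Simulate ultrafiltration buffer/plasma chamber concentration pairs.

    ``fu_truth`` maps matrix label to the true unbound fraction (0-1].
    """
    for m, fu in fu_truth.items():
        if not 0 < fu <= 1:
            raise ValueError(f"fu_truth[{m!r}] must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for matrix, fu in fu_truth.items():
        for c0 in nominal_concs:
            for r in range(replicates):
                c_plasma = c0 * _lognormal(rng, noise_cv)
                c_buffer = fu * c_plasma * _lognormal(rng, noise_cv)
                rows.append(dict(matrix=matrix, nominal_conc=c0,
                                 replicate=r + 1, c_buffer=c_buffer,
                                 c_plasma=c_plasma))
    return pd.DataFrame(rows)
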