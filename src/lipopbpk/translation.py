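"""Monkey-to-human translation: allometric clearance scaling, BSA-based
human-equivalent dose, and ultrafiltration plasma-protein-binding maths.

Single-species allometry uses CL_human = CL_animal * (BW_h/BW_a)^b with a
fixed exponent b = 0.8, the value that predicts human clearance of
macromolecules with low average fold error.  The human-equivalent dose (HED)
follows the standard body-surface-area conversion with Km factors (monkey
12, human 37), divided by a safety factor and reported rounded to the
nearest 10 mg.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import yaml

DEFAULT_EXPONENT = 0.8


def load_constants() -> dict:
    """Bundled translation constants (Km factors, reference weights, drug)."""
    ref = resources.files("lipopbpk.datasets") / "constants.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ScalingInput:
    animal_cl: float                 # L/h
    animal_bw: float                 # kg
    human_bw: float                  # kg
    exponent: float = DEFAULT_EXPONENT

    def __post_init__(self):
        if min(self.animal_cl, self.animal_bw, self.human_bw) <= 0:
            raise ValueError("clearance and body weights must be > 0")


@dataclass(frozen=True)
class BindingMeasurement:
    matrix: str
    nominal_conc: float              # ug/ml
    conc_buffer: float               # ug/ml, ultrafiltrate side
    conc_plasma: float               # ug/ml, plasma chamber

    def __post_init__(self):
        if self.conc_buffer < 0 or self.nominal_conc < 0:
            raise ValueError("concentrations must be >= 0")
        if self.conc_plasma <= 0:
            raise ValueError("plasma-chamber concentration must be > 0")


@dataclass(frozen=True)
class HedResult:
    hed_mg_per_kg: float             # BSA-converted human dose per kg
    raw_dose_mg: float               # before rounding
    reported_dose_mg: float          # rounded to nearest 10 mg


def allometric_cl(inp: ScalingInput) -> float:
    """CL_human = CL_animal * (BW_human / BW_animal)^exponent (L/h)."""
    return inp.animal_cl * (inp.human_bw / inp.animal_bw) ** inp.exponent


def hed_dose(animal_dose_mg_per_kg: float, km_animal: float = 12.0,
             km_human: float = 37.0, human_bw: float = 60.0,
             safety_factor: float = 10.0) -> HedResult:
    """BSA-based first-in-human dose from an animal mg/kg dose.

    HED (mg/kg) = animal dose * Km_animal / Km_human; the absolute starting
    dose is HED * BW_human / safety factor.
    """
    if min(km_animal, km_human) <= 0:
        raise ValueError("Km factors must be > 0")
    if animal_dose_mg_per_kg <= 0 or human_bw <= 0 or safety_factor <= 0:
        raise ValueError("dose, body weight and safety factor must be > 0")
    hed = animal_dose_mg_per_kg * km_animal / km_human
    raw = hed * human_bw / safety_factor
    return HedResult(hed_mg_per_kg=hed, raw_dose_mg=raw,
                     reported_dose_mg=round(raw / 10.0) * 10.0)


def fraction_unbound(m: BindingMeasurement) -> dict:
    """fu% = 100 * C_buffer / C_plasma from one ultrafiltration pair.

    Returns both the unbound and the bound percentage (they sum to 100).
    A buffer concentration above the plasma-chamber concentration is
    nonphysical; values are still returned with ``warning`` set.
    """
    fu = 100.0 * m.conc_buffer / m.conc_plasma
    return {
        "matrix": m.matrix,
        "nominal_conc": m.nominal_conc,
        "fu_percent": fu,
        "bound_percent": 100.0 - fu,
        "warning": m.conc_buffer > m.conc_plasma,
    }


def mean_monkey_cl_L_per_h(cl_ml_per_kg_h: list[float],
                           monkey_bw_kg: float = 6.0) -> float:
    """Mean per-kg monkey clearance (ml/kg/h) -> absolute L/h."""
    if not cl_ml_per_kg_h:
        raise ValueError("need at least one clearance value")
    mean = sum(cl_ml_per_kg_h) / len(cl_ml_per_kg_h)
    return mean * monkey_bw_kg / 1000.0


def scale_monkey_to_human(cl_ml_per_kg_h: list[float], monkey_bw: float = 6.0,
                          human_bw: float = 60.0,
                          exponent: float = DEFAULT_EXPONENT) -> float:
    """Convenience chain: mean per-kg monkey CL -> allometric human CL (L/h)."""
    cl_abs = mean_monkey_cl_L_per_h(cl_ml_per_kg_h, monkey_bw)
    return allometric_cl(ScalingInput(cl_abs, monkey_bw, human_bw, exponent))
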