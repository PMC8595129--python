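"""Species physiology for the 14-compartment whole-body topology.

Bundled reference tables (monkey, rat, 60 kg Chinese adult male) describe a
parallel systemic circulation: every non-lung tissue is perfused between the
arterial and venous pools, and the lung carries total cardiac output.  Tables
live under ``lipopbpk/datasets`` as commented CSVs and can be overridden
entry-by-entry through the pipeline config.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import pandas as pd

SUPPORTED_SPECIES = ("monkey", "rat", "human_chinese_male")

#: the 14 lumped tissues of the whole-body model (blood pools excluded)
TISSUES_14 = (
    "heart", "lung", "brain", "adipose", "muscle", "skin", "spleen",
    "reproductive", "gut", "liver", "kidney", "yellow_marrow", "red_marrow",
    "rest_of_body",
)
BLOOD_POOLS = ("arterial_blood", "venous_blood")

# relative slack on the systemic-flow balance and whole-body volume checks
FLOW_BALANCE_RTOL = 0.01
VOLUME_BW_FACTOR = 1.05


@dataclass(frozen=True)
class TissueSpec:
    """One perfused compartment: volume (L) and blood flow (L/h)."""

    name: str
    volume: float
    blood_flow: float


@dataclass(frozen=True)
class PhysiologySpec:
    """Whole-body physiology of one species."""

    species: str
    body_weight: float          # kg
    cardiac_output: float       # L/h
    hematocrit: float           # fraction
    tissues: tuple[TissueSpec, ...] = field(default_factory=tuple)

    @property
    def tissue_map(self) -> dict[str, TissueSpec]:
        return {t.name: t for t in self.tissues}

    @property
    def perfused_tissues(self) -> tuple[TissueSpec, ...]:
        """Tissues exchanging with the blood pools (lung included)."""
        return tuple(t for t in self.tissues if t.name not in BLOOD_POOLS)

    @property
    def systemic_tissues(self) -> tuple[TissueSpec, ...]:
        """Perfused tissues excluding the lung (which carries total CO)."""
        return tuple(t for t in self.perfused_tissues if t.name != "lung")

    @property
    def blood_volume(self) -> float:
        return sum(t.volume for t in self.tissues if t.name in BLOOD_POOLS)

    @property
    def plasma_volume(self) -> float:
        return self.blood_volume * (1.0 - self.hematocrit)

    def with_overrides(self, overrides: Mapping[str, Mapping[str, float]]) -> "PhysiologySpec":
        """Return a copy with per-tissue volume/flow entries replaced.

        ``overrides`` maps tissue name to ``{"volume": ..., "blood_flow": ...}``
        (either key optional).
        """
        tmap = self.tissue_map
        new = []
        for t in self.tissues:
            ov = overrides.get(t.name, {})
            new.append(replace(t, volume=ov.get("volume", t.volume),
                               blood_flow=ov.get("blood_flow", t.blood_flow)))
        unknown = set(overrides) - set(tmap)
        if unknown:
            raise KeyError(f"physiology override for unknown tissue(s): {sorted(unknown)}")
        return replace(self, tissues=tuple(new))


class UnsupportedSpeciesError(ValueError):
    pass


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str]

    def __bool__(self) -> bool:
        return self.passed


def _read_table(species: str) -> tuple[pd.DataFrame, dict]:
    ref = resources.files("lipopbpk.datasets") / f"physiology_{species}.csv"
    meta: dict = {}
    with ref.open() as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#") and ":" in line:
            key, _, val = line.lstrip("# ").partition(":")
            key, val = key.strip(), val.strip()
            if key in ("body_weight_kg", "cardiac_output_L_per_h", "hematocrit"):
                meta[key] = float(val)
            elif key == "species":
                meta[key] = val
    import io
    body = "".join(ln for ln in lines if not ln.startswith("#"))
    df = pd.read_csv(io.StringIO(body))
    return df, meta


def load_physiology(species: str) -> PhysiologySpec:
    """Load the bundled physiology table for ``species``.

    Raises
    ------
    UnsupportedSpeciesError
        If ``species`` is not one of :data:`SUPPORTED_SPECIES`.
    """
    if species not in SUPPORTED_SPECIES:
        raise UnsupportedSpeciesError(
            f"unsupported species {species!r}; expected one of {SUPPORTED_SPECIES}")
    df, meta = _read_table(species)
    tissues = tuple(
        TissueSpec(name=row.tissue, volume=float(row.volume_L),
                   blood_flow=float(row.flow_L_per_h))
        for row in df.itertuples()
    )
    spec = PhysiologySpec(
        species=species,
        body_weight=meta["body_weight_kg"],
        cardiac_output=meta["cardiac_output_L_per_h"],
        hematocrit=meta["hematocrit"],
        tissues=tissues,
    )
    report = validate_physiology(spec)
    if not report:
        raise ValueError(f"bundled {species} physiology fails validation: {report.violations}")
    return spec


def validate_physiology(spec: PhysiologySpec) -> ValidationReport:
    """Check structural invariants; violations are reported, never raised.

    Rules: positive volumes and non-negative flows per tissue; lung flow
    equals cardiac output; systemic flows sum to cardiac output within 1%;
    total volume at most 1.05x body weight (unit density).
    """
    v: list[str] = []
    tmap = spec.tissue_map
    for t in spec.tissues:
        if not t.volume > 0:
            v.append(f"{t.name}: volume must be > 0 (got {t.volume})")
        if t.blood_flow < 0:
            v.append(f"{t.name}: blood_flow must be >= 0 (got {t.blood_flow})")
    if "lung" in tmap:
        q = tmap["lung"].blood_flow
        if abs(q - spec.cardiac_output) > 1e-9 * max(1.0, spec.cardiac_output):
            v.append(f"lung: blood_flow {q} must equal cardiac output {spec.cardiac_output}")
    else:
        v.append("lung: compartment missing")
    for pool in BLOOD_POOLS:
        if pool not in tmap:
            v.append(f"{pool}: compartment missing")
    qsys = sum(t.blood_flow for t in spec.systemic_tissues)
    if spec.cardiac_output > 0:
        ratio = qsys / spec.cardiac_output
        if not (1 - FLOW_BALANCE_RTOL <= ratio <= 1 + FLOW_BALANCE_RTOL):
            v.append(
                "flow balance: systemic flows sum to "
                f"{qsys:.4g} L/h = {ratio:.3f}x cardiac output (must be within 1%)")
    else:
        v.append("cardiac_output must be > 0")
    total_volume = sum(t.volume for t in spec.tissues)
    if total_volume > VOLUME_BW_FACTOR * spec.body_weight:
        v.append(
            f"volume closure: total volume {total_volume:.4g} L exceeds "
            f"{VOLUME_BW_FACTOR}x body weight {spec.body_weight} kg")
    if not 0 < spec.hematocrit < 1:
        v.append(f"hematocrit must be in (0,1) (got {spec.hematocrit})")
    return ValidationReport(passed=not v, violations=v)
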