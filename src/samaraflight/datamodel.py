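"""Core record types, physical constants, and unit conversion.

Everything downstream of the I/O boundary computes in SI units.  The CSV
interchange dialect uses the units customary in the seed-dispersal
literature: milligrams for mass, millimetres for span and chord, cm² for
plan-view area, m/s for descent velocity, rad/s for angular velocity, and
degrees for the coning angle.  The coning angle ``theta`` is measured from
the descent (spin) axis and routinely exceeds 90° for nutlet-down flight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "SamaraMorphology",
    "SamaraDynamics",
    "PerturbationRecord",
    "ValidationReport",
    "to_si",
    "to_io",
    "validate_population",
    "morphology_records",
    "read_population_csv",
    "write_population_csv",
    "read_perturbation_csv",
    "write_perturbation_csv",
    "POPULATION_COLUMNS",
    "PERTURBATION_COLUMNS",
    "MORPHOLOGY_COLUMNS",
]

# Unit factors applied at the I/O boundary.
MG_TO_KG = 1e-6
MM_TO_M = 1e-3
CM2_TO_M2 = 1e-4

MORPHOLOGY_COLUMNS = [
    "specimen_id",
    "species",
    "mass_mg",
    "span_mm",
    "chord_mm",
    "area_cm2",
]

POPULATION_COLUMNS = [
    "specimen_id",
    "species",
    "replicate",
    "mass_mg",
    "span_mm",
    "chord_mm",
    "area_cm2",
    "v_d_m_s",
    "omega_rad_s",
    "theta_deg",
]

PERTURBATION_COLUMNS = POPULATION_COLUMNS + [
    "kind",
    "level_index",
    "m_ratio",
    "a_ratio",
    "failed",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Gravitational acceleration and air density used by the force model.

    Air density defaults to 1.23 kg/m³ (dry air near 15 °C at sea level).
    Both values may be overridden, e.g. for altitude corrections.
    """

    g: float = 9.81  # m/s²
    rho_air: float = 1.23  # kg/m³


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class SamaraMorphology:
    """One specimen's geometry and mass, in SI units.

    ``span`` is the longest dimension of the whole samara silhouette,
    ``chord`` the maximum dimension perpendicular to the span line, and
    ``area`` the plan-view area of nutlet plus wing.
    """

    specimen_id: str
    species: str
    m: float  # kg
    S: float  # m
    c: float  # m
    A: float  # m²


@dataclass(frozen=True)
class SamaraDynamics:
    """One stable-hover flight observation."""

    specimen_id: str
    replicate: int
    v_d: float  # descent velocity, m/s
    omega: float  # angular velocity, rad/s
    theta_deg: float  # coning angle from the spin axis, degrees


@dataclass(frozen=True)
class PerturbationRecord:
    """One altered-specimen observation in reduced-variable bookkeeping."""

    specimen_id: str
    kind: str  # mass_add | mass_sub | ablation
    level_index: int
    m_ratio: float
    a_ratio: float
    dynamics: SamaraDynamics
    failed: bool = False


@dataclass
class ValidationReport:
    n_records: int
    n_passing: int
    violations: list[str] = field(default_factory=list)
    empty: bool = False

    @property
    def ok(self) -> bool:
        return self.n_records > 0 and not self.violations


_SI_FIELDS = {
    "mass_mg": ("m", MG_TO_KG),
    "span_mm": ("S", MM_TO_M),
    "chord_mm": ("c", MM_TO_M),
    "area_cm2": ("A", CM2_TO_M2),
}


def to_si(record: Mapping) -> SamaraMorphology:
    """Convert a raw I/O record (paper units) to an SI morphology record.

    Raises :class:`SchemaError` naming the offending field when a value is
    missing, non-finite, or non-positive.
    """
    values = {}
    for column, (attr, factor) in _SI_FIELDS.items():
        if column not in record:
            raise SchemaError(f"missing field {column!r}")
        raw = record[column]
        try:
            x = float(raw)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"field {column!r} is not numeric: {raw!r}") from exc
        if not math.isfinite(x) or x <= 0:
            raise SchemaError(f"field {column!r} must be finite and positive, got {raw!r}")
        values[attr] = x * factor
    return SamaraMorphology(
        specimen_id=str(record.get("specimen_id", "")),
        species=str(record.get("species", "synthetic")),
        **values,
    )


def to_io(m: SamaraMorphology) -> dict:
    """Inverse of :func:`to_si`; round-trips to 1e-12 relative."""
    return {
        "specimen_id": m.specimen_id,
        "species": m.species,
        "mass_mg": m.m / MG_TO_KG,
        "span_mm": m.S / MM_TO_M,
        "chord_mm": m.c / MM_TO_M,
        "area_cm2": m.A / CM2_TO_M2,
    }


def validate_population(records: Iterable[SamaraMorphology]) -> ValidationReport:
    """Check every morphology invariant, listing violations per specimen.

    Invariants: all quantities strictly positive, chord ≤ span, and
    area ≤ chord × span (the silhouette fits its span-aligned bounding box).
    """
    records = list(records)
    if not records:
        return ValidationReport(n_records=0, n_passing=0, empty=True,
                                violations=["empty population"])
    violations: list[str] = []
    n_passing = 0
    for r in records:
        errs = []
        for name in ("m", "S", "c", "A"):
            v = getattr(r, name)
            if not math.isfinite(v) or v <= 0:
                errs.append(f"{name} non-positive")
        if not errs:
            if r.c > r.S * (1 + 1e-12):
                errs.append(f"chord exceeds span (c={r.c:.6g} m > S={r.S:.6g} m)")
            if r.A > r.c * r.S * (1 + 1e-12):
                errs.append(f"area exceeds chord*span (A={r.A:.6g} m^2 > {r.c * r.S:.6g} m^2)")
        if errs:
            violations.extend(f"{r.specimen_id}: {e}" for e in errs)
        else:
            n_passing += 1
    return ValidationReport(n_records=len(records), n_passing=n_passing,
                            violations=violations)


def morphology_records(df: pd.DataFrame) -> list[SamaraMorphology]:
    """SI morphology records from a population table, one per specimen."""
    unique = df.drop_duplicates(subset="specimen_id")
    return [to_si(row) for row in unique.to_dict("records")]


def _check_schema(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    numeric = [c for c in columns if c not in
               ("specimen_id", "species", "kind", "failed")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: column {col!r} is not numeric at row {int(bad[0])}")
        df[col] = coerced


def read_population_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, POPULATION_COLUMNS, path)
    return df


def write_population_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=POPULATION_COLUMNS)


def read_perturbation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, PERTURBATION_COLUMNS, path)
    df["failed"] = df["failed"].astype(bool)
    return df


def write_perturbation_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=PERTURBATION_COLUMNS)
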