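"""Reduced-variable analysis of mass-alteration and wing-ablation series.

Each perturbed specimen carries a level-0 (unaltered) baseline; dividing
every dynamic quantity by its specimen's baseline gives the reduced
variables V_d/V_d0, omega/omega_0, theta/theta_0, which are fitted as power
laws of the driver m/m_0 (mass series) or A/A_0 (ablation series).
Records flagged ``failed`` (no stable autorotation) are excluded from fits
but retained when summarising the extremal ratios a species sustains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CONSTANTS, MG_TO_KG, CM2_TO_M2, PhysicalConstants
from .errors import DomainError, MissingBaselineError, SingularFitError
from .scaling import PowerLawFit, fit_power_law, _linear_r2

__all__ = [
    "ResponseFit",
    "RobustnessSummary",
    "WingLoadingComparison",
    "reduce",
    "fit_responses",
    "robustness_summary",
    "wing_loading_check",
    "RESPONSES",
]

RESPONSES = ("v_ratio", "omega_ratio", "theta_ratio")

_ABSOLUTE = {
    "v_ratio": "v_d_m_s",
    "omega_ratio": "omega_rad_s",
    "theta_ratio": "theta_deg",
}

MASS_KINDS = ("mass_add", "mass_sub")


@dataclass(frozen=True)
class ResponseFit:
    response: str  # v_ratio | omega_ratio | theta_ratio
    driver: str  # m_ratio | a_ratio
    fit: PowerLawFit
    species_scope: str = "all"


@dataclass(frozen=True)
class RobustnessSummary:
    species: str
    max_m_ratio_sustained: float
    min_m_ratio_sustained: float
    min_a_ratio_sustained: float
    predicted_v_change_at_double_mass: float


@dataclass(frozen=True)
class WingLoadingComparison:
    """Wing-loading R² within altered series vs across unaltered specimens."""

    r2_within_mean: float
    r2_across: float
    n_specimens: int


def reduce(records: pd.DataFrame) -> pd.DataFrame:
    """Divide each dynamic quantity by its specimen's level-0 value.

    Accepts a perturbation table with absolute dynamics columns or an
    already-reduced table (idempotent: baselines are exactly 1, so a second
    application divides by 1).  Raises :class:`MissingBaselineError` naming
    the first specimen without a level-0 row.
    """
    df = records.copy()
    reduced_input = all(col in df.columns for col in RESPONSES)
    # A specimen subjected to several studies repeats its unaltered row;
    # the baseline dynamics are identical, keep the first.
    baselines = (df[df["level_index"] == 0]
                 .drop_duplicates(subset="specimen_id")
                 .set_index("specimen_id"))
    for sid in df["specimen_id"].unique():
        if sid not in baselines.index:
            raise MissingBaselineError(f"specimen {sid!r} has no level-0 record")
    for ratio_col in RESPONSES:
        source = ratio_col if reduced_input else _ABSOLUTE[ratio_col]
        base = df["specimen_id"].map(baselines[source])
        df[ratio_col] = df[source].to_numpy(dtype=float) / base.to_numpy(dtype=float)
    # Baselines are 1 by definition; enforce exactly to avoid 1-ulp noise.
    df.loc[df["level_index"] == 0, list(RESPONSES)] = 1.0
    return df


def fit_responses(reduced: pd.DataFrame, driver: str = "m_ratio",
                  scope: str = "all",
                  kinds: tuple[str, ...] | None = None) -> list[ResponseFit]:
    """Power-law fits of the three reduced responses against the driver.

    ``driver`` is ``m_ratio`` for mass series or ``a_ratio`` for ablation.
    ``kinds`` restricts the perturbation kinds pooled (e.g. only
    ``("mass_add",)`` to drop the subtraction branch); by default mass
    drivers pool both branches and ablation uses ablation records.
    """
    if driver not in ("m_ratio", "a_ratio"):
        raise DomainError(f"unknown driver {driver!r}")
    if kinds is None:
        kinds = MASS_KINDS if driver == "m_ratio" else ("ablation",)
    df = reduced if scope == "all" else reduced[reduced["species"] == scope]
    kind_rows = df[df["kind"].isin(kinds) & (df["level_index"] > 0)]
    if kind_rows.empty:
        raise SingularFitError(
            f"no altered records for driver {driver} in scope {scope!r}")
    altered = kind_rows[~kind_rows["failed"].astype(bool)]
    if altered.empty:
        warnings.warn(f"every altered record in scope {scope!r} failed; "
                      "no response fit", stacklevel=2)
        return []
    # Baselines participate in the fits only for specimens that actually
    # have altered records of the requested kinds.
    baselines = (df[(df["level_index"] == 0)
                    & df["specimen_id"].isin(altered["specimen_id"])]
                 .drop_duplicates(subset="specimen_id"))
    df = pd.concat([baselines, altered], ignore_index=True)
    x = df[driver].to_numpy(dtype=float)
    if np.unique(np.round(x, 12)).size < 3:
        raise SingularFitError(
            f"driver {driver} takes fewer than 3 distinct values in scope {scope!r}")
    return [
        ResponseFit(response=resp, driver=driver,
                    fit=fit_power_law(x, df[resp].to_numpy(dtype=float)),
                    species_scope=scope)
        for resp in RESPONSES
    ]


def _v_mass_exponent(fits: list[ResponseFit]) -> float:
    for f in fits:
        if f.response == "v_ratio" and f.driver == "m_ratio":
            return f.fit.exponent
    raise DomainError("no V-vs-mass response fit supplied")


def robustness_summary(records: pd.DataFrame,
                       fits: list[ResponseFit]) -> list[RobustnessSummary]:
    """Extremal sustained ratios per species plus the velocity-change
    prediction 2^b − 1 at a 100 % mass increase, where b is the fitted
    V-vs-mass exponent."""
    b = _v_mass_exponent(fits)
    predicted = 2.0**b - 1.0
    out = []
    ok = records[~records["failed"].astype(bool)]
    for species, grp in ok.groupby("species"):
        mass = grp[grp["kind"].isin(MASS_KINDS) | (grp["level_index"] == 0)]
        abl = grp[(grp["kind"] == "ablation") | (grp["level_index"] == 0)]
        out.append(RobustnessSummary(
            species=str(species),
            max_m_ratio_sustained=float(mass["m_ratio"].max()),
            min_m_ratio_sustained=float(mass["m_ratio"].min()),
            min_a_ratio_sustained=float(abl["a_ratio"].min()),
            predicted_v_change_at_double_mass=predicted,
        ))
    return out


def wing_loading_check(records: pd.DataFrame,
                       constants: PhysicalConstants = CONSTANTS) -> WingLoadingComparison:
    """Test how well altered specimens obey V_d² ~ m g / A.

    Fits V_d² against m g/A separately within each altered specimen's
    series (absolute values, non-failed records) and across the unaltered
    level-0 specimens, reporting the two R² side by side.
    """
    ok = records[~records["failed"].astype(bool)].copy()
    ok["_wl"] = (ok["mass_mg"].to_numpy() * MG_TO_KG * constants.g
                 / (ok["area_cm2"].to_numpy() * CM2_TO_M2))
    ok["_v2"] = ok["v_d_m_s"].to_numpy(dtype=float) ** 2
    r2s = []
    for _, grp in ok.groupby("specimen_id"):
        if len(grp) < 3 or np.ptp(grp["_wl"].to_numpy()) == 0:
            continue
        r2s.append(_linear_r2(grp["_wl"].to_numpy(), grp["_v2"].to_numpy()))
    if not r2s:
        raise SingularFitError("no specimen has an alterable series to fit")
    base = ok[ok["level_index"] == 0]
    r2_across = _linear_r2(base["_wl"].to_numpy(), base["_v2"].to_numpy())
    return WingLoadingComparison(r2_within_mean=float(np.mean(r2s)),
                                 r2_across=float(r2_across),
                                 n_specimens=len(r2s))
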