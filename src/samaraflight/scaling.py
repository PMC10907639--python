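"""Power-law fitting, interspecific drag-coefficient estimation, and the
allometry suite.

Power laws y = a x^b are fitted by ordinary least squares in log10–log10
space, the standard convention for allometric scaling.  A fit may impose a
fixed exponent (only the prefactor is estimated), in which case R² is
computed as 1 − SS_res/SS_tot against the mean of log10 y and can be
negative.  For free fits R² is the squared Pearson correlation in fit
space; the two definitions coincide there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aeromodel import force_table, wing_loading
from .datamodel import CONSTANTS, MG_TO_KG, MM_TO_M, CM2_TO_M2, PhysicalConstants
from .errors import DomainError, SingularFitError

__all__ = [
    "PowerLawFit",
    "DragModelFit",
    "ModelComparison",
    "fit_power_law",
    "fit_drag_model",
    "allometry_suite",
    "compare_models",
    "ALLOMETRY_FIXED_EXPONENTS",
]

# Two-dimensional allometry: A ~ m^(2/3) ~ S^2 ~ c^2 ~ cS.
ALLOMETRY_FIXED_EXPONENTS = {
    "A_vs_m": 2.0 / 3.0,
    "A_vs_S": 2.0,
    "A_vs_c": 2.0,
    "A_vs_cS": 1.0,
}


@dataclass(frozen=True)
class PowerLawFit:
    """y = 10^log10_prefactor * x^exponent, fitted in log10 space."""

    exponent: float
    log10_prefactor: float
    r2: float
    n: int
    exponent_fixed: bool = False

    @property
    def prefactor(self) -> float:
        return 10.0**self.log10_prefactor

    def evaluate(self, x):
        """Predicted y at x."""
        return self.prefactor * np.asarray(x, dtype=float) ** self.exponent

    def describe(self, y: str = "y", x: str = "x") -> str:
        tag = " (fixed exponent)" if self.exponent_fixed else ""
        return f"{y} ~ {x}^{self.exponent:.2f}, R^2 = {self.r2:.2f}{tag}"


@dataclass(frozen=True)
class DragModelFit:
    """Linear fit of the lumped force rho V² A |cos(theta)| against weight.

    The force balance absorbs the ½ C_D factor into the slope, so
    C_D = 2/slope.  The intercept is retained as a diagnostic: species that
    sit off the interspecific trend pull it away from zero.
    """

    slope: float
    intercept: float
    r2: float
    n: int

    @property
    def c_d(self) -> float:
        return 2.0 / self.slope


@dataclass(frozen=True)
class ModelComparison:
    """R² of the wing-loading correlation vs the coning-angle drag model."""

    r2_wing_loading: float
    r2_drag_model: float
    n: int

    @property
    def difference(self) -> float:
        return self.r2_drag_model - self.r2_wing_loading


def _as_positive(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    bad = np.flatnonzero(~np.isfinite(arr) | (arr <= 0))
    if bad.size:
        raise DomainError(
            f"{name} must be positive and finite; offending index {int(bad[0])}")
    return arr


def fit_power_law(x, y, fixed_exponent: float | None = None) -> PowerLawFit:
    """OLS power-law fit in log10–log10 space.

    With ``fixed_exponent`` only the prefactor is estimated.  Free fits
    need n >= 3, fixed fits n >= 2, and the regressor must have spread.
    """
    lx = np.log10(_as_positive(x, "x"))
    ly = np.log10(_as_positive(y, "y"))
    if lx.size != ly.size:
        raise DomainError("x and y must have equal length")
    n = lx.size
    sstot = float(np.sum((ly - ly.mean()) ** 2))
    if fixed_exponent is None:
        if n < 3:
            raise DomainError("free-exponent fit requires at least 3 points")
        if np.ptp(lx) == 0:
            raise SingularFitError("regressor has no spread")
        slope, intercept = np.polyfit(lx, ly, 1)
        resid = ly - (slope * lx + intercept)
        r2 = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else 1.0
        return PowerLawFit(float(slope), float(intercept), r2, n, False)
    if n < 2:
        raise DomainError("fixed-exponent fit requires at least 2 points")
    b = float(fixed_exponent)
    intercept = float(np.mean(ly - b * lx))
    resid = ly - (b * lx + intercept)
    r2 = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else 1.0
    return PowerLawFit(b, intercept, r2, n, True)


def _specimen_means(forces: pd.DataFrame) -> pd.DataFrame:
    return forces.groupby("specimen_id", as_index=False)[
        ["f_d_n", "weight_n"]].mean()


def fit_drag_model(forces: pd.DataFrame,
                   per_replicate: bool = False,
                   through_origin: bool = False) -> DragModelFit:
    """Least-squares line of lumped force F_D against weight m g.

    Points default to specimen means over replicates (each wind-tunnel
    observation comprises three replicates); ``per_replicate`` fits raw
    observations instead.
    """
    pts = forces if per_replicate else _specimen_means(forces)
    x = pts["weight_n"].to_numpy(dtype=float)
    y = pts["f_d_n"].to_numpy(dtype=float)
    n = x.size
    if np.ptp(x) == 0:
        raise SingularFitError("all weights equal; drag fit is singular")
    if through_origin:
        if n < 2:
            raise DomainError("through-origin drag fit requires >= 2 points")
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    else:
        if n < 3 and not (n == 2):
            raise DomainError("drag fit requires >= 2 points")
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    resid = y - (slope * x + intercept)
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else 1.0
    return DragModelFit(slope, intercept, r2, n)


def allometry_suite(morphology: pd.DataFrame) -> dict[str, PowerLawFit]:
    """Free and fixed-exponent fits of A against m, S, c, and cS.

    Works on an I/O-unit morphology table (one row per specimen); exponents
    are unit-invariant, prefactors refer to SI.
    """
    unique = morphology.drop_duplicates(subset="specimen_id")
    if len(unique) < 3:
        raise DomainError("allometry suite requires at least 3 specimens")
    m = unique["mass_mg"].to_numpy() * MG_TO_KG
    S = unique["span_mm"].to_numpy() * MM_TO_M
    c = unique["chord_mm"].to_numpy() * MM_TO_M
    A = unique["area_cm2"].to_numpy() * CM2_TO_M2
    drivers = {"A_vs_m": m, "A_vs_S": S, "A_vs_c": c, "A_vs_cS": c * S}
    fits: dict[str, PowerLawFit] = {}
    for name, x in drivers.items():
        fits[f"{name}_free"] = fit_power_law(x, A)
        fits[f"{name}_fixed"] = fit_power_law(
            x, A, fixed_exponent=ALLOMETRY_FIXED_EXPONENTS[name])
    return fits


def _linear_r2(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0:
        raise SingularFitError("regressor has no spread")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sstot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else 1.0


def compare_models(population: pd.DataFrame,
                   constants: PhysicalConstants = CONSTANTS,
                   convention: str = "abs_cos") -> ModelComparison:
    """R² of V_d² ~ m g/A against R² of the coning-angle drag fit.

    Both models are evaluated on specimen means of the same joined
    morphology + dynamics table.
    """
    if population["specimen_id"].nunique() < 3:
        raise DomainError("model comparison requires at least 3 specimens")
    means = population.groupby("specimen_id", as_index=False)[
        ["mass_mg", "area_cm2", "v_d_m_s"]].mean()
    wl = wing_loading(means["mass_mg"].to_numpy() * MG_TO_KG,
                      means["area_cm2"].to_numpy() * CM2_TO_M2, constants)
    r2_wl = _linear_r2(np.asarray(wl), means["v_d_m_s"].to_numpy() ** 2)
    drag = fit_drag_model(force_table(population, constants, convention))
    return ModelComparison(r2_wing_loading=r2_wl, r2_drag_model=drag.r2,
                           n=len(means))
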