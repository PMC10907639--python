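"""Force constructs for autorotating samara descent.

The central model is a vertical force balance for a hovering (terminal
velocity) samara treated as a rotating blunt body,

    m g = (1/2) C_D rho V_d^2 A |cos(theta)|,

where ``A |cos(theta)|`` is the plan-view area projected onto the plane
normal to the vertical, ``theta`` the coning angle measured from the spin
axis.  Because nutlet-down autorotation gives theta > 90°, cos(theta) is
negative; the magnitude is the physically meaningful projection factor, so
``|cos|`` is the default projection convention.  A ``sin`` convention is
provided for data sets that report the coning angle from the horizontal.

The classical "wing loading" correlation V_d^2 ~ m g / A is the weaker,
drag-coefficient-free alternative that the model comparison in
:mod:`samaraflight.scaling` evaluates against this balance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import CONSTANTS, MG_TO_KG, MM_TO_M, CM2_TO_M2, PhysicalConstants
from .errors import DomainError, NoEquilibriumError

__all__ = [
    "wing_loading",
    "drag_force",
    "velocity_from_balance",
    "angle_of_attack",
    "centrifugal_force",
    "projection_factor",
    "force_table",
    "FORCE_COLUMNS",
]

FORCE_COLUMNS = [
    "specimen_id",
    "replicate",
    "f_d_n",
    "weight_n",
    "f_c_n",
    "wing_loading_n_m2",
    "phi_deg",
]


def projection_factor(theta_deg, convention: str = "abs_cos"):
    """Projected-area factor for coning angle ``theta_deg``.

    ``abs_cos`` (default) treats theta as measured from the spin axis;
    ``sin`` treats it as measured from the horizontal plane.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= 180):
        raise DomainError("theta must lie in (0, 180) degrees")
    rad = np.deg2rad(theta)
    if convention == "abs_cos":
        out = np.abs(np.cos(rad))
    elif convention == "sin":
        out = np.sin(rad)
    else:
        raise DomainError(f"unknown projection convention {convention!r}")
    return out if out.ndim else float(out)


def wing_loading(m, A, constants: PhysicalConstants = CONSTANTS):
    """Weight per unit plan-view area, m g / A  [N/m²]."""
    m = np.asarray(m, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise DomainError("area must be positive")
    if np.any(m <= 0):
        raise DomainError("mass must be positive")
    out = m * constants.g / A
    return out if out.ndim else float(out)


def drag_force(v_d, A, theta_deg, constants: PhysicalConstants = CONSTANTS,
               convention: str = "abs_cos"):
    """Lumped aerodynamic force rho V_d² A |cos(theta)|  [N].

    Lift and form drag both oppose descent; this lumps them into a single
    force acting on the projected area.
    """
    v_d = np.asarray(v_d, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(v_d < 0):
        raise DomainError("descent velocity must be non-negative")
    if np.any(A <= 0):
        raise DomainError("area must be positive")
    out = constants.rho_air * v_d**2 * A * projection_factor(theta_deg, convention)
    return out if out.ndim else float(out)


def velocity_from_balance(m, A, theta_deg, c_d,
                          constants: PhysicalConstants = CONSTANTS,
                          convention: str = "abs_cos"):
    """Descent velocity solving m g = ½ C_D rho V² A |cos(theta)|  [m/s]."""
    m = np.asarray(m, dtype=float)
    A = np.asarray(A, dtype=float)
    c_d = np.asarray(c_d, dtype=float)
    if np.any(m <= 0) or np.any(A <= 0) or np.any(c_d <= 0):
        raise DomainError("mass, area, and drag coefficient must be positive")
    proj = np.asarray(projection_factor(theta_deg, convention))
    if np.any(proj < 1e-12):
        raise NoEquilibriumError(
            "projected area vanishes (theta = 90 deg); no hover equilibrium")
    out = np.sqrt(2.0 * m * constants.g / (c_d * constants.rho_air * A * proj))
    return out if out.ndim else float(out)


def angle_of_attack(v_d, S, omega):
    """Effective blade pitch at the 0.75-span station, degrees.

    phi = arctan(V_d / (0.75 S omega)), in (0, 90) for V_d > 0.
    """
    v_d = np.asarray(v_d, dtype=float)
    S = np.asarray(S, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if np.any(S <= 0) or np.any(omega <= 0):
        raise DomainError("span and angular velocity must be positive")
    out = np.degrees(np.arctan2(v_d, 0.75 * S * omega))
    return out if out.ndim else float(out)


def centrifugal_force(m, omega, r_c):
    """Centrifugal force m omega² r_c on the centroid path  [N].

    The radius convention is configurable upstream; the default places the
    spin axis at the nutlet end with the centroid at 0.25 S (the complement
    of the 0.75 S blade station used for the angle of attack).
    """
    m = np.asarray(m, dtype=float)
    omega = np.asarray(omega, dtype=float)
    r_c = np.asarray(r_c, dtype=float)
    if np.any(m < 0) or np.any(omega < 0) or np.any(r_c < 0):
        raise DomainError("mass, omega, and radius must be non-negative")
    out = m * omega**2 * r_c
    return out if out.ndim else float(out)


def force_table(population: pd.DataFrame,
                constants: PhysicalConstants = CONSTANTS,
                convention: str = "abs_cos",
                r_c_fraction: float = 0.25) -> pd.DataFrame:
    """Per-observation force records from a joined population table."""
    m = population["mass_mg"].to_numpy() * MG_TO_KG
    A = population["area_cm2"].to_numpy() * CM2_TO_M2
    S = population["span_mm"].to_numpy() * MM_TO_M
    v = population["v_d_m_s"].to_numpy()
    omega = population["omega_rad_s"].to_numpy()
    theta = population["theta_deg"].to_numpy()
    return pd.DataFrame({
        "specimen_id": population["specimen_id"].to_numpy(),
        "replicate": population["replicate"].to_numpy(),
        "f_d_n": drag_force(v, A, theta, constants, convention),
        "weight_n": m * constants.g,
        "f_c_n": centrifugal_force(m, omega, r_c_fraction * S),
        "wing_loading_n_m2": wing_loading(m, A, constants),
        "phi_deg": angle_of_attack(v, S, omega),
    })
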