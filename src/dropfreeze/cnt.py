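"""Classical nucleation theory for ice in supercooled water.

The machinery needed to draw a critical-ice-cap size line against
temperature and to drive the homogeneous-freezing simulator:

* chemical-potential difference between supercooled water and ice,
  Δμ(T) = k_B T ln(p_liq/p_ice), from saturation-vapor-pressure
  parameterizations (default: Murphy & Koop 2005);
* ice–water interfacial energy σ_iw(T) (pluggable parameterizations);
* critical embryo radius r* = 2 σ_iw v_ice / Δμ and the diameter of the
  spherical cap it forms on a surface with contact angle γ — reported both
  as the embryo-sphere diameter 2 r* and as the cap footprint 2 r* sin γ;
* the spherical-cap shape factor f(γ) = (2 + cos γ)(1 − cos γ)²/4 that
  scales the homogeneous nucleation barrier;
* homogeneous and heterogeneous nucleation rates, either in CNT form
  A·exp(−ΔG*/k_B T) or via the empirical water-activity parameterization
  of homogeneous nucleation (Koop et al. 2000).

Everything here works in kelvin; conversion from °C happens at the module
boundary.  All outputs carry the parameterization ids that produced them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from ._errors import ValidationError

__all__ = [
    "KB",
    "T_MELT_K",
    "CNTParameterization",
    "DEFAULT_CNT",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "p_vap_liquid",
    "p_vap_ice",
    "dmu",
    "sigma_iw",
    "shape_factor",
    "critical_radius",
    "cap_diameter",
    "delta_g_hom",
    "j_hom",
    "j_het",
    "cnt_line",
    "equilibrium_temperature",
]

KB = 1.380649e-23  # J/K
T_MELT_K = 273.15
T_TRIPLE_K = 273.16

# validity window enforced for thermodynamic evaluations (K); the upper
# bound is the triple point, where the default liquid and ice curves cross
_T_MIN, _T_MAX = 150.0, T_TRIPLE_K


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + 273.15


def kelvin_to_celsius(t_k):
    return np.asarray(t_k, dtype=float) - 273.15


def _check_range(T, name="T"):
    T = np.asarray(T, dtype=float)
    if np.any((T <= _T_MIN) | (T > _T_MAX)):
        raise ValidationError(
            f"{name} outside the vapor-pressure parameterization range "
            f"({_T_MIN:g} K, {_T_MAX:g} K]"
        )
    return T


def p_vap_liquid(T):
    """Saturation vapor pressure over supercooled liquid water (Pa).

    Murphy & Koop (2005) formulation, valid 123–332 K.
    """
    T = _check_range(T)
    lnp = (
        54.842763
        - 6763.22 / T
        - 4.210 * np.log(T)
        + 0.000367 * T
        + np.tanh(0.0415 * (T - 218.8))
        * (53.878 - 1331.22 / T - 9.44523 * np.log(T) + 0.014025 * T)
    )
    return np.exp(lnp)


def p_vap_ice(T):
    """Saturation vapor pressure over hexagonal ice (Pa).

    Murphy & Koop (2005) formulation, valid above 110 K.
    """
    T = _check_range(T)
    return np.exp(
        9.550426 - 5723.265 / T + 3.53068 * np.log(T) - 0.00728332 * T
    )


@dataclass(frozen=True)
class CNTParameterization:
    """Physical constants and parameterization choices for ice CNT.

    Attributes
    ----------
    contact_angle_deg:
        Contact angle γ of the ice embryo on the nucleating surface.
    sigma_id:
        Ice–water interfacial-energy parameterization:
        ``"cnt_fit_linear"`` (default) — σ(T_C) = 29.5773 + 0.11483·T_C
        mJ m⁻², a linear fit calibrated in this package so that the CNT
        rate with ``prefactor_hom`` reproduces the empirical
        water-activity homogeneous rate over 234–239 K;
        ``"pruppacher_klett"`` — σ(T_C) = 28.0 + 0.25·T_C mJ m⁻²;
        ``"constant"`` — the value of ``sigma_const``.
    sigma_const:
        Interfacial energy in J m⁻² used when ``sigma_id="constant"``.
    v_ice:
        Volume per molecule in ice (m³); 3.25e-29 corresponds to an ice
        density of ~0.92 g cm⁻³ and is treated as constant — its
        variation over 230–273 K is far below other uncertainties.
    prefactor_hom, prefactor_het:
        Kinetic prefactors (cm⁻³ s⁻¹ and cm⁻² s⁻¹), literature
        order-of-magnitude constants.
    jhom_param:
        ``"koop2000"`` (default) selects the empirical water-activity
        parameterization of the homogeneous rate; ``None`` selects the
        CNT form with ``prefactor_hom`` and ``sigma_id``.
    vp_id:
        Vapor-pressure parameterization id (recorded in outputs).
    """

    contact_angle_deg: float = 45.0
    sigma_id: str = "cnt_fit_linear"
    sigma_const: float = 30.0e-3
    v_ice: float = 3.25e-29
    prefactor_hom: float = 1.0e37
    prefactor_het: float = 1.0e26
    jhom_param: Optional[str] = "koop2000"
    vp_id: str = "murphy_koop_2005"

    def __post_init__(self):
        if not 0.0 <= self.contact_angle_deg <= 180.0:
            raise ValidationError("contact angle must be in [0, 180] degrees")
        if self.sigma_id not in ("cnt_fit_linear", "pruppacher_klett", "constant"):
            raise ValidationError(f"unknown sigma_id {self.sigma_id!r}")
        if self.jhom_param not in (None, "koop2000"):
            raise ValidationError(f"unknown jhom_param {self.jhom_param!r}")
        if self.sigma_const <= 0 or self.v_ice <= 0:
            raise ValidationError("sigma_const and v_ice must be > 0")
        if self.prefactor_hom <= 0 or self.prefactor_het <= 0:
            raise ValidationError("kinetic prefactors must be > 0")

    @property
    def ids(self) -> dict:
        """Parameterization identifiers carried into every output."""
        return {
            "vp_id": self.vp_id,
            "sigma_id": self.sigma_id,
            "jhom_param": self.jhom_param or "cnt_form",
            "contact_angle_deg": self.contact_angle_deg,
        }


DEFAULT_CNT = CNTParameterization()


def dmu(T, params: CNTParameterization = DEFAULT_CNT):
    """Chemical-potential difference Δμ(T) = k_B T ln(p_liq/p_ice), J/molecule.

    Positive for supercooled water; vanishes at liquid–ice equilibrium
    (the default vapor-pressure curves cross at the triple point,
    273.160 K, so a residual of order 1e-4 k_B T remains at 273.15 K).
    """
    T = _check_range(T)
    return KB * T * np.log(p_vap_liquid(T) / p_vap_ice(T))


def _ln_vp_ratio_unchecked(T: float) -> float:
    # raw formulas, no supercooling range check: the crossing sits just
    # above the nominal melting point, at the triple point
    lnp_liq = (
        54.842763
        - 6763.22 / T
        - 4.210 * math.log(T)
        + 0.000367 * T
        + math.tanh(0.0415 * (T - 218.8))
        * (53.878 - 1331.22 / T - 9.44523 * math.log(T) + 0.014025 * T)
    )
    lnp_ice = 9.550426 - 5723.265 / T + 3.53068 * math.log(T) - 0.00728332 * T
    return lnp_liq - lnp_ice


def equilibrium_temperature(params: CNTParameterization = DEFAULT_CNT) -> float:
    """Temperature (K) where the liquid and ice vapor pressures cross."""
    from scipy.optimize import brentq

    return float(brentq(_ln_vp_ratio_unchecked, 272.5, 274.0))


def sigma_iw(T, params: CNTParameterization = DEFAULT_CNT):
    """Ice–water interfacial energy σ_iw(T) in J m⁻²."""
    T = np.asarray(T, dtype=float)
    tc = T - 273.15
    if params.sigma_id == "cnt_fit_linear":
        s = (29.5773 + 0.11483 * tc) * 1e-3
    elif params.sigma_id == "pruppacher_klett":
        s = (28.0 + 0.25 * tc) * 1e-3
    else:
        s = np.full_like(T, params.sigma_const)
    if np.any(s <= 0):
        raise ValidationError("sigma_iw parameterization gives non-positive values here")
    return s


def shape_factor(gamma_deg: float) -> float:
    """Spherical-cap shape factor f(γ) = (2 + cos γ)(1 − cos γ)² / 4.

    f(0) = 0 (perfect wetting, no barrier); f(90°) = 1/2 (hemisphere);
    f(180°) = 1 (no surface assistance, full homogeneous barrier).
    """
    if not 0.0 <= gamma_deg <= 180.0:
        raise ValidationError("contact angle must be in [0, 180] degrees")
    c = math.cos(math.radians(gamma_deg))
    return (2.0 + c) * (1.0 - c) ** 2 / 4.0


def critical_radius(T, params: CNTParameterization = DEFAULT_CNT):
    """Critical ice-embryo radius of curvature r* = 2 σ_iw v_ice / Δμ, in nm.

    Diverges at the melting point; raises for T at or above it.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T > T_MELT_K):
        raise ValidationError(
            "no finite critical embryo at or above the melting point"
        )
    d = dmu(T, params)
    if np.any(d <= 0):
        raise ValidationError("no finite critical embryo: Δμ(T) <= 0")
    return 2.0 * sigma_iw(T, params) * params.v_ice / d * 1e9


def cap_diameter(T, params: CNTParameterization = DEFAULT_CNT, mode: str = "sphere"):
    """Diameter (nm) of the critical spherical ice cap at temperature T (K).

    ``mode="sphere"`` returns the embryo-sphere diameter 2 r*;
    ``mode="footprint"`` returns the diameter of the circle the cap cuts
    on the surface, 2 r* sin γ — the quantity limited by the size of a
    flat binding site.  Both conventions are reported in output tables.
    """
    if mode not in ("sphere", "footprint"):
        raise ValidationError(f"unknown cap-diameter mode {mode!r}")
    r = critical_radius(T, params)
    if mode == "sphere":
        return 2.0 * r
    return 2.0 * r * math.sin(math.radians(params.contact_angle_deg))


def delta_g_hom(T, params: CNTParameterization = DEFAULT_CNT):
    """Homogeneous nucleation barrier ΔG* = 16π σ³ v² / (3 Δμ²), in J."""
    d = dmu(T, params)
    s = sigma_iw(T, params)
    return 16.0 * np.pi * s**3 * params.v_ice**2 / (3.0 * d**2)


def _j_hom_koop2000(T):
    """Empirical homogeneous rate (cm⁻³ s⁻¹) from the water-activity criterion.

    log10 J = −906.7 + 8502 Δa_w − 26924 Δa_w² + 29180 Δa_w³ with
    Δa_w = 1 − p_ice/p_liq for pure water.  The cubic was fitted for
    0.26 < Δa_w < 0.34 (J between ~1e-7 and 1e13 cm⁻³ s⁻¹); outside that
    window it is a smooth extrapolation that underflows to 0 at weak
    supercooling, which is the behavior a cooling-ramp simulator needs.
    """
    T = _check_range(T)
    daw = 1.0 - p_vap_ice(T) / p_vap_liquid(T)
    log10j = -906.7 + daw * (8502.0 + daw * (-26924.0 + daw * 29180.0))
    return 10.0 ** np.clip(log10j, -300.0, 300.0)


def j_hom(T, params: CNTParameterization = DEFAULT_CNT):
    """Homogeneous ice nucleation rate per unit volume (cm⁻³ s⁻¹)."""
    if params.jhom_param == "koop2000":
        return _j_hom_koop2000(T)
    T = _check_range(T)
    dg = delta_g_hom(T, params)
    return params.prefactor_hom * np.exp(-dg / (KB * np.asarray(T, dtype=float)))


def j_het(T, params: CNTParameterization = DEFAULT_CNT):
    """Heterogeneous rate per unit surface area (cm⁻² s⁻¹).

    The barrier is the homogeneous one scaled by the spherical-cap shape
    factor of the configured contact angle.
    """
    T = _check_range(T)
    f = shape_factor(params.contact_angle_deg)
    dg = delta_g_hom(T, params)
    return params.prefactor_het * np.exp(-f * dg / (KB * np.asarray(T, dtype=float)))


def cnt_line(
    grid_c, params: CNTParameterization = DEFAULT_CNT
) -> pd.DataFrame:
    """Critical-cap-diameter table over a temperature grid in °C.

    Columns: ``temp_C``, ``temp_K``, ``d_sphere_nm`` (embryo sphere
    diameter 2 r*) and ``d_footprint_nm`` (cap footprint 2 r* sin γ).
    Parameterization ids are stored in ``DataFrame.attrs``.
    """
    grid_c = np.atleast_1d(np.asarray(grid_c, dtype=float))
    if grid_c.size == 0:
        raise ValidationError("temperature grid is empty")
    T = celsius_to_kelvin(grid_c)
    table = pd.DataFrame(
        {
            "temp_C": grid_c,
            "temp_K": T,
            "d_sphere_nm": cap_diameter(T, params, "sphere"),
            "d_footprint_nm": cap_diameter(T, params, "footprint"),
        }
    )
    table.attrs.update(params.ids)
    return table
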