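"""Ice-binding-site geometry of ice-binding proteins.

A flat rectangular ice-binding site of sides d1 ≤ d2 can host a spherical
ice cap up to d1 across; anything larger must be ellipsoidal with
diameters d1 and d2.  To compare such a cap with the spherical critical
cap of nucleation theory, the two diameters are condensed into one
equivalent spherical diameter via the mean-curvature (Young–Laplace)
argument: equal mean curvature means the harmonic mean

    d_eq = 2 / (1/d1 + 1/d2).

When only the molecular weight of a protein is known, its linear size is
estimated by treating it as a cube of typical globular-protein density:
edge = (MW / (N_A ρ))^(1/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from ._errors import ValidationError
from .cnt import CNTParameterization, DEFAULT_CNT, cap_diameter, celsius_to_kelvin

__all__ = [
    "AVOGADRO",
    "DEFAULT_PROTEIN_DENSITY",
    "IceBindingSite",
    "equivalent_spherical_diameter",
    "cube_edge_from_mw",
    "SiteComparison",
    "site_vs_cnt",
]

AVOGADRO = 6.02214076e23  # 1/mol

#: classical globular-protein mass density, g/cm³
DEFAULT_PROTEIN_DENSITY = 1.35


def equivalent_spherical_diameter(d1: float, d2: float) -> float:
    """Equivalent spherical diameter d_eq = 2 (1/d1 + 1/d2)⁻¹ (nm).

    Symmetric in its arguments and bounded by min(d1, d2) and
    max(d1, d2); equals d for a square site (d, d).
    """
    if d1 <= 0 or d2 <= 0:
        raise ValidationError("site dimensions must be > 0 nm")
    return 2.0 / (1.0 / d1 + 1.0 / d2)


def cube_edge_from_mw(
    mw_kda: float, density: float = DEFAULT_PROTEIN_DENSITY
) -> float:
    """Cube edge length (nm) of a protein of given molar mass (kDa).

    Assumes a cubic protein of uniform density (default 1.35 g cm⁻³).
    """
    if mw_kda <= 0:
        raise ValidationError("molecular weight must be > 0 kDa")
    if density <= 0:
        raise ValidationError("density must be > 0 g/cm³")
    volume_cm3 = mw_kda * 1e3 / (AVOGADRO * density)
    return volume_cm3 ** (1.0 / 3.0) * 1e7  # cm -> nm


@dataclass(frozen=True)
class IceBindingSite:
    """Rectangular ice-binding site with derived size measures."""

    d1: float
    d2: float
    label: str = ""
    mw_kda: Optional[float] = None
    density: float = DEFAULT_PROTEIN_DENSITY

    def __post_init__(self):
        if not 0 < self.d1 <= self.d2:
            raise ValidationError("require 0 < d1 <= d2 (shorter side first)")
        if self.mw_kda is not None and self.mw_kda <= 0:
            raise ValidationError("molecular weight must be > 0 kDa")

    @property
    def d_eq(self) -> float:
        return equivalent_spherical_diameter(self.d1, self.d2)

    @property
    def cube_edge(self) -> Optional[float]:
        if self.mw_kda is None:
            return None
        return cube_edge_from_mw(self.mw_kda, self.density)


@dataclass(frozen=True)
class SiteComparison:
    """Binding-site size versus the CNT critical cap at one temperature.

    ``consistent`` is True when the critical-cap diameter (in the chosen
    convention) lies within [site_lower, site_upper], boundaries
    inclusive: a site exactly as large as the critical cap can host it.
    The site range is [d1, d_eq]; when a molecular weight is available
    the cube edge is recorded as an alternative lower bound.
    """

    label: str
    t_het_c: float
    d_cnt_sphere_nm: float
    d_cnt_footprint_nm: float
    mode: str
    site_lower_nm: float
    site_upper_nm: float
    alt_lower_nm: Optional[float]
    consistent: bool

    @property
    def d_cnt_nm(self) -> float:
        return (
            self.d_cnt_footprint_nm if self.mode == "footprint" else self.d_cnt_sphere_nm
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "t_het_C": self.t_het_c,
            "d_cnt_sphere_nm": self.d_cnt_sphere_nm,
            "d_cnt_footprint_nm": self.d_cnt_footprint_nm,
            "cap_diameter_mode": self.mode,
            "site_lower_nm": self.site_lower_nm,
            "site_upper_nm": self.site_upper_nm,
            "cube_edge_nm": self.alt_lower_nm,
            "consistent": self.consistent,
        }


def site_vs_cnt(
    site: IceBindingSite,
    t_het_c: float,
    params: CNTParameterization = DEFAULT_CNT,
    mode: str = "footprint",
) -> SiteComparison:
    """Compare a binding site with the CNT critical cap at T_het (°C).

    Both cap-diameter conventions are computed; ``mode`` selects which one
    the verdict uses (default: the cap footprint, since a flat binding
    site limits the footprint of the cap it can host).
    """
    if mode not in ("sphere", "footprint"):
        raise ValidationError(f"unknown cap-diameter mode {mode!r}")
    if not math.isfinite(t_het_c):
        raise ValidationError("t_het must be finite")
    T = celsius_to_kelvin(t_het_c)
    d_sphere = float(cap_diameter(T, params, "sphere"))
    d_foot = float(cap_diameter(T, params, "footprint"))
    d_used = d_foot if mode == "footprint" else d_sphere
    lower, upper = site.d1, site.d_eq
    return SiteComparison(
        label=site.label,
        t_het_c=float(t_het_c),
        d_cnt_sphere_nm=d_sphere,
        d_cnt_footprint_nm=d_foot,
        mode=mode,
        site_lower_nm=lower,
        site_upper_nm=upper,
        alt_lower_nm=site.cube_edge,
        consistent=bool(lower <= d_used <= upper),
    )
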