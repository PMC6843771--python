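"""Mass-normalized ice-active-site density spectra.

Under the singular (active-site) description of droplet freezing, droplets
freeze when cooling reaches the characteristic temperature of their best
nucleation site.  With sites distributed Poisson among droplets, the
cumulative number of sites per unit solute mass active at or above
temperature T is recovered from the frozen fraction as

    n_m(T) = -ln(1 - f_ice(T)) / m,

where m is the solute mass per droplet.  Because n_m normalizes away
concentration, spectra measured at different concentrations of the same
material must collapse onto one curve — the standard self-consistency
check that the dissolved material, not something else, nucleates the ice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from ._errors import ValidationError
from .assay import FrozenFractionCurve, SiteDensitySpectrum

__all__ = [
    "droplet_volume",
    "mass_per_droplet",
    "nm_spectrum",
    "collapse_check",
    "CollapseReport",
]


def droplet_volume(diameter_um: float) -> float:
    """Spherical droplet volume in cm³ from its diameter in µm."""
    if diameter_um <= 0:
        raise ValidationError("droplet diameter must be > 0 µm")
    d_cm = diameter_um * 1e-4
    return np.pi / 6.0 * d_cm**3


def mass_per_droplet(conc_mg_ml: float, volume_cm3: float) -> float:
    """Solute mass per droplet in g from mg/mL concentration and cm³ volume."""
    if conc_mg_ml < 0:
        raise ValidationError("concentration must be >= 0 mg/mL")
    if volume_cm3 <= 0:
        raise ValidationError("droplet volume must be > 0 cm³")
    return conc_mg_ml * 1e-3 * volume_cm3


def nm_spectrum(
    curve: FrozenFractionCurve, mass_g: float, label: str = ""
) -> SiteDensitySpectrum:
    """Cumulative site-density spectrum n_m(T) from a frozen-fraction curve.

    Grid points with f_ice = 0 (no sites resolved, n_m = 0 boundary) or
    f_ice = 1 (estimator divergent) are excluded and tallied.
    """
    if mass_g <= 0:
        raise ValidationError("mass per droplet must be > 0 g")
    f = curve.f_ice
    keep = (f > 0.0) & (f < 1.0)
    excluded = int(f.size - keep.sum())
    if not np.any(keep):
        raise ValidationError(
            "no grid point has 0 < f_ice < 1; spectrum is empty"
        )
    nm = -np.log1p(-f[keep]) / mass_g
    return SiteDensitySpectrum(
        temps=curve.temps[keep],
        nm=nm,
        mass_per_droplet=mass_g,
        excluded_points=excluded,
        label=label,
    )


@dataclass(frozen=True)
class PairStatistic:
    label_a: str
    label_b: str
    median_abs_log10_ratio: float
    n_points: int


@dataclass(frozen=True)
class CollapseReport:
    """Pairwise agreement of spectra at overlapping temperatures."""

    pairs: Tuple[PairStatistic, ...]
    threshold: float
    passed: bool

    def to_dict(self) -> dict:
        return {
            "threshold_log10": self.threshold,
            "passed": self.passed,
            "pairs": [
                {
                    "a": p.label_a,
                    "b": p.label_b,
                    "median_abs_log10_ratio": p.median_abs_log10_ratio,
                    "n_points": p.n_points,
                }
                for p in self.pairs
            ],
        }


def _interp_log10(spectrum: SiteDensitySpectrum, temps: np.ndarray) -> np.ndarray:
    # np.interp wants ascending x
    x = spectrum.temps[::-1]
    y = np.log10(spectrum.nm[::-1])
    return np.interp(temps, x, y)


def collapse_check(
    spectra: Sequence[SiteDensitySpectrum], threshold: float = 0.3
) -> CollapseReport:
    """Check that mass-normalized spectra collapse onto a single curve.

    For every pair, spectra are compared at the grid points of both
    members that fall inside their common temperature support; the
    statistic is the median |log10(n_m ratio)| (log-linear interpolation
    in temperature).  The default threshold 0.3 corresponds to agreement
    within a factor of 2.
    """
    if len(spectra) < 2:
        raise ValidationError("collapse check needs at least two spectra")
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    pairs: List[PairStatistic] = []
    for (i, a), (j, b) in itertools.combinations(enumerate(spectra), 2):
        la = a.label or f"spectrum_{i}"
        lb = b.label or f"spectrum_{j}"
        lo = max(a.temps.min(), b.temps.min())
        hi = min(a.temps.max(), b.temps.max())
        if lo > hi:
            raise ValidationError(
                "no overlapping temperature support between "
                f"{la} [{a.temps.min():.2f}, {a.temps.max():.2f}] °C and "
                f"{lb} [{b.temps.min():.2f}, {b.temps.max():.2f}] °C"
            )
        common = np.unique(
            np.concatenate(
                [
                    a.temps[(a.temps >= lo) & (a.temps <= hi)],
                    b.temps[(b.temps >= lo) & (b.temps <= hi)],
                ]
            )
        )
        diff = _interp_log10(a, common) - _interp_log10(b, common)
        pairs.append(
            PairStatistic(
                label_a=la,
                label_b=lb,
                median_abs_log10_ratio=float(np.median(np.abs(diff))),
                n_points=int(common.size),
            )
        )
    passed = all(p.median_abs_log10_ratio <= threshold for p in pairs)
    return CollapseReport(pairs=tuple(pairs), threshold=threshold, passed=passed)
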