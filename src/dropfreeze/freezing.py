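"""Frozen-fraction curves, median freezing temperatures, buffer correction.

The cumulative frozen fraction is

    f_ice(T) = (number of droplets with freeze temperature >= T) / n_total,

with censored (never-frozen) droplets kept in the denominator.  The median
freezing temperature T50 is the sample median over *all* droplets, censored
droplets ranked colder than any observed temperature — they provably did
not freeze within the ramp.  Uncertainty comes from a droplet bootstrap
(resampling droplets with replacement, percentile interval).

Dissolved buffer salts depress both the melting point and the homogeneous
nucleation temperature (a colligative effect).  To compare protein-induced
nucleation temperatures with pure-water theory, the measured median is
shifted by the water-minus-buffer offset:

    T_het = T50(sample) + [T50(water) - T50(buffer)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from ._errors import UndefinedStatisticError, ValidationError
from .assay import FreezingAssay, FrozenFractionCurve, MedianFreezingResult

__all__ = [
    "frozen_fraction",
    "t50",
    "BufferCorrection",
    "buffer_correct",
    "buffer_correct_result",
]


def frozen_fraction(
    assay: FreezingAssay, grid: Union[str, Sequence[float]] = "auto"
) -> FrozenFractionCurve:
    """Cumulative frozen fraction of an assay on a temperature grid.

    ``grid="auto"`` uses the sorted unique observed freezing temperatures
    (warm to cold).  An explicit grid is deduplicated and sorted warm to
    cold.  Censored droplets count toward ``n_total`` only.
    """
    if isinstance(grid, str):
        if grid != "auto":
            raise ValidationError(f"unknown grid spec {grid!r}")
        if assay.n_frozen == 0:
            raise ValidationError(
                "cannot build an automatic grid: no droplet froze"
            )
        grid_arr = np.unique(assay.freeze_temps)[::-1]
    else:
        grid_arr = np.unique(np.asarray(grid, dtype=float))[::-1]
        if grid_arr.size == 0:
            raise ValidationError("temperature grid is empty")
        if np.any(~np.isfinite(grid_arr)):
            raise ValidationError("temperature grid must be finite")

    sorted_temps = np.sort(assay.freeze_temps)  # ascending
    # droplets with freeze_temp >= T
    counts = assay.n_frozen - np.searchsorted(sorted_temps, grid_arr, side="left")
    f = counts / assay.n_total
    return FrozenFractionCurve(temps=grid_arr, f_ice=f, n_total=assay.n_total)


def _median_with_censored(temps: np.ndarray) -> float:
    """Sample median; censored droplets enter as -inf (colder than all)."""
    return float(np.median(temps))


def t50(
    assay: FreezingAssay,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MedianFreezingResult:
    """Median freezing temperature with a percentile-bootstrap CI.

    The median is taken over all droplets; censored droplets rank below
    every observed temperature.  If fewer than half the droplets froze the
    median falls on a censored droplet and T50 is undefined.

    Bootstrap resamples (droplets with replacement) whose median lands on
    a censored droplet are discarded; with a defined point estimate these
    are rare and the discard count is reflected in the effective sample.
    """
    if not 0 < ci_level < 1:
        raise ValidationError("ci_level must be in (0, 1)")
    if n_boot < 0:
        raise ValidationError("n_boot must be >= 0")
    values = np.concatenate(
        [assay.freeze_temps, np.full(assay.n_censored, -np.inf)]
    )
    point = _median_with_censored(values)
    if not math.isfinite(point):
        raise UndefinedStatisticError(
            "T50 undefined: fewer than half the droplets froze during the ramp"
        )
    if n_boot == 0:
        return MedianFreezingResult(point, point, point, 0, seed)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    meds = np.median(values[idx], axis=1)
    meds = meds[np.isfinite(meds)]
    if meds.size == 0:
        raise UndefinedStatisticError(
            "T50 undefined in every bootstrap resample"
        )
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(meds, [alpha / 2.0, 1.0 - alpha / 2.0])
    # the percentile interval can, for tiny samples, miss the point
    # estimate by one order statistic; keep the bracket invariant
    lo, hi = min(float(lo), point), max(float(hi), point)
    return MedianFreezingResult(point, lo, hi, int(n_boot), int(seed))


@dataclass(frozen=True)
class BufferCorrection:
    """Colligative buffer offset: T50(water) minus T50(buffer)."""

    t50_wat: float
    t50_buf: float

    def __post_init__(self):
        if not (math.isfinite(self.t50_wat) and math.isfinite(self.t50_buf)):
            raise ValidationError("buffer correction inputs must be finite")

    @property
    def offset(self) -> float:
        return self.t50_wat - self.t50_buf


def buffer_correct(t50_ibp: float, corr: BufferCorrection) -> float:
    """Heterogeneous nucleation temperature on the pure-water scale.

    T_het = T50(sample) + [T50(water) - T50(buffer)].
    """
    if not math.isfinite(t50_ibp):
        raise ValidationError("t50_ibp must be finite")
    return t50_ibp + corr.offset


def buffer_correct_result(
    ibp: MedianFreezingResult,
    wat: Optional[MedianFreezingResult] = None,
    buf: Optional[MedianFreezingResult] = None,
) -> MedianFreezingResult:
    """Apply the buffer correction to a full median result.

    The point estimate shifts by the offset; when water and buffer results
    carry their own confidence intervals, the three half-widths combine in
    quadrature (independent uncertainties).
    """
    if wat is None or buf is None:
        raise ValidationError("water and buffer medians are both required")
    corr = BufferCorrection(t50_wat=wat.t50, t50_buf=buf.t50)
    center = buffer_correct(ibp.t50, corr)
    hw = math.sqrt(ibp.half_width**2 + wat.half_width**2 + buf.half_width**2)
    return MedianFreezingResult(
        t50=center,
        ci_low=center - hw,
        ci_high=center + hw,
        n_boot=ibp.n_boot,
        seed=ibp.seed,
    )
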