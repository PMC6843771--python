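"""Domain types and file I/O for droplet-freezing assays.

A droplet-freezing experiment cools an array of monodisperse droplets at a
constant rate and records, for each droplet, the temperature at which it
froze.  Droplets still liquid at the end of the ramp are *censored*: they
carry no freezing temperature but remain part of the droplet population and
therefore depress the frozen fraction.

All temperatures in files and in these containers are degrees Celsius;
kelvin appears only inside the nucleation-theory module.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._errors import FormatError, ValidationError

__all__ = [
    "FreezingAssay",
    "FrozenFractionCurve",
    "MedianFreezingResult",
    "SiteDensitySpectrum",
    "read_assay",
    "write_results",
    "read_results",
]

MEDIA = ("water", "buffer", "buffer_plus_solute")

#: decimal places preserved by CSV round-trips (0.1 mK — far below any
#: cold-stage accuracy)
_TEMP_DECIMALS = 4


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class FreezingAssay:
    """One droplet-array experiment.

    Parameters
    ----------
    label:
        Free-text identifier (e.g. ``"ibp_0.5"``).
    freeze_temps:
        Freezing temperature in °C, one entry per droplet that froze.
    n_censored:
        Number of droplets still unfrozen at the end of the cooling ramp.
    droplet_diameter:
        Droplet diameter in µm.
    cooling_rate:
        Cooling rate in °C min⁻¹.
    solute_conc:
        Solute (protein) mass concentration in mg mL⁻¹; 0 for pure water
        or buffer-only droplets.
    solute_mw:
        Solute molar mass in kDa, if known.
    medium:
        One of ``water``, ``buffer``, ``buffer_plus_solute``.
    """

    label: str
    freeze_temps: np.ndarray
    n_censored: int = 0
    droplet_diameter: float = 90.0
    cooling_rate: float = 1.0
    solute_conc: float = 0.0
    solute_mw: Optional[float] = None
    medium: str = "water"

    def __post_init__(self):
        temps = _as_float_array(self.freeze_temps, "freeze_temps")
        object.__setattr__(self, "freeze_temps", temps)
        if np.any(~np.isfinite(temps)):
            raise ValidationError("freeze_temps must be finite")
        bad = np.flatnonzero((temps >= 0.0) | (temps <= -273.15))
        if bad.size:
            raise ValidationError(
                "freeze temperatures must lie in (-273.15, 0) °C; "
                f"offending indices: {bad.tolist()}"
            )
        if self.n_censored < 0:
            raise ValidationError("n_censored must be >= 0")
        if self.n_total < 1:
            raise ValidationError("assay needs at least one droplet")
        if self.droplet_diameter <= 0:
            raise ValidationError("droplet_diameter must be > 0 µm")
        if self.cooling_rate <= 0:
            raise ValidationError("cooling_rate must be > 0 °C/min")
        if self.solute_conc < 0:
            raise ValidationError("solute_conc must be >= 0 mg/mL")
        if self.medium not in MEDIA:
            raise ValidationError(f"medium must be one of {MEDIA}")

    @property
    def n_frozen(self) -> int:
        return int(self.freeze_temps.size)

    @property
    def n_total(self) -> int:
        return self.n_frozen + int(self.n_censored)


@dataclass(frozen=True)
class FrozenFractionCurve:
    """Cumulative fraction of droplets frozen, f_ice(T), for one assay.

    ``temps`` is strictly decreasing (the direction of cooling) and
    ``f_ice`` is non-decreasing along it: freezing is cumulative.
    """

    temps: np.ndarray
    f_ice: np.ndarray
    n_total: int

    def __post_init__(self):
        temps = _as_float_array(self.temps, "temps")
        f = _as_float_array(self.f_ice, "f_ice")
        object.__setattr__(self, "temps", temps)
        object.__setattr__(self, "f_ice", f)
        if temps.size == 0:
            raise ValidationError("curve must have at least one grid point")
        if temps.size != f.size:
            raise ValidationError("temps and f_ice must have equal length")
        if np.any(np.diff(temps) >= 0):
            raise ValidationError("temperature grid must be strictly decreasing")
        if np.any((f < 0) | (f > 1)):
            raise ValidationError("f_ice must lie in [0, 1]")
        if np.any(np.diff(f) < 0):
            raise ValidationError("f_ice must be non-decreasing as temperature falls")
        if self.n_total < 1:
            raise ValidationError("n_total must be >= 1")


@dataclass(frozen=True)
class MedianFreezingResult:
    """Median freezing temperature T50 with a bootstrap confidence interval."""

    t50: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def __post_init__(self):
        if not (self.ci_low <= self.t50 <= self.ci_high):
            raise ValidationError("confidence interval must bracket t50")

    @property
    def half_width(self) -> float:
        return 0.5 * (self.ci_high - self.ci_low)


@dataclass(frozen=True)
class SiteDensitySpectrum:
    """Mass-normalized cumulative ice-active-site density n_m(T).

    ``nm`` is in sites per gram of solute.  Grid points where the frozen
    fraction was exactly 0 (no sites resolved) or exactly 1 (estimator
    divergent) carry no estimate; they are dropped and tallied in
    ``excluded_points``.
    """

    temps: np.ndarray
    nm: np.ndarray
    mass_per_droplet: float
    excluded_points: int = 0
    label: str = ""

    def __post_init__(self):
        temps = _as_float_array(self.temps, "temps")
        nm = _as_float_array(self.nm, "nm")
        object.__setattr__(self, "temps", temps)
        object.__setattr__(self, "nm", nm)
        if temps.size == 0:
            raise ValidationError("spectrum must have at least one point")
        if temps.size != nm.size:
            raise ValidationError("temps and nm must have equal length")
        if np.any(np.diff(temps) >= 0):
            raise ValidationError("temperature grid must be strictly decreasing")
        if np.any(nm <= 0):
            raise ValidationError("nm must be > 0 at every reported point")
        if np.any(np.diff(nm) < 0):
            raise ValidationError("nm must be non-decreasing as temperature falls")
        if self.mass_per_droplet <= 0:
            raise ValidationError("mass_per_droplet must be > 0 g")
        if self.excluded_points < 0:
            raise ValidationError("excluded_points must be >= 0")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_ASSAY_COLUMNS = ("droplet_id", "freeze_temp_C", "censored")


def read_assay(path, meta: Optional[dict] = None, **meta_kwargs) -> FreezingAssay:
    """Read a per-droplet CSV (``droplet_id,freeze_temp_C,censored``).

    Assay metadata (diameter, cooling rate, concentration, medium, ...)
    is taken from ``meta`` / keyword arguments; if neither supplies it, a
    ``<path>.meta.json`` sidecar written by :func:`write_assay` is used.
    Row order never affects downstream results.
    """
    path = Path(path)
    meta = dict(meta or {})
    meta.update(meta_kwargs)
    sidecar = Path(str(path) + ".meta.json")
    if sidecar.exists():
        stored = json.loads(sidecar.read_text())
        for key, value in stored.items():
            meta.setdefault(key, value)
    meta.setdefault("label", path.stem)

    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty or unreadable CSV") from exc
    missing = [c for c in _ASSAY_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    censored_raw = pd.to_numeric(table["censored"], errors="coerce")
    if censored_raw.isna().any() or not censored_raw.isin([0, 1]).all():
        rows = table.index[~censored_raw.isin([0, 1])].tolist()
        raise ValidationError(f"{path}: censored flag must be 0 or 1; rows {rows}")
    censored = censored_raw.astype(bool)

    temps_raw = pd.to_numeric(table["freeze_temp_C"], errors="coerce")
    bad_frozen = table.index[(~censored) & temps_raw.isna()].tolist()
    if bad_frozen:
        raise ValidationError(
            f"{path}: non-numeric or missing freeze_temp_C on uncensored rows {bad_frozen}"
        )
    temps = temps_raw[~censored].to_numpy(dtype=float)
    out_of_range = table.index[
        (~censored) & ((temps_raw >= 0) | (temps_raw <= -273.15))
    ].tolist()
    if out_of_range:
        raise ValidationError(
            f"{path}: freeze_temp_C out of (-273.15, 0) °C on rows {out_of_range}"
        )

    allowed = {f.name for f in dataclasses.fields(FreezingAssay)}
    meta = {k: v for k, v in meta.items() if k in allowed}
    return FreezingAssay(
        freeze_temps=temps, n_censored=int(censored.sum()), **meta
    )


def write_assay(assay: FreezingAssay, path) -> Path:
    """Write an assay as a per-droplet CSV plus a metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = assay.n_total
    temps = np.round(assay.freeze_temps, _TEMP_DECIMALS)
    rows = [
        {"droplet_id": i, "freeze_temp_C": f"{t:.{_TEMP_DECIMALS}f}", "censored": 0}
        for i, t in enumerate(temps)
    ]
    rows += [
        {"droplet_id": assay.n_frozen + j, "freeze_temp_C": "", "censored": 1}
        for j in range(assay.n_censored)
    ]
    pd.DataFrame(rows, columns=list(_ASSAY_COLUMNS)).to_csv(path, index=False)
    meta = {
        "type": "FreezingAssay",
        "label": assay.label,
        "droplet_diameter": assay.droplet_diameter,
        "cooling_rate": assay.cooling_rate,
        "solute_conc": assay.solute_conc,
        "solute_mw": assay.solute_mw,
        "medium": assay.medium,
        "n_total": n,
    }
    _write_sidecar(path, meta)
    return path


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".meta.json")


def _write_sidecar(path: Path, meta: dict) -> None:
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


ResultType = Union[FrozenFractionCurve, SiteDensitySpectrum, MedianFreezingResult]


def write_results(obj: ResultType, path) -> Path:
    """Write a derived result as tidy CSV plus a JSON metadata sidecar.

    Curves and spectra become long-format CSV (one row per grid point);
    a median-freezing result, being scalar, is written as JSON directly.
    The pair is round-trippable through :func:`read_results`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, FrozenFractionCurve):
        df = pd.DataFrame(
            {"temp_C": np.round(obj.temps, _TEMP_DECIMALS), "f_ice": obj.f_ice}
        )
        df.to_csv(path, index=False, float_format="%.10g")
        _write_sidecar(path, {"type": "FrozenFractionCurve", "n_total": obj.n_total})
    elif isinstance(obj, SiteDensitySpectrum):
        df = pd.DataFrame(
            {"temp_C": np.round(obj.temps, _TEMP_DECIMALS), "nm_per_g": obj.nm}
        )
        df.to_csv(path, index=False, float_format="%.10g")
        _write_sidecar(
            path,
            {
                "type": "SiteDensitySpectrum",
                "mass_per_droplet_g": obj.mass_per_droplet,
                "excluded_points": obj.excluded_points,
                "label": obj.label,
            },
        )
    elif isinstance(obj, MedianFreezingResult):
        payload = {
            "type": "MedianFreezingResult",
            "t50_C": obj.t50,
            "ci_low_C": obj.ci_low,
            "ci_high_C": obj.ci_high,
            "n_boot": obj.n_boot,
            "seed": obj.seed,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValidationError(f"cannot write object of type {type(obj).__name__}")
    return path


def read_results(path) -> ResultType:
    """Inverse of :func:`write_results`."""
    path = Path(path)
    if path.suffix == ".json" and not str(path).endswith(".meta.json"):
        payload = json.loads(path.read_text())
        if payload.get("type") != "MedianFreezingResult":
            raise FormatError(f"{path}: unknown result type {payload.get('type')!r}")
        return MedianFreezingResult(
            t50=payload["t50_C"],
            ci_low=payload["ci_low_C"],
            ci_high=payload["ci_high_C"],
            n_boot=payload["n_boot"],
            seed=payload["seed"],
        )
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"{path}: missing metadata sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    kind = meta.get("type")
    if kind == "FrozenFractionCurve":
        return FrozenFractionCurve(
            temps=df["temp_C"].to_numpy(),
            f_ice=df["f_ice"].to_numpy(),
            n_total=meta["n_total"],
        )
    if kind == "SiteDensitySpectrum":
        return SiteDensitySpectrum(
            temps=df["temp_C"].to_numpy(),
            nm=df["nm_per_g"].to_numpy(),
            mass_per_droplet=meta["mass_per_droplet_g"],
            excluded_points=meta["excluded_points"],
            label=meta.get("label", ""),
        )
    raise FormatError(f"{path}: unknown result type {kind!r}")
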