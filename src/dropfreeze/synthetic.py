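"""Synthetic droplet-freezing assays with known ground truth.

Three generative models, matching the statistical structure the analysis
assumes:

homogeneous
    Pure-water droplets freeze stochastically under a volume nucleation
    rate J_hom(T).  The cooling ramp is discretized in small temperature
    steps; over one step of duration dt each unfrozen droplet freezes
    with probability 1 − exp(−J_hom V dt).

singular
    Each droplet carries Poisson-distributed active sites from an
    exponential (log-linear) site-density spectrum
    n*(T) = exp(a + b (T0 − T)); the droplet freezes when cooling reaches
    its best site's characteristic temperature.  The closed form inverse
    — draw u ~ U(0,1) and solve m n*(T) = −ln u — makes exact analytic
    oracles available (e.g. the median freezes where m n*(T50) = ln 2).

combined
    Per droplet, the warmer of a singular and a homogeneous draw, then a
    constant colligative buffer shift applied to every freezing event.

The generator's defaults are the study conditions of the droplet assays
this package analyzes: 90 µm droplets cooled at 1 °C min⁻¹, a 2.5 °C
buffer depression, and a spectrum calibrated so that protein solutions
between 0.03 and 0.5 mg mL⁻¹ give buffer-scale medians between −37.2 and
−35.7 °C.  All simulators are reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional

import numpy as np
import yaml

from ._errors import ValidationError
from .assay import FreezingAssay, write_assay
from .cnt import CNTParameterization, DEFAULT_CNT, celsius_to_kelvin, j_hom
from .site_density import droplet_volume, mass_per_droplet

__all__ = [
    "SimulationConfig",
    "simulate_homogeneous",
    "simulate_singular",
    "simulate_combined",
    "make_fixture_suite",
    "singular_t50_closed_form",
    "FIXTURE_CONCENTRATIONS",
]

#: concentration series of the fixture suite, mg/mL (endpoints are the
#: documented experimental range; the middle two values are placeholders)
FIXTURE_CONCENTRATIONS = (0.03, 0.1, 0.25, 0.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated assay.

    The spectrum is n*(T) = exp(a + b (T0 − T)) in sites per gram, with
    ``spectrum_b > 0`` so the spectrum steepens toward colder
    temperatures.  ``buffer_shift`` (°C, positive = depression) is applied
    by the combined model only.
    """

    n_droplets: int = 300
    droplet_diameter: float = 90.0  # µm
    cooling_rate: float = 1.0  # °C/min
    t_start: float = -10.0  # °C
    t_end: float = -45.0  # °C
    model: str = "combined"
    spectrum_a: float = 23.5135  # ln n* at T0, g^-1
    spectrum_b: float = 1.8756  # 1/°C
    spectrum_t0: float = -34.0  # °C
    conc: float = 0.0  # mg/mL
    mw: Optional[float] = 6.5  # kDa
    buffer_shift: float = 2.5  # °C
    temp_step: float = 0.05  # °C, ramp discretization
    seed: int = 0

    def __post_init__(self):
        if self.n_droplets < 1:
            raise ValidationError("n_droplets must be >= 1")
        if self.t_start <= self.t_end:
            raise ValidationError("t_start must be warmer than t_end")
        if self.spectrum_b <= 0:
            raise ValidationError("spectrum slope b must be > 0")
        if self.droplet_diameter <= 0 or self.cooling_rate <= 0:
            raise ValidationError("diameter and cooling rate must be > 0")
        if self.conc < 0:
            raise ValidationError("conc must be >= 0 mg/mL")
        if self.temp_step <= 0:
            raise ValidationError("temp_step must be > 0 °C")
        if self.model not in ("homogeneous", "singular", "combined"):
            raise ValidationError(f"unknown model {self.model!r}")
        if not 0 <= self.seed < 2**31:
            raise ValidationError("seed must be in [0, 2^31)")

    def spectrum_density(self, t_c) -> np.ndarray:
        """Ground-truth n*(T) in sites per gram."""
        t_c = np.asarray(t_c, dtype=float)
        return np.exp(self.spectrum_a + self.spectrum_b * (self.spectrum_t0 - t_c))

    @property
    def mass_per_droplet_g(self) -> float:
        return mass_per_droplet(self.conc, droplet_volume(self.droplet_diameter))


def singular_t50_closed_form(cfg: SimulationConfig) -> float:
    """Temperature (°C) where m n*(T) = ln 2: the singular-model median."""
    if cfg.conc <= 0:
        raise ValidationError("closed-form T50 needs conc > 0")
    m = cfg.mass_per_droplet_g
    return cfg.spectrum_t0 - (np.log(np.log(2.0) / m) - cfg.spectrum_a) / cfg.spectrum_b


def _homogeneous_draws(
    cfg: SimulationConfig, params: CNTParameterization, rng: np.random.Generator
) -> np.ndarray:
    """Per-droplet freezing temperatures (°C); -inf marks a censored droplet.

    Inverse-transform sampling on the discrete cumulative hazard of the
    stepped ramp — distributionally identical to per-step Bernoulli
    freezing with probability 1 − exp(−J V dt).
    """
    edges = np.arange(cfg.t_start, cfg.t_end - 1e-12, -cfg.temp_step)
    step_ends = edges[1:] if edges.size > 1 else np.array([cfg.t_end])
    if step_ends.size == 0 or step_ends[-1] > cfg.t_end:
        step_ends = np.append(step_ends, cfg.t_end)
    volume = droplet_volume(cfg.droplet_diameter)
    dt_s = cfg.temp_step / cfg.cooling_rate * 60.0
    rates = j_hom(celsius_to_kelvin(step_ends), params)
    cum_hazard = np.cumsum(rates * volume * dt_s)
    targets = -np.log(rng.random(cfg.n_droplets))
    idx = np.searchsorted(cum_hazard, targets)
    temps = np.where(idx < step_ends.size, step_ends[np.minimum(idx, step_ends.size - 1)], -np.inf)
    return temps


def _singular_draws(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Freezing temperatures (°C) under the singular model; -inf = censored."""
    m = cfg.mass_per_droplet_g
    if m <= 0:
        return np.full(cfg.n_droplets, -np.inf)
    targets = -np.log(rng.random(cfg.n_droplets))  # m n*(T) at freezing
    temps = cfg.spectrum_t0 - (np.log(targets / m) - cfg.spectrum_a) / cfg.spectrum_b
    temps = np.minimum(temps, cfg.t_start)  # sites active before the ramp fire at start
    return np.where(temps >= cfg.t_end, temps, -np.inf)


def _build_assay(
    cfg: SimulationConfig, temps: np.ndarray, label: str, medium: str
) -> FreezingAssay:
    frozen = temps[np.isfinite(temps)]
    return FreezingAssay(
        label=label,
        freeze_temps=np.sort(frozen)[::-1],
        n_censored=int(np.sum(~np.isfinite(temps))),
        droplet_diameter=cfg.droplet_diameter,
        cooling_rate=cfg.cooling_rate,
        solute_conc=cfg.conc if medium == "buffer_plus_solute" else 0.0,
        solute_mw=cfg.mw if medium == "buffer_plus_solute" else None,
        medium=medium,
    )


def simulate_homogeneous(
    cfg: SimulationConfig,
    params: CNTParameterization = DEFAULT_CNT,
    label: str = "water",
) -> FreezingAssay:
    """Pure-water droplets freezing under the volume rate J_hom(T)."""
    rng = np.random.default_rng(cfg.seed)
    temps = _homogeneous_draws(cfg, params, rng)
    return _build_assay(cfg, temps, label, "water")


def simulate_singular(cfg: SimulationConfig, label: str = "ibp") -> FreezingAssay:
    """Solute droplets freezing at the characteristic temperature of
    their best Poisson-distributed active site (no homogeneous background,
    no buffer shift)."""
    if cfg.conc <= 0:
        raise ValidationError("singular model requires conc > 0")
    rng = np.random.default_rng(cfg.seed)
    temps = _singular_draws(cfg, rng)
    return _build_assay(cfg, temps, label, "buffer_plus_solute")


def simulate_combined(
    cfg: SimulationConfig,
    params: CNTParameterization = DEFAULT_CNT,
    label: Optional[str] = None,
) -> FreezingAssay:
    """Heterogeneous sites plus homogeneous background, buffer-shifted.

    Each droplet freezes at the warmer of its singular and homogeneous
    draws, minus the constant buffer depression; droplets pushed below
    the ramp end are censored.  With ``conc=0`` this is the buffer-only
    control: a shifted homogeneous assay.
    """
    rng = np.random.default_rng(cfg.seed)
    singular = (
        _singular_draws(cfg, rng)
        if cfg.conc > 0
        else np.full(cfg.n_droplets, -np.inf)
    )
    homogeneous = _homogeneous_draws(cfg, params, rng)
    temps = np.maximum(singular, homogeneous) - cfg.buffer_shift
    temps = np.where(temps >= cfg.t_end, temps, -np.inf)
    medium = "buffer_plus_solute" if cfg.conc > 0 else "buffer"
    if label is None:
        label = "buffer" if cfg.conc == 0 else f"ibp_{cfg.conc:g}"
    return _build_assay(cfg, temps, label, medium)


def make_fixture_suite(
    out_dir,
    seed: int = 20260,
    n_droplets: int = 300,
    base_cfg: Optional[SimulationConfig] = None,
    params: CNTParameterization = DEFAULT_CNT,
) -> Path:
    """Write a deterministic six-assay suite and its manifest.

    One pure-water assay, one buffer-only control, and four protein
    concentrations (0.03, 0.1, 0.25, 0.5 mg/mL).  Regeneration with the
    same seed is byte-identical.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg0 = base_cfg or SimulationConfig()
    cfg0 = replace(cfg0, n_droplets=n_droplets)

    entries: List[dict] = []

    water = simulate_homogeneous(replace(cfg0, conc=0.0, seed=seed), params, "water")
    write_assay(water, out_dir / "water.csv")
    entries.append({"path": "water.csv", "role": "water", "label": "water", "conc": 0.0})

    buffer_assay = simulate_combined(replace(cfg0, conc=0.0, seed=seed + 1), params)
    write_assay(buffer_assay, out_dir / "buffer.csv")
    entries.append({"path": "buffer.csv", "role": "buffer", "label": "buffer", "conc": 0.0})

    for k, conc in enumerate(FIXTURE_CONCENTRATIONS):
        assay = simulate_combined(replace(cfg0, conc=conc, seed=seed + 2 + k), params)
        name = f"ibp_{conc:g}.csv"
        write_assay(assay, out_dir / name)
        entries.append(
            {
                "path": name,
                "role": "sample",
                "label": assay.label,
                "conc": conc,
                "mw_kda": cfg0.mw,
            }
        )

    manifest = {
        "droplet_diameter_um": cfg0.droplet_diameter,
        "cooling_rate_c_min": cfg0.cooling_rate,
        "buffer_shift_c": cfg0.buffer_shift,
        "seed": seed,
        "n_droplets": n_droplets,
        "site": {"d1_nm": 1.7, "d2_nm": 4.7, "mw_kda": 6.5},
        "assays": entries,
    }
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path
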