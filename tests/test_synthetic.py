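"""Synthetic assay generators: reproducibility and analytic ground truth."""

from dataclasses import replace

import numpy as np
import pytest
import yaml

from dropfreeze import (
    SimulationConfig,
    ValidationError,
    frozen_fraction,
    make_fixture_suite,
    nm_spectrum,
    simulate_combined,
    simulate_homogeneous,
    simulate_singular,
    singular_t50_closed_form,
    t50,
)


class TestHomogeneous:
    def test_reproducible_under_seed(self):
        cfg = SimulationConfig(model="homogeneous", n_droplets=100, seed=9)
        a = simulate_homogeneous(cfg)
        b = simulate_homogeneous(cfg)
        np.testing.assert_array_equal(a.freeze_temps, b.freeze_temps)
        assert a.n_censored == b.n_censored

    def test_different_seeds_differ_but_agree_statistically(self):
        a = simulate_homogeneous(SimulationConfig(model="homogeneous", seed=1))
        b = simulate_homogeneous(SimulationConfig(model="homogeneous", seed=2))
        assert not np.array_equal(a.freeze_temps, b.freeze_temps)
        assert abs(t50(a, n_boot=0).t50 - t50(b, n_boot=0).t50) < 0.5

    def test_negligible_rate_censors_everything(self):
        """Over a ramp ending at weak supercooling the homogeneous rate
        is effectively zero and no droplet freezes."""
        cfg = SimulationConfig(
            model="homogeneous", t_start=-5.0, t_end=-15.0, n_droplets=50, seed=3
        )
        assay = simulate_homogeneous(cfg)
        assert assay.n_censored == 50
        assert assay.n_frozen == 0

    def test_median_near_pure_water_reference(self):
        """300 droplets of 90 um at 1 C/min freeze with a median near
        -35.7 C; the residual offset (~1.1 C here) is set by the choice
        of published homogeneous-rate parameterization."""
        assay = simulate_homogeneous(SimulationConfig(model="homogeneous", seed=20260))
        assert t50(assay, n_boot=0).t50 == pytest.approx(-35.7, abs=1.5)


class TestSingular:
    def test_median_matches_closed_form_within_ci(self):
        cfg = SimulationConfig(model="singular", conc=0.25, seed=12)
        assay = simulate_singular(cfg)
        res = t50(assay, n_boot=1000, seed=13)
        assert res.ci_low <= singular_t50_closed_form(cfg) <= res.ci_high

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValidationError):
            simulate_singular(SimulationConfig(model="singular", conc=0.0))

    def test_doubling_concentration_preserves_spectrum(self):
        spectra = []
        for i, conc in enumerate((0.25, 0.5)):
            cfg = SimulationConfig(model="singular", conc=conc, seed=30 + i)
            assay = simulate_singular(cfg)
            spectra.append(
                nm_spectrum(frozen_fraction(assay), cfg.mass_per_droplet_g)
            )
        from dropfreeze import collapse_check

        assert collapse_check(spectra).passed

    def test_spectrum_recovery_against_ground_truth(self):
        """nm_spectrum inverts the generator: recovered n_m matches the
        generating spectrum within 0.15 decades where 0.05<f_ice<0.95."""
        cfg = SimulationConfig(model="singular", conc=0.25, seed=77)
        assay = simulate_singular(cfg)
        curve = frozen_fraction(assay)
        spec = nm_spectrum(curve, cfg.mass_per_droplet_g)
        window = (curve.f_ice > 0.05) & (curve.f_ice < 0.95)
        temps = curve.temps[window]
        keep = np.isin(spec.temps, temps)
        err = np.abs(np.log10(spec.nm[keep] / cfg.spectrum_density(spec.temps[keep])))
        assert np.median(err) < 0.15


class TestCombined:
    def test_buffer_only_is_exactly_shifted_homogeneous(self):
        """With conc=0 the combined model consumes the same random draws
        as the homogeneous one, so freeze temperatures shift by exactly
        the buffer depression."""
        cfg = SimulationConfig(model="combined", conc=0.0, buffer_shift=2.5, seed=6)
        water = simulate_homogeneous(replace(cfg, model="homogeneous"))
        buffered = simulate_combined(cfg)
        np.testing.assert_allclose(
            buffered.freeze_temps, water.freeze_temps - 2.5, rtol=0, atol=1e-12
        )

    def test_negligible_spectrum_reduces_to_shifted_homogeneous(self):
        cfg = SimulationConfig(
            model="combined", conc=0.25, spectrum_a=-40.0, buffer_shift=2.5, seed=8
        )
        buffered = simulate_combined(cfg)
        water = simulate_homogeneous(replace(cfg, model="homogeneous", conc=0.0))
        assert t50(buffered, n_boot=0).t50 == pytest.approx(
            t50(water, n_boot=0).t50 - 2.5, abs=0.3
        )

    def test_t50_ordering_monotone_in_concentration(self):
        """Stochastic dominance of the max construction: more protein
        mass can only warm the freezing temperatures."""
        t50s = []
        for i, conc in enumerate((0.0, 0.03, 0.1, 0.25, 0.5)):
            cfg = SimulationConfig(model="combined", conc=conc, seed=50 + i)
            t50s.append(t50(simulate_combined(cfg), n_boot=0).t50)
        assert all(b >= a - 0.15 for a, b in zip(t50s, t50s[1:]))
        assert t50s[-1] > t50s[0]


class TestFixtureSuite:
    def test_manifest_lists_six_assays(self, suite_manifest):
        manifest = yaml.safe_load(suite_manifest.read_text())
        assert len(manifest["assays"]) == 6
        roles = [e["role"] for e in manifest["assays"]]
        assert roles.count("water") == 1
        assert roles.count("buffer") == 1
        assert roles.count("sample") == 4

    def test_regeneration_is_byte_identical(self, suite_manifest, tmp_path):
        again = make_fixture_suite(tmp_path / "suite2", seed=20260, n_droplets=300)
        for path in sorted(suite_manifest.parent.glob("*.csv")):
            assert (again.parent / path.name).read_bytes() == path.read_bytes()

    def test_end_to_end_t50s_monotone_in_concentration(self, suite_manifest):
        from dropfreeze import read_assay

        manifest = yaml.safe_load(suite_manifest.read_text())
        t50s = []
        for entry in manifest["assays"]:
            if entry["role"] != "sample":
                continue
            assay = read_assay(suite_manifest.parent / entry["path"])
            t50s.append((entry["conc"], t50(assay, n_boot=0).t50))
        t50s.sort()
        values = [v for _, v in t50s]
        assert all(b >= a - 0.15 for a, b in zip(values, values[1:]))
        assert values[-1] > values[0]


def test_config_validation():
    with pytest.raises(ValidationError):
        SimulationConfig(n_droplets=0)
    with pytest.raises(ValidationError):
        SimulationConfig(t_start=-45.0, t_end=-10.0)
    with pytest.raises(ValidationError):
        SimulationConfig(spectrum_b=-1.0)
    with pytest.raises(ValidationError):
        SimulationConfig(seed=2**31)
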