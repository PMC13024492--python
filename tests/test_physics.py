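"""Closed-form frequency-mass relations and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ptfm
from ptfm.errors import ConfigurationError, DomainError, ValidityWarning
from ptfm.physics import MassLoad, ResonatorSpec


class TestResonatorSpec:
    def test_rejects_nonpositive_fields(self):
        with pytest.raises(ConfigurationError):
            ResonatorSpec(f0_hz=-1.0)
        with pytest.raises(ConfigurationError):
            ResonatorSpec(f0_hz=8500.0, q=0.0)

    def test_q_bandwidth_consistency_enforced(self):
        ResonatorSpec(f0_hz=8500.0, q=27.6, bandwidth_hz=8500.0 / 27.6)
        with pytest.raises(ConfigurationError):
            ResonatorSpec(f0_hz=8500.0, q=27.6, bandwidth_hz=500.0)

    def test_area_diameter_consistency(self):
        a = math.pi * 0.25 ** 2
        ResonatorSpec(f0_hz=8500.0, diameter_mm=5.0, area_cm2=a)
        with pytest.raises(ConfigurationError):
            ResonatorSpec(f0_hz=8500.0, diameter_mm=5.0, area_cm2=2 * a)

    def test_area_derived_from_diameter(self):
        spec = ResonatorSpec(f0_hz=8500.0, diameter_mm=5.0)
        assert spec.area == pytest.approx(math.pi * 0.0625, rel=1e-12)

    def test_json_round_trip(self, device):
        clone = ResonatorSpec.from_json(device.to_json())
        assert clone == device


class TestSauerbrey:
    def test_zero_load_gives_zero_shift(self, quartz):
        assert ptfm.sauerbrey_shift(quartz, 0.0) == 0.0

    def test_reference_quartz_value(self, quartz):
        # independent arithmetic: 2*(5e6)^2*1e-6 / (1*sqrt(2.648*2.947e11))
        expected = -2 * (5e6) ** 2 * 1e-6 / math.sqrt(2.648 * 2.947e11)
        assert ptfm.sauerbrey_shift(quartz, 1.0) == pytest.approx(expected)
        assert ptfm.sauerbrey_shift(quartz, 1.0) == pytest.approx(-56.6, abs=0.05)

    @given(st.floats(0.0, 100.0), st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_homogeneity_and_sign(self, quartz, dm, a):
        base = ptfm.sauerbrey_shift(quartz, dm)
        assert base <= 0.0
        assert ptfm.sauerbrey_shift(quartz, a * dm) == pytest.approx(
            a * base, rel=1e-12, abs=1e-12)

    def test_missing_constants_raise(self, device):
        with pytest.raises(ConfigurationError):
            ptfm.sauerbrey_shift(device, 1.0)  # PVDF spec has no rho_q/mu_q

    def test_negative_mass_rejected(self, quartz):
        with pytest.raises(DomainError):
            ptfm.sauerbrey_shift(quartz, MassLoad(delta_m_ug=-1.0))


class TestSensitivity:
    def test_theoretical_matches_shift_identity(self, quartz):
        s = ptfm.theoretical_sensitivity(quartz)
        assert s.units == "Hz/ug"
        for dm in np.linspace(0.0, 9.0, 25):
            assert ptfm.sauerbrey_shift(quartz, dm) == pytest.approx(
                -s.value * dm, rel=1e-12, abs=1e-12)

    def test_quadratic_in_f0(self, quartz):
        doubled = ResonatorSpec(f0_hz=2 * quartz.f0_hz, area_cm2=1.0,
                                rho_q=quartz.rho_q, mu_q=quartz.mu_q)
        assert ptfm.theoretical_sensitivity(doubled).value == pytest.approx(
            4 * ptfm.theoretical_sensitivity(quartz).value, rel=1e-12)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_identity_over_random_specs(self, seed):
        rng = np.random.default_rng(seed)
        spec = ResonatorSpec(f0_hz=float(rng.uniform(1e3, 1e7)),
                             area_cm2=float(rng.uniform(0.01, 10)),
                             rho_q=float(rng.uniform(0.5, 10)),
                             mu_q=float(rng.uniform(1e9, 1e12)))
        dm = float(rng.uniform(0, 50))
        s = ptfm.theoretical_sensitivity(spec).value
        assert ptfm.sauerbrey_shift(spec, dm) == pytest.approx(
            -s * dm, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("df,dm,expected", [
        (-56.6, 1.0, 56.6), (0.0, 5.0, 0.0), (-10.0, 2.0, 5.0)])
    def test_empirical_sensitivity(self, df, dm, expected):
        assert ptfm.empirical_sensitivity(df, dm).value == pytest.approx(expected)

    def test_empirical_sensitivity_zero_mass_rejected(self):
        with pytest.raises(DomainError):
            ptfm.empirical_sensitivity(-5.0, 0.0)


class TestFilmShift:
    def test_zero_areal_load(self, device):
        assert ptfm.film_shift(device, 0.0) == 0.0

    def test_full_areal_density_gives_half_f0(self, device):
        rho_t = device.rho_g_cm3 * device.thickness_cm
        with pytest.warns(ValidityWarning):
            assert ptfm.film_shift(device, rho_t) == pytest.approx(
                -device.f0_hz / 2, rel=1e-12)

    def test_reference_pvdf_value(self, device):
        # -8500 * 1e-6 / (2 * 1.78 * 2.8e-3), PVDF density is a package default
        expected = -8500.0 * 1e-6 / (2 * 1.78 * 2.8e-3)
        got = ptfm.film_shift(device, 1e-6)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-0.853, abs=5e-4)

    def test_scaling_laws(self, device):
        """Direct in f0, inverse in density and thickness."""
        base = ptfm.film_shift(device, 1e-6)
        f2 = ResonatorSpec(f0_hz=2 * device.f0_hz, diameter_mm=5.0,
                           rho_g_cm3=device.rho_g_cm3,
                           thickness_um=device.thickness_um)
        assert ptfm.film_shift(f2, 1e-6) == pytest.approx(2 * base, rel=1e-12)
        r2 = ResonatorSpec(f0_hz=device.f0_hz, diameter_mm=5.0,
                           rho_g_cm3=2 * device.rho_g_cm3,
                           thickness_um=device.thickness_um)
        assert ptfm.film_shift(r2, 1e-6) == pytest.approx(base / 2, rel=1e-12)
        t2 = ResonatorSpec(f0_hz=device.f0_hz, diameter_mm=5.0,
                           rho_g_cm3=device.rho_g_cm3,
                           thickness_um=2 * device.thickness_um)
        assert ptfm.film_shift(t2, 1e-6) == pytest.approx(base / 2, rel=1e-12)

    @pytest.mark.filterwarnings("ignore::ptfm.errors.ValidityWarning")
    @given(st.floats(0.0, 1e-4), st.floats(0.01, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_homogeneity_and_sign(self, device, dmA, a):
        base = ptfm.film_shift(device, dmA)
        assert base <= 0.0
        assert ptfm.film_shift(device, a * dmA) == pytest.approx(
            a * base, rel=1e-12, abs=1e-12)

    def test_total_vs_areal_consistency(self, quartz):
        """Sauerbrey from a total mass equals the same computed from the
        equivalent areal loading."""
        load_total = MassLoad(delta_m_ug=3.0)
        load_areal = MassLoad(delta_mA=3.0e-6 / quartz.area)
        assert ptfm.sauerbrey_shift(quartz, load_total) == pytest.approx(
            ptfm.sauerbrey_shift(quartz, load_areal), rel=1e-12)

    def test_thin_load_warning_threshold(self, device):
        rho_t = device.rho_g_cm3 * device.thickness_cm
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error", ValidityWarning)
            ptfm.film_shift(device, 0.05 * rho_t)  # below 10%: silent
        with pytest.warns(ValidityWarning):
            ptfm.film_shift(device, 0.2 * rho_t)


class TestQualityFactor:
    def test_measured_device_value(self):
        assert ptfm.quality_factor(8500.0, 308.0) == pytest.approx(27.6, abs=0.05)

    @pytest.mark.parametrize("f", [1.0, 440.0, 8500.0, 5e6])
    def test_equal_inputs_give_unity(self, f):
        assert ptfm.quality_factor(f, f) == pytest.approx(1.0)

    def test_arithmetic(self):
        assert ptfm.quality_factor(8500.0, 425.0) == pytest.approx(20.0)

    @given(st.floats(1.0, 1e7), st.floats(0.1, 1e5))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, f0, bw):
        q = ptfm.quality_factor(f0, bw)
        assert ptfm.bandwidth_from_q(f0, q) == pytest.approx(bw, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            ptfm.quality_factor(0.0, 300.0)
        with pytest.raises(DomainError):
            ptfm.bandwidth_from_q(8500.0, -1.0)


class TestInvertMass:
    def test_reference_value(self):
        assert ptfm.invert_mass(-56.6, 56.6) == pytest.approx(1.0)

    def test_zero_shift(self):
        assert ptfm.invert_mass(0.0, 12.3) == 0.0

    @given(st.floats(0.001, 100.0), st.floats(0.001, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_with_empirical_sensitivity(self, m, s):
        df = -s * m
        s_m = ptfm.empirical_sensitivity(df, m)
        assert ptfm.invert_mass(df, s_m) == pytest.approx(m, rel=1e-12)

    def test_nonpositive_sensitivity_rejected(self):
        with pytest.raises(DomainError):
            ptfm.invert_mass(-5.0, 0.0)


def test_units_audit_ug_to_g_conversion(quartz):
    """1 ug on 1 cm^2 equals an areal loading of 1e-6 g/cm^2 exactly."""
    load = MassLoad(delta_m_ug=1.0)
    assert load.areal_g_cm2(1.0) == pytest.approx(1e-6, rel=1e-9)
    back = MassLoad(delta_mA=1e-6)
    assert back.total_ug(1.0) == pytest.approx(1.0, rel=1e-9)
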