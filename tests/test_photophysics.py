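"""Spectral model, dosimetry and conversion/bleaching/turnover kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendratrack import photophysics as pp


@pytest.mark.parametrize("name,attr,peak", [
    ("gD2", "excitation_curve", 490.0),
    ("gD2", "emission_curve", 507.0),
    ("rD2", "excitation_curve", 553.0),
    ("rD2", "emission_curve", 573.0),
])
def test_reference_spectra_peak_at_published_wavelength(
        grid, references, name, attr, peak):
    spec = next(s for s in references if s.name == name)
    curve = getattr(spec, attr)
    assert grid.wavelengths[np.argmax(curve)] == peak


def test_reference_curves_normalized_and_nonnegative(references):
    for spec in references:
        for curve in (spec.excitation_curve, spec.emission_curve):
            assert np.all(curve >= 0)
            assert curve.max() == pytest.approx(1.0)


def test_grid_missing_peak_is_refused():
    narrow = pp.WavelengthGrid(400.0, 560.0, 1.0)
    with pytest.raises(ValueError, match="573"):
        pp.build_reference_spectra(narrow)


class TestFilters:
    def test_long_pass_blocks_green_emission(self, grid, references):
        gd2 = next(s for s in references if s.name == "gD2")
        filtered = pp.apply_filter(gd2.emission_curve,
                                   pp.FilterSpec(cutoff_nm=561.0), grid)
        i507 = grid.index_of(507.0)
        assert filtered[i507] <= 0.01 * gd2.emission_curve.max()

    def test_filtered_rd2_argmax_matches_sharp_edge_oracle(self, grid,
                                                           references):
        rd2 = next(s for s in references if s.name == "rD2")
        filtered = pp.apply_filter(rd2.emission_curve,
                                   pp.FilterSpec(cutoff_nm=561.0), grid)
        # oracle: ideal hard-edged long-pass
        sharp = rd2.emission_curve * (grid.wavelengths >= 561.0)
        oracle_argmax = grid.wavelengths[np.argmax(sharp)]
        assert grid.wavelengths[np.argmax(filtered)] >= 561.0
        assert abs(grid.wavelengths[np.argmax(filtered)]
                   - oracle_argmax) <= 2.0

    def test_identity_filter_below_grid_start(self, grid, references):
        gd2 = next(s for s in references if s.name == "gD2")
        out = pp.apply_filter(gd2.emission_curve,
                              pp.FilterSpec(cutoff_nm=100.0,
                                            transition_width_nm=1.0), grid)
        np.testing.assert_allclose(out, gd2.emission_curve, rtol=1e-9)

    def test_grid_mismatch_rejected(self, grid):
        with pytest.raises(ValueError):
            pp.apply_filter(np.ones(10), pp.FilterSpec(), grid)


class TestDosimetry:
    def test_hand_computed_fluence(self):
        # 100 µW for 300 s over 0.20 mm² = 100e-6 · 300 / 2.0e-3 J/cm²
        proto = pp.IlluminationProtocol(405.0, 100.0, 300.0, 2.0e5)
        assert pp.radiant_exposure(proto) == pytest.approx(15.0)

    def test_zero_duration_gives_zero_fluence(self):
        proto = pp.IlluminationProtocol(405.0, 100.0, 0.0, 2.0e5)
        assert pp.radiant_exposure(proto) == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            pp.IlluminationProtocol(405.0, 100.0, 300.0, 0.0)

    @given(power=st.floats(1.0, 500.0), duration=st.floats(1.0, 600.0),
           area=st.floats(100.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_fluence_scales_linearly_and_inversely(self, power, duration,
                                                   area):
        base = pp.radiant_exposure(
            pp.IlluminationProtocol(405.0, power, duration, area))
        assert pp.radiant_exposure(
            pp.IlluminationProtocol(405.0, 2 * power, duration, area)
        ) == pytest.approx(2 * base)
        assert pp.radiant_exposure(
            pp.IlluminationProtocol(405.0, power, duration, 2 * area)
        ) == pytest.approx(base / 2)

    def test_transmittance_applies_only_at_retina(self):
        cornea = pp.radiant_exposure(pp.IN_VIVO_LOCAL)
        retina = pp.radiant_exposure(pp.IN_VIVO_LOCAL, at_retina=True)
        assert retina == pytest.approx(cornea * 0.4)


class TestConversionKinetics:
    def test_lossless_limit_converts_everything(self):
        rates = pp.KineticRates(k_bleach_g=0.0, k_bleach_r=0.0)
        proto = pp.IlluminationProtocol(405.0, 75.0, 4000.0, 365.0 ** 2,
                                        transmittance=0.4)
        traj = pp.photoconvert(pp.DendraPool(g=1.0), rates, proto, dt_s=1.0)
        assert traj.final.r == pytest.approx(1.0, abs=1e-6)
        assert traj.final.g == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(traj.g + traj.r, 1.0, rtol=1e-9)

    def test_bleaching_makes_conversion_strictly_incomplete(self,
                                                            default_rates):
        # 10× a saturating dose still leaves r strictly below the total
        proto = pp.IlluminationProtocol(405.0, 75.0, 40000.0, 365.0 ** 2,
                                        transmittance=0.4)
        final = pp.photoconvert(pp.DendraPool(g=1.0), default_rates, proto,
                                dt_s=2.0).final
        assert final.r < 1.0

    def test_step_halving_changes_endpoint_below_contract(self,
                                                          default_rates):
        pool = pp.DendraPool(g=1.0)
        coarse = pp.photoconvert(pool, default_rates, pp.IN_VIVO_LOCAL,
                                 dt_s=1.0).final
        fine = pp.photoconvert(pool, default_rates, pp.IN_VIVO_LOCAL,
                               dt_s=0.1).final
        assert abs(coarse.r - fine.r) / fine.r < 1e-3
        assert abs(coarse.g - fine.g) / max(fine.g, 1e-12) < 1e-3

    def test_closed_form_agreement_for_constant_irradiance(self,
                                                           default_rates):
        """Integration matches the analytic solution of the linear system."""
        r = default_rates
        proto = pp.IN_VIVO_LOCAL
        I = pp.irradiance(proto, at_retina=True)
        traj = pp.photoconvert(pp.DendraPool(g=1.0), r, proto, dt_s=0.5)
        t = traj.times_s
        a = (r.k_conv + r.k_bleach_g) * I
        b = r.k_bleach_r * I
        g_true = np.exp(-a * t)
        r_true = r.k_conv * I / (b - a) * (np.exp(-a * t) - np.exp(-b * t))
        np.testing.assert_allclose(traj.g, g_true, rtol=1e-3)
        np.testing.assert_allclose(traj.r[1:], r_true[1:], rtol=1e-3)

    def test_monotone_during_conversion(self, default_rates):
        traj = pp.photoconvert(pp.DendraPool(g=1.0), default_rates,
                               pp.IN_VIVO_LOCAL, dt_s=1.0)
        assert np.all(np.diff(traj.g) <= 0)
        # r rises wherever conversion influx beats red bleaching
        # (dr/dt = k_conv·I·g − k_bleach_r·I·r ≥ 0 ⇔ g ≥ (k_br/k_conv)·r)
        gaining = traj.g[:-1] * default_rates.k_conv \
            >= traj.r[:-1] * default_rates.k_bleach_r
        assert np.all(np.diff(traj.r)[gaining] >= -1e-12)

    @given(k_conv=st.floats(0.01, 2.0), k_bg=st.floats(0.0, 0.5),
           k_br=st.floats(0.0, 0.5), dose_s=st.floats(10.0, 1000.0))
    @settings(max_examples=25, deadline=None)
    def test_pool_conservation_under_any_illumination(self, k_conv, k_bg,
                                                      k_br, dose_s):
        rates = pp.KineticRates(k_conv=k_conv, k_bleach_g=k_bg,
                                k_bleach_r=k_br)
        proto = pp.IlluminationProtocol(405.0, 75.0, dose_s, 365.0 ** 2,
                                        transmittance=0.4)
        traj = pp.photoconvert(pp.DendraPool(g=1.0), rates, proto, dt_s=1.0)
        np.testing.assert_allclose(traj.g + traj.r + traj.bleached, 1.0,
                                   rtol=1e-9)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            pp.KineticRates(k_conv=-0.1)


class TestImagingBleach:
    def test_488_exposure_never_converts(self, default_rates):
        proto = pp.IlluminationProtocol(488.0, 120.0, 100.0, 365.0 ** 2)
        pool = pp.DendraPool(g=0.7, r=0.3)
        traj = pp.bleach_under_excitation(pool, default_rates, proto,
                                          dt_s=0.5)
        np.testing.assert_allclose(traj.r, 0.3, rtol=1e-12)
        assert np.all(np.diff(traj.g) <= 0)

    def test_green_decay_matches_closed_form(self, default_rates):
        proto = pp.IlluminationProtocol(488.0, 120.0, 100.0, 365.0 ** 2)
        I = pp.irradiance(proto)
        traj = pp.bleach_under_excitation(pp.DendraPool(g=1.0),
                                          default_rates, proto, dt_s=0.25)
        expected = np.exp(-default_rates.k_bleach_g * I * traj.times_s)
        np.testing.assert_allclose(traj.g, expected, rtol=1e-3)


class TestTurnover:
    def test_zero_days_is_identity(self, default_rates):
        pool = pp.DendraPool(g=0.2, r=0.8)
        final = pp.turnover(pool, 0.0, default_rates).final
        assert final.g == pytest.approx(0.2, abs=1e-12)
        assert final.r == pytest.approx(0.8, abs=1e-12)

    def test_red_residual_below_5pct_at_one_week(self, default_rates):
        pool = pp.DendraPool(g=0.0, r=1.0)
        final = pp.turnover(pool, 7.0, default_rates).final
        assert final.r <= 0.05

    def test_red_decay_matches_exponential(self, default_rates):
        traj = pp.turnover(pp.DendraPool(g=0.0, r=1.0), 7.0, default_rates,
                           n_per_day=4)
        t_days = traj.times_s / 86400.0
        np.testing.assert_allclose(
            traj.r, np.exp(-default_rates.k_turnover_r * t_days),
            rtol=1e-9)

    def test_green_relaxes_to_synthesis_steady_state(self, default_rates):
        final = pp.turnover(pp.DendraPool(g=0.01), 60.0,
                            default_rates).final
        g_ss = default_rates.k_synth_g / default_rates.k_turnover_r
        assert final.g == pytest.approx(g_ss, rel=1e-6)


class TestEmittedSpectrum:
    def test_pure_green_pool_is_scaled_filtered_gd2(self, grid, references):
        pool = pp.DendraPool(g=0.5, r=0.0)
        spec = pp.emitted_spectrum(pool, 488.0, references)
        gd2 = next(s for s in references if s.name == "gD2")
        expected = pp.apply_filter(gd2.emission_curve,
                                   pp.DEFAULT_FILTERS[488.0], grid)
        ratio = spec[expected > 1e-6] / expected[expected > 1e-6]
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_pure_red_pool_peaks_beyond_long_pass(self, grid, references):
        pool = pp.DendraPool(g=0.0, r=1.0)
        spec = pp.emitted_spectrum(pool, 561.0, references)
        assert grid.wavelengths[np.argmax(spec)] >= 561.0

    def test_red_gain_outpaces_green_loss_for_equal_transfer(self, grid,
                                                             references):
        """With brightness_r/brightness_g = 2, moving molecules g→r raises
        the red peak faster than it lowers the green peak."""
        i_g = grid.index_of(507.0)
        i_r = grid.index_of(573.0)
        before = pp.DendraPool(g=1.0, r=0.0)
        after = pp.DendraPool(g=0.7, r=0.3)

        def peaks(pool):
            s = (pp.emitted_spectrum(pool, 488.0, references)
                 + pp.emitted_spectrum(pool, 561.0, references))
            return s[i_g], s[i_r]

        g0, r0 = peaks(before)
        g1, r1 = peaks(after)
        assert (r1 - r0) > (g0 - g1) > 0

    def test_unknown_excitation_line_rejected(self, references):
        with pytest.raises(ValueError):
            pp.emitted_spectrum(pp.DendraPool(g=1.0), 633.0, references)
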