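import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cannaqnmr import (LineshapeParams, SampleComposition, Spectrum1D,
                       apodize_exponential, auto_phase, baseline_correct,
                       default_acquisition, fourier_transform, hz_to_ppm,
                       oil_matrix, ppm_to_hz, process, reference_to_tms,
                       synthesize_fid, zero_fill)

from conftest import TEST_FWHM_HZ

NOISELESS = LineshapeParams(noise_sigma=0.0, fwhm_hz=TEST_FWHM_HZ)


def multi_peak_fid(acq, seed=1):
    """No-hump multi-line composition for phase/baseline round trips."""
    comp = SampleComposition({"delta9-THC": 800.0, "delta8-THC": 500.0,
                              "CBN": 600.0})
    return synthesize_fid(comp, acq, NOISELESS, seed=seed)


class TestUnitConversion:
    def test_suppression_band_edge_maps_to_printed_shift(self):
        assert hz_to_ppm(2156.0, 400.0) == pytest.approx(5.39)
        assert hz_to_ppm(347.0, 400.0) == pytest.approx(0.8675)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-1e4, 1e4), st.floats(50.0, 1200.0))
    def test_round_trip(self, hz, sf):
        assert ppm_to_hz(hz_to_ppm(hz, sf), sf) == pytest.approx(hz, abs=1e-9)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            hz_to_ppm(100.0, 0.0)


class TestZeroFill:
    def test_doubles_real_point_count(self):
        acq = default_acquisition()
        fid = synthesize_fid(SampleComposition({"CBN": 100.0}), acq, NOISELESS, 0)
        filled = zero_fill(fid, 262144)
        assert filled.data.size == 131072          # complex points
        assert filled.acq.td == 262144             # real points
        np.testing.assert_array_equal(filled.data[:65536], fid.data)
        assert np.all(filled.data[65536:] == 0)

    def test_identity_and_zero_cases(self, small_acq):
        fid = synthesize_fid(SampleComposition({"CBN": 10.0}), small_acq, NOISELESS, 0)
        same = zero_fill(fid, small_acq.td)
        np.testing.assert_array_equal(same.data, fid.data)
        blank = synthesize_fid(SampleComposition(), small_acq, NOISELESS, 0)
        assert np.all(zero_fill(blank, 2 * small_acq.td).data == 0)

    def test_shrinking_rejected(self, small_acq):
        fid = synthesize_fid(SampleComposition(), small_acq, NOISELESS, 0)
        with pytest.raises(ValueError):
            zero_fill(fid, small_acq.td // 2)


class TestApodization:
    def test_final_attenuation_matches_exponential_formula(self):
        acq = default_acquisition()
        fid = synthesize_fid(SampleComposition({"CBN": 100.0}), acq,
                             LineshapeParams(noise_sigma=0.0), 0)
        out = apodize_exponential(fid, 0.30)
        t_end = (fid.data.size - 1) * acq.dwell_s
        expected = np.exp(-np.pi * 0.30 * t_end)    # ~5.5e-4 over the ~8 s FID
        assert expected == pytest.approx(5.5e-4, rel=0.02)
        ratio = out.data[-1] / fid.data[-1]
        assert ratio == pytest.approx(expected, rel=1e-12)

    def test_first_point_unchanged_and_lb0_identity(self, small_acq):
        fid = multi_peak_fid(small_acq)
        assert apodize_exponential(fid, 2.0).data[0] == fid.data[0]
        np.testing.assert_array_equal(apodize_exponential(fid, 0.0).data, fid.data)
        with pytest.raises(ValueError):
            apodize_exponential(fid, -0.1)

    def test_line_broadening_widens_peaks(self, small_acq):
        fid = synthesize_fid(SampleComposition({"CBN": 500.0}), small_acq,
                             NOISELESS, 0)

        def fwhm_points(fid_in):
            spec = fourier_transform(zero_fill(fid_in, small_acq.si))
            sl = spec.window_slice(8.3, 8.1)
            y = spec.real[sl]
            return np.count_nonzero(y > y.max() / 2)

        assert fwhm_points(apodize_exponential(fid, 0.3)) >= fwhm_points(fid)


class TestFourierTransform:
    def test_pure_tone_lands_at_its_shift(self, small_acq):
        nu = ppm_to_hz(2.0 - small_acq.o1_ppm, small_acq.sf_mhz)
        t = np.arange(small_acq.n_complex) * small_acq.dwell_s
        from cannaqnmr import FID
        fid = FID(np.exp(2j * np.pi * nu * t), small_acq)
        spec = fourier_transform(fid)
        assert spec.ppm[np.argmax(np.abs(spec.complex))] == pytest.approx(2.0, abs=1e-3)

    def test_zero_fid_gives_zero_spectrum(self, small_acq):
        blank = synthesize_fid(SampleComposition(), small_acq, NOISELESS, 0)
        spec = fourier_transform(blank)
        assert np.all(spec.real == 0) and np.all(spec.imag == 0)

    def test_lorentzian_tone_integral_matches_synthesis_amplitude(self, small_acq):
        # two compositions differing 2x in concentration -> 2x integral
        a = synthesize_fid(SampleComposition({"CBN": 400.0}), small_acq, NOISELESS, 0)
        b = synthesize_fid(SampleComposition({"CBN": 800.0}), small_acq, NOISELESS, 0)
        sa = fourier_transform(zero_fill(a, small_acq.si))
        sb = fourier_transform(zero_fill(b, small_acq.si))
        assert sb.integrate(8.3, 8.1) / sa.integrate(8.3, 8.1) == pytest.approx(2.0, rel=0.01)

    def test_parseval(self, small_acq):
        fid = multi_peak_fid(small_acq)
        spec = fourier_transform(fid, halve_first_point=False)
        p_freq = np.sum(np.abs(spec.complex) ** 2) / fid.data.size
        p_time = np.sum(np.abs(fid.data) ** 2)
        assert p_freq == pytest.approx(p_time, rel=1e-6)


class TestAutoPhase:
    def test_already_phased_spectrum_is_fixed_point(self, small_acq):
        spec = fourier_transform(zero_fill(multi_peak_fid(small_acq), small_acq.si))
        out = auto_phase(spec)
        assert abs(out.provenance[-1]["phi0_deg"]) < 1.0

    def test_injected_zero_order_rotation_recovered(self, small_acq):
        spec = fourier_transform(zero_fill(multi_peak_fid(small_acq), small_acq.si))
        ref = auto_phase(spec).provenance[-1]["phi0_deg"]
        c = spec.complex * np.exp(1j * np.deg2rad(30.0))
        rot = Spectrum1D(c.real, c.imag, spec.ppm, spec.sf_mhz, spec.acq)
        rec = auto_phase(rot).provenance[-1]["phi0_deg"]
        assert rec == pytest.approx(-30.0 + ref, abs=1.0)

    def test_mixed_order_rotation_integrals_restored(self, small_acq):
        spec = fourier_transform(zero_fill(multi_peak_fid(small_acq), small_acq.si))
        ref_area = spec.integrate(6.21, 6.09)
        n = spec.n_points
        x = np.linspace(-0.5, 0.5, n)
        c = spec.complex * np.exp(1j * (np.deg2rad(40.0) + np.deg2rad(25.0) * x))
        rot = Spectrum1D(c.real, c.imag, spec.ppm, spec.sf_mhz, spec.acq)
        out = auto_phase(rot)
        assert out.integrate(6.21, 6.09) == pytest.approx(ref_area, rel=0.01)

    def test_blank_spectrum_flagged_degenerate(self, small_acq):
        blank = fourier_transform(synthesize_fid(SampleComposition(), small_acq,
                                                 NOISELESS, 0))
        out = auto_phase(blank)
        assert out.provenance[-1]["flag"] == "degenerate"


class TestBaseline:
    def test_constant_offset_removed(self, small_acq, proc_params):
        spec = fourier_transform(zero_fill(multi_peak_fid(small_acq), small_acq.si))
        c = 1000.0
        shifted = Spectrum1D(spec.real + c, spec.imag, spec.ppm, spec.sf_mhz, spec.acq)
        out = baseline_correct(shifted, exclude=proc_params.baseline_exclude)
        free = out.real[out.window_slice(11.0, 9.0)]
        assert abs(np.median(free)) < 0.01 * c

    def test_linear_ramp_does_not_bias_peak_areas(self, small_acq, proc_params):
        spec = fourier_transform(zero_fill(multi_peak_fid(small_acq), small_acq.si))
        ref = baseline_correct(spec, exclude=proc_params.baseline_exclude)
        ramp = np.linspace(0.0, 5e4, spec.n_points)
        tilted = Spectrum1D(spec.real + ramp, spec.imag, spec.ppm, spec.sf_mhz,
                            spec.acq)
        out = baseline_correct(tilted, exclude=proc_params.baseline_exclude)
        for win in [(8.3, 8.1), (6.21, 6.09)]:
            assert out.integrate(*win) == pytest.approx(ref.integrate(*win), rel=0.01)

    def test_zero_spectrum_unchanged(self, small_acq):
        blank = fourier_transform(synthesize_fid(SampleComposition(), small_acq,
                                                 NOISELESS, 0))
        out = baseline_correct(blank)
        assert np.allclose(out.real, 0.0)

    def test_everything_excluded_raises(self, small_acq):
        spec = fourier_transform(multi_peak_fid(small_acq))
        whole = [(float(spec.ppm[0]), float(spec.ppm[-1]))]
        with pytest.raises(ValueError):
            baseline_correct(spec, exclude=whole)


class TestTmsReferencing:
    def test_offset_tms_shifts_axis_back(self, small_acq):
        comp = SampleComposition({"TMS": 324.0, "CBN": 500.0})
        fid = synthesize_fid(comp, small_acq, NOISELESS, 0)
        spec = fourier_transform(zero_fill(fid, small_acq.si))
        shifted = Spectrum1D(spec.real, spec.imag, spec.ppm + 0.03,
                             spec.sf_mhz, spec.acq)
        out = reference_to_tms(shifted)
        assert out.provenance[-1]["shift_ppm"] == pytest.approx(-0.03, abs=2e-3)
        sl = out.window_slice(0.02, -0.02)
        assert out.real[sl].max() == out.real[out.window_slice(0.2, -0.2)].max()

    def test_no_tms_flags_and_leaves_axis(self, small_acq):
        fid = multi_peak_fid(small_acq)
        spec = fourier_transform(zero_fill(fid, small_acq.si))
        with pytest.warns(UserWarning):
            out = reference_to_tms(spec)
        assert out.provenance[-1]["flag"] == "no_tms"
        np.testing.assert_array_equal(out.ppm, spec.ppm)


class TestFullChain:
    def test_blank_fid_gives_flat_spectrum(self, small_acq, proc_params):
        blank = synthesize_fid(SampleComposition(), small_acq, NOISELESS, 0)
        with pytest.warns(UserWarning):
            spec = process(blank, proc_params)
        assert np.abs(spec.real).max() == pytest.approx(0.0, abs=1e-9)
        steps = [p["step"] for p in spec.provenance]
        assert steps == ["apodize_exponential", "zero_fill", "fourier_transform",
                         "auto_phase", "baseline_correct", "reference_to_tms"]

    def test_two_component_area_ratio_matches_composition(self, small_acq, proc_params):
        comp = SampleComposition({"TMS": 324.0, "CBN": 300.0, "delta9-THC": 900.0})
        spec = process(synthesize_fid(comp, small_acq, NOISELESS, 0), proc_params)
        a_thc = spec.integrate(6.21, 6.09)
        a_cbn = spec.integrate(8.3, 8.1)
        expected = (900.0 / 314.47) / (300.0 / 310.44)
        assert a_thc / a_cbn == pytest.approx(expected, rel=0.01)

    def test_round_trip_centers_within_two_mppm(self, small_acq, proc_params):
        comp = oil_matrix("hemp").with_analyte("delta9-THC", 900.0) \
            .with_analyte("CBN", 700.0)
        spec = process(synthesize_fid(comp, small_acq, NOISELESS, 0), proc_params)
        # singlet and J-merged doublet positions (a resolved J = 8 Hz doublet
        # has its maxima at the component lines, not the multiplet centre)
        for center, win in [(6.15, (6.21, 6.09)), (8.21, (8.3, 8.1)),
                            (0.0, (0.05, -0.05))]:
            sl = spec.window_slice(*win)
            found = spec.ppm[sl][np.argmax(spec.real[sl])]
            assert found == pytest.approx(center, abs=0.002)

    def test_zero_fill_invariant_integrals(self, small_acq, proc_params):
        import dataclasses
        comp = SampleComposition({"CBN": 500.0})
        fid = synthesize_fid(comp, small_acq, NOISELESS, 0)
        p1 = dataclasses.replace(proc_params, si=2 * small_acq.td, tms_reference=False)
        p2 = dataclasses.replace(proc_params, si=8 * small_acq.td, tms_reference=False)
        a1 = process(fid, p1).integrate(8.3, 8.1)
        a2 = process(fid, p2).integrate(8.3, 8.1)
        assert a2 == pytest.approx(a1, rel=1e-3)
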