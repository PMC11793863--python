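import numpy as np
import pytest

from nirstreat.io import RawIntensityRecording
from nirstreat.montage import TaskParadigm
from nirstreat.preprocess import (ChannelQCReport, DPFCoefficients,
                                  ExtinctionTable, HemoglobinSeries,
                                  OpticalDensitySeries, bandpass,
                                  baseline_correct, channel_qc, compute_dpf,
                                  correct_motion_spline, correct_motion_wavelet,
                                  detect_motion, detrend_linear,
                                  hemoglobin_to_od, intensity_to_od,
                                  load_extinction, od_to_hemoglobin)

FS = 10.0
NT = 1700
T = np.arange(NT) / FS


def make_od(data, fs=FS):
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None, None, :]
    elif data.ndim == 2:
        data = data[:, None, :]
    n_ch = data.shape[0]
    return OpticalDensitySeries(
        data=data,
        channel_ids=tuple(f"C{i+1}" for i in range(n_ch)),
        wavelengths=(830.0,) if data.shape[1] == 1 else (695.0, 830.0),
        sampling_rate=fs,
    )


def make_hb(hbo, fs=FS, paradigm=None):
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float))
    return HemoglobinSeries(
        hbo=hbo,
        hbr=-hbo / 3.0,
        channel_ids=tuple(f"C{i+1}" for i in range(hbo.shape[0])),
        sampling_rate=fs,
        paradigm=paradigm or TaskParadigm(sampling_rate=fs),
    )


class TestOpticalDensity:
    def _rec(self, intensity, montage, paradigm):
        n_ch = intensity.shape[0]
        return RawIntensityRecording(
            "S", 30.0, intensity, tuple(montage.channel_ids[:n_ch]), paradigm=paradigm
        )

    def test_constant_intensity_gives_zero_od(self, montage, paradigm):
        intensity = np.full((2, 2, NT), 1.7)
        od = intensity_to_od(self._rec(intensity, montage, paradigm))
        np.testing.assert_allclose(od.data, 0.0, atol=1e-15)

    def test_single_sample_dip_matches_log_ratio_oracle(self, montage, paradigm):
        intensity = np.full((1, 2, NT), 2.0)
        intensity[0, 0, 500] = 0.2
        od = intensity_to_od(self._rec(intensity, montage, paradigm))
        i0 = intensity[0, 0].mean()  # the realized whole-duration mean
        assert od.data[0, 0, 500] == pytest.approx(-np.log10(0.2 / i0), rel=1e-12)
        assert od.data[0, 0, 10] == pytest.approx(-np.log10(2.0 / i0), rel=1e-12)

    def test_scaling_intensity_leaves_od_unchanged(self, montage, paradigm):
        rng = np.random.default_rng(0)
        intensity = rng.uniform(0.5, 1.5, size=(3, 2, NT))
        od1 = intensity_to_od(self._rec(intensity, montage, paradigm))
        od2 = intensity_to_od(self._rec(2.0 * intensity, montage, paradigm))
        np.testing.assert_allclose(od1.data, od2.data, atol=1e-14)


class TestMotionDetection:
    def test_clean_slow_sine_has_empty_mask(self):
        od = make_od(0.01 * np.sin(2 * np.pi * 0.05 * T))
        assert not detect_motion(od).any()

    def test_large_spike_is_flagged_with_mask_dilation(self):
        y = 0.001 * np.sin(2 * np.pi * 0.05 * T)
        y[800:815] += 50 * y.std()  # transient excursion of 50 clean-signal SDs
        od = make_od(y)
        mask = detect_motion(od, t_motion=0.5, t_mask=1.0, std_thresh=5.0)
        # brute-force oracle: centred 5-sample window excursion against the
        # same realized channel SD, dilated by t_mask (10 samples) both sides
        pad = 10
        sd = y.std(ddof=1)
        flagged = np.zeros(NT, dtype=bool)
        for i in range(2, NT - 2):
            seg = y[i - 2:i + 3]
            if seg.max() - seg.min() > 5.0 * sd:
                flagged[max(0, i - pad):i + pad + 1] = True
        assert flagged.any()
        np.testing.assert_array_equal(mask[0, 50:-50], flagged[50:-50])

    def test_infinite_thresholds_disable_detection(self):
        rng = np.random.default_rng(1)
        od = make_od(rng.standard_normal(NT))
        mask = detect_motion(od, std_thresh=np.inf, amp_thresh=np.inf)
        assert not mask.any()

    def test_overlong_window_rejected(self):
        od = make_od(np.zeros(100))
        with pytest.raises(ValueError):
            detect_motion(od, t_motion=20.0)


class TestSplineCorrection:
    def test_empty_mask_is_identity(self):
        rng = np.random.default_rng(2)
        od = make_od(rng.standard_normal(NT))
        out = correct_motion_spline(od, np.zeros((1, NT), dtype=bool))
        np.testing.assert_array_equal(out.data, od.data)

    def test_boxcar_artifact_on_flat_baseline_is_flattened(self):
        y = np.zeros(NT)
        y[600:700] = 0.5  # boxcar artefact, exactly covered by the mask
        mask = np.zeros((1, NT), dtype=bool)
        mask[0, 600:700] = True
        out = correct_motion_spline(make_od(y), mask, p=0.99)
        # the smoothing spline of a constant segment is that constant, so the
        # segment collapses onto the preceding clean level (zero)
        np.testing.assert_allclose(out.data[0, 0], 0.0, atol=1e-6)

    @pytest.mark.parametrize("p", [0.0, -1.0, 1.5])
    def test_invalid_smoothing_parameter_rejected(self, p):
        od = make_od(np.zeros(NT))
        with pytest.raises(ValueError):
            correct_motion_spline(od, np.zeros((1, NT), dtype=bool), p=p)


class TestWaveletCorrection:
    def test_smooth_periodic_signal_passes_through(self):
        # integer cycle count and dyadic-friendly length: the periodised DWT
        # sees a smooth signal with no outlier coefficients
        n = 1696
        y = np.sin(2 * np.pi * 8 * np.arange(n) / n)
        out = correct_motion_wavelet(make_od(y))
        assert np.max(np.abs(out.data[0, 0] - y)) < 1e-8

    def test_spike_amplitude_reduced_by_90_percent(self):
        rng = np.random.default_rng(3)
        y = np.sin(2 * np.pi * 8 * np.arange(NT) / NT) + 0.01 * rng.standard_normal(NT)
        spike = 100 * y.std()
        y_sp = y.copy()
        y_sp[850] += spike
        out = correct_motion_wavelet(make_od(y_sp))
        residual = out.data[0, 0, 850] - y[850]
        assert abs(residual) < 0.1 * spike

    def test_infinite_iqr_factor_recovers_identity(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(NT)
        out = correct_motion_wavelet(make_od(y), iqr_factor=np.inf)
        np.testing.assert_allclose(out.data[0, 0], y, atol=1e-10)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError):
            correct_motion_wavelet(make_od(np.zeros(4)))


class TestDetrendAndBandpass:
    def test_ramp_detrends_to_zero(self):
        out = detrend_linear(make_od(3.0 * T + 2.0))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_sine_plus_ramp_matches_normal_equation_oracle(self):
        y = np.sin(2 * np.pi * 0.05 * T) + 0.3 * T - 4.0
        out = detrend_linear(make_od(y))
        # independent least-squares line via the normal equations
        A = np.column_stack([T, np.ones(NT)])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        oracle = y - A @ beta
        np.testing.assert_allclose(out.data[0, 0], oracle, atol=1e-9)

    def _gain(self, freq):
        """Steady-state gain measured by sinusoid regression (the oracle)."""
        y = np.sin(2 * np.pi * freq * T)
        out = bandpass(make_od(y)).data[0, 0]
        keep = slice(300, 1400)  # avoid filter edge transients
        basis = np.column_stack(
            [np.sin(2 * np.pi * freq * T[keep]), np.cos(2 * np.pi * freq * T[keep])]
        )
        coef = np.linalg.lstsq(basis, out[keep], rcond=None)[0]
        return float(np.hypot(*coef)), float(np.degrees(np.arctan2(coef[1], coef[0])))

    def test_passband_gain_at_005_hz(self):
        gain, phase = self._gain(0.05)
        assert 0.9 <= gain <= 1.0
        assert abs(phase) < 1.0  # zero-phase filtering

    def test_stopband_rejection_at_1_hz(self):
        gain, _ = self._gain(1.0)
        assert gain < 0.01

    def test_dc_offset_removed(self):
        out = bandpass(make_od(np.full(NT, 5.0)))
        assert abs(out.data.mean()) < 1e-6

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            bandpass(make_od(np.zeros(NT)), low=0.2, high=0.1)
        with pytest.raises(ValueError):
            bandpass(make_od(np.zeros(NT)), low=0.01, high=6.0)


class TestDPF:
    @staticmethod
    def _oracle(age, lam, delta=-5.723e-7):
        # independent plain-arithmetic evaluation of the DPF polynomial
        return (223.3 + 0.05624 * age**0.8493
                + delta * lam**3 + 0.001245 * lam**2 - 0.9025 * lam)

    @pytest.mark.parametrize("age, lam", [(30, 830), (30, 695), (55, 830), (21, 695)])
    def test_matches_arithmetic_oracle(self, age, lam):
        assert compute_dpf(age, lam) == pytest.approx(self._oracle(age, lam), rel=1e-12)

    def test_reference_values(self):
        assert compute_dpf(30, 830) == pytest.approx(5.68, abs=0.01)
        assert compute_dpf(30, 695) == pytest.approx(6.32, abs=0.01)

    def test_age_zero_drops_the_age_term(self):
        lam = 760.0
        expected = 223.3 - 5.723e-7 * lam**3 + 0.001245 * lam**2 - 0.9025 * lam
        assert compute_dpf(0, lam) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_in_age(self):
        ages = np.linspace(0, 100, 51)
        for lam in (695.0, 830.0):
            vals = [compute_dpf(a, lam) for a in ages]
            assert np.all(np.diff(vals) > 0)
            assert min(vals) > 0

    def test_printed_delta_scale_is_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            compute_dpf(30, 830, DPFCoefficients(delta=-5.723e-3))


class TestMBLL:
    def test_zero_od_gives_zero_hemoglobin(self, montage):
        od = make_od(np.zeros((2, 2, NT)))
        hb = od_to_hemoglobin(od, montage, age=30)
        np.testing.assert_array_equal(hb.hbo, 0.0)
        np.testing.assert_array_equal(hb.hbr, 0.0)

    def test_forward_inverse_round_trip(self, montage):
        rng = np.random.default_rng(5)
        hbo = 1e-6 * rng.standard_normal((4, NT))
        hbr = 1e-6 * rng.standard_normal((4, NT))
        od_data = hemoglobin_to_od(hbo, hbr, montage, age=42.0)
        od = OpticalDensitySeries(od_data, tuple(montage.channel_ids[:4]),
                                  (695.0, 830.0), FS)
        hb = od_to_hemoglobin(od, montage, age=42.0)
        np.testing.assert_allclose(hb.hbo, hbo, rtol=1e-10)
        np.testing.assert_allclose(hb.hbr, hbr, rtol=1e-10)

    def test_doubling_distance_halves_concentrations(self, montage):
        from dataclasses import replace
        rng = np.random.default_rng(6)
        data = 0.01 * rng.standard_normal((2, 2, NT))
        od = make_od(data)
        hb1 = od_to_hemoglobin(od, montage, age=30)
        far = replace(montage, source_detector_distance_cm=6.0)
        hb2 = od_to_hemoglobin(od, far, age=30)
        np.testing.assert_allclose(hb2.hbo, hb1.hbo / 2.0, rtol=1e-12)

    def test_singular_extinction_rejected(self, montage):
        bad = ExtinctionTable({695.0: {"HbO": 1.0, "HbR": 2.0},
                               830.0: {"HbO": 2.0, "HbR": 4.0}})
        od = make_od(np.zeros((1, 2, NT)))
        with pytest.raises(ValueError, match="singular"):
            od_to_hemoglobin(od, montage, age=30, extinction=bad)


class TestBaselineCorrection:
    def test_pure_ramp_removed(self, paradigm):
        hb = make_hb(2e-6 * T + 1e-6, paradigm=paradigm)
        out = baseline_correct(hb)
        np.testing.assert_allclose(out.hbo, 0.0, atol=1e-10)

    def test_constant_removed(self, paradigm):
        out = baseline_correct(make_hb(np.full(NT, 3e-6), paradigm=paradigm))
        np.testing.assert_allclose(out.hbo, 0.0, atol=1e-10)

    def test_window_means_are_zero_after_correction(self, paradigm):
        rng = np.random.default_rng(7)
        out = baseline_correct(make_hb(1e-6 * rng.standard_normal(NT), paradigm=paradigm))
        s1 = paradigm.slice_s(*paradigm.b1_bounds_s)
        s2 = paradigm.slice_s(*paradigm.b2_bounds_s)
        assert abs(out.hbo[0, s1].mean()) < 1e-10 * 1e-6 + 1e-16
        assert abs(out.hbo[0, s2].mean()) < 1e-10 * 1e-6 + 1e-16


class TestChannelQC:
    def test_band_power_ratio_keeps_clean_channel(self, paradigm):
        # SNR oracle: two sinusoids 1e-4 (0.05 Hz) and 1e-6 (4.8 Hz) give a
        # band-power ratio of (1e-4/1e-6)^2 = 1e4 >> 10.
        y = 1e-4 * np.sin(2 * np.pi * 0.05 * T) + 1e-6 * np.sin(2 * np.pi * 4.8 * T)
        od = make_od(y)
        hb = make_hb(1e-6 * np.sin(2 * np.pi * 0.05 * T), paradigm=paradigm)
        report = channel_qc(od, hb)
        assert report.keep[0]
        assert report.snr[0] > 100

    def test_amplitude_threshold_discards(self, paradigm):
        od = make_od(1e-4 * np.sin(2 * np.pi * 0.05 * T))
        hb = make_hb(1e-3 * np.sin(2 * np.pi * 0.05 * T), paradigm=paradigm)  # 2e-3 M range
        report = channel_qc(od, hb)
        assert not report.keep[0]
        assert report.reasons[0] == "amplitude"

    def test_all_zero_channel_is_degenerate(self, paradigm):
        report = channel_qc(make_od(np.zeros(NT)), make_hb(np.zeros(NT), paradigm=paradigm))
        assert not report.keep[0]
        assert report.reasons[0] == "degenerate"

    def test_literal_mode_flips_snr_direction(self, paradigm):
        y = 1e-4 * np.sin(2 * np.pi * 0.05 * T) + 1e-6 * np.sin(2 * np.pi * 4.8 * T)
        od = make_od(y)
        hb = make_hb(1e-6 * np.sin(2 * np.pi * 0.05 * T), paradigm=paradigm)
        assert channel_qc(od, hb).keep[0]
        literal = channel_qc(od, hb, literal=True)
        assert not literal.keep[0]
        assert literal.reasons[0] == "snr"


class TestLinearity:
    """detrend, bandpass and baseline correction commute with scaling."""

    def test_stages_commute_with_scalar_multiplication(self, paradigm):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(NT)
        c = 3.7
        for stage in (detrend_linear, bandpass):
            a = stage(make_od(c * y)).data
            b = c * stage(make_od(y)).data
            np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)
        a = baseline_correct(make_hb(c * y, paradigm=paradigm)).hbo
        b = c * baseline_correct(make_hb(y, paradigm=paradigm)).hbo
        np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)
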