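"""Raw intensity -> motion-corrected, filtered hemoglobin concentration.

The chain follows the standard fNIRS order: optical density, motion
detection, segment-wise spline correction, wavelet despiking, linear
detrend, zero-phase Butterworth band-pass (0.01-0.1 Hz), modified
Beer-Lambert conversion with an age/wavelength-dependent differential
pathlength factor, two-point baseline correction against the pre-task (b1)
and late post-task (b2) windows, and channel quality control based on a
spectral SNR and the min-max amplitude of recovered ΔHbO.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pywt
import yaml
from scipy import interpolate, signal

from .io import RawIntensityRecording
from .montage import Montage, TaskParadigm

__all__ = [
    "OpticalDensitySeries",
    "HemoglobinSeries",
    "DPFCoefficients",
    "ExtinctionTable",
    "ChannelQCReport",
    "intensity_to_od",
    "detect_motion",
    "correct_motion_spline",
    "correct_motion_wavelet",
    "detrend_linear",
    "bandpass",
    "compute_dpf",
    "od_to_hemoglobin",
    "hemoglobin_to_od",
    "baseline_correct",
    "channel_qc",
    "load_extinction",
    "preprocess_recording",
]


@dataclass
class OpticalDensitySeries:
    """ΔOD per channel and wavelength: shape (channels, wavelengths, time)."""

    data: np.ndarray
    channel_ids: tuple[str, ...]
    wavelengths: tuple[float, ...]
    sampling_rate: float
    motion_corrected: bool = False
    detrended: bool = False
    filtered: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ΔOD must be (channels, wavelengths, time)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ΔOD contains non-finite values")

    def copy_with(self, data: np.ndarray, **flags) -> "OpticalDensitySeries":
        out = replace(self, **flags)
        out.data = np.asarray(data, dtype=float)
        return out


@dataclass
class HemoglobinSeries:
    """ΔHbO/ΔHbR concentration change (molar), shape (channels, time)."""

    hbo: np.ndarray
    hbr: np.ndarray
    channel_ids: tuple[str, ...]
    sampling_rate: float
    paradigm: TaskParadigm = field(default_factory=TaskParadigm)

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("ΔHbO and ΔHbR must have the same shape")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValueError("hemoglobin series contains non-finite values")


@dataclass(frozen=True)
class DPFCoefficients:
    """Coefficients of the age/wavelength differential-pathlength polynomial.

    DPF = alpha + beta*age**gamma + delta*lam**3 + epsilon*lam**2 + zeta*lam.

    The default ``delta`` is -5.723e-7, the scale at which the polynomial
    produces physiological DPF values (about 5-7) across 600-1000 nm; a
    delta on the 1e-3 scale drives the cubic term to millions and is
    rejected at evaluation time.
    """

    alpha: float = 223.3
    beta: float = 0.05624
    gamma: float = 0.8493
    delta: float = -5.723e-7
    epsilon: float = 0.001245
    zeta: float = -0.9025


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients (cm^-1/M) per wavelength."""

    coefficients: dict[float, dict[str, float]]

    def matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        """2x2 matrix [[e_HbR,l1, e_HbO,l1], [e_HbR,l2, e_HbO,l2]]."""
        rows = []
        for wl in wavelengths:
            if wl not in self.coefficients:
                raise KeyError(f"no extinction coefficients at {wl:g} nm")
            c = self.coefficients[wl]
            rows.append([c["HbR"], c["HbO"]])
        m = np.asarray(rows, dtype=float)
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("extinction matrix is singular; check configuration")
        return m


@dataclass
class ChannelQCReport:
    """Per-channel SNR / amplitude QC decisions."""

    channel_ids: tuple[str, ...]
    snr: np.ndarray
    amplitude_range: np.ndarray
    keep: np.ndarray
    reasons: tuple[str, ...]

    @property
    def kept_channels(self) -> tuple[str, ...]:
        return tuple(c for c, k in zip(self.channel_ids, self.keep) if k)

    @property
    def discarded_channels(self) -> tuple[str, ...]:
        return tuple(c for c, k in zip(self.channel_ids, self.keep) if not k)


def load_extinction(path: str | Path | None = None) -> ExtinctionTable:
    if path is None:
        with resources.files("nirstreat.data").joinpath("extinction.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    table = {float(wl): {k: float(v) for k, v in d.items()} for wl, d in raw["extinction"].items()}
    return ExtinctionTable(coefficients=table)


# ---------------------------------------------------------------------------
# optical density

def intensity_to_od(rec: RawIntensityRecording) -> OpticalDensitySeries:
    """ΔOD(t, λ) = -log10(I / I0) with I0 the whole-recording mean of I."""
    i0 = rec.intensity.mean(axis=2, keepdims=True)
    od = -np.log10(rec.intensity / i0)
    return OpticalDensitySeries(
        data=od,
        channel_ids=rec.channel_ids,
        wavelengths=rec.wavelengths,
        sampling_rate=rec.paradigm.sampling_rate,
    )


# ---------------------------------------------------------------------------
# motion artefacts

def detect_motion(
    od: OpticalDensitySeries,
    t_motion: float = 0.5,
    t_mask: float = 1.0,
    std_thresh: float = 20.0,
    amp_thresh: float = 5.0,
) -> np.ndarray:
    """Boolean artefact mask, shape (channels, time).

    A sample is flagged when, in any window of ``t_motion`` seconds covering
    it (at either wavelength), the signal excursion (max - min) exceeds
    ``std_thresh`` times that channel's standard deviation or exceeds
    ``amp_thresh`` OD units.  Flags are dilated by ``t_mask`` seconds on both
    sides.
    """
    if t_motion <= 0 or t_mask < 0 or std_thresh <= 0 or amp_thresh <= 0:
        raise ValueError("motion-detection thresholds must be positive")
    fs = od.sampling_rate
    nt = od.data.shape[2]
    w = int(round(t_motion * fs))
    if w >= nt:
        raise ValueError("t_motion must be shorter than the recording")
    w = max(w, 2)
    from scipy.ndimage import maximum_filter1d, minimum_filter1d, binary_dilation

    nc = od.data.shape[0]
    mask = np.zeros((nc, nt), dtype=bool)
    for j in range(od.data.shape[1]):
        x = od.data[:, j, :]
        sd = x.std(axis=1, ddof=1)
        excursion = maximum_filter1d(x, size=w, axis=1) - minimum_filter1d(x, size=w, axis=1)
        thr = np.minimum(std_thresh * sd, amp_thresh)[:, None]
        mask |= excursion > thr
    pad = int(round(t_mask * fs))
    if pad > 0:
        mask = binary_dilation(mask, structure=np.ones((1, 2 * pad + 1), dtype=bool))
    return mask


def _segments(flags: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as [start, stop) pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], flags.astype(int), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def correct_motion_spline(
    od: OpticalDensitySeries, mask: np.ndarray, p: float = 0.99
) -> OpticalDensitySeries:
    """Segment-wise smoothing-spline motion correction.

    Within each flagged segment a cubic smoothing spline (csaps-style
    parameter ``p`` in (0, 1], mapped to the roughness penalty
    ``lam = (1-p)/p``) is fitted and subtracted, and the segment is
    re-levelled to the mean of the preceding clean segment (or the following
    one when the artefact starts the recording).  Clean samples are
    untouched.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("spline parameter p must lie in (0, 1]")
    lam = (1.0 - p) / p
    out = od.data.copy()
    fs = od.sampling_rate
    for i in range(out.shape[0]):
        segs = _segments(mask[i])
        if not segs:
            continue
        for j in range(out.shape[1]):
            y = out[i, j]
            for a, b in segs:
                seg = y[a:b].copy()
                t = np.arange(a, b) / fs
                if b - a >= 4:
                    spl = interpolate.make_smoothing_spline(t, seg, lam=lam)
                    fit = spl(t)
                else:
                    fit = np.full(b - a, seg.mean())
                if a > 0:
                    prev = _preceding_clean_mean(y, mask[i], a)
                    level = prev
                else:
                    level = _following_clean_mean(y, mask[i], b)
                y[a:b] = seg - fit + level
        # segments re-levelled per wavelength above
    return od.copy_with(out, motion_corrected=True)


def _preceding_clean_mean(y: np.ndarray, flags: np.ndarray, start: int) -> float:
    i = start - 1
    while i >= 0 and flags[i]:
        i -= 1
    if i < 0:
        return _following_clean_mean(y, flags, start)
    j = i
    while j >= 0 and not flags[j]:
        j -= 1
    return float(y[j + 1 : i + 1].mean())


def _following_clean_mean(y: np.ndarray, flags: np.ndarray, stop: int) -> float:
    n = len(y)
    i = stop
    while i < n and flags[i]:
        i += 1
    if i >= n:
        return 0.0
    j = i
    while j < n and not flags[j]:
        j += 1
    return float(y[i:j].mean())


def correct_motion_wavelet(
    od: OpticalDensitySeries, iqr_factor: float = 1.5, wavelet: str = "db4", level: int = 4
) -> OpticalDensitySeries:
    """Wavelet despiking: zero detail coefficients outside the Tukey fences.

    Each channel is decomposed (periodised DWT); within every detail level,
    coefficients below ``q1 - iqr_factor*IQR`` or above ``q3 +
    iqr_factor*IQR`` are set to zero before reconstruction.  Decomposition
    depth 4 at 10 Hz leaves the <= 0.3 Hz band (the hemodynamic range)
    untouched.
    """
    if iqr_factor <= 0:
        raise ValueError("iqr_factor must be positive")
    nt = od.data.shape[2]
    max_level = pywt.dwt_max_level(nt, pywt.Wavelet(wavelet).dec_len)
    if max_level < 1:
        raise ValueError("recording too short for one wavelet decomposition level")
    level = min(level, max_level)
    out = np.empty_like(od.data)
    for i in range(od.data.shape[0]):
        for j in range(od.data.shape[1]):
            coeffs = pywt.wavedec(od.data[i, j], wavelet, mode="periodization", level=level)
            cleaned = [coeffs[0]]
            for d in coeffs[1:]:
                if np.isfinite(iqr_factor):
                    q1, q3 = np.percentile(d, [25, 75])
                    iqr = q3 - q1
                    lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
                    d = np.where((d < lo) | (d > hi), 0.0, d)
                cleaned.append(d)
            rec = pywt.waverec(cleaned, wavelet, mode="periodization")
            out[i, j] = rec[:nt]
    return od.copy_with(out, motion_corrected=True)


# ---------------------------------------------------------------------------
# detrend / filter

def detrend_linear(od: OpticalDensitySeries) -> OpticalDensitySeries:
    if od.data.shape[2] < 2:
        raise ValueError("need at least two samples to detrend")
    out = signal.detrend(od.data, axis=2, type="linear")
    return od.copy_with(out, detrended=True)


def bandpass(
    od: OpticalDensitySeries,
    low: float = 0.01,
    high: float = 0.1,
    lp_order: int = 3,
    hp_order: int = 5,
) -> OpticalDensitySeries:
    """Zero-phase Butterworth band-pass: order-5 high-pass at ``low`` then
    order-3 low-pass at ``high``, each applied forward-backward."""
    nyq = od.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"need 0 < low < high < Nyquist ({nyq:g} Hz)")
    sos_hp = signal.butter(hp_order, low, btype="highpass", fs=od.sampling_rate, output="sos")
    sos_lp = signal.butter(lp_order, high, btype="lowpass", fs=od.sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos_hp, od.data, axis=2)
    out = signal.sosfiltfilt(sos_lp, out, axis=2)
    return od.copy_with(out, filtered=True)


# ---------------------------------------------------------------------------
# modified Beer-Lambert law

def compute_dpf(age: float, wavelength: float, coeffs: DPFCoefficients = DPFCoefficients()) -> float:
    """Differential pathlength factor for a given age (years) and wavelength (nm)."""
    if age < 0:
        raise ValueError("age must be nonnegative")
    if not (600.0 < wavelength < 1000.0):
        raise ValueError("wavelength must lie in (600, 1000) nm")
    dpf = (
        coeffs.alpha
        + coeffs.beta * age**coeffs.gamma
        + coeffs.delta * wavelength**3
        + coeffs.epsilon * wavelength**2
        + coeffs.zeta * wavelength
    )
    if dpf <= 0:
        raise ValueError(
            f"DPF evaluated to {dpf:.3g} (must be positive); the delta coefficient "
            "is probably on the wrong scale"
        )
    return float(dpf)


def od_to_hemoglobin(
    od: OpticalDensitySeries,
    montage: Montage,
    age: float,
    extinction: ExtinctionTable | None = None,
    coeffs: DPFCoefficients = DPFCoefficients(),
    paradigm: TaskParadigm | None = None,
) -> HemoglobinSeries:
    """Solve the 2x2 modified Beer-Lambert system per channel and sample.

    [ΔHbR; ΔHbO] = d^-1 ε^-1 [ΔOD(λ1)/DPF(λ1); ΔOD(λ2)/DPF(λ2)].
    """
    if len(od.wavelengths) != 2:
        raise ValueError("MBLL conversion requires exactly two wavelengths")
    extinction = extinction or load_extinction()
    d = montage.source_detector_distance_cm
    eps = extinction.matrix(tuple(od.wavelengths))  # rows: wavelengths; cols: HbR, HbO
    dpf = np.array([compute_dpf(age, wl, coeffs) for wl in od.wavelengths])
    scaled = od.data / dpf[None, :, None]  # (ch, wl, t)
    inv = np.linalg.inv(eps) / d
    hb = np.einsum("kw,cwt->ckt", inv, scaled)  # (ch, [HbR, HbO], t)
    paradigm = paradigm or TaskParadigm(sampling_rate=od.sampling_rate)
    return HemoglobinSeries(
        hbo=hb[:, 1, :],
        hbr=hb[:, 0, :],
        channel_ids=od.channel_ids,
        sampling_rate=od.sampling_rate,
        paradigm=paradigm,
    )


def hemoglobin_to_od(
    hbo: np.ndarray,
    hbr: np.ndarray,
    montage: Montage,
    age: float,
    wavelengths: tuple[float, float] = (695.0, 830.0),
    extinction: ExtinctionTable | None = None,
    coeffs: DPFCoefficients = DPFCoefficients(),
) -> np.ndarray:
    """Forward Beer-Lambert model: (ch, t) hemoglobin -> (ch, wl, t) ΔOD.

    The inverse of :func:`od_to_hemoglobin`; also the forward model used by
    the synthetic-cohort generator.
    """
    extinction = extinction or load_extinction()
    eps = extinction.matrix(wavelengths)
    d = montage.source_detector_distance_cm
    dpf = np.array([compute_dpf(age, wl, coeffs) for wl in wavelengths])
    conc = np.stack([hbr, hbo], axis=1)  # (ch, [HbR, HbO], t)
    od = np.einsum("wk,ckt->cwt", eps, conc) * d * dpf[None, :, None]
    return od


# ---------------------------------------------------------------------------
# baseline correction and QC

def baseline_correct(hb: HemoglobinSeries, paradigm: TaskParadigm | None = None) -> HemoglobinSeries:
    """Two-point linear baseline through the b1 and b2 window means.

    Per channel, the line through (center of b1, mean over b1) and (center of
    b2, mean over b2) is subtracted from both chromophores; afterwards both
    window means are zero to numerical precision.
    """
    paradigm = paradigm or hb.paradigm
    fs = paradigm.sampling_rate
    nt = hb.hbo.shape[1]
    s1 = paradigm.slice_s(*paradigm.b1_bounds_s)
    s2 = paradigm.slice_s(*paradigm.b2_bounds_s)
    if s1.stop > nt or s2.stop > nt or s1.start < 0 or s2.start < 0:
        raise ValueError("baseline windows fall outside the recording")
    t = np.arange(nt) / fs
    c1 = t[s1].mean()
    c2 = t[s2].mean()
    if abs(c2 - c1) < 1.0 / fs:
        raise ValueError("degenerate baseline windows (identical centers)")

    def _correct(x: np.ndarray) -> np.ndarray:
        m1 = x[:, s1].mean(axis=1)
        m2 = x[:, s2].mean(axis=1)
        slope = (m2 - m1) / (c2 - c1)
        intercept = m1 - slope * c1
        return x - (slope[:, None] * t[None, :] + intercept[:, None])

    return HemoglobinSeries(
        hbo=_correct(hb.hbo),
        hbr=_correct(hb.hbr),
        channel_ids=hb.channel_ids,
        sampling_rate=hb.sampling_rate,
        paradigm=paradigm,
    )


def channel_qc(
    od_prefilter: OpticalDensitySeries,
    hb: HemoglobinSeries,
    snr_thresh: float = 10.0,
    amp_thresh: float = 1.5e-3,
    literal: bool = False,
) -> ChannelQCReport:
    """Channel quality control.

    SNR is the Welch band-power of frequencies below 0.1 Hz (the hemodynamic
    range) divided by the band-power above 4.5 Hz (line-noise range),
    computed on the pre-bandpass, motion-corrected ΔOD (worst case across
    wavelengths).  Amplitude is the min-max range of ΔHbO in molar units.

    Default mode discards channels whose SNR falls below ``snr_thresh`` or
    whose amplitude range exceeds ``amp_thresh``.  ``literal=True`` flips the
    SNR direction (discarding SNR above threshold).
    """
    fs = od_prefilter.sampling_rate
    nt = od_prefilter.data.shape[2]
    nperseg = min(512, nt)
    if nt < 8:
        raise ValueError("recording too short for a Welch periodogram")
    freqs, psd = signal.welch(od_prefilter.data, fs=fs, nperseg=nperseg, axis=2)
    low_band = freqs < 0.1
    high_band = freqs > 4.5
    if not high_band.any():
        raise ValueError("no spectral content above 4.5 Hz; check the sampling rate")
    low_power = psd[:, :, low_band].sum(axis=2)
    high_power = psd[:, :, high_band].sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr_per_wl = low_power / high_power
    snr = np.min(snr_per_wl, axis=1)  # NaN (0/0) propagates -> degenerate
    amp = hb.hbo.max(axis=1) - hb.hbo.min(axis=1)

    keep = np.ones(len(hb.channel_ids), dtype=bool)
    reasons = []
    for i in range(len(hb.channel_ids)):
        degenerate = not np.isfinite(snr[i])
        if degenerate:
            keep[i] = False
            reasons.append("degenerate")
            continue
        snr_bad = (snr[i] > snr_thresh) if literal else (snr[i] < snr_thresh)
        amp_bad = amp[i] > amp_thresh
        if snr_bad and amp_bad:
            keep[i] = False
            reasons.append("snr+amplitude")
        elif snr_bad:
            keep[i] = False
            reasons.append("snr")
        elif amp_bad:
            keep[i] = False
            reasons.append("amplitude")
        else:
            reasons.append("ok")
    return ChannelQCReport(
        channel_ids=tuple(hb.channel_ids),
        snr=snr,
        amplitude_range=amp,
        keep=keep,
        reasons=tuple(reasons),
    )


# ---------------------------------------------------------------------------
# full chain

def preprocess_recording(
    rec: RawIntensityRecording,
    montage: Montage,
    extinction: ExtinctionTable | None = None,
    dpf_coeffs: DPFCoefficients = DPFCoefficients(),
    t_motion: float = 0.5,
    t_mask: float = 1.0,
    std_thresh: float = 20.0,
    amp_thresh_od: float = 5.0,
    spline_p: float = 0.99,
    iqr_factor: float = 1.5,
    qc_snr_thresh: float = 10.0,
    qc_amp_thresh: float = 1.5e-3,
    qc_literal: bool = False,
) -> tuple[HemoglobinSeries, ChannelQCReport]:
    """Run the full preprocessing chain on one recording.

    Returns the baseline-corrected hemoglobin series together with the
    channel QC report (QC only marks channels; it does not drop rows).
    """
    od = intensity_to_od(rec)
    mask = detect_motion(od, t_motion, t_mask, std_thresh, amp_thresh_od)
    od = correct_motion_spline(od, mask, spline_p)
    od = correct_motion_wavelet(od, iqr_factor)
    od_for_snr = od  # SNR measured pre-bandpass, post motion correction
    od = detrend_linear(od)
    od = bandpass(od)
    hb = od_to_hemoglobin(od, montage, rec.age, extinction, dpf_coeffs, rec.paradigm)
    hb = baseline_correct(hb, rec.paradigm)
    qc = channel_qc(od_for_snr, hb, qc_snr_thresh, qc_amp_thresh, literal=qc_literal)
    return hb, qc
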