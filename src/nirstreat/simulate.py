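"""Seeded synthetic fNIRS + miRNA cohort generator.

The generator emulates the statistical structure the prediction method
assumes, so every pipeline stage is testable without clinical data:

* a verbal-fluency block paradigm (10 s pre-scan, 30 s pre-task, 60 s task,
  70 s post-task at 10 Hz) driving a canonical double-gamma hemodynamic
  response, with response amplitude and latency depending on the response
  group (NR/PR/R);
* dominant per-subject nuisance: a multiplicative lognormal gain on the
  hemodynamic response and a lognormal gain on the connectivity signal
  amplitude, both much larger than the group effects they mask;
* group-dependent functional connectivity: two channel communities whose
  cross-community coupling increases from NR to R;
* physiological noise (linear drift, 0.1 Hz Mayer, 0.25 Hz respiratory,
  1.1 Hz cardiac, white noise) and seeded motion spikes;
* three miRNA expression values drawn log-normally with group-shifted
  means, and HAM-D score pairs generated consistently with each label.

ΔHbR is tied to ΔHbO (anticorrelated, ratio -1/3 by default) and the
forward Beer-Lambert model converts the planted hemodynamics into raw
dual-wavelength intensity, the generator's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.special import gammaln

from .io import MIRNA_FEATURES, RawIntensityRecording
from .montage import Montage, ResponseLabel, TaskParadigm, annotate_response, load_montage
from .preprocess import DPFCoefficients, ExtinctionTable, hemoglobin_to_od, load_extinction

__all__ = ["SimulationConfig", "SyntheticSubject", "SyntheticCohort",
           "simulate_subject", "simulate_cohort", "quiet_config"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Group effects are deliberately small against the subject nuisance gains:
    the premise of the variability-reduction routine is that inter-subject
    variation dominates the leading feature-variance directions.
    """

    n_nr: int = 24
    n_pr: int = 15
    n_r: int = 13
    # hemodynamic response (molar peak amplitude of task ΔHbO)
    group_amplitude: Mapping[str, float] = field(
        default_factory=lambda: {"NR": 3.0e-7, "PR": 4.5e-7, "R": 6.0e-7}
    )
    # group response latency added to the canonical ~5 s peak delay
    group_peak_delay_s: Mapping[str, float] = field(
        default_factory=lambda: {"NR": 0.0, "PR": 0.0, "R": 0.0}
    )
    # within-task habituation: activation decays with time constant tau;
    # non-responders habituate quickly, responders sustain the response
    group_sustain_tau_s: Mapping[str, float] = field(
        default_factory=lambda: {"NR": 20.0, "PR": 45.0, "R": 1.0e9}
    )
    sustain_jitter: float = 0.15  # lognormal sigma on tau
    # cross-community coupling of the connectivity latents
    group_cross_coupling: Mapping[str, float] = field(
        default_factory=lambda: {"NR": 0.35, "PR": 0.45, "R": 0.55}
    )
    # subject nuisance (dominant): lognormal sigmas and latency jitter
    gain_sigma: float = 0.6
    coupling_gain_sigma: float = 0.8
    phys_gain_sigma: float = 0.0
    latency_jitter_s: float = 1.0
    # physiological noise amplitudes (molar)
    latent_amplitude: float = 1.5e-7
    drift_slope: float = 2.0e-9  # molar per second, uniform +/-
    mayer_amplitude: float = 4.0e-8
    resp_amplitude: float = 3.0e-8
    cardiac_amplitude: float = 2.0e-8
    white_sigma: float = 1.0e-8
    mayer_freq: float = 0.1
    resp_freq: float = 0.25
    cardiac_freq: float = 1.1
    # motion artefacts
    spike_rate_per_min: float = 0.3
    spike_amplitude: float = 5.0e-6
    spike_decay_s: float = 0.6
    # chromophore coupling
    hbr_ratio: float = -1.0 / 3.0
    # miRNA log-normal model (natural-log means per group)
    mirna_log_mean: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "NR": (0.0, 1.0, -0.2),
            "PR": (0.4, 0.6, 0.4),
            "R": (0.8, 0.2, -0.1),
        }
    )
    mirna_log_sigma: float = 0.45
    age_range: tuple[float, float] = (21.0, 49.0)
    store_truth_series: bool = False  # keep the planted ΔHbO in truth (tests)
    hamd_baseline_range: tuple[int, int] = (18, 30)
    paradigm: TaskParadigm = field(default_factory=TaskParadigm)

    def __post_init__(self) -> None:
        if min(self.n_nr, self.n_pr, self.n_r) <= 0:
            raise ValueError("group sizes must be positive")
        for name in ("gain_sigma", "coupling_gain_sigma", "phys_gain_sigma",
                     "latency_jitter_s",
                     "latent_amplitude", "mayer_amplitude", "resp_amplitude",
                     "cardiac_amplitude", "white_sigma", "spike_rate_per_min",
                     "spike_amplitude", "mirna_log_sigma", "drift_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"NR": self.n_nr, "PR": self.n_pr, "R": self.n_r}


def quiet_config(cfg: SimulationConfig | None = None) -> SimulationConfig:
    """A copy of ``cfg`` with all nuisance and noise terms silenced.

    Used for planted-effect recovery checks: only the group-dependent
    response and connectivity structure remain.
    """
    cfg = cfg or SimulationConfig()
    return replace(
        cfg,
        gain_sigma=0.0,
        coupling_gain_sigma=0.0,
        phys_gain_sigma=0.0,
        latency_jitter_s=0.0,
        sustain_jitter=0.0,
        drift_slope=0.0,
        mayer_amplitude=0.0,
        resp_amplitude=0.0,
        cardiac_amplitude=0.0,
        white_sigma=0.0,
        spike_rate_per_min=0.0,
    )


@dataclass
class SyntheticSubject:
    recording: RawIntensityRecording
    mirna: dict[str, float]
    label: ResponseLabel
    truth: dict[str, float | str]


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    config: SimulationConfig
    seed: int

    @property
    def recordings(self) -> dict[str, RawIntensityRecording]:
        return {s.recording.subject_id: s.recording for s in self.subjects}

    @property
    def mirna_table(self) -> pd.DataFrame:
        rows = {s.recording.subject_id: s.mirna for s in self.subjects}
        return pd.DataFrame.from_dict(rows, orient="index")[list(MIRNA_FEATURES)]

    @property
    def labels(self) -> list[ResponseLabel]:
        return [s.label for s in self.subjects]

    @property
    def label_series(self) -> pd.Series:
        return pd.Series(
            {s.recording.subject_id: s.label.label for s in self.subjects}, name="label"
        )

    @property
    def truth(self) -> dict[str, dict]:
        return {s.recording.subject_id: s.truth for s in self.subjects}


def _double_gamma_hrf(t: np.ndarray, peak: float = 5.0, under: float = 15.0,
                      ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma impulse response (unit-normalized later)."""

    def g(t, shape, scale):
        tt = np.clip(t, 1e-12, None)
        return np.exp((shape - 1) * np.log(tt) - tt / scale
                      - gammaln(shape) - shape * np.log(scale))

    a1 = peak + 1.0
    a2 = under + 1.0
    h = g(t, a1, 1.0) - g(t, a2, 1.0) / ratio
    h[t < 0] = 0.0
    return h


def _task_response(paradigm: TaskParadigm, delay_s: float,
                   sustain_tau_s: float = 1.0e9) -> np.ndarray:
    """HRF-convolved task boxcar with within-task habituation.

    The boxcar decays with time constant ``sustain_tau_s`` during the task
    block, is convolved with the canonical HRF, peak-normalized to 1, and
    shifted by ``delay_s``.
    """
    fs = paradigm.sampling_rate
    n = paradigm.n_samples
    t = np.arange(n) / fs
    box = ((t >= paradigm.task_onset_s) & (t < paradigm.task_offset_s)).astype(float)
    if np.isfinite(sustain_tau_s) and sustain_tau_s > 0:
        decay = np.exp(-np.clip(t - paradigm.task_onset_s, 0.0, None) / sustain_tau_s)
        box = box * decay
    hrf_t = np.arange(0, 30.0, 1.0 / fs)
    hrf = _double_gamma_hrf(hrf_t)
    resp = np.convolve(box, hrf)[:n] / fs
    peak = np.abs(resp).max()
    if peak > 0:
        resp = resp / peak
    if delay_s != 0.0:
        resp = np.interp(t - delay_s, t, resp, left=0.0, right=resp[-1])
    return resp


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        low: float = 0.02, high: float = 0.09) -> np.ndarray:
    x = rng.standard_normal(n)
    sos = sp_signal.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    y = sp_signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _spike_train(rng: np.random.Generator, n: int, fs: float, rate_per_min: float,
                 amplitude: float, decay_s: float) -> np.ndarray:
    out = np.zeros(n)
    if rate_per_min <= 0 or amplitude <= 0:
        return out
    expected = rate_per_min * (n / fs) / 60.0
    k = rng.poisson(expected)
    if k == 0:
        return out
    starts = rng.integers(0, n, size=k)
    length = max(int(decay_s * fs), 1)
    kernel = np.exp(-np.arange(length) / (decay_s * fs / 3.0 + 1e-9))
    for s in starts:
        amp = amplitude * rng.choice([-1.0, 1.0]) * rng.uniform(0.7, 1.3)
        stop = min(s + length, n)
        out[s:stop] += amp * kernel[: stop - s]
    return out


def _activation_profile(montage: Montage) -> np.ndarray:
    """Deterministic per-channel activation weight (stronger over PFC)."""
    n = len(montage.channel_ids)
    in_use = set(montage.in_use_mask)
    w = np.empty(n)
    for i, ch in enumerate(montage.channel_ids):
        base = 1.0 if ch in in_use else 0.25
        w[i] = base * (0.75 + 0.25 * np.cos(2.0 * np.pi * i / n))
    return w


def _communities(montage: Montage) -> dict[str, int]:
    """Split the in-use channels into two connectivity communities."""
    in_use = list(montage.in_use_mask)
    half = len(in_use) // 2
    return {ch: (0 if k < half else 1) for k, ch in enumerate(in_use)}


def simulate_subject(
    cfg: SimulationConfig,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "S00",
    montage: Montage | None = None,
    extinction: ExtinctionTable | None = None,
    dpf_coeffs: DPFCoefficients = DPFCoefficients(),
) -> SyntheticSubject:
    """Generate one subject's raw recording, miRNA triplet and label."""
    if group not in ("NR", "PR", "R"):
        raise ValueError(f"unknown group {group!r}")
    montage = montage or load_montage()
    extinction = extinction or load_extinction()
    paradigm = cfg.paradigm
    fs = paradigm.sampling_rate
    n = paradigm.n_samples
    nc = len(montage.channel_ids)
    t = np.arange(n) / fs

    age = float(rng.uniform(*cfg.age_range))
    gain = float(np.exp(rng.normal(0.0, cfg.gain_sigma))) if cfg.gain_sigma > 0 else 1.0
    coupling_gain = (
        float(np.exp(rng.normal(0.0, cfg.coupling_gain_sigma)))
        if cfg.coupling_gain_sigma > 0
        else 1.0
    )
    phys_gain = (
        float(np.exp(rng.normal(0.0, cfg.phys_gain_sigma)))
        if cfg.phys_gain_sigma > 0
        else 1.0
    )
    delay = cfg.group_peak_delay_s[group] + (
        rng.normal(0.0, cfg.latency_jitter_s) if cfg.latency_jitter_s > 0 else 0.0
    )
    delay = float(max(delay, 0.0))
    amplitude = cfg.group_amplitude[group] * gain
    tau = cfg.group_sustain_tau_s[group]
    if cfg.sustain_jitter > 0 and np.isfinite(tau):
        tau = float(tau * np.exp(rng.normal(0.0, cfg.sustain_jitter)))

    response = _task_response(paradigm, delay, tau)
    profile = _activation_profile(montage)
    hbo = amplitude * profile[:, None] * response[None, :]

    # group-dependent connectivity latents on the in-use channels
    x = cfg.group_cross_coupling[group]
    u_shared = _band_limited_noise(rng, n, fs)
    u_comm = [_band_limited_noise(rng, n, fs), _band_limited_noise(rng, n, fs)]
    comm = _communities(montage)
    latent_scale = cfg.latent_amplitude * coupling_gain
    for i, ch in enumerate(montage.channel_ids):
        if ch not in comm:
            continue
        u = np.sqrt(1.0 - x) * u_comm[comm[ch]] + np.sqrt(x) * u_shared
        hbo[i] += latent_scale * (0.8 + 0.4 * rng.random()) * u

    # physiological noise: subject-common phases, per-channel amplitude jitter
    phases = rng.uniform(0, 2 * np.pi, size=3)
    osc = (
        phys_gain * cfg.mayer_amplitude * np.sin(2 * np.pi * cfg.mayer_freq * t + phases[0]),
        phys_gain * cfg.resp_amplitude * np.sin(2 * np.pi * cfg.resp_freq * t + phases[1]),
        phys_gain * cfg.cardiac_amplitude * np.sin(2 * np.pi * cfg.cardiac_freq * t + phases[2]),
    )
    subject_drift = rng.uniform(-cfg.drift_slope, cfg.drift_slope) if cfg.drift_slope > 0 else 0.0
    for i in range(nc):
        jitter = 0.8 + 0.4 * rng.random(3)
        for j, wave in enumerate(osc):
            hbo[i] += jitter[j] * wave
        ch_drift = subject_drift + (
            rng.uniform(-cfg.drift_slope, cfg.drift_slope) if cfg.drift_slope > 0 else 0.0
        )
        hbo[i] += ch_drift * (t - t.mean())
        if cfg.white_sigma > 0:
            hbo[i] += rng.normal(0.0, phys_gain * cfg.white_sigma, size=n)
        hbo[i] += _spike_train(rng, n, fs, cfg.spike_rate_per_min,
                               cfg.spike_amplitude, cfg.spike_decay_s)

    hbr = cfg.hbr_ratio * hbo
    if cfg.white_sigma > 0:
        hbr = hbr + rng.normal(0.0, 0.3 * cfg.white_sigma, size=hbo.shape)

    od = hemoglobin_to_od(hbo, hbr, montage, age, extinction=extinction, coeffs=dpf_coeffs)
    i0 = rng.uniform(0.5, 2.0, size=(nc, od.shape[1], 1))
    intensity = i0 * np.power(10.0, -od)

    recording = RawIntensityRecording(
        subject_id=subject_id,
        age=age,
        intensity=intensity,
        channel_ids=tuple(montage.channel_ids),
        paradigm=paradigm,
    )

    log_means = cfg.mirna_log_mean[group]
    mirna = {
        name: float(np.exp(rng.normal(mu, cfg.mirna_log_sigma)))
        for name, mu in zip(MIRNA_FEATURES, log_means)
    }

    label = _sample_hamd_label(cfg, group, rng, subject_id)
    truth = {
        "group": group,
        "amplitude": amplitude,
        "gain": gain,
        "coupling_gain": coupling_gain,
        "phys_gain": phys_gain,
        "delay_s": delay,
        "sustain_tau_s": tau,
        "cross_coupling": x,
        "age": age,
    }
    if cfg.store_truth_series:
        truth["hbo"] = hbo.copy()
    return SyntheticSubject(recording=recording, mirna=mirna, label=label, truth=truth)


def _sample_hamd_label(cfg: SimulationConfig, group: str, rng: np.random.Generator,
                       subject_id: str) -> ResponseLabel:
    """HAM-D pair consistent with the planted group under the annotation rule."""
    ranges = {"NR": (2.0, 20.0), "PR": (27.0, 48.0), "R": (55.0, 85.0)}
    lo, hi = ranges[group]
    for _ in range(100):
        baseline = int(rng.integers(cfg.hamd_baseline_range[0], cfg.hamd_baseline_range[1] + 1))
        reduction = rng.uniform(lo, hi)
        post = int(round(baseline * (1.0 - reduction / 100.0)))
        post = max(post, 0)
        lab = annotate_response(baseline, post, subject_id)
        if lab.label == group:
            return lab
    raise RuntimeError("could not draw a HAM-D pair consistent with the group")


def simulate_cohort(
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    montage: Montage | None = None,
) -> SyntheticCohort:
    """Generate the full cohort (default composition 24 NR / 15 PR / 13 R)."""
    cfg = cfg or SimulationConfig()
    montage = montage or load_montage()
    rng = np.random.default_rng(seed)
    subjects = []
    k = 0
    for group in ("NR", "PR", "R"):
        for _ in range(cfg.group_sizes[group]):
            k += 1
            sid = f"S{k:02d}"
            subjects.append(
                simulate_subject(cfg, group, rng, subject_id=sid, montage=montage)
            )
    return SyntheticCohort(subjects=subjects, config=cfg, seed=seed)
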