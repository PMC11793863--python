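"""Time-domain activation features of the task-period ΔHbO response.

Thirteen summary statistics are computed from a single prefrontal trace
obtained by averaging the baseline-corrected ΔHbO over the kept in-use
channels.  The set includes the mean, dispersion and shape moments of the
task window plus response-timing quantities (time to peak, power-weighted
centroid time, onset and recovery slopes).  The feature list is pluggable so
an alternative definition table can be substituted via configuration.
"""

from __future__ import annotations

import numpy as np

from .montage import Montage, TaskParadigm
from .preprocess import ChannelQCReport, HemoglobinSeries

__all__ = ["TIME_FEATURE_NAMES", "extract_time_features"]

TIME_FEATURE_NAMES = (
    "mean",
    "std",
    "variance",
    "coeff_variation",
    "range",
    "peak",
    "time_to_peak_s",
    "centroid_time_s",
    "auc",
    "onset_slope",
    "recovery_slope",
    "skewness",
    "kurtosis",
)


class TimeFeatureError(RuntimeError):
    """Raised when no usable channel remains for feature extraction."""


def _lsq_slope(t: np.ndarray, y: np.ndarray) -> float:
    t = t - t.mean()
    denom = float((t**2).sum())
    if denom == 0.0:
        return 0.0
    return float((t * (y - y.mean())).sum() / denom)


def extract_time_features(
    hb: HemoglobinSeries,
    paradigm: TaskParadigm | None = None,
    montage: Montage | None = None,
    qc: ChannelQCReport | None = None,
    slope_window_s: float = 10.0,
) -> dict[str, float]:
    """Thirteen time-domain activation features from baseline-corrected ΔHbO.

    The task-period trace averaged over the kept in-use channels is
    summarised.  Timing features are in seconds relative to task onset;
    moments of a zero-variance trace are defined as 0.
    """
    paradigm = paradigm or hb.paradigm
    fs = paradigm.sampling_rate
    channels = list(hb.channel_ids)
    use = set(montage.in_use_mask) if montage is not None else set(channels)
    if qc is not None:
        use &= set(qc.kept_channels)
    rows = [i for i, c in enumerate(channels) if c in use]
    if not rows:
        raise TimeFeatureError("no in-use channel survived QC; cannot extract features")
    trace = hb.hbo[rows].mean(axis=0)

    task = trace[paradigm.task_slice]
    t_task = np.arange(len(task)) / fs  # seconds from task onset
    mean = float(task.mean())
    sd = float(task.std(ddof=1))
    var = float(task.var(ddof=1))
    cv = sd / mean if mean != 0.0 else 0.0
    rng = float(task.max() - task.min())
    ipeak = int(np.argmax(task))
    peak = float(task[ipeak])
    ttp = float(t_task[ipeak])
    power = task**2
    total_power = float(power.sum())
    centroid = float((power * t_task).sum() / total_power) if total_power > 0 else 0.0
    auc = float(np.trapezoid(task, dx=1.0 / fs))

    w = int(round(slope_window_s * fs))
    onset = _lsq_slope(t_task[:w], task[:w])
    post = trace[paradigm.slice_s(paradigm.task_offset_s, paradigm.task_offset_s + slope_window_s)]
    recovery = _lsq_slope(np.arange(len(post)) / fs, post)

    if sd > 0:
        z = (task - mean) / task.std(ddof=0)
        skew = float((z**3).mean())
        kurt = float((z**4).mean())
    else:
        skew = kurt = 0.0

    values = (mean, sd, var, cv, rng, peak, ttp, centroid, auc, onset, recovery, skew, kurt)
    out = dict(zip(TIME_FEATURE_NAMES, values))
    assert len(out) == 13
    return out
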