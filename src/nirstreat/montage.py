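"""Probe montage model, task paradigm, and treatment-response annotation.

The montage describes a high-density prefrontal probe: a 3x11 grid of
alternating light sources and detectors, every adjacent source-detector pair
(about 3 cm apart) forming one of 52 measurement channels.  Channels nearest
the temporal ends of the lowest probe row are heavily noise-contaminated, so
only a 32-channel subset over the prefrontal cortex is analysed; that subset
ships as the ``in_use`` mask of the packaged default montage and is plain
configuration that users can replace.

Two channels are *neighbours* when they share a source or a detector optode.
Neighbourhood drives the reconstruction of discarded channels during the
functional-connectivity analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Montage",
    "TaskParadigm",
    "ResponseLabel",
    "MontageFormatError",
    "load_montage",
    "neighbors",
    "annotate_response",
    "RESPONSE_CLASSES",
]

RESPONSE_CLASSES = ("NR", "PR", "R")


class MontageFormatError(ValueError):
    """Raised when a montage file violates the montage invariants."""


@dataclass(frozen=True)
class Montage:
    """Optode/channel geometry of the probe.

    Parameters
    ----------
    channel_ids : ordered channel labels (``C1`` .. ``C52`` for the default).
    optode_pairs : mapping channel -> (source_id, detector_id).
    in_use_mask : channels retained for analysis (32 for the default probe).
    source_detector_distance_cm : optode separation ``d`` used by the
        modified Beer-Lambert conversion.
    """

    channel_ids: tuple[str, ...]
    optode_pairs: Mapping[str, tuple[str, str]]
    in_use_mask: tuple[str, ...]
    source_detector_distance_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.source_detector_distance_cm <= 0:
            raise MontageFormatError("source-detector distance must be > 0")
        seen_pairs: dict[tuple[str, str], str] = {}
        for ch in self.channel_ids:
            if ch not in self.optode_pairs:
                raise MontageFormatError(f"channel {ch!r} has no optode pair")
            pair = tuple(self.optode_pairs[ch])
            if len(pair) != 2:
                raise MontageFormatError(f"channel {ch!r}: optode pair must be (source, detector)")
            if pair in seen_pairs:
                raise MontageFormatError(
                    f"duplicated optode pair {pair} for channels {seen_pairs[pair]!r} and {ch!r}"
                )
            seen_pairs[pair] = ch
        known = set(self.channel_ids)
        for ch in self.in_use_mask:
            if ch not in known:
                raise MontageFormatError(f"in-use channel {ch!r} not among channel ids")
        if len(set(self.in_use_mask)) != len(self.in_use_mask):
            raise MontageFormatError("duplicate entries in in-use mask")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_ids.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel id {channel!r}") from None


@dataclass(frozen=True)
class TaskParadigm:
    """Verbal-fluency block paradigm timing (seconds).

    The default session lasts 170 s: 10 s pre-scan, 30 s pre-task, 60 s task
    and 70 s post-task.  ``b1`` is a 10 s baseline window immediately before
    task onset; ``b2`` is a 55 s baseline window placed at the end of the
    post-task block (the first 15 s of post-task are skipped so the
    hemodynamic recovery does not contaminate the baseline).
    """

    sampling_rate: float = 10.0
    pre_scan_s: float = 10.0
    pre_task_s: float = 30.0
    task_s: float = 60.0
    post_task_s: float = 70.0
    b1_window_s: float = 10.0
    b2_window_s: float = 55.0

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "pre_scan_s", "pre_task_s", "task_s", "post_task_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.b1_window_s <= 0 or self.b1_window_s > self.pre_task_s:
            raise ValueError("b1 window must be positive and lie inside the pre-task period")
        if self.b2_window_s <= 0 or self.b2_window_s > self.post_task_s:
            raise ValueError("b2 window must be positive and lie inside the post-task period")

    @property
    def duration_s(self) -> float:
        return self.pre_scan_s + self.pre_task_s + self.task_s + self.post_task_s

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))

    @property
    def task_onset_s(self) -> float:
        return self.pre_scan_s + self.pre_task_s

    @property
    def task_offset_s(self) -> float:
        return self.task_onset_s + self.task_s

    @property
    def b1_bounds_s(self) -> tuple[float, float]:
        """The b1 baseline window, ending at task onset."""
        return (self.task_onset_s - self.b1_window_s, self.task_onset_s)

    @property
    def b2_bounds_s(self) -> tuple[float, float]:
        """The b2 baseline window, ending at the end of the session."""
        end = self.duration_s
        return (end - self.b2_window_s, end)

    def slice_s(self, start_s: float, stop_s: float) -> slice:
        """Sample slice covering [start_s, stop_s)."""
        i0 = int(round(start_s * self.sampling_rate))
        i1 = int(round(stop_s * self.sampling_rate))
        return slice(i0, i1)

    @property
    def task_slice(self) -> slice:
        return self.slice_s(self.task_onset_s, self.task_offset_s)


@dataclass(frozen=True)
class ResponseLabel:
    """Treatment-response annotation for one subject."""

    subject_id: str
    label: str
    hamd_baseline: int | None = None
    hamd_post: int | None = None

    def __post_init__(self) -> None:
        if self.label not in RESPONSE_CLASSES:
            raise ValueError(f"label must be one of {RESPONSE_CLASSES}, got {self.label!r}")


def load_montage(path: str | Path | None = None) -> Montage:
    """Load a montage from a YAML file, or the packaged default.

    The packaged default is the 3x11 prefrontal grid with 52 channels and a
    32-channel in-use mask.
    """
    if path is None:
        with resources.files("nirstreat.data").joinpath("montage_etg4000.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    try:
        channels = raw["channels"]
        in_use = raw["in_use"]
    except (TypeError, KeyError) as exc:
        raise MontageFormatError(f"montage file missing required key: {exc}") from exc
    pairs = {}
    for ch, spec in channels.items():
        try:
            pairs[ch] = (str(spec["source"]), str(spec["detector"]))
        except (TypeError, KeyError):
            raise MontageFormatError(f"channel {ch!r}: expected {{source, detector}} mapping") from None
    return Montage(
        channel_ids=tuple(channels.keys()),
        optode_pairs=pairs,
        in_use_mask=tuple(in_use),
        source_detector_distance_cm=float(raw.get("source_detector_distance_cm", 3.0)),
    )


def neighbors(montage: Montage, channel: str, exclude: Iterable[str] = ()) -> set[str]:
    """In-use channels sharing a source or detector optode with ``channel``.

    ``exclude`` removes channels from the result; reconstructed channels are
    passed here so they are never used as donors for another reconstruction.
    """
    if channel not in montage.optode_pairs:
        raise KeyError(f"unknown channel id {channel!r}")
    excl = set(exclude)
    own = set(montage.optode_pairs[channel])
    out = set()
    for other in montage.in_use_mask:
        if other == channel or other in excl:
            continue
        if own & set(montage.optode_pairs[other]):
            out.add(other)
    return out


def annotate_response(
    hamd_baseline: float, hamd_post: float, subject_id: str = ""
) -> ResponseLabel:
    """Annotate treatment response from a pre/post HAM-D score pair.

    The percentage reduction ``r = 100 * (baseline - post) / baseline`` maps
    to NR when r < 25, PR when 25 <= r <= 50 (closed interval: both boundary
    percentages are partial response), and R when r > 50.  A post score above
    baseline (worsening) yields NR with a warning.
    """
    if hamd_baseline < 0 or hamd_post < 0:
        raise ValueError("HAM-D scores must be nonnegative")
    if hamd_baseline == 0:
        raise ZeroDivisionError("HAM-D baseline of 0 leaves the reduction undefined")
    r = 100.0 * (hamd_baseline - hamd_post) / hamd_baseline
    if r < 0:
        warnings.warn(
            f"subject {subject_id or '<unknown>'}: post-treatment HAM-D above baseline "
            f"(reduction {r:.1f}%); annotated NR",
            stacklevel=2,
        )
        label = "NR"
    elif r < 25.0:
        label = "NR"
    elif r <= 50.0:
        label = "PR"
    else:
        label = "R"
    return ResponseLabel(
        subject_id=subject_id,
        label=label,
        hamd_baseline=int(hamd_baseline) if float(hamd_baseline).is_integer() else None,
        hamd_post=int(hamd_post) if float(hamd_post).is_integer() else None,
    )
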