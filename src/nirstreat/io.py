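"""Readers/writers for raw recordings, miRNA tables, response labels.

Raw intensity goes through either a minimal SNIRF 1.0 container (HDF5, via
h5py) or a hand-inspectable plain-CSV dialect: one row per channel and
wavelength, a header row, leading ``channel`` and ``wavelength_nm`` columns,
then one column per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import Montage, ResponseLabel, TaskParadigm, annotate_response, load_montage

__all__ = [
    "RawIntensityRecording",
    "RecordingValidationError",
    "MIRNA_FEATURES",
    "read_recording_csv",
    "write_recording_csv",
    "read_snirf",
    "write_snirf",
    "load_mirna",
    "write_mirna",
    "load_labels",
    "write_labels",
    "join_cohort",
]

MIRNA_FEATURES = ("hsa-miR-550b-2-5p", "hsa-miR-125a-5p", "hsa-miR-374b-3p")

DEFAULT_WAVELENGTHS = (695.0, 830.0)


class RecordingValidationError(ValueError):
    """Raised when a recording violates its invariants."""


@dataclass
class RawIntensityRecording:
    """Dual-wavelength raw light-intensity recording for one subject.

    ``intensity`` has shape (n_channels, n_wavelengths, n_samples), strictly
    positive, in arbitrary units.  Sample count must match the paradigm.
    """

    subject_id: str
    age: float
    intensity: np.ndarray
    channel_ids: tuple[str, ...]
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS
    paradigm: TaskParadigm = field(default_factory=TaskParadigm)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise RecordingValidationError("intensity must be (channels, wavelengths, time)")
        nc, nw, nt = self.intensity.shape
        if nc != len(self.channel_ids):
            raise RecordingValidationError(
                f"{nc} intensity rows for {len(self.channel_ids)} channel ids"
            )
        if nw != len(self.wavelengths):
            raise RecordingValidationError(
                f"{nw} wavelength planes for {len(self.wavelengths)} wavelengths"
            )
        if nt != self.paradigm.n_samples:
            raise RecordingValidationError(
                f"recording length {nt} does not match paradigm "
                f"({self.paradigm.n_samples} samples)"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise RecordingValidationError("intensity contains non-finite samples")
        if np.any(self.intensity <= 0):
            ch, wl, t = np.unravel_index(int(np.argmin(self.intensity)), self.intensity.shape)
            raise RecordingValidationError(
                f"nonpositive intensity at channel {self.channel_ids[ch]!r}, "
                f"wavelength {self.wavelengths[wl]:g} nm, sample {t}"
            )
        if self.age < 0:
            raise RecordingValidationError("age must be nonnegative")

    @property
    def sampling_rate(self) -> float:
        return self.paradigm.sampling_rate


# ---------------------------------------------------------------------------
# plain-CSV dialect

def write_recording_csv(rec: RawIntensityRecording, path: str | Path) -> None:
    nc, nw, nt = rec.intensity.shape
    rows = []
    for i, ch in enumerate(rec.channel_ids):
        for j, wl in enumerate(rec.wavelengths):
            rows.append([ch, wl, *rec.intensity[i, j]])
    cols = ["channel", "wavelength_nm", *[f"t{k}" for k in range(nt)]]
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(f"# subject_id={rec.subject_id} age={rec.age!r} "
                 f"sampling_rate={rec.paradigm.sampling_rate!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_recording_csv(path: str | Path, paradigm: TaskParadigm | None = None) -> RawIntensityRecording:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh)
    paradigm = paradigm or TaskParadigm(sampling_rate=float(meta.get("sampling_rate", 10.0)))
    channels = list(dict.fromkeys(df["channel"]))
    wavelengths = sorted(set(df["wavelength_nm"]))
    nt = df.shape[1] - 2
    data = np.empty((len(channels), len(wavelengths), nt))
    for i, ch in enumerate(channels):
        for j, wl in enumerate(wavelengths):
            row = df[(df["channel"] == ch) & (df["wavelength_nm"] == wl)]
            if len(row) != 1:
                raise RecordingValidationError(
                    f"expected exactly one row for channel {ch!r} at {wl:g} nm"
                )
            data[i, j] = row.iloc[0, 2:].to_numpy(dtype=float)
    return RawIntensityRecording(
        subject_id=str(meta.get("subject_id", Path(path).stem)),
        age=float(meta.get("age", 0.0)),
        intensity=data,
        channel_ids=tuple(channels),
        wavelengths=tuple(float(w) for w in wavelengths),
        paradigm=paradigm,
    )


# ---------------------------------------------------------------------------
# minimal SNIRF 1.0 container

def write_snirf(rec: RawIntensityRecording, path: str | Path, montage: Montage | None = None) -> None:
    """Write a raw (continuous-wave intensity, dataType 1) SNIRF file."""
    montage = montage or load_montage()
    sources = sorted({montage.optode_pairs[c][0] for c in montage.channel_ids})
    detectors = sorted({montage.optode_pairs[c][1] for c in montage.channel_ids})
    s_index = {s: i + 1 for i, s in enumerate(sources)}
    d_index = {d: i + 1 for i, d in enumerate(detectors)}
    nc, nw, nt = rec.intensity.shape
    t = np.arange(nt) / rec.paradigm.sampling_rate
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("age", data=float(rec.age))
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, dtype=float))
        probe.create_dataset("sourceLabels", data=np.array(sources, dtype=object),
                             dtype=h5py.string_dtype())
        probe.create_dataset("detectorLabels", data=np.array(detectors, dtype=object),
                             dtype=h5py.string_dtype())
        data = nirs.create_group("data1")
        series = rec.intensity.reshape(nc * nw, nt).T  # time x measurement
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=t)
        k = 0
        for i, ch in enumerate(rec.channel_ids):
            src, det = montage.optode_pairs[ch]
            for j in range(nw):
                ml = data.create_group(f"measurementList{k + 1}")
                ml.create_dataset("sourceIndex", data=s_index[src])
                ml.create_dataset("detectorIndex", data=d_index[det])
                ml.create_dataset("wavelengthIndex", data=j + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
                k += 1


def read_snirf(path: str | Path, montage: Montage | None = None,
               paradigm: TaskParadigm | None = None) -> RawIntensityRecording:
    montage = montage or load_montage()
    pair_to_channel = {
        tuple(montage.optode_pairs[c]): c for c in montage.channel_ids
    }
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        meta = nirs["metaDataTags"]
        subject = _h5str(meta["SubjectID"][()])
        age = float(meta["age"][()]) if "age" in meta else 0.0
        probe = nirs["probe"]
        wavelengths = tuple(float(w) for w in probe["wavelengths"][()])
        sources = [_h5str(s) for s in probe["sourceLabels"][()]]
        detectors = [_h5str(d) for d in probe["detectorLabels"][()]]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"][()], dtype=float)
        t = np.asarray(data["time"][()], dtype=float)
        n_meas = series.shape[1]
        ml_keys = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if len(ml_keys) != n_meas:
            raise RecordingValidationError("measurementList count does not match data columns")
        per_channel: dict[str, dict[int, np.ndarray]] = {}
        order: list[str] = []
        for col, key in enumerate(ml_keys):
            ml = data[key]
            src = sources[int(ml["sourceIndex"][()]) - 1]
            det = detectors[int(ml["detectorIndex"][()]) - 1]
            wli = int(ml["wavelengthIndex"][()]) - 1
            ch = pair_to_channel.get((src, det))
            if ch is None:
                raise RecordingValidationError(
                    f"source/detector pair ({src}, {det}) not in montage"
                )
            if ch not in per_channel:
                per_channel[ch] = {}
                order.append(ch)
            per_channel[ch][wli] = series[:, col]
    if len(t) > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        fs = 10.0
    paradigm = paradigm or TaskParadigm(sampling_rate=float(np.round(fs, 6)))
    nt = len(t)
    intensity = np.empty((len(order), len(wavelengths), nt))
    for i, ch in enumerate(order):
        planes = per_channel[ch]
        if set(planes) != set(range(len(wavelengths))):
            raise RecordingValidationError(f"channel {ch!r} missing a wavelength plane")
        for j in range(len(wavelengths)):
            intensity[i, j] = planes[j]
    return RawIntensityRecording(
        subject_id=subject,
        age=age,
        intensity=intensity,
        channel_ids=tuple(order),
        wavelengths=wavelengths,
        paradigm=paradigm,
    )


def _h5str(value) -> str:
    if isinstance(value, bytes):
        return value.decode()
    return str(value)


# ---------------------------------------------------------------------------
# miRNA and response-label tables

def load_mirna(path: str | Path) -> pd.DataFrame:
    """miRNA expression table: index subject_id, the three named features."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("miRNA table needs a subject_id column")
    missing = [c for c in MIRNA_FEATURES if c not in df.columns]
    if missing:
        raise ValueError(f"miRNA table missing feature columns: {missing}")
    df = df.set_index("subject_id")[list(MIRNA_FEATURES)].astype(float)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing miRNA values for subjects {bad}")
    return df


def write_mirna(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("subject_id").to_csv(path, float_format="%.17g")


def load_labels(path: str | Path) -> list[ResponseLabel]:
    """Load response labels; HAM-D pairs are re-annotated when present."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        has_scores = {"hamd_baseline", "hamd_post"} <= set(df.columns) and not (
            pd.isna(row.get("hamd_baseline")) or pd.isna(row.get("hamd_post"))
        )
        if has_scores:
            lab = annotate_response(float(row["hamd_baseline"]), float(row["hamd_post"]), sid)
            if "label" in df.columns and not pd.isna(row["label"]) and row["label"] != lab.label:
                raise ValueError(
                    f"subject {sid}: stated label {row['label']!r} inconsistent with "
                    f"HAM-D pair ({lab.label} expected)"
                )
            out.append(lab)
        else:
            out.append(ResponseLabel(subject_id=sid, label=str(row["label"])))
    return out


def write_labels(labels: list[ResponseLabel], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [l.subject_id for l in labels],
            "label": [l.label for l in labels],
            "hamd_baseline": [l.hamd_baseline for l in labels],
            "hamd_post": [l.hamd_post for l in labels],
        }
    ).to_csv(path, index=False)


def join_cohort(
    recordings: dict[str, RawIntensityRecording],
    mirna: pd.DataFrame,
    labels: list[ResponseLabel],
) -> tuple[list[str], list[str]]:
    """Intersect the three modalities on subject id.

    Returns (kept_subject_ids, dropped_subject_ids); subjects missing any
    modality are dropped with a warning, mirroring the exclusion of subjects
    with missing measurements from the clinical cohort.
    """
    by_label = {l.subject_id for l in labels}
    all_ids = sorted(set(recordings) | set(mirna.index.astype(str)) | by_label)
    kept, dropped = [], []
    for sid in all_ids:
        if sid in recordings and sid in set(mirna.index.astype(str)) and sid in by_label:
            kept.append(sid)
        else:
            dropped.append(sid)
    if dropped:
        warnings.warn(
            f"{len(dropped)} subject(s) missing a modality were excluded: {dropped}",
            stacklevel=2,
        )
    return kept, dropped
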