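"""End-to-end orchestration: recordings -> features -> projection -> SVM.

``extract_features`` turns raw recordings into the 20-column fNIRS feature
matrix (13 time-domain activation features + 7 connectivity network
metrics).  ``run_pipeline`` applies the optional reference-group PCA
projection, fuses the selected modalities with the miRNA table, trains the
seeded RBF SVM and returns a fully reproducible report (config, seed, fold
map, confusion matrix, metrics, manifest hash).  ``run_grid`` and
``run_ablation`` reproduce the modality-by-projection experiment grids.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import classify as _classify
from .classify import (FusedFeatureTable, downsample_balanced, evaluate,
                       fuse_features, merge_binary, train_svm)
from .features_fc import (DisconnectedGraphError, NETWORK_METRIC_NAMES,
                          connectivity_matrix, extract_task_segment,
                          graph_metrics, omst_binarize, reconstruct_channels)
from .features_time import TIME_FEATURE_NAMES, TimeFeatureError, extract_time_features
from .io import MIRNA_FEATURES, RawIntensityRecording
from .montage import Montage, load_montage
from .preprocess import preprocess_recording
from .reduce import fit_projection, project

__all__ = ["RunConfig", "extract_features", "run_pipeline", "run_cohort",
           "run_grid", "run_ablation", "MODALITY_GRID"]

MODALITY_GRID = (
    ("time",),
    ("fc",),
    ("mirna",),
    ("time", "fc"),
    ("time", "mirna"),
    ("fc", "mirna"),
    ("time", "fc", "mirna"),
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one classification run."""

    modalities: tuple[str, ...] = ("time", "fc", "mirna")
    pca: bool = True
    theta: float = 0.99
    pca_mode: str = "exclude-leading"
    leakage: str = "paper"  # "paper": fit projection on all NR; "fold_safe": refit per fold
    binary: bool = False
    downsample: bool = False
    folds: int = 5
    iters: int = 1000
    seed: int = 0
    qc_literal: bool = False

    def __post_init__(self) -> None:
        bad = set(self.modalities) - {"time", "fc", "mirna"}
        if bad:
            raise ValueError(f"unknown modalities: {sorted(bad)}")
        if not self.modalities:
            raise ValueError("at least one modality is required")
        if self.leakage not in ("paper", "fold_safe"):
            raise ValueError("leakage must be 'paper' or 'fold_safe'")


def extract_features(
    recordings: dict[str, RawIntensityRecording],
    montage: Montage | None = None,
    qc_literal: bool = False,
    metric_seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-subject fNIRS feature extraction.

    Returns (features, exclusions): a subjects x 20 table (13 time + 7
    network metrics) and a map of excluded subject -> reason (no usable
    channels, disconnected connectivity graph).
    """
    montage = montage or load_montage()
    rows: dict[str, dict[str, float]] = {}
    exclusions: dict[str, str] = {}
    in_use = [c for c in montage.channel_ids if c in set(montage.in_use_mask)]
    for sid in sorted(recordings):
        rec = recordings[sid]
        try:
            hb, qc = preprocess_recording(rec, montage, qc_literal=qc_literal)
            tf = extract_time_features(hb, rec.paradigm, montage, qc)
            task = extract_task_segment(hb, rec.paradigm)
            idx = [rec.channel_ids.index(c) for c in in_use]
            task_in_use = task[idx]
            task_rec = reconstruct_channels(task_in_use, tuple(in_use), qc, montage)
            cm = connectivity_matrix(task_rec, tuple(in_use))
            graph = omst_binarize(cm)
            nm = graph_metrics(graph, seed=metric_seed)
        except (TimeFeatureError, DisconnectedGraphError, RuntimeError, ValueError) as exc:
            exclusions[sid] = f"{type(exc).__name__}: {exc}"
            continue
        rows[sid] = {**{f"time_{k}": v for k, v in tf.items()},
                     **{f"fc_{k}": v for k, v in nm.items()}}
    features = pd.DataFrame.from_dict(rows, orient="index")
    expected = [f"time_{k}" for k in TIME_FEATURE_NAMES] + [
        f"fc_{k}" for k in NETWORK_METRIC_NAMES
    ]
    if not features.empty:
        features = features[expected]
    return features, exclusions


def _modal_columns(features: pd.DataFrame, modalities: tuple[str, ...]) -> list[str]:
    cols = []
    if "time" in modalities:
        cols += [c for c in features.columns if c.startswith("time_")]
    if "fc" in modalities:
        cols += [c for c in features.columns if c.startswith("fc_")]
    return cols


def run_pipeline(
    features: pd.DataFrame,
    mirna: pd.DataFrame | None,
    labels: pd.Series,
    cfg: RunConfig,
) -> dict:
    """One classification run on extracted features.

    The projection (when enabled) is fitted on the NR reference rows of the
    selected fNIRS features and applied to every group; miRNA columns pass
    through unscaled.
    """
    labels = labels.astype(str)
    ids = [i for i in labels.index if i in features.index]
    if "mirna" in cfg.modalities:
        if mirna is None:
            raise ValueError("mirna modality requested but no miRNA table given")
        ids = [i for i in ids if i in mirna.index]
    labels = labels.loc[ids]
    work_labels = merge_binary(labels) if cfg.binary else labels

    fn_cols = _modal_columns(features, cfg.modalities)
    mirna_part = mirna.loc[ids, list(MIRNA_FEATURES)] if "mirna" in cfg.modalities else None
    fnirs_part = features.loc[ids, fn_cols] if fn_cols else None

    basis_info = None
    fold_transform = None
    if cfg.pca and fnirs_part is not None:
        ref_rows = labels == "NR"
        if cfg.leakage == "paper":
            warnings.warn(
                "projection fitted on all NR subjects before cross-validation "
                "(replication mode); use leakage='fold_safe' for a leakage-free fit",
                stacklevel=2,
            )
            basis = fit_projection(fnirs_part.loc[ref_rows], cfg.theta, cfg.pca_mode)
            fnirs_part = project(fnirs_part, basis)
            basis_info = {
                "n_discarded": basis.n_discarded,
                "n_retained": basis.n_retained,
                "discarded_ev_percent": float(
                    basis.explained_variance_ratio[: basis.n_discarded].sum() * 100.0
                ),
            }
        else:
            n_fn = len(fn_cols)

            def fold_transform(train_df, test_df, train_labels, _n=n_fn,
                               _theta=cfg.theta, _mode=cfg.pca_mode):
                fn_tr = train_df.iloc[:, :_n]
                ref = fn_tr.loc[train_labels == "NR"]
                b = fit_projection(ref, _theta, _mode)
                p_tr = project(fn_tr, b).to_numpy()
                p_te = project(test_df.iloc[:, :_n], b).to_numpy()
                rest_tr = train_df.iloc[:, _n:].to_numpy(dtype=float)
                rest_te = test_df.iloc[:, _n:].to_numpy(dtype=float)
                return np.hstack([p_tr, rest_tr]), np.hstack([p_te, rest_te])

    table = fuse_features(fnirs_part, mirna_part, work_labels)
    if cfg.downsample:
        table = downsample_balanced(table, seed=cfg.seed)

    result = train_svm(table, folds=cfg.folds, iters=cfg.iters, seed=cfg.seed,
                       fold_transform=fold_transform)
    report = evaluate(result.oof_predictions, table.labels,
                      classes=sorted(table.labels.unique()))

    payload = {
        "config": {**asdict(cfg), "modalities": list(cfg.modalities)},
        "seed": cfg.seed,
        "n_subjects": table.n_subjects,
        "n_features": table.values.shape[1] if fold_transform is None else None,
        "projection": basis_info,
        "hyperparameters": {"C": result.C, "gamma": result.gamma},
        "cv_error_ucb": result.cv_error_ucb,
        "folds": result.fold_assignments.to_dict(),
        "report": report.to_dict(),
    }
    payload["manifest_sha256"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    return payload


def run_cohort(cohort, cfg: RunConfig, montage: Montage | None = None) -> dict:
    """Convenience wrapper: extract features from a cohort, then run."""
    features, exclusions = extract_features(
        cohort.recordings, montage, qc_literal=cfg.qc_literal
    )
    out = run_pipeline(features, cohort.mirna_table, cohort.label_series, cfg)
    out["exclusions"] = exclusions
    return out


def run_grid(
    features: pd.DataFrame,
    mirna: pd.DataFrame,
    labels: pd.Series,
    base: RunConfig | None = None,
) -> dict[str, dict]:
    """The 7-modality x {projection on, off} grid (14 reports)."""
    base = base or RunConfig()
    out = {}
    for modalities in MODALITY_GRID:
        for pca in (True, False):
            cfg = replace(base, modalities=modalities, pca=pca)
            key = "+".join(modalities) + ("/pca" if pca else "/raw")
            out[key] = run_pipeline(features, mirna, labels, cfg)
    return out


def run_ablation(
    features: pd.DataFrame,
    mirna: pd.DataFrame,
    labels: pd.Series,
    base: RunConfig | None = None,
    thetas: tuple[float, ...] = (0.95, 0.99),
) -> dict[str, dict]:
    """Explained-variance ablation: theta x {exclude, include} (4 reports)."""
    base = base or RunConfig()
    out = {}
    for theta in thetas:
        for mode in ("exclude-leading", "include-leading"):
            cfg = replace(base, pca=True, theta=theta, pca_mode=mode)
            key = f"theta={theta:g}/{mode.split('-')[0]}"
            out[key] = run_pipeline(features, mirna, labels, cfg)
    return out
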