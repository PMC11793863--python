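"""Feature fusion and 3-level response classification with an RBF SVM.

Hyperparameters (box constraint C and kernel scale gamma) are chosen by a
seeded random search over a log-uniform grid, scoring each candidate by
stratified 5-fold cross-validated error and selecting the lowest upper
confidence bound (mean fold error + 1 standard error) - the "best point"
rule.  Multi-class decomposition is one-vs-one.  Metrics follow the
multi-class confusion-matrix accounting: per-class TP/FN/FP/TN, overall
accuracy = sum(TP_i)/n, and macro-averaged sensitivity, precision and
specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import MIRNA_FEATURES

__all__ = [
    "FusedFeatureTable",
    "ClassificationReport",
    "SVMResult",
    "fuse_features",
    "train_svm",
    "evaluate",
    "merge_binary",
    "downsample_balanced",
    "feature_diagnostics",
]


@dataclass
class FusedFeatureTable:
    """Per-subject fused feature rows plus response labels."""

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels must be index-aligned with features")
        if self.values.isna().any().any():
            raise ValueError("fused table contains missing values")

    @property
    def n_subjects(self) -> int:
        return len(self.values)


@dataclass
class SVMResult:
    """Fitted model with out-of-fold predictions and search provenance."""

    model: SVC
    oof_predictions: pd.Series
    fold_assignments: pd.Series
    C: float
    gamma: float
    seed: int
    n_candidates: int
    cv_error_ucb: float


@dataclass
class ClassificationReport:
    """Confusion matrix with per-class counts and macro-averaged metrics."""

    classes: tuple[str, ...]
    confusion: np.ndarray  # rows: true, cols: predicted
    per_class: pd.DataFrame  # TP/FN/FP/TN, sensitivity, precision, specificity
    accuracy: float
    macro_sensitivity: float
    macro_precision: float
    macro_specificity: float

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class.to_dict(orient="index"),
            "accuracy": self.accuracy,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_precision": self.macro_precision,
            "macro_specificity": self.macro_specificity,
        }


def fuse_features(
    projected: pd.DataFrame | None,
    mirna: pd.DataFrame | None,
    labels: pd.Series,
    standardize_mirna: bool = False,
) -> FusedFeatureTable:
    """Inner-join selected modalities on subject id.

    ``projected`` carries the (optionally PCA-projected) fNIRS features and
    ``mirna`` the three expression values, passed through unscaled by
    default (``standardize_mirna=True`` z-scores them - RBF kernels are
    scale-sensitive, but the faithful default leaves them unmanipulated).
    Either modality may be None to reproduce unimodal/bimodal
    configurations.
    """
    if mirna is not None and standardize_mirna:
        sd = mirna.std(ddof=1).replace(0.0, 1.0)
        mirna = (mirna - mirna.mean()) / sd
    parts = [p for p in (projected, mirna) if p is not None]
    if not parts:
        raise ValueError("at least one modality is required")
    ids = set(labels.index)
    for p in parts:
        ids &= set(p.index)
    if not ids:
        raise ValueError("empty subject intersection across modalities")
    order = [i for i in labels.index if i in ids]
    dropped = sorted(set(labels.index) - ids)
    if dropped:
        warnings.warn(f"subjects missing a modality were excluded: {dropped}", stacklevel=2)
    fused = pd.concat([p.loc[order] for p in parts], axis=1)
    return FusedFeatureTable(values=fused, labels=labels.loc[order])


def merge_binary(labels: pd.Series) -> pd.Series:
    """Collapse partial responders into responders (PR -> R)."""
    return labels.replace({"PR": "R"})


def downsample_balanced(
    table: FusedFeatureTable, per_class: int | None = None, seed: int = 0
) -> FusedFeatureTable:
    """Seeded uniform down-sampling to ``per_class`` subjects per response class."""
    counts = table.labels.value_counts()
    if per_class is None:
        per_class = int(counts.min())
    if per_class > counts.min():
        raise ValueError(
            f"per_class={per_class} exceeds the smallest class ({counts.min()})"
        )
    rng = np.random.default_rng(seed)
    keep: list = []
    for cls in sorted(counts.index):
        members = list(table.labels.index[table.labels == cls])
        chosen = rng.choice(len(members), size=per_class, replace=False)
        keep.extend(members[i] for i in sorted(chosen))
    keep = [i for i in table.labels.index if i in set(keep)]
    return FusedFeatureTable(values=table.values.loc[keep], labels=table.labels.loc[keep])


def _sample_candidates(rng: np.random.Generator, iters: int,
                       lo: float = 1e-3, hi: float = 1e3) -> np.ndarray:
    log_lo, log_hi = np.log10(lo), np.log10(hi)
    return 10.0 ** rng.uniform(log_lo, log_hi, size=(iters, 2))


def train_svm(
    table: FusedFeatureTable,
    folds: int = 5,
    iters: int = 1000,
    seed: int = 0,
    fold_transform: Callable[[pd.DataFrame, pd.DataFrame, pd.Series], tuple[np.ndarray, np.ndarray]] | None = None,
) -> SVMResult:
    """Seeded hyperparameter search + stratified k-fold cross-validation.

    ``iters`` (C, gamma) candidates are drawn log-uniformly over
    [1e-3, 1e3]^2; each is scored by mean CV error plus one standard error
    across folds, and the minimizer (first on ties) is refitted on all data.
    ``fold_transform``, when given, maps (train_X, test_X, train_y) to
    transformed arrays inside every fold (used for the leakage-safe
    projection mode).  Identical seeds give identical folds, candidates and
    predictions.
    """
    y = table.labels.to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    class_counts = pd.Series(y).value_counts()
    if class_counts.min() < folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} subjects < {folds} folds; "
            "reduce the fold count or rebalance"
        )
    X = table.values
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    rng = np.random.default_rng(seed)
    candidates = _sample_candidates(rng, iters)

    fold_data = []
    for train_idx, test_idx in splits:
        if fold_transform is None:
            xtr = X.iloc[train_idx].to_numpy(dtype=float)
            xte = X.iloc[test_idx].to_numpy(dtype=float)
        else:
            xtr, xte = fold_transform(
                X.iloc[train_idx], X.iloc[test_idx], table.labels.iloc[train_idx]
            )
        fold_data.append((xtr, y[train_idx], xte, y[test_idx], test_idx))

    best = None
    for C, gamma in candidates:
        errors = []
        for xtr, ytr, xte, yte, _ in fold_data:
            clf = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
            clf.fit(xtr, ytr)
            errors.append(float(np.mean(clf.predict(xte) != yte)))
        errors = np.asarray(errors)
        se = errors.std(ddof=1) / np.sqrt(folds) if folds > 1 else 0.0
        ucb = errors.mean() + se
        if best is None or ucb < best[0] - 1e-15:
            best = (ucb, C, gamma)
    assert best is not None
    ucb, C, gamma = best

    oof = np.empty(len(y), dtype=object)
    fold_of = np.empty(len(y), dtype=int)
    for f, (xtr, ytr, xte, yte, test_idx) in enumerate(fold_data):
        clf = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
        clf.fit(xtr, ytr)
        oof[test_idx] = clf.predict(xte)
        fold_of[test_idx] = f

    if fold_transform is None:
        final_X = X.to_numpy(dtype=float)
    else:
        final_X, _ = fold_transform(X, X, table.labels)
        final_X = np.asarray(final_X)
    model = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
    model.fit(final_X, y)
    return SVMResult(
        model=model,
        oof_predictions=pd.Series(oof.astype(str), index=X.index, name="prediction"),
        fold_assignments=pd.Series(fold_of, index=X.index, name="fold"),
        C=float(C),
        gamma=float(gamma),
        seed=seed,
        n_candidates=iters,
        cv_error_ucb=float(ucb),
    )


def evaluate(
    predictions: Sequence[str] | pd.Series,
    labels: Sequence[str] | pd.Series,
    classes: Sequence[str] | None = None,
) -> ClassificationReport:
    """Multi-class confusion accounting and macro-averaged metrics.

    Per class i: sensitivity = TP/(TP+FN), precision = TP/(TP+FP),
    specificity = TN/(TN+FP); zero denominators yield 0 with a warning so
    macro averages stay defined.  Accuracy = trace/n.
    """
    y_pred = np.asarray(list(predictions), dtype=object)
    y_true = np.asarray(list(labels), dtype=object)
    if len(y_pred) != len(y_true):
        raise ValueError("predictions and labels must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    l = len(classes)
    cm = np.zeros((l, l), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    n = cm.sum()

    rows = {}
    for i, cls in enumerate(classes):
        tp = int(cm[i, i])
        fn = int(cm[i].sum() - tp)
        fp = int(cm[:, i].sum() - tp)
        tn = int(n - tp - fn - fp)
        sens = _safe_ratio(tp, tp + fn, f"sensitivity of class {cls!r}")
        prec = _safe_ratio(tp, tp + fp, f"precision of class {cls!r}")
        spec = _safe_ratio(tn, tn + fp, f"specificity of class {cls!r}")
        rows[cls] = dict(TP=tp, FN=fn, FP=fp, TN=tn,
                         sensitivity=sens, precision=prec, specificity=spec)
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    return ClassificationReport(
        classes=classes,
        confusion=cm,
        per_class=per_class,
        accuracy=float(np.trace(cm) / n),
        macro_sensitivity=float(per_class["sensitivity"].mean()),
        macro_precision=float(per_class["precision"].mean()),
        macro_specificity=float(per_class["specificity"].mean()),
    )


def _safe_ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} has a zero denominator; defined as 0", stacklevel=3)
        return 0.0
    return num / den


def feature_diagnostics(
    features: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    k_values: Sequence[int] = (2, 3, 4),
    collinearity_threshold: float = 0.7,
) -> dict:
    """Per-feature one-way ANOVA, k-means silhouette scan, collinearity count.

    Returns a dict with ``anova_p`` (constant features skipped with a note),
    ``silhouette`` per k (squared-Euclidean k-means), and the number of
    feature pairs with |Pearson r| above the threshold.
    """
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if labels.value_counts().min() < 3:
        raise ValueError("need at least three subjects per group")
    anova_p: dict[str, float] = {}
    notes: dict[str, str] = {}
    for col in features.columns:
        samples = [features.loc[labels == g, col].to_numpy() for g in groups]
        if features[col].nunique() <= 1:
            notes[col] = "constant feature; ANOVA skipped"
            continue
        anova_p[col] = float(stats.f_oneway(*samples).pvalue)

    x = features.to_numpy(dtype=float)
    xs = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1.0, x.std(axis=0))
    silhouette: dict[int, float] = {}
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels_k = km.fit_predict(xs)
        silhouette[k] = float(silhouette_score(xs, labels_k, metric="sqeuclidean"))

    corr = np.corrcoef(x, rowvar=False)
    iu = np.triu_indices(corr.shape[0], k=1)
    strong = int(np.sum(np.abs(corr[iu]) > collinearity_threshold))
    return {
        "anova_p": anova_p,
        "notes": notes,
        "silhouette": silhouette,
        "n_collinear_pairs": strong,
        "n_pairs": len(iu[0]),
    }
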