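"""Reference-group PCA inter-subject-variability reduction.

The feature matrix is z-scored with statistics of the non-responder (NR)
reference group, principal components are fitted on the reference rows
only, and the *leading* subspace holding at least ``theta`` (default 99%) of
the explained variance is discarded.  All response groups are then projected
onto the retained trailing components ``V``: ``P = z(X) @ V``.  The premise
is that dominant inter-subject nuisance variation (gain/offset differences)
loads on the leading components, while group-discriminative structure
survives in the near-constant trailing directions.

An ``include-leading`` mode (projecting onto the leading subspace instead)
is exposed for ablation experiments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix", "ProjectionBasis", "fit_projection", "project"]


@dataclass
class FeatureMatrix:
    """Subjects x features table with per-row group labels."""

    values: pd.DataFrame  # index: subject ids, columns: feature names
    labels: pd.Series  # index-aligned group labels

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels index must match the feature-matrix index")
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def restrict(self, group: str) -> "FeatureMatrix":
        keep = self.labels == group
        return FeatureMatrix(self.values.loc[keep], self.labels.loc[keep])


@dataclass
class ProjectionBasis:
    """Z-score statistics + retained principal components.

    ``components`` holds all PCs as columns ordered by descending explained
    variance; ``n_discarded`` leading ones are dropped in exclude-leading
    mode, and ``V`` is the retained (n_features x l) projection matrix.
    """

    feature_names: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (n_features, n_features), columns = PCs
    explained_variance_ratio: np.ndarray
    n_discarded: int
    theta: float
    mode: str  # "exclude-leading" | "include-leading"

    @property
    def matrix(self) -> np.ndarray:
        if self.mode == "exclude-leading":
            return self.components[:, self.n_discarded:]
        return self.components[:, : self.n_discarded]

    @property
    def n_retained(self) -> int:
        return self.matrix.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_discarded": self.n_discarded,
            "theta": self.theta,
            "mode": self.mode,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProjectionBasis":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=tuple(d["feature_names"]),
            mean=np.asarray(d["mean"]),
            scale=np.asarray(d["scale"]),
            components=np.asarray(d["components"]),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"]),
            n_discarded=int(d["n_discarded"]),
            theta=float(d["theta"]),
            mode=d["mode"],
        )


def fit_projection(
    X_ref: FeatureMatrix | pd.DataFrame,
    theta: float = 0.99,
    mode: str = "exclude-leading",
) -> ProjectionBasis:
    """Fit the reference-group projection basis.

    Features are z-scored with the reference rows' mean and standard
    deviation (ddof=1), PCs are extracted from the covariance of the
    z-scored matrix and ordered by descending explained variance, and
    ``k = min{j : sum_{i<=j} EV_i >= theta}`` leading components are marked
    for discarding.  PC signs follow the largest-magnitude-loading-positive
    convention so bases are reproducible across linear-algebra backends.
    """
    if mode not in ("exclude-leading", "include-leading"):
        raise ValueError("mode must be 'exclude-leading' or 'include-leading'")
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must lie in [0, 1]")
    df = X_ref.values if isinstance(X_ref, FeatureMatrix) else X_ref
    if df.shape[0] < 2:
        raise ValueError("need at least two reference rows to fit a projection")
    x = df.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance feature(s) in reference group: {[df.columns[i] for i in zero]}"
        )
    z = (x - mean) / scale
    # PCs of the (m-1)-divisor covariance of z via thin SVD
    u, s, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=True)
    ev = s**2
    n = x.shape[1]
    if len(ev) < n:
        ev = np.concatenate([ev, np.zeros(n - len(ev))])
    ratio = ev / ev.sum()
    comps = vt.T  # columns are PCs, descending variance
    # sign convention: largest-|loading| entry positive
    for j in range(comps.shape[1]):
        i = int(np.argmax(np.abs(comps[:, j])))
        if comps[i, j] < 0:
            comps[:, j] = -comps[:, j]
    cum = np.cumsum(ratio)
    if theta <= 0.0:
        k = 0
    else:
        k = int(np.searchsorted(cum, theta - 1e-12)) + 1
    if mode == "exclude-leading" and k >= n:
        raise ValueError(
            f"discard rule removes all {n} components (theta={theta}); lower theta"
        )
    return ProjectionBasis(
        feature_names=tuple(df.columns),
        mean=mean,
        scale=scale,
        components=comps,
        explained_variance_ratio=ratio,
        n_discarded=k,
        theta=theta,
        mode=mode,
    )


def project(X: FeatureMatrix | pd.DataFrame, basis: ProjectionBasis) -> pd.DataFrame:
    """Project rows onto the retained components: ``P = z(X) @ V``.

    Rows are z-scored with the basis's *reference* statistics; column names
    must match the basis exactly (order-checked).
    """
    df = X.values if isinstance(X, FeatureMatrix) else X
    if tuple(df.columns) != basis.feature_names:
        missing = set(basis.feature_names) - set(df.columns)
        extra = set(df.columns) - set(basis.feature_names)
        raise ValueError(
            f"feature columns do not match projection basis "
            f"(missing: {sorted(missing)}, unexpected: {sorted(extra)}, "
            f"order must also match)"
        )
    z = (df.to_numpy(dtype=float) - basis.mean) / basis.scale
    p = z @ basis.matrix
    if basis.mode == "exclude-leading":
        names = [f"PC{basis.n_discarded + j + 1}" for j in range(p.shape[1])]
    else:
        names = [f"PC{j + 1}" for j in range(p.shape[1])]
    return pd.DataFrame(p, index=df.index, columns=names)
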