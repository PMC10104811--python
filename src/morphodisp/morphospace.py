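"""PCA morphospace of normalised outline coefficients.

The coefficient matrix is analysed by covariance-matrix PCA (centred, not
scaled to unit variance: harmonic coefficients share units, so
standardising would inflate the high-order, low-amplitude harmonics).
Specimens become points in the space of principal component scores;
per-group, per-time-slice occupation is summarised as per-PC score ranges.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["MorphospaceModel", "fit_pca", "project", "pc_ranges"]

#: PCs with eigenvalue below this fraction of total variance are numerical
#: noise and are not retained.
EIGENVALUE_FLOOR = 1e-12

META_COLS = ["specimen_id", "group", "time_slice"]


@dataclass
class MorphospaceModel:
    """Fitted PCA morphospace.

    ``loadings`` is (n_retained, n_features) with orthonormal rows,
    ``eigenvalues`` holds every sample eigenvalue (descending, (n-1)
    denominator), ``scores`` the retained-PC scores with specimen metadata.
    """

    mean: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    scores: pd.DataFrame
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.loadings.shape[0]

    @property
    def pc_columns(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_retained)]

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    @property
    def explained_variance_fraction(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
            "feature_names": list(self.feature_names),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def fit_pca(features: pd.DataFrame) -> MorphospaceModel:
    """Fit the covariance-PCA morphospace to a coefficient matrix.

    ``features`` must carry the metadata columns ``specimen_id, group,
    time_slice`` ahead of the numeric coefficient columns.  Eigenvector
    sign is fixed by requiring the largest-magnitude loading of each
    component to be positive, removing platform-dependent sign flips; all
    PCs with eigenvalue above a 1e-12 fraction of total variance are
    retained.
    """
    meta = features[META_COLS].reset_index(drop=True)
    X = features.drop(columns=META_COLS)
    feature_names = list(X.columns)
    X = X.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA requires at least 3 specimens")
    if np.isnan(X).any():
        raise ValueError("missing values in feature matrix")
    total_var = float(X.var(axis=0, ddof=1).sum())
    if total_var <= 0:
        raise ValueError("constant feature matrix: zero total variance")

    pca = PCA(n_components=min(n - 1, p), svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    eigenvalues = pca.explained_variance_

    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(loadings[np.arange(len(loadings)), np.abs(loadings).argmax(axis=1)])
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]

    retain = eigenvalues > EIGENVALUE_FLOOR * total_var
    k = int(retain.sum())
    score_df = pd.concat(
        [meta, pd.DataFrame(scores[:, :k], columns=[f"PC{i+1}" for i in range(k)])],
        axis=1,
    )
    return MorphospaceModel(
        mean=pca.mean_,
        loadings=loadings[:k],
        eigenvalues=eigenvalues,
        scores=score_df,
        feature_names=feature_names,
    )


def project(model: MorphospaceModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Project (held-out) feature rows into the fitted morphospace.

    scores = (features - mean) @ loadings.T
    """
    if isinstance(features, pd.DataFrame):
        drop = [c for c in META_COLS if c in features.columns]
        features = features.drop(columns=drop).to_numpy(dtype=float)
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature count {features.shape[1]} != model {model.mean.shape[0]}"
        )
    return (features - model.mean) @ model.loadings.T


def pc_ranges(
    model: MorphospaceModel,
    pcs: list[int] | None = None,
    groups: list[str] | None = None,
    time_slices: list[str] | None = None,
) -> pd.DataFrame:
    """Per-PC score ranges occupied by each group x time-slice subset.

    Ranges are computed on the untreated (non-bootstrapped) scores.  Rows
    are emitted for every combination of the requested groups and time
    slices; an empty subset yields n = 0 with NaN min/max/range rather
    than being silently dropped.
    """
    sc = model.scores
    pc_cols = model.pc_columns
    if pcs is not None:
        pc_cols = [f"PC{i}" for i in pcs]
        missing = set(pc_cols) - set(model.pc_columns)
        if missing:
            raise ValueError(f"unknown PCs: {sorted(missing)}")
    groups = list(groups) if groups is not None else sorted(sc["group"].unique())
    slices = (
        list(time_slices)
        if time_slices is not None
        else sorted(sc["time_slice"].unique())
    )
    rows = []
    for g in groups:
        for s in slices:
            sub = sc[(sc["group"] == g) & (sc["time_slice"] == s)]
            for pc in pc_cols:
                if len(sub):
                    lo, hi = float(sub[pc].min()), float(sub[pc].max())
                    rows.append((g, s, pc, lo, hi, hi - lo, len(sub)))
                else:
                    rows.append((g, s, pc, np.nan, np.nan, np.nan, 0))
    return pd.DataFrame(
        rows, columns=["group", "time_slice", "pc", "min", "max", "range", "n"]
    )
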