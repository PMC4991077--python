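"""Autoscaling, the two-component PCA map, and loading interpretation.

The descriptor matrix mixes unit scales (molecular weight against bare
counts), so the map is a correlation-matrix PCA: columns are autoscaled
(mean 0, sd 1, sample sd), constant columns are dropped and reported, and
the principal components are eigenvectors of the resulting correlation
matrix.  With autoscaled data the eigenvalues sum to the number of retained
descriptors, so explained fractions are eigenvalue / #retained.

Sign conventions are deterministic: each loading column has its
largest-magnitude entry positive, and a component is additionally flipped
when its orientation key descriptor correlates negatively with it.  The
default keys are cation molecular weight (MW^C) for the first component and
anion molecular weight (MW^A) for the second, so PC1 grows with overall ion
size and PC2 with anion size — the orientation under which the downstream
trend rules are stated.

A variable is flagged significant for a component by Malinowski's rule:
|Pearson correlation between the variable and the component's scores| must
*exceed* the threshold (default 0.7, strict inequality).  For autoscaled
data that correlation equals loading x sqrt(eigenvalue), an identity used
as an internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: relative sd tolerance under which a descriptor column counts as constant
CONSTANT_SD_RTOL = 1e-12


@dataclass(frozen=True)
class ScalingStats:
    """Per-descriptor mean and sd, plus the constant columns that were dropped."""

    names: tuple[str, ...]          # retained descriptor names, in order
    mean: np.ndarray                # shape (len(names),)
    sd: np.ndarray                  # sample sd (ddof=1), all > tolerance
    dropped: tuple[str, ...]        # constant descriptors, excluded from the map


@dataclass(frozen=True)
class ChemSpaceModel:
    """Fitted PCA map: loadings, eigenvalues, training scores."""

    loadings: np.ndarray            # (n_retained, n_components), orthonormal cols
    eigenvalues: np.ndarray         # all eigenvalues, non-increasing
    explained_fraction: np.ndarray  # per retained component
    training_scores: np.ndarray     # (n_samples, n_components)
    n_components: int
    descriptor_names: tuple[str, ...]
    il_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class LoadingReport:
    """Variable-vs-component correlations with Malinowski significance flags."""

    correlations: pd.DataFrame      # retained descriptor x component, r in [-1, 1]
    significant: pd.DataFrame       # boolean, |r| > threshold (strict)
    threshold: float


def autoscale(X: pd.DataFrame) -> tuple[pd.DataFrame, ScalingStats]:
    """Standardize columns to mean 0, sd 1; drop and report constant columns.

    Raises on missing values (naming the first offending cell) and on fewer
    than two rows.
    """
    if len(X) < 2:
        raise ValueError(f"autoscaling needs at least 2 rows, got {len(X)}")
    if X.isna().any().any():
        col = X.columns[X.isna().any()][0]
        row = X.index[X[col].isna()][0]
        raise ValueError(f"missing value at row {row!r}, column {col!r}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    scale_floor = np.maximum(np.abs(mean), 1.0) * CONSTANT_SD_RTOL
    constant = sd <= scale_floor
    dropped = tuple(X.columns[constant])
    kept = X.columns[~constant]
    scaled = (X[kept] - mean[kept]) / sd[kept]
    stats = ScalingStats(names=tuple(kept),
                         mean=mean[kept].to_numpy(),
                         sd=sd[kept].to_numpy(),
                         dropped=dropped)
    return scaled, stats


def fit_pca(scaled: pd.DataFrame, n_components: int = 2,
            orientation_keys: tuple[str | None, ...] = ("MW^C", "MW^A"),
            ) -> ChemSpaceModel:
    """Eigendecompose the sample covariance of (auto)scaled data.

    Components are ordered by non-increasing eigenvalue; signs follow the
    module's deterministic convention.  ``orientation_keys[k]`` names the
    descriptor whose positive correlation fixes component k's direction
    (ignored when absent from the columns).
    """
    n, p = scaled.shape
    if n_components > p:
        raise ValueError(f"n_components={n_components} exceeds {p} retained descriptors")
    Xc = scaled.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.maximum(eigvals[order], 0.0)
    eigvecs = eigvecs[:, order]
    loadings = eigvecs[:, :n_components].copy()
    # sign convention: largest-|loading| entry of each component positive
    for k in range(n_components):
        pivot = np.argmax(np.abs(loadings[:, k]))
        if loadings[pivot, k] < 0:
            loadings[:, k] *= -1.0
    scores = Xc @ loadings
    # orientation override: key descriptor must correlate positively
    columns = list(scaled.columns)
    for k in range(n_components):
        key = orientation_keys[k] if k < len(orientation_keys) else None
        if key is None or key not in columns:
            continue
        x = Xc[:, columns.index(key)]
        if np.std(scores[:, k]) > 0 and np.corrcoef(x, scores[:, k])[0, 1] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    total = eigvals.sum()
    return ChemSpaceModel(
        loadings=loadings,
        eigenvalues=eigvals,
        explained_fraction=eigvals[:n_components] / total,
        training_scores=scores,
        n_components=n_components,
        descriptor_names=tuple(columns),
        il_ids=tuple(str(i) for i in scaled.index),
    )


def project(model: ChemSpaceModel, stats: ScalingStats,
            vector: dict[str, float] | pd.Series) -> np.ndarray:
    """Project one raw descriptor vector onto the fitted components.

    The vector must cover every retained descriptor by name; extra entries
    (including ones for dropped constant columns) are ignored.
    """
    if isinstance(vector, pd.Series):
        vector = vector.to_dict()
    missing = [n for n in stats.names if n not in vector]
    if missing:
        raise KeyError(f"descriptor vector is missing {len(missing)} name(s): "
                       f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    x = np.array([vector[n] for n in stats.names], dtype=float)
    z = (x - stats.mean) / stats.sd
    return z @ model.loadings


def project_table(model: ChemSpaceModel, stats: ScalingStats,
                  X: pd.DataFrame) -> pd.DataFrame:
    """Project many raw descriptor rows; returns PC columns indexed like X."""
    scores = np.vstack([project(model, stats, row) for _, row in X.iterrows()])
    cols = [f"PC{k + 1}" for k in range(model.n_components)]
    return pd.DataFrame(scores, index=X.index, columns=cols)


def interpret_loadings(model: ChemSpaceModel, scaled: pd.DataFrame,
                       threshold: float = 0.7) -> LoadingReport:
    """Pearson correlation of every retained descriptor with every score
    column, flagged by Malinowski's strict |r| > threshold rule."""
    if tuple(scaled.columns) != model.descriptor_names:
        raise ValueError("scaled matrix columns do not match the fitted model")
    scores = model.training_scores
    if np.any(np.std(scores, axis=0) == 0):
        raise ValueError("a score column is constant; correlations undefined")
    Xc = scaled.to_numpy(dtype=float)
    r = np.empty((Xc.shape[1], model.n_components))
    for k in range(model.n_components):
        for j in range(Xc.shape[1]):
            r[j, k] = np.corrcoef(Xc[:, j], scores[:, k])[0, 1]
    # internal identity for autoscaled fits: r = loading * sqrt(eigenvalue)
    sd = Xc.std(axis=0, ddof=1)
    if np.allclose(sd, 1.0, atol=1e-8):
        expected = model.loadings * np.sqrt(model.eigenvalues[: model.n_components])
        if not np.allclose(r, expected, atol=1e-8):
            raise AssertionError("loading/correlation identity violated on autoscaled fit")
    cols = [f"PC{k + 1}" for k in range(model.n_components)]
    corr = pd.DataFrame(r, index=list(scaled.columns), columns=cols)
    return LoadingReport(correlations=corr,
                         significant=corr.abs() > threshold,
                         threshold=threshold)
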