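"""Group-separability metrics for feature matrices.

Feature matrices are feature x sample DataFrames with an accompanying
per-sample group label (cancer type, ICB response group, ...).  The
metrics here quantify how well a feature type separates the groups:
hierarchical clustering of samples, PCA projection, the percentage of
feature variance explained by group membership (between-group rate), and
pairwise Mahalanobis distances between group centroids.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "preprocess_lcs",
    "hierarchical_cluster",
    "pca_project",
    "between_group_rate",
    "mahalanobis_group_distance",
]


def preprocess_lcs(m: pd.DataFrame) -> pd.DataFrame:
    """log2(x+1)-transform, then center and scale each feature row.

    Rows that are constant after the log transform carry no information
    and are dropped with a warning.  Surviving rows have mean 0 and unit
    standard deviation (ddof=0).
    """
    if (m.to_numpy() < 0).any():
        raise ValueError("preprocess_lcs expects non-negative values")
    logged = np.log2(m.to_numpy(dtype=float) + 1.0)
    sd = logged.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"preprocess_lcs: dropping {int((~keep).sum())} constant rows")
    logged = logged[keep]
    scaled = (logged - logged.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(scaled, index=m.index[keep], columns=m.columns)


def hierarchical_cluster(
    m: pd.DataFrame, k: int, method: str = "complete"
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering of samples on Euclidean distance, cut at *k*.

    Returns (per-sample cluster labels 1..k, the scipy linkage matrix).
    Deterministic given input order; linkage method defaults to complete
    (``average`` and ``ward`` also supported).
    """
    n = m.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    Z = linkage(m.to_numpy(dtype=float).T, method=method, metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=m.columns, name="cluster"), Z


def pca_project(
    m: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the top principal components of the feature space.

    Features (rows) are mean-centered; components come from the SVD of the
    centered sample matrix.  Returns (sample x component score DataFrame,
    explained-variance fractions, non-increasing and summing to <= 1).
    """
    X = m.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(X)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    U, S = U * signs, S
    scores = U[:, :n_components] * S[:n_components]
    explained = (S**2) / (S**2).sum()
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=m.columns, columns=cols),
        explained[:n_components],
    )


def between_group_rate(m: pd.DataFrame, labels: pd.Series) -> float:
    """Percentage of feature variance explained by group membership.

    Each feature row is first scaled to unit variance, then the one-way
    ANOVA decomposition is pooled across features:

        rate = 100 * sum_f SS_between(f) / sum_f SS_total(f)

    with SS_between = sum_g n_g (mean_g - grand_mean)^2.  Because of the
    unit-variance pre-step the rate is invariant to per-feature affine
    rescaling of the input.
    """
    labels = labels.loc[m.columns]
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("between_group_rate needs >=2 groups")
    X = m.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    X = X[keep] / sd[keep][:, None]
    grand = X.mean(axis=1, keepdims=True)
    ss_total = ((X - grand) ** 2).sum()
    ss_between = 0.0
    for g in groups:
        cols = (labels == g).to_numpy()
        if cols.sum() == 0:
            raise ValueError(f"group {g!r} has no samples")
        ss_between += cols.sum() * ((X[:, cols].mean(axis=1) - grand[:, 0]) ** 2).sum()
    return float(100.0 * ss_between / ss_total)


def mahalanobis_group_distance(
    scores: pd.DataFrame, labels: pd.Series
) -> pd.DataFrame:
    """Pairwise Mahalanobis distance between group centroids.

    For each pair of groups the covariance is the pooled within-group
    covariance of that pair, so the distance reflects the separation of
    the two clouds relative to their own spread (the quantity a pair of
    confidence ellipses illustrates).  Requires each group to have more
    samples than the score dimensionality.
    """
    labels = labels.loc[scores.index]
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("mahalanobis_group_distance needs >=2 groups")
    d = scores.shape[1]
    X = {g: scores.loc[(labels == g).to_numpy()].to_numpy(dtype=float) for g in groups}
    for g, xg in X.items():
        if xg.shape[0] <= d:
            raise ValueError(
                f"group {g!r} has {xg.shape[0]} samples for {d} dimensions"
            )
    out = pd.DataFrame(0.0, index=groups, columns=groups)
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            xi, xj = X[gi], X[gj]
            ni, nj = xi.shape[0], xj.shape[0]
            Si = np.cov(xi, rowvar=False, ddof=1)
            Sj = np.cov(xj, rowvar=False, ddof=1)
            pooled = ((ni - 1) * Si + (nj - 1) * Sj) / (ni + nj - 2)
            pooled = np.atleast_2d(pooled)
            delta = xi.mean(axis=0) - xj.mean(axis=0)
            try:
                dist2 = float(delta @ np.linalg.solve(pooled, delta))
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"singular pooled covariance for pair ({gi!r}, {gj!r})"
                ) from exc
            dist = float(np.sqrt(max(dist2, 0.0)))
            out.loc[gi, gj] = out.loc[gj, gi] = dist
    return out
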