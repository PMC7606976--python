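"""Reclassification of samples into ROS clusters and cancer types into groups.

Samples are clustered hierarchically in five-index space (Ward linkage on
Euclidean distance over z-scored indexes by default).  The number of
clusters can be fixed (the paper-faithful pipeline uses k = 8) or selected
by mean silhouette over a candidate range.  Cancer types are grouped by
clustering the arithmetic mean index vector of each type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .io import ValidationError
from .scoring import INDEX_COLUMNS, IndexTable

logger = logging.getLogger(__name__)

#: silhouette below which a selected k is reported low-confidence
LOW_CONFIDENCE_SILHOUETTE = 0.25


def _as_matrix(table) -> pd.DataFrame:
    """Accept an IndexTable or a plain samples x indexes DataFrame."""
    if isinstance(table, IndexTable):
        return table.values
    df = pd.DataFrame(table)
    cols = [c for c in INDEX_COLUMNS if c in df.columns]
    return df[cols] if cols else df


@dataclass
class ClusterAssignment:
    """Sample -> cluster labels (1..k) with linkage metadata."""

    labels: pd.Series
    k: int
    linkage: str
    metric: str
    selection_trace: pd.DataFrame | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        uniq = np.unique(self.labels.to_numpy())
        if not np.array_equal(uniq, np.arange(1, self.k + 1)):
            raise ValidationError(
                f"labels must be contiguous 1..{self.k}, got {uniq.tolist()}"
            )


@dataclass
class GroupAssignment:
    """Cancer type -> group labels (1..g) plus per-type mean index vectors."""

    groups: pd.Series
    type_means: pd.DataFrame
    g: int
    linkage: str
    metric: str
    selection_trace: pd.DataFrame | None = None


def _relabel_contiguous(raw_labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to 1..k in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw_labels)
    for i, lab in enumerate(raw_labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def _cut_tree(X: np.ndarray, k: int, method: str, metric: str) -> np.ndarray:
    if method == "ward" and metric != "euclidean":
        raise ValidationError("ward linkage requires the euclidean metric")
    Z = scipy_linkage(X, method=method, metric=metric)
    return _relabel_contiguous(fcluster(Z, t=k, criterion="maxclust"))


def hierarchical_cluster(
    table,
    k: int,
    linkage: str = "ward",
    metric: str = "euclidean",
) -> ClusterAssignment:
    """Agglomerative clustering of samples in index space, cut at k clusters."""
    X_df = _as_matrix(table)
    X = X_df.to_numpy(dtype=float)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(X_df):
        raise ValidationError(f"k = {k} exceeds n = {len(X_df)} samples")
    labels = _cut_tree(X, k, linkage, metric)
    return ClusterAssignment(
        labels=pd.Series(labels, index=X_df.index, name="cluster"),
        k=int(labels.max()),
        linkage=linkage,
        metric=metric,
    )


def select_k(
    table,
    k_range=range(2, 13),
    linkage: str = "ward",
    metric: str = "euclidean",
) -> ClusterAssignment:
    """Choose k maximizing mean silhouette (ties to the smallest k).

    The full distance matrix is computed once and reused across candidate
    cuts.  A winning silhouette below 0.25 is flagged low-confidence (the
    data may carry no real cluster structure).
    """
    X_df = _as_matrix(table)
    X = X_df.to_numpy(dtype=float)
    ks = [k for k in k_range if 2 <= k <= len(X_df) - 1]
    if not ks:
        raise ValidationError("k_range has no feasible candidate")
    if linkage == "ward" and metric != "euclidean":
        raise ValidationError("ward linkage requires the euclidean metric")
    dist = pdist(X, metric=metric)
    Z = scipy_linkage(X, method=linkage, metric=metric)
    D = squareform(dist)
    rows = []
    best_k, best_score, best_labels = None, -np.inf, None
    for k in ks:
        labels = _relabel_contiguous(fcluster(Z, t=k, criterion="maxclust"))
        if len(np.unique(labels)) < 2:
            score = np.nan
        else:
            score = float(silhouette_score(D, labels, metric="precomputed"))
        rows.append({"k": k, "silhouette": score})
        if np.isfinite(score) and score > best_score + 1e-12:
            best_k, best_score, best_labels = k, score, labels
    if best_k is None:
        raise ValidationError("no candidate k produced a valid partition")
    trace = pd.DataFrame(rows)
    low_conf = best_score < LOW_CONFIDENCE_SILHOUETTE
    if low_conf:
        warnings.warn(
            f"best silhouette {best_score:.3f} < {LOW_CONFIDENCE_SILHOUETTE}: "
            "weak cluster structure",
            stacklevel=2,
        )
    return ClusterAssignment(
        labels=pd.Series(best_labels, index=X_df.index, name="cluster"),
        k=int(np.max(best_labels)),
        linkage=linkage,
        metric=metric,
        selection_trace=trace,
        low_confidence=low_conf,
    )


def cluster_composition(
    assignment: ClusterAssignment, annotations: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cluster annotation composition and dominant-type homogeneity.

    Returns (composition, homogeneity): composition has one row per
    (cluster, annotation value) with count and fraction; homogeneity is the
    per-cluster maximum fraction.
    """
    ann = annotations.reindex(assignment.labels.index)
    if ann.isna().any():
        missing = ann.index[ann.isna()].tolist()
        raise ValidationError(f"annotations missing for samples {missing[:5]}")
    df = pd.DataFrame({"cluster": assignment.labels, "annotation": ann})
    counts = (
        df.groupby(["cluster", "annotation"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("cluster")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    homogeneity = counts.groupby("cluster")["fraction"].max().rename("homogeneity")
    return counts, homogeneity


def group_cancer_types(
    table,
    cancer_type: pd.Series,
    g: int | None = 5,
    linkage: str = "ward",
    metric: str = "euclidean",
    k_range=range(2, 13),
) -> GroupAssignment:
    """Cluster cancer types by the arithmetic mean of their index vectors.

    With ``g=None`` the group count is silhouette-selected over ``k_range``.
    """
    X_df = _as_matrix(table)
    ctype = cancer_type.reindex(X_df.index)
    if ctype.isna().any():
        raise ValidationError("cancer_type missing for some samples")
    means = X_df.groupby(ctype.to_numpy()).mean()
    means.index.name = "cancer_type"
    if len(means) < 2:
        raise ValidationError("need at least 2 cancer types to group")
    if np.allclose(means.to_numpy().var(axis=0), 0):
        warnings.warn("all cancer-type mean vectors identical: one effective group",
                      stacklevel=2)
        groups = pd.Series(1, index=means.index, name="group")
        return GroupAssignment(groups=groups, type_means=means, g=1,
                               linkage=linkage, metric=metric)
    if g is None:
        assignment = select_k(means, k_range=k_range, linkage=linkage, metric=metric)
        labels, trace = assignment.labels, assignment.selection_trace
    else:
        assignment = hierarchical_cluster(means, k=g, linkage=linkage, metric=metric)
        labels, trace = assignment.labels, None
    return GroupAssignment(
        groups=labels.rename("group"),
        type_means=means,
        g=assignment.k,
        linkage=linkage,
        metric=metric,
        selection_trace=trace,
    )


def index_density_summary(table, assignment: ClusterAssignment) -> pd.DataFrame:
    """Per-cluster, per-index location/scale/quantile summary."""
    X_df = _as_matrix(table)
    labels = assignment.labels.reindex(X_df.index)
    rows = []
    for cluster, sub in X_df.groupby(labels.to_numpy()):
        for col in sub.columns:
            v = sub[col].to_numpy(dtype=float)
            q25, q50, q75 = np.quantile(v, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "cluster": cluster,
                    "index": col,
                    "n": len(v),
                    "mean": v.mean(),
                    "sd": v.std(ddof=0),
                    "q25": q25,
                    "median": q50,
                    "q75": q75,
                }
            )
    return pd.DataFrame(rows)


def embed_2d(table, method: str = "tsne", seed: int = 0,
             perplexity: float | None = None) -> pd.DataFrame:
    """2-D embedding of samples in index space (visualization only).

    Deterministic under ``seed``; returns finite coordinates, one row per
    sample.
    """
    from sklearn.manifold import TSNE

    X_df = _as_matrix(table)
    n = len(X_df)
    if n < 3:
        raise ValidationError("embedding requires at least 3 samples")
    if method != "tsne":
        raise ValidationError(f"unknown embedding method {method!r}")
    if perplexity is None:
        perplexity = float(min(30.0, max(1.0, (n - 1) / 3.0)))
    coords = TSNE(
        n_components=2,
        random_state=seed,
        perplexity=perplexity,
        init="pca",
    ).fit_transform(X_df.to_numpy(dtype=float))
    out = pd.DataFrame(coords, index=X_df.index, columns=["dim1", "dim2"])
    if not np.isfinite(out.to_numpy()).all():
        raise ValidationError("embedding produced non-finite coordinates")
    return out
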