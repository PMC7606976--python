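"""Gene-set geometric-mean scoring, the five ROS indexes, and outlier trimming.

The score of a gene set in a sample is the geometric mean of the (linear,
pseudocounted) expression of its member genes,

    score_s = exp( mean_g log(x_gs + eps) ),

a scale-equivariant single-sample signature summary.  Category log-scores
average the log-score over every set of a redox category, and the five
indexes are linear combinations of those category scores:

    index IV (biosynthesis)      = B
    index III (scavenging)       = S
    index II (oxidative stress)  = R
    index V (subcellular source) = M - C        (mito minus cyto, a log-ratio)
    index I (accumulation)       = B - lambda*S (generation minus weighted
                                                 scavenging)

where B, S, R, M, C are the biosynthesis / scavenging / stress-response /
mitochondrial-source / cytoplasmic-source category log-scores.  A higher
index V means more ROS of mitochondrial origin.  Indexes are z-scored across
the analyzed cohort by default so they are comparable across cancer types
and clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    GeneSet,
    GeneSetCollection,
    REQUIRED_CATEGORIES,
    ValidationError,
    map_to_universe,
)

#: Canonical index column order.
INDEX_COLUMNS = ("index_I", "index_II", "index_III", "index_IV", "index_V")

#: What each index measures, for reports.
INDEX_MEANING = {
    "index_I": "ROS accumulation",
    "index_II": "oxidative stress",
    "index_III": "ROS scavenging ability",
    "index_IV": "ROS biosynthetic ability",
    "index_V": "subcellular ROS origin (mitochondria vs cytoplasm)",
}


@dataclass(frozen=True)
class IndexParams:
    """Parameters of index computation.

    pseudocount
        Added to linear expression before the log; RNA-seq zeros would
        otherwise annihilate a geometric mean.
    scavenging_coupling
        Weight ``lambda`` of the scavenging category inside index I
        (accumulation = biosynthesis - lambda * scavenging).
    standardize
        z-score each index over the scored samples.
    """

    pseudocount: float = 0.01
    scavenging_coupling: float = 0.5
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.scavenging_coupling < 0:
            raise ValidationError("scavenging_coupling must be >= 0")


@dataclass(frozen=True)
class OutlierParams:
    """Outlier-trimming policy applied per index, union across indexes."""

    mode: str = "quantile"  # "quantile" (tail fractions) or "fences" (IQR)
    tail_fraction: float = 0.05
    fence_multiplier: float = 1.5

    def __post_init__(self) -> None:
        if self.mode not in ("quantile", "fences"):
            raise ValidationError(f"unknown outlier mode {self.mode!r}")
        if not 0 <= self.tail_fraction < 0.5:
            raise ValidationError("tail_fraction must be in [0, 0.5)")
        if self.fence_multiplier <= 0:
            raise ValidationError("fence_multiplier must be > 0")


@dataclass
class IndexTable:
    """Per-sample values of the five ROS indexes.

    ``values`` holds the working (possibly z-scored) indexes, ``raw`` the
    pre-standardization log-space values; both are samples x 5 frames with
    identical row order.  ``outlier_flag`` marks samples flagged by
    :func:`filter_outliers` (always False on a freshly scored table).
    """

    values: pd.DataFrame
    raw: pd.DataFrame
    standardized: bool
    params: IndexParams = field(default_factory=IndexParams)
    outlier_flag: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.outlier_flag is None:
            self.outlier_flag = pd.Series(False, index=self.values.index)
        if list(self.values.columns) != list(INDEX_COLUMNS):
            raise ValidationError(f"index columns must be {INDEX_COLUMNS}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("non-finite index values")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out["outlier_flag"] = self.outlier_flag.astype(bool)
        return out


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    if (sd == 0).any():
        zero = sd.index[sd == 0].tolist()
        raise ValidationError(f"cannot standardize constant index(es): {zero}")
    return (df - mu) / sd


def geometric_mean_score(
    expr: pd.DataFrame,
    gene_set: GeneSet | Sequence[str],
    pseudocount: float = 0.01,
) -> pd.Series:
    """Geometric-mean score of one gene set across samples.

    ``expr`` is genes x samples, linear scale.  Gene symbols are matched
    case-insensitively.  Returns a strictly positive per-sample Series.
    """
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else tuple(gene_set)
    name = gene_set.name if isinstance(gene_set, GeneSet) else None
    lookup = {str(g).strip().upper(): g for g in expr.index}
    rows = [lookup[str(g).strip().upper()] for g in genes
            if str(g).strip().upper() in lookup]
    if not rows:
        raise ValidationError(f"gene set {name or genes}: no genes in expression matrix")
    sub = expr.loc[rows].to_numpy(dtype=float)
    if not np.isfinite(sub).all():
        raise ValidationError("expression contains non-finite values")
    if pseudocount < 0 or (pseudocount == 0 and (sub <= 0).any()):
        raise ValidationError("non-positive expression requires pseudocount > 0")
    score = np.exp(np.log(sub + pseudocount).mean(axis=0))
    return pd.Series(score, index=expr.columns, name=name)


def category_score(
    expr: pd.DataFrame,
    collection: GeneSetCollection,
    category: str,
    pseudocount: float = 0.01,
) -> pd.Series:
    """Category log-score: mean over the category's sets of log geometric-mean.

    Scaling all expression by a constant c shifts every category log-score
    by exactly log c.
    """
    sets = collection.by_category(category)
    if not sets:
        raise ValidationError(f"no gene set in category {category!r}")
    logs = [np.log(geometric_mean_score(expr, s, pseudocount)) for s in sets]
    out = pd.concat(logs, axis=1).mean(axis=1)
    out.name = category
    return out


def compute_indexes(
    expr: pd.DataFrame,
    collection: GeneSetCollection,
    params: IndexParams | None = None,
    min_coverage: float = 0.5,
) -> IndexTable:
    """Compute the five ROS indexes for every sample of ``expr``.

    The collection is first mapped onto the expression universe (sets with
    poor coverage dropped); every required category must survive.
    """
    params = params or IndexParams()
    mapped, _ = map_to_universe(collection, expr.index, min_coverage=min_coverage)
    mapped.require_index_categories()
    if params.standardize and expr.shape[1] < 2:
        raise ValidationError("standardization requires at least 2 samples")

    cat = {
        c: category_score(expr, mapped, c, params.pseudocount)
        for c in REQUIRED_CATEGORIES
    }
    B, S, R = cat["biosynthesis"], cat["scavenging"], cat["stress_response"]
    M, C = cat["mito_source"], cat["cyto_source"]
    raw = pd.DataFrame(
        {
            "index_I": B - params.scavenging_coupling * S,
            "index_II": R,
            "index_III": S,
            "index_IV": B,
            "index_V": M - C,
        }
    )
    values = _standardize(raw) if params.standardize else raw.copy()
    return IndexTable(values=values, raw=raw, standardized=params.standardize,
                      params=params)


def _outlier_mask(raw: pd.DataFrame, params: OutlierParams) -> pd.Series:
    """True for samples flagged extreme on ANY index."""
    flagged = np.zeros(len(raw), dtype=bool)
    for col in raw.columns:
        v = raw[col].to_numpy(dtype=float)
        if params.mode == "quantile":
            lo = np.quantile(v, params.tail_fraction)
            hi = np.quantile(v, 1 - params.tail_fraction)
        else:
            q1, q3 = np.quantile(v, [0.25, 0.75])
            iqr = q3 - q1
            lo = q1 - params.fence_multiplier * iqr
            hi = q3 + params.fence_multiplier * iqr
        flagged |= (v < lo) | (v > hi)
    return pd.Series(flagged, index=raw.index)


def filter_outliers(
    table: IndexTable,
    params: OutlierParams | None = None,
) -> tuple[IndexTable, list]:
    """Trim per-index extreme samples (union across the five indexes).

    Quantile mode removes samples strictly outside the
    [tail, 1 - tail] quantile band of each index; fences mode removes
    samples outside the Tukey fences Q1 - k*IQR, Q3 + k*IQR.  Retained
    indexes are re-standardized from the raw values when the table is
    standardized.  Returns (retained table, removed sample IDs).
    """
    params = params or OutlierParams()
    if len(table) < 10:
        raise ValidationError("outlier filtering requires >= 10 samples")
    mask = _outlier_mask(table.raw, params)
    removed = table.raw.index[mask].tolist()
    if mask.all():
        raise ValidationError("outlier filtering would remove every sample")
    raw = table.raw.loc[~mask]
    values = _standardize(raw) if table.standardized else raw.copy()
    retained = IndexTable(
        values=values,
        raw=raw,
        standardized=table.standardized,
        params=table.params,
        outlier_flag=pd.Series(False, index=raw.index),
    )
    return retained, removed


def index_correlations(table: IndexTable, method: str = "pearson") -> pd.DataFrame:
    """Index-index correlation matrix (Pearson default, Spearman by flag)."""
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    return table.values.corr(method=method)
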