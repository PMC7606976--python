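"""Per-cluster multi-omics characterization.

Each cluster is compared against all remaining samples ("cluster vs rest"):
chi-square (2x2, no continuity correction; Fisher's exact when any expected
cell is below 5) for binary mutations, a strict >10% frequency rule for
characteristic CNVs, and Welch's t-test for continuous miRNA/GO-style
features.  Benjamini-Hochberg FDR is applied jointly within each omics
layer.  Microenvironment scores (tumor purity, immune, stromal) are
external inputs correlated against the indexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .scoring import INDEX_COLUMNS
from .classify import _as_matrix

CNV_STATES = ("amp", "del", "neutral")


@dataclass(frozen=True)
class CharacterizeParams:
    """Thresholds of the cluster-vs-rest screens."""

    cnv_frequency_threshold: float = 0.10
    fdr_threshold: float = 0.05
    min_cluster_size: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.cnv_frequency_threshold < 1:
            raise ValidationError("cnv_frequency_threshold must be in (0,1)")
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError("fdr_threshold must be in (0,1)")


def _labels_of(assignment) -> pd.Series:
    return assignment.labels if hasattr(assignment, "labels") else pd.Series(assignment)


def _align(matrix: pd.DataFrame, labels: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    common = matrix.columns.intersection(labels.index)
    if len(common) == 0:
        raise ValidationError("no samples shared by feature matrix and clustering")
    return matrix[common], labels.loc[common]


def mutation_enrichment(
    mutations: pd.DataFrame,
    assignment,
    params: CharacterizeParams | None = None,
) -> pd.DataFrame:
    """Chi-square screen for cluster-characteristic mutations.

    ``mutations`` is features x samples with 0/1 entries.  For every
    (feature, cluster with >= min_cluster_size samples) a 2x2 cluster-vs-rest
    table is tested; q-values are BH across all tests.
    """
    params = params or CharacterizeParams()
    labels = _labels_of(assignment)
    mat, labels = _align(mutations, labels)
    values = mat.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValidationError("mutation matrix must be binary 0/1")

    rows = []
    lab = labels.to_numpy()
    for cluster in sorted(pd.unique(lab).tolist()):
        inside = lab == cluster
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        if n_in < params.min_cluster_size or n_out == 0:
            continue
        for feature in mat.index:
            v = mat.loc[feature].to_numpy()
            a = int(v[inside].sum())          # mutated inside
            b = n_in - a                      # wild-type inside
            c = int(v[~inside].sum())         # mutated outside
            d = n_out - c
            table = np.array([[a, b], [c, d]], dtype=float)
            freq_in, freq_out = a / n_in, c / n_out
            if table.sum() == 0 or freq_in == freq_out:
                stat, p = 0.0, 1.0
            else:
                expected = stats.contingency.expected_freq(table)
                if (expected < 5).any():
                    stat = np.nan
                    p = stats.fisher_exact(table.astype(int))[1]
                else:
                    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append(
                {
                    "feature": feature,
                    "cluster": cluster,
                    "statistic": stat,
                    "p": p,
                    "freq_in": freq_in,
                    "freq_out": freq_out,
                    "direction": "enriched" if freq_in > freq_out else (
                        "depleted" if freq_in < freq_out else "none"),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def cnv_characteristic(
    cnv: pd.DataFrame,
    assignment,
    params: CharacterizeParams | None = None,
) -> pd.DataFrame:
    """Characteristic CNVs: per-cluster amp/del frequency strictly above threshold.

    ``cnv`` is loci x samples with values in {"amp", "del", "neutral"}.
    A frequency exactly at the threshold is NOT characteristic (strict >).
    """
    params = params or CharacterizeParams()
    labels = _labels_of(assignment)
    mat, labels = _align(cnv, labels)
    bad = set(np.unique(mat.to_numpy().astype(str))) - set(CNV_STATES)
    if bad:
        raise ValidationError(f"unknown CNV call(s): {sorted(bad)}")
    rows = []
    lab = labels.to_numpy()
    for cluster in sorted(pd.unique(lab).tolist()):
        inside = mat.loc[:, lab == cluster]
        n_in = inside.shape[1]
        if n_in == 0:
            continue
        for kind in ("amp", "del"):
            freq = (inside == kind).sum(axis=1) / n_in
            for locus, f in freq.items():
                if f > params.cnv_frequency_threshold:
                    rows.append(
                        {"cluster": cluster, "locus": locus, "kind": kind,
                         "frequency": float(f)}
                    )
    return pd.DataFrame(rows, columns=["cluster", "locus", "kind", "frequency"])


def continuous_feature_screen(
    features: pd.DataFrame,
    assignment,
    params: CharacterizeParams | None = None,
) -> pd.DataFrame:
    """Welch t-test screen for cluster-altered continuous features.

    ``features`` is features x samples (miRNA scores, GO activity, RPPA...).
    Direction is "up" when the cluster mean exceeds the rest mean.
    """
    params = params or CharacterizeParams()
    labels = _labels_of(assignment)
    mat, labels = _align(features, labels)
    values = mat.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("continuous features contain non-finite values")
    rows = []
    lab = labels.to_numpy()
    for cluster in sorted(pd.unique(lab).tolist()):
        inside = lab == cluster
        if inside.sum() < params.min_cluster_size or (~inside).sum() < 2:
            continue
        x_in = values[:, inside]
        x_out = values[:, ~inside]
        stat, p = stats.ttest_ind(x_in, x_out, axis=1, equal_var=False)
        diff = x_in.mean(axis=1) - x_out.mean(axis=1)
        for i, feature in enumerate(mat.index):
            rows.append(
                {
                    "feature": feature,
                    "cluster": cluster,
                    "statistic": float(stat[i]),
                    "p": float(p[i]),
                    "mean_diff": float(diff[i]),
                    "direction": "up" if diff[i] > 0 else ("down" if diff[i] < 0 else "none"),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def microenv_correlation(table, scores: pd.DataFrame) -> pd.DataFrame:
    """Correlate each index with each microenvironment score.

    ``scores`` is samples x score columns (e.g. purity, immune, stromal),
    computed upstream (the package does not re-derive them).  Returns one
    row per (index, score) with Pearson and Spearman r and p.
    """
    X = _as_matrix(table)
    common = X.index.intersection(scores.index)
    if len(common) < 3:
        raise ValidationError("too few samples shared by indexes and scores")
    X = X.loc[common]
    S = scores.loc[common]
    rows = []
    for idx_col in X.columns:
        for score_col in S.columns:
            x = X[idx_col].to_numpy(dtype=float)
            y = S[score_col].to_numpy(dtype=float)
            pr, pp = stats.pearsonr(x, y)
            sr, sp = stats.spearmanr(x, y)
            rows.append(
                {
                    "index": idx_col,
                    "score": score_col,
                    "pearson_r": float(pr),
                    "pearson_p": float(pp),
                    "spearman_r": float(sr),
                    "spearman_p": float(sp),
                    "n": len(common),
                }
            )
    return pd.DataFrame(rows)
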