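"""ROS-index-based drug-efficacy network and combination recommendations.

Cell lines are scored with the same five indexes as tumor samples; each
(drug, index) pair gets a Spearman correlation between the index and
ln IC50 across cell lines.  Edges passing |rho| and FDR thresholds form a
bipartite index-drug network.  A drug is resistant in a cell line when its
ln IC50 exceeds the ln maximum screening concentration (ties are
sensitive).  Resistant drugs whose IC50 rises with ROS accumulation
(positive index-I edge) are recommended for combination with a ROS
scavenger such as N-acetyl-L-cysteine; resistant drugs whose IC50 falls
with oxidative stress (negative index-II edge) are recommended for
combination with an antioxidant inhibitor.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .classify import _as_matrix

SENSITIVE, RESISTANT = "sensitive", "resistant"

STATUS_SENSITIVE = "sensitive_as_is"
STATUS_SCAVENGER = "combine_with_ROS_scavenger"
STATUS_ANTIOXIDANT = "combine_with_antioxidant_inhibitor"
STATUS_NO_RULE = "no_rule"


def classify_sensitivity(ln_ic50, ln_max_conc):
    """Resistant iff ln IC50 > ln maximum screening concentration.

    Both values must be on the same (ln) scale; equality is sensitive.
    Scalar or array-like input; missing max concentration gives no call
    (None / NaN passthrough).
    """
    ic = np.asarray(ln_ic50, dtype=float)
    mx = np.asarray(ln_max_conc, dtype=float)
    out = np.where(ic > mx, RESISTANT, SENSITIVE).astype(object)
    out[~np.isfinite(mx)] = None
    out[~np.isfinite(ic)] = None
    if out.ndim == 0:
        return out.item()
    return out


def index_drug_correlation(
    table,
    responses: pd.DataFrame,
    min_cell_lines: int = 20,
) -> pd.DataFrame:
    """Spearman correlation of every index with every drug's ln IC50.

    ``responses`` is cell lines x drugs; missing responses are dropped
    pairwise.  Returns edges (drug, index, rho, p, q, direction, n) with BH
    q-values across all edges.
    """
    X = _as_matrix(table)
    common = X.index.intersection(responses.index)
    if len(common) < min_cell_lines:
        raise ValidationError(
            f"need >= {min_cell_lines} cell lines with both indexes and responses"
        )
    X = X.loc[common]
    R = responses.loc[common]
    rows = []
    for drug in R.columns:
        y = R[drug].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < min_cell_lines:
            continue
        for idx_col in X.columns:
            x = X[idx_col].to_numpy(dtype=float)[ok]
            rho, p = stats.spearmanr(x, y[ok])
            rows.append(
                {
                    "drug": drug,
                    "index": idx_col,
                    "rho": float(rho),
                    "p": float(p),
                    "direction": int(np.sign(rho)),
                    "n": int(ok.sum()),
                }
            )
    if not rows:
        raise ValidationError("no (drug, index) pair could be correlated")
    edges = pd.DataFrame(rows)
    edges["q"] = multipletests(edges["p"].to_numpy(), method="fdr_bh")[1]
    return edges


def build_network(
    edges: pd.DataFrame,
    rho_threshold: float = 0.3,
    q_threshold: float = 0.05,
    drug_targets: pd.Series | None = None,
) -> nx.Graph:
    """Bipartite index-drug graph of edges with |rho| >= threshold, q < threshold.

    Optional drug -> target annotation edges are attached as a third node
    layer.  Edge attributes carry rho, p, q; node attribute ``kind`` is
    "index", "drug" or "target".
    """
    g = nx.Graph()
    if len(edges):
        passing = edges[
            (edges["rho"].abs() >= rho_threshold) & (edges["q"] < q_threshold)
        ]
        for _, row in passing.iterrows():
            g.add_node(row["index"], kind="index")
            g.add_node(row["drug"], kind="drug")
            g.add_edge(row["index"], row["drug"], rho=row["rho"], p=row["p"],
                       q=row["q"], sign=int(np.sign(row["rho"])))
    if drug_targets is not None:
        for drug, target in drug_targets.items():
            if drug in g and pd.notna(target) and target != "":
                g.add_node(target, kind="target")
                g.add_edge(drug, target, kind="targets")
    return g


def summarize_network(edges: pd.DataFrame, q_threshold: float = 0.05,
                      rho_threshold: float = 0.0) -> dict:
    """Fraction of drugs with >= 1 significant index edge, and per-index degree."""
    total = edges["drug"].nunique()
    passing = edges[(edges["q"] < q_threshold) & (edges["rho"].abs() >= rho_threshold)]
    n_correlated = passing["drug"].nunique()
    per_index = passing.groupby("index")["drug"].nunique().to_dict()
    return {
        "n_drugs": total,
        "n_drugs_correlated": n_correlated,
        "frac_drugs_correlated": n_correlated / total if total else float("nan"),
        "per_index_degree": per_index,
    }


def recommend_combination(
    drug: str,
    edges: pd.DataFrame,
    sensitivity_call: str | None,
    rho_threshold: float = 0.3,
    q_threshold: float = 0.05,
) -> tuple[str, str]:
    """Combination recommendation for one drug given its network edges.

    Sensitive drugs need no combination.  A resistant drug positively
    correlated with index I (accumulation antagonizes efficacy) pairs with
    a ROS scavenger; the index-I rule takes precedence when a drug also has
    a negative index-II edge.  Returns (status, rationale).
    """
    if sensitivity_call is None:
        return STATUS_NO_RULE, "no sensitivity call (missing screening concentration)"
    if sensitivity_call == SENSITIVE:
        return STATUS_SENSITIVE, "IC50 within the maximum screening concentration"
    sub = edges[(edges["drug"] == drug) & (edges["q"] < q_threshold)
                & (edges["rho"].abs() >= rho_threshold)]
    pos_i = sub[(sub["index"] == "index_I") & (sub["rho"] > 0)]
    neg_ii = sub[(sub["index"] == "index_II") & (sub["rho"] < 0)]
    if len(pos_i):
        return (
            STATUS_SCAVENGER,
            f"resistant and IC50 rises with ROS accumulation "
            f"(rho = {pos_i['rho'].iloc[0]:.2f}): combine with a ROS "
            f"scavenger (e.g. N-acetyl-L-cysteine)",
        )
    if len(neg_ii):
        return (
            STATUS_ANTIOXIDANT,
            f"resistant and IC50 falls with oxidative stress "
            f"(rho = {neg_ii['rho'].iloc[0]:.2f}): combine with an "
            f"antioxidant inhibitor",
        )
    return STATUS_NO_RULE, "resistant but no qualifying index edge"


def recommend_combinations(
    edges: pd.DataFrame,
    sensitivity_calls: pd.Series,
    rho_threshold: float = 0.3,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Vectorized :func:`recommend_combination` over a drug -> call Series."""
    rows = []
    for drug, call in sensitivity_calls.items():
        status, rationale = recommend_combination(
            drug, edges, call, rho_threshold=rho_threshold, q_threshold=q_threshold
        )
        rows.append({"drug": drug, "status": status, "rationale": rationale})
    return pd.DataFrame(rows).set_index("drug")
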