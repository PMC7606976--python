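"""Index biomarkers: hub genes from a PPI edge list, then correlation filtering.

A hub is a node whose degree strictly exceeds 1.5x the mean degree of the
input graph.  Hub genes whose expression correlates with an index at
|R| strictly greater than 0.2 become direction-tagged biomarkers of that
index (positive-direction when R > 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, ValidationError
from .classify import _as_matrix

logger = logging.getLogger(__name__)

#: Categories whose gene sets feed each index's candidate pool.
INDEX_CATEGORIES = {
    "index_I": ("biosynthesis", "scavenging"),
    "index_II": ("stress_response",),
    "index_III": ("scavenging",),
    "index_IV": ("biosynthesis",),
    "index_V": ("mito_source", "cyto_source"),
}


@dataclass(frozen=True)
class HubParams:
    """Hub rule: degree > multiplier x mean degree (strict)."""

    degree_multiplier: float = 1.5

    def __post_init__(self) -> None:
        if self.degree_multiplier <= 0:
            raise ValidationError("degree_multiplier must be > 0")


def _graph_from_edges(edges) -> nx.Graph:
    """Build a simple undirected graph; duplicate edges and self-loops collapse."""
    g = nx.Graph()
    if isinstance(edges, pd.DataFrame):
        pairs = edges.iloc[:, :2].itertuples(index=False, name=None)
    else:
        pairs = edges
    for a, b in pairs:
        a, b = str(a).strip(), str(b).strip()
        if a.upper() == b.upper():
            continue
        g.add_edge(a, b)
    return g


def hub_genes(edges, params: HubParams | None = None) -> pd.DataFrame:
    """Degrees and hub calls for a PPI edge list.

    Returns a frame indexed by gene with columns ``degree`` and ``is_hub``
    (degree strictly above multiplier x mean degree).  An empty graph gives
    an empty result with a warning.
    """
    params = params or HubParams()
    g = _graph_from_edges(edges)
    if g.number_of_nodes() == 0:
        logger.warning("empty PPI graph: no hubs")
        return pd.DataFrame(columns=["degree", "is_hub"])
    degrees = pd.Series(dict(g.degree()), name="degree").sort_values(ascending=False)
    threshold = params.degree_multiplier * degrees.mean()
    out = degrees.to_frame()
    out["is_hub"] = degrees > threshold
    out.index.name = "gene"
    return out


def index_hub_candidates(
    collection: GeneSetCollection,
    ppi_edges,
    params: HubParams | None = None,
) -> dict[str, list[str]]:
    """Per-index hub candidates from the PPI subgraph of the index's gene sets.

    For each index, the PPI is restricted to genes of the categories that
    feed that index, and the hub rule is applied to that subgraph.
    """
    params = params or HubParams()
    g = _graph_from_edges(ppi_edges)
    out: dict[str, list[str]] = {}
    for index_name, cats in INDEX_CATEGORIES.items():
        genes = {
            gene.upper()
            for c in cats
            for s in collection.by_category(c)
            for gene in s.genes
        }
        nodes = [n for n in g.nodes if n.upper() in genes]
        sub = g.subgraph(nodes)
        if sub.number_of_edges() == 0:
            out[index_name] = []
            continue
        hubs = hub_genes(list(sub.edges()), params)
        out[index_name] = hubs.index[hubs["is_hub"]].tolist()
    return out


def index_biomarkers(
    expr: pd.DataFrame,
    table,
    candidates,
    r_threshold: float = 0.2,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation-filtered biomarkers per index.

    ``candidates`` is either a flat gene list (tested against every index)
    or a dict index -> gene list (e.g. from :func:`index_hub_candidates`).
    Records are kept where |R| is strictly greater than ``r_threshold``;
    direction follows the sign of R.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    X = _as_matrix(table)
    common = X.index.intersection(expr.columns)
    if len(common) < 3:
        raise ValidationError("too few samples shared by expression and indexes")
    X = X.loc[common]
    lookup = {str(g).upper(): g for g in expr.index}

    if isinstance(candidates, dict):
        pairs = [(idx, g) for idx, genes in candidates.items() for g in genes]
    else:
        pairs = [(idx, g) for idx in X.columns for g in candidates]

    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for index_name, gene in pairs:
        key = str(gene).upper()
        if key not in lookup:
            raise ValidationError(f"candidate gene {gene!r} not in expression matrix")
        x = expr.loc[lookup[key], common].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        r, p = corr(x, X[index_name].to_numpy(dtype=float))
        if abs(r) > r_threshold:
            rows.append(
                {
                    "gene": lookup[key],
                    "index": index_name,
                    "R": float(r),
                    "p": float(p),
                    "direction": "positive" if r > 0 else "negative",
                }
            )
    return pd.DataFrame(rows, columns=["gene", "index", "R", "p", "direction"])


def biomarker_table(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot biomarker records into an index x direction gene-list layout."""
    rows = []
    for index_name, sub in records.groupby("index"):
        pos = sub.loc[sub["direction"] == "positive", "gene"].tolist()
        neg = sub.loc[sub["direction"] == "negative", "gene"].tolist()
        rows.append(
            {
                "index": index_name,
                "positive_direction": ", ".join(pos) if pos else "NA",
                "negative_direction": ", ".join(neg) if neg else "NA",
            }
        )
    return pd.DataFrame(rows, columns=["index", "positive_direction",
                                       "negative_direction"])
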