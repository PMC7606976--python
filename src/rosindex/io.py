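"""Reading, validation and mapping of ROS gene-set collections and tabular inputs.

Gene sets travel in standard GMT (one set per line: name, description,
genes...).  Because public GMT files carry no machine-readable redox
category, the description field is used to hold a ``category=<tag>`` token;
lines without one fall back to the ``regulation`` category.  Expression is
accepted as plain TSV (genes in rows, header row of sample IDs) or GCT 1.2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Redox categories a gene set may be tagged with.  The first five are the
#: substrate of the five indexes; ``regulation`` sets are carried along but
#: not used by index computation.
CATEGORIES = (
    "biosynthesis",
    "scavenging",
    "stress_response",
    "mito_source",
    "cyto_source",
    "regulation",
)

#: Categories that must each contribute at least one set for the five
#: indexes to be computable.
REQUIRED_CATEGORIES = CATEGORIES[:5]


class GmtParseError(ValueError):
    """A GMT line could not be parsed."""


class ValidationError(ValueError):
    """An input table violated its contract."""


class CategoryCoverageError(ValidationError):
    """A required redox category has no usable gene set."""


def _norm(symbol: str) -> str:
    """Case-insensitive gene-symbol key (trimmed, upper-cased)."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named gene set tagged with one redox category.

    Genes are stored in input order, de-duplicated case-insensitively.
    """

    name: str
    category: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"gene set {self.name!r}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} has no genes")
        seen: set[str] = set()
        deduped = []
        for g in self.genes:
            key = _norm(g)
            if key in seen:
                continue
            seen.add(key)
            deduped.append(g)
        if len(deduped) != len(self.genes):
            logger.warning(
                "gene set %s: %d duplicate gene symbol(s) removed",
                self.name,
                len(self.genes) - len(deduped),
            )
            object.__setattr__(self, "genes", tuple(deduped))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list[GeneSet]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate gene set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def by_category(self, category: str) -> list[GeneSet]:
        if category not in CATEGORIES:
            raise ValidationError(f"unknown category {category!r}")
        return [s for s in self.sets if s.category == category]

    def require_index_categories(self) -> None:
        """Raise unless every category needed by the indexes has a set."""
        missing = [c for c in REQUIRED_CATEGORIES if not self.by_category(c)]
        if missing:
            raise CategoryCoverageError(
                f"no gene set left in required categories: {missing}"
            )

    @property
    def gene_universe(self) -> set[str]:
        return {_norm(g) for s in self.sets for g in s.genes}


def read_gmt(path: str | Path, provenance: str | None = None) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    The description field (second column) is scanned for a
    ``category=<tag>`` token; lines without one are tagged ``regulation``.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected >= 3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name, description = fields[0].strip(), fields[1]
            genes = tuple(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise ValidationError(f"{path.name}:{lineno}: set {name!r} has no genes")
            category = "regulation"
            for token in description.replace(";", " ").split():
                if token.startswith("category="):
                    category = token.split("=", 1)[1].strip()
            try:
                sets.append(GeneSet(name=name, category=category, genes=genes))
            except ValidationError as exc:
                raise GmtParseError(f"{path.name}:{lineno}: {exc}") from exc
    return GeneSetCollection(sets=sets, provenance=provenance or str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT, preserving category tags."""
    path = Path(path)
    with path.open("w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, f"category={s.category}", *s.genes]) + "\n")


@dataclass
class CoverageReport:
    """Per-set outcome of mapping a collection onto an expression universe."""

    coverage: pd.Series  # set name -> fraction of genes found in the universe
    dropped: list[str] = field(default_factory=list)


def map_to_universe(
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_coverage: float = 0.5,
) -> tuple[GeneSetCollection, CoverageReport]:
    """Intersect each set with a gene universe (case-insensitive).

    Sets retaining less than ``min_coverage`` of their genes are dropped with
    a warning; a required category left empty is a hard error.  Mapped genes
    adopt the universe's spelling, which makes the operation idempotent.
    """
    universe = list(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    lookup = {_norm(g): g for g in universe}
    mapped_sets: list[GeneSet] = []
    cov: dict[str, float] = {}
    dropped: list[str] = []
    for s in collection:
        hits = [lookup[_norm(g)] for g in s.genes if _norm(g) in lookup]
        frac = len(hits) / len(s.genes)
        cov[s.name] = frac
        if frac < min_coverage or not hits:
            dropped.append(s.name)
            logger.warning(
                "gene set %s dropped: coverage %.3f < %.3f", s.name, frac, min_coverage
            )
            continue
        mapped_sets.append(GeneSet(name=s.name, category=s.category, genes=tuple(hits)))
    out = GeneSetCollection(sets=mapped_sets, provenance=collection.provenance)
    missing = [c for c in REQUIRED_CATEGORIES if collection.by_category(c)
               and not out.by_category(c)]
    if missing:
        raise CategoryCoverageError(
            f"mapping removed every set of required categories: {missing}"
        )
    report = CoverageReport(coverage=pd.Series(cov, name="coverage"), dropped=dropped)
    return out, report


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples expression matrix (linear scale, >= 0)."""
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene IDs: {dupes[:5]}")
    if expr.columns.duplicated().any():
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample IDs: {dupes[:5]}")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("expression contains NaN or infinite values")
    if (values < 0).any():
        raise ValidationError("expression contains negative values; linear scale expected")
    return expr.astype(float)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression matrix from TSV or GCT 1.2.

    Returns a genes x samples :class:`pandas.DataFrame` of floats.  The
    number of output samples always equals the number of input columns.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if df.columns[0].lower() == "description":
            df = df.drop(columns=df.columns[0])
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.apply(pd.to_numeric)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path.name}: non-numeric expression values") from exc
    return validate_expression(df)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical table: columns sample, cancer_type, time (days), event.

    Times must be positive and finite; events must be coded 0/1.  The result
    is indexed by sample ID.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "cancer_type", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
    time = pd.to_numeric(df["time"], errors="coerce")
    if time.isna().any() or not np.isfinite(time).all():
        raise ValidationError("non-numeric survival time")
    if (time <= 0).any():
        bad = df.loc[time <= 0, "sample"].tolist()
        raise ValidationError(f"non-positive survival time for samples {bad[:5]}")
    event = pd.to_numeric(df["event"], errors="coerce")
    if not event.isin([0, 1]).all():
        raise ValidationError("event must be coded 0 (censored) or 1 (event)")
    df = df.assign(time=time.astype(float), event=event.astype(int))
    if df["sample"].duplicated().any():
        raise ValidationError("duplicate sample IDs in clinical table")
    return df.set_index("sample")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a two-column undirected edge list; self-loops and duplicate
    (unordered) pairs are removed, with counts logged."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("edge list must have two columns")
    df = df.iloc[:, :2]
    df.columns = ["gene_a", "gene_b"]
    df = df.apply(lambda c: c.str.strip())
    n0 = len(df)
    df = df[df["gene_a"].map(_norm) != df["gene_b"].map(_norm)]
    n_loops = n0 - len(df)
    if n_loops:
        logger.info("dropped %d self-loop edge(s)", n_loops)
    key = df.apply(lambda r: tuple(sorted((_norm(r.gene_a), _norm(r.gene_b)))), axis=1)
    df = df.loc[~key.duplicated()].reset_index(drop=True)
    return df


def read_table(path: str | Path, index_col: int | str | None = 0) -> pd.DataFrame:
    """Generic TSV reader for drug/omics tables with named columns."""
    return pd.read_csv(path, sep="\t", index_col=index_col)
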