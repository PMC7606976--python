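"""End-to-end orchestration: read -> score -> trim -> cluster -> screens -> network.

The pipeline consumes a flat config (YAML or constructed in code), executes
the stages in order, writes every artifact as TSV/JSON into an output
directory together with a manifest (stage list, input SHA-256 hashes,
parameters, package version), and logs one structured line per stage with
input/output row counts so sample accounting is always reconstructible.
Optional inputs (drug panel, omics layers, PPI, microenvironment scores)
skip their stage with a warning instead of aborting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import biomarkers as bm
from . import characterize as ch
from . import classify as cl
from . import drugnet as dn
from . import io
from . import scoring as sc
from . import survival as sv

logger = logging.getLogger(__name__)

STAGES = (
    "read",
    "score",
    "filter_outliers",
    "cluster",
    "composition",
    "survival",
    "characterize",
    "drugnet",
    "biomarkers",
)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run."""

    expression: str
    gmt: str
    clinical: str
    outdir: str
    # optional inputs
    drug_responses: str | None = None
    drug_meta: str | None = None
    cellline_expression: str | None = None
    mutations: str | None = None
    cnv: str | None = None
    features: str | None = None
    microenv: str | None = None
    ppi: str | None = None
    # parameters
    index_params: sc.IndexParams = field(default_factory=sc.IndexParams)
    outlier_params: sc.OutlierParams = field(default_factory=sc.OutlierParams)
    characterize_params: ch.CharacterizeParams = field(
        default_factory=ch.CharacterizeParams
    )
    hub_params: bm.HubParams = field(default_factory=bm.HubParams)
    k: int = 8
    linkage: str = "ward"
    rho_threshold: float = 0.3
    q_threshold: float = 0.05
    r_threshold: float = 0.2
    fdr_threshold: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, klass in (
            ("index_params", sc.IndexParams),
            ("outlier_params", sc.OutlierParams),
            ("characterize_params", ch.CharacterizeParams),
            ("hub_params", bm.HubParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
        return out


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, outdir: Path, name: str, **kwargs) -> str:
    path = outdir / name
    df.to_csv(path, sep="\t", **kwargs)
    return name


@dataclass
class PipelineResult:
    """Artifacts of a run, in memory plus the written manifest."""

    outdir: Path
    manifest: dict
    index_table: sc.IndexTable
    assignment: cl.ClusterAssignment
    screen: sv.ScreenResult | None = None


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; every artifact is written under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": config.to_dict(),
        "stages": [],
        "inputs": {},
        "outputs": [],
        "skipped": [],
        "counts": {},
    }

    def stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage %s", name)

    def fail(name: str, exc: Exception):
        raise StageError(name, exc)

    # --- read -------------------------------------------------------------
    stage("read")
    try:
        for key in ("expression", "gmt", "clinical", "drug_responses", "drug_meta",
                    "cellline_expression", "mutations", "cnv", "features",
                    "microenv", "ppi"):
            path = getattr(config, key)
            if path:
                manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
        expr = io.read_expression(config.expression)
        collection = io.read_gmt(config.gmt)
        clinical = io.read_clinical(config.clinical)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        fail("read", exc)
    manifest["counts"]["samples_in"] = expr.shape[1]
    manifest["counts"]["genes_in"] = expr.shape[0]

    # --- score ------------------------------------------------------------
    stage("score")
    try:
        table = sc.compute_indexes(expr, collection, config.index_params)
    except Exception as exc:
        fail("score", exc)

    # --- outlier filtering --------------------------------------------------
    stage("filter_outliers")
    try:
        table, removed = sc.filter_outliers(table, config.outlier_params)
    except Exception as exc:
        fail("filter_outliers", exc)
    manifest["counts"]["samples_removed_outlier"] = len(removed)
    manifest["counts"]["samples_retained"] = len(table)
    logger.info("outlier filtering: %d -> %d samples",
                manifest["counts"]["samples_in"], len(table))
    manifest["outputs"].append(_write(table.to_frame(), outdir, "indexes.tsv",
                                      index_label="sample"))

    # --- clustering -------------------------------------------------------
    stage("cluster")
    try:
        assignment = cl.hierarchical_cluster(table, k=config.k,
                                             linkage=config.linkage)
    except Exception as exc:
        fail("cluster", exc)
    manifest["outputs"].append(
        _write(assignment.labels.to_frame(), outdir, "clusters.tsv",
               index_label="sample")
    )

    # --- composition / densities -------------------------------------------
    stage("composition")
    try:
        clin = clinical.reindex(table.sample_ids).dropna(subset=["cancer_type"])
        composition, homogeneity = cl.cluster_composition(
            cl.ClusterAssignment(
                labels=assignment.labels.loc[clin.index],
                k=assignment.k, linkage=assignment.linkage,
                metric=assignment.metric,
            ) if len(clin) < len(table) else assignment,
            clin["cancer_type"],
        )
        density = cl.index_density_summary(table, assignment)
        groups = cl.group_cancer_types(table, clin["cancer_type"], g=None) \
            if clin["cancer_type"].nunique() >= 3 else None
    except Exception as exc:
        fail("composition", exc)
    manifest["outputs"].append(_write(composition, outdir, "composition.tsv",
                                      index=False))
    manifest["outputs"].append(_write(density, outdir, "index_density.tsv",
                                      index=False))
    if groups is not None:
        manifest["outputs"].append(
            _write(groups.groups.to_frame(), outdir, "type_groups.tsv",
                   index_label="cancer_type")
        )

    # --- survival ----------------------------------------------------------
    stage("survival")
    screen = None
    try:
        scores = table.values.T  # units (indexes) x samples
        screen = sv.prognostic_screen(scores, clinical,
                                      fdr_threshold=config.fdr_threshold)
        lr = sv.cluster_logrank(assignment, clinical)
        manifest["counts"]["cluster_logrank_p"] = lr.p
    except Exception as exc:
        fail("survival", exc)
    manifest["outputs"].append(_write(screen.table, outdir, "survival_screen.tsv",
                                      index=False))

    # --- characterize -------------------------------------------------------
    stage("characterize")
    try:
        if config.mutations:
            mut = io.read_table(config.mutations)
            hits = ch.mutation_enrichment(mut, assignment,
                                          config.characterize_params)
            manifest["outputs"].append(_write(hits, outdir, "mutation_hits.tsv",
                                              index=False))
        else:
            manifest["skipped"].append("characterize:mutations")
        if config.cnv:
            cnv = io.read_table(config.cnv)
            flags = ch.cnv_characteristic(cnv, assignment,
                                          config.characterize_params)
            manifest["outputs"].append(_write(flags, outdir, "cnv_characteristic.tsv",
                                              index=False))
        else:
            manifest["skipped"].append("characterize:cnv")
        if config.features:
            feats = io.read_table(config.features)
            fhits = ch.continuous_feature_screen(feats, assignment,
                                                 config.characterize_params)
            manifest["outputs"].append(_write(fhits, outdir, "feature_hits.tsv",
                                              index=False))
        else:
            manifest["skipped"].append("characterize:features")
        if config.microenv:
            micro = io.read_table(config.microenv)
            mcorr = ch.microenv_correlation(table, micro)
            manifest["outputs"].append(_write(mcorr, outdir, "microenv_correlation.tsv",
                                              index=False))
        else:
            manifest["skipped"].append("characterize:microenv")
    except Exception as exc:
        fail("characterize", exc)

    # --- drug network --------------------------------------------------------
    stage("drugnet")
    try:
        if config.drug_responses and config.cellline_expression:
            cl_expr = io.read_expression(config.cellline_expression)
            responses = io.read_table(config.drug_responses)
            cl_table = sc.compute_indexes(cl_expr, collection, config.index_params)
            edges = dn.index_drug_correlation(cl_table, responses)
            manifest["outputs"].append(_write(edges, outdir, "drug_edges.tsv",
                                              index=False))
            summary = dn.summarize_network(edges, q_threshold=config.q_threshold)
            manifest["counts"]["drugnet"] = summary
            targets = None
            if config.drug_meta:
                meta = io.read_table(config.drug_meta)
                targets = meta["target"] if "target" in meta.columns else None
                if "max_screen_conc" in meta.columns:
                    median_ic50 = responses.median(axis=0)
                    calls = pd.Series(
                        dn.classify_sensitivity(
                            median_ic50.to_numpy(),
                            meta["max_screen_conc"].reindex(median_ic50.index)
                            .to_numpy(),
                        ),
                        index=median_ic50.index,
                    )
                    recs = dn.recommend_combinations(
                        edges, calls, rho_threshold=config.rho_threshold,
                        q_threshold=config.q_threshold,
                    )
                    manifest["outputs"].append(
                        _write(recs, outdir, "recommendations.tsv")
                    )
            network = dn.build_network(edges, rho_threshold=config.rho_threshold,
                                       q_threshold=config.q_threshold,
                                       drug_targets=targets)
            import networkx as nx

            nx.write_graphml(network, outdir / "drug_network.graphml")
            manifest["outputs"].append("drug_network.graphml")
        else:
            manifest["skipped"].append("drugnet")
            logger.warning("drugnet stage skipped: no drug panel supplied")
    except Exception as exc:
        fail("drugnet", exc)

    # --- biomarkers -----------------------------------------------------------
    stage("biomarkers")
    try:
        if config.ppi:
            ppi = io.read_edge_list(config.ppi)
            candidates = bm.index_hub_candidates(collection, ppi, config.hub_params)
            records = bm.index_biomarkers(
                expr[table.sample_ids], table,
                {k: v for k, v in candidates.items() if v},
                r_threshold=config.r_threshold,
            )
            manifest["outputs"].append(_write(records, outdir, "biomarkers.tsv",
                                              index=False))
            manifest["outputs"].append(
                _write(bm.biomarker_table(records), outdir, "biomarker_table.tsv",
                       index=False)
            )
        else:
            manifest["skipped"].append("biomarkers")
            logger.warning("biomarkers stage skipped: no PPI supplied")
    except Exception as exc:
        fail("biomarkers", exc)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return PipelineResult(outdir=outdir, manifest=manifest, index_table=table,
                          assignment=assignment, screen=screen)


def validate_run(outdir: str | Path, truth_path: str | Path | None = None) -> dict:
    """Compare a run's outputs against generator truth, when available.

    The truth file is JSON with optional keys ``cluster_labels``
    (sample -> planted cluster), ``index_correlations`` (pairs of index
    names -> planted r) and ``drug_signs`` (drug -> planted slope sign).
    Without a truth file the report is marked ``"truth": "absent"``.
    """
    from sklearn.metrics import adjusted_rand_score

    outdir = Path(outdir)
    report: dict = {"outdir": str(outdir)}
    if truth_path is None or not Path(truth_path).exists():
        report["truth"] = "absent"
        return report
    with open(truth_path) as fh:
        truth = json.load(fh)
    report["truth"] = "present"

    if "cluster_labels" in truth and (outdir / "clusters.tsv").exists():
        found = pd.read_csv(outdir / "clusters.tsv", sep="\t", index_col=0)["cluster"]
        planted = pd.Series(truth["cluster_labels"])
        common = found.index.intersection(planted.index)
        report["cluster_ari"] = float(
            adjusted_rand_score(planted.loc[common], found.loc[common])
        )
    if "index_correlations" in truth and (outdir / "indexes.tsv").exists():
        idx = pd.read_csv(outdir / "indexes.tsv", sep="\t", index_col=0)
        errs = {}
        for key, planted_r in truth["index_correlations"].items():
            a, b = key.split(":")
            r = float(np.corrcoef(idx[a], idx[b])[0, 1])
            errs[key] = {"computed": r, "planted": planted_r,
                         "abs_error": abs(r - planted_r)}
        report["index_correlations"] = errs
    if "drug_signs" in truth and (outdir / "drug_edges.tsv").exists():
        edges = pd.read_csv(outdir / "drug_edges.tsv", sep="\t")
        sig = edges[edges["q"] < 0.05]
        correct = total = 0
        for drug, sign in truth["drug_signs"].items():
            sub = sig[sig["drug"] == drug]
            if len(sub):
                total += 1
                best = sub.loc[sub["rho"].abs().idxmax()]
                correct += int(np.sign(best["rho"]) == np.sign(sign))
        report["drug_sign_accuracy"] = correct / total if total else None
    return report
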