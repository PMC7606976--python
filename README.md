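# rosindex

Transcriptome-based evaluation of reactive-oxygen-species (ROS) metabolism
in bulk tumor samples: five redox indexes computed from gene-set geometric
means, pan-cancer sample reclassification, prognostic and multi-omics
screens, an index-based drug-efficacy network, and index biomarkers — with
a seeded synthetic-cohort generator so the whole pipeline is testable
without any external download.

## The problem

Tumor redox state is hard to measure: fluorescent ROS probes require
dissociated live cells and perturb the quantity they measure, while assays
of single enzymes (SOD, GPX, PRDX, ...) capture one step of what is a
cascade of generation, scavenging and response reactions. A
transcriptome-level summary sidesteps both problems: gene programs for ROS
biosynthesis, scavenging and stress response are read out directly from
bulk RNA-seq, for every sample of a cohort.

## The five ROS indexes

For a gene set *G* and sample *s* with linear expression *x*, the signature
score is the geometric mean

&nbsp;&nbsp;&nbsp;&nbsp;score(G, s) = exp( (1/|G|) Σ_{g∈G} log(x_gs + ε) ),&nbsp;&nbsp;ε = 0.01.

Gene sets are tagged with one of five redox categories; the per-category
log-score (mean over the category's sets) gives B (biosynthesis),
S (scavenging), R (stress response), M (mitochondrial source) and
C (cytoplasmic source). The indexes are linear combinations in log space:

| index | meaning | formula |
|---|---|---|
| I | ROS accumulation | B − λ·S (λ = 0.5) |
| II | oxidative stress | R |
| III | scavenging ability | S |
| IV | biosynthetic ability | B |
| V | subcellular origin (mito/cyto log-ratio) | M − C |

Indexes are z-scored across the cohort, per-index extreme samples are
trimmed (top/bottom 5% by default, union over the five indexes), and the
retained samples are reclassified by Ward hierarchical clustering in
five-index space (k = 8 for the paper-faithful pipeline, or
silhouette-selected). Downstream: univariate Cox screens per cancer type
with Benjamini–Hochberg FDR (hazard ratios below 1 displayed as −1/HR),
log-rank comparisons between clusters, cluster-vs-rest chi-square / Welch-t
/ CNV-frequency (>10%) screens, Spearman correlation of cell-line indexes
against drug ln IC50 to build a bipartite index–drug network with
combination recommendations (ROS scavenger for resistant drugs antagonized
by accumulation; antioxidant inhibitor for resistant drugs potentiated by
oxidative stress), and PPI hub genes filtered at |R| > 0.2 as per-index
biomarkers.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from rosindex import (SyntheticConfig, simulate_cohort, compute_indexes,
                      index_correlations, select_k, prognostic_screen)

# 1. correlation-structure cohort: B,S independent; A = B - 0.5*S + eps
cfg = SyntheticConfig(seed=13, n_samples=7559)
cohort = simulate_cohort(cfg, structure="iid")
table = compute_indexes(cohort.expression, cohort.collection)
corr = index_correlations(table)
print(f"r(index I, index IV)   = {corr.loc['index_I', 'index_IV']:.3f}")
print(f"r(index III, index IV) = {corr.loc['index_III', 'index_IV']:.3f}")

# 2. cluster-structured cohort: 8 planted archetypes in index space
cfg8 = SyntheticConfig(seed=13, samples_per_archetype=250)
cohort8 = simulate_cohort(cfg8, structure="archetypes")
table8 = compute_indexes(cohort8.expression, cohort8.collection)
assignment = select_k(table8, k_range=range(2, 13))
ari = adjusted_rand_score(cohort8.cluster_labels, assignment.labels)
print(f"selected k = {assignment.k}, ARI vs planted clusters = {ari:.2f}")

screen = prognostic_screen(table8.values.T, cohort8.clinical)
s = screen.summary()
print(f"indexes prognostic in >= 1 cancer type (FDR < 0.05): "
      f"{s['units_significant_ge1_type_q']}/{s['n_units']}")
```

prints

```
r(index I, index IV)   = 0.811
r(index III, index IV) = 0.004
selected k = 8, ARI vs planted clusters = 0.94
indexes prognostic in >= 1 cancer type (FDR < 0.05): 5/5
```

The first two numbers recover the generator's planted correlation
structure through the full expression → scoring path: accumulation tracks
biosynthesis at r ≈ 0.81 while scavenging and biosynthesis are
independent. The clustering block shows that silhouette-selected Ward
clustering of the computed indexes finds the 8 planted metabolic
archetypes and assigns samples back to them with adjusted Rand index 0.94,
and the Cox screen flags every index as prognostic in at least one
synthetic cancer type (each type's hazard is driven by one index by
construction).

## Command line

```bash
rosindex simulate --seed 13 --structure archetypes -o data/
rosindex score --expr data/expression.tsv --gmt data/ros_sets.gmt -o indexes.tsv
rosindex cluster --indexes indexes.tsv --select-k 2:12 -o clusters.tsv
rosindex survival --indexes indexes.tsv --clinical data/clinical.tsv -o screen.tsv
rosindex run --config pipeline.yaml     # full pipeline with manifest
rosindex validate --outdir out/ --truth data/truth.json
```

Real cohorts plug in the same way: expression as TSV/GCT, gene sets as GMT
with `category=` tags in the description field, clinical/drug/omics tables
as TSV, PPI as a two-column edge list.

## Layout

- `src/rosindex/io.py` — GMT / expression / clinical / edge-list readers
- `src/rosindex/scoring.py` — geometric-mean scores, indexes, outlier trim
- `src/rosindex/simulate.py` — synthetic cohorts, drug panels, omics layers
- `src/rosindex/classify.py` — clustering, k selection, composition, t-SNE
- `src/rosindex/survival.py` — Cox / log-rank / Kaplan–Meier screens
- `src/rosindex/characterize.py` — cluster-vs-rest omics screens
- `src/rosindex/drugnet.py` — index–drug network and recommendations
- `src/rosindex/biomarkers.py` — PPI hubs and correlation-filtered markers
- `src/rosindex/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model details, parameter choices, limitations
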