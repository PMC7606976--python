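# Methods

## Index model

All scoring happens in log space on linear, pseudocounted expression. The
geometric-mean score of a gene set is `exp(mean(log(x + eps)))` with
`eps = 0.01`; the pseudocount is required because RNA-seq matrices contain
exact zeros, which would annihilate a geometric mean, and 0.01 is small
relative to typical linear expression values (the generator's baseline is
`exp(3) ≈ 20`). Scores are scale-equivariant: multiplying a sample's
expression by c multiplies every score by c, so log-score *differences*
(index I and index V) are invariant to per-sample depth factors — one
reason the index formulas are built as log-space contrasts.

A category's log-score is the unweighted mean of its sets' log scores.
The five indexes are:

- **index IV** (biosynthesis) = B, **index III** (scavenging) = S,
  **index II** (oxidative stress) = R — direct category read-outs;
- **index V** (subcellular origin) = M − C, a mitochondria/cytoplasm
  log-ratio; higher values mean more ROS of mitochondrial origin;
- **index I** (accumulation) = B − λ·S: net accumulation is generation
  minus weighted elimination. λ (`IndexParams.scavenging_coupling`,
  default 0.5) sets how strongly measured scavenging capacity discounts
  measured biosynthesis. The exact published combination coefficients are
  not available; these linear log-space forms are this package's explicit
  reconstruction, and λ is an exposed knob, not a recovered constant.
  λ = 0.5 reproduces the reported cohort-level correlation structure
  (r(I, IV) ≈ 0.81 with r(III, IV) ≈ 0) under the synthetic generator's
  matching latent model.

Indexes are z-scored over the analyzed cohort by default (population SD),
because every downstream use — cross-cancer-type comparison, clustering,
density summaries — compares samples across the cohort. Standardization is
recomputed from raw values after outlier trimming.

### Outlier trimming

Default: per index, samples strictly outside the [5%, 95%] quantile band
are flagged, and a sample flagged on *any* index is removed. A Tukey-fence
mode (Q1 − 1.5·IQR, Q3 + 1.5·IQR) is provided as the alternative reading
of "outliers indicated by R" (boxplot fences). Two practical notes:

- the union rule is aggressive in five dimensions: on independent indexes
  it removes up to 1 − 0.9⁵ ≈ 41% of samples; correlation among indexes
  reduces this (≈ 36% on the generator's default cohort). Fence mode is
  much milder on near-Gaussian indexes.
- trimming truncates the index distributions, which attenuates
  correlations measured afterwards (r(I, IV) drops from 0.81 to ≈ 0.79 on
  the default cohort). The headline correlation structure is therefore
  computed on the untrimmed cohort; trimming is applied before clustering
  and survival analysis.
- trimming is global by default; per-cancer-type trimming is available by
  running the filter per stratum (whether the original analysis trimmed
  globally or per type is not stated).

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
not real TCGA/GDSC covariance. Per sample it draws latent redox programs
B, S, R, M, C (i.i.d. standard normal in the unstructured cohort) and an
accumulation latent

    A = B − w·S + ε,   ε ~ N(0, σ²),   w = 0.5,  σ² = 0.274,

which fixes corr(A, B) = 1/√(1 + w² + σ²) ≈ 0.810. Genes are emitted
log-normally: `x = exp(mu_g + loading·L + noise)` with per-gene baseline
`mu_g ~ N(3, 0.5²)`, loading 1.0, gene noise SD 0.5 and 200 genes per
category. The category score then recovers its program with attenuation
1/√(1 + σ_g²/(loading²·n_genes)) ≈ 0.999.

**The accumulation disturbance is expressed through scavenging.** A drives
no gene program of its own — accumulation is only recoverable through the
index-I formula. If ε left no transcriptional trace at all, the computed
index I would equal B − w·S exactly and corr(I, IV) would be
1/√1.25 ≈ 0.894 regardless of σ². The generator therefore routes the
disturbance through the *measured* scavenging program,

    S_prog = S − ε/w,

i.e. scavenger transcription reads low exactly when accumulation runs
above what biosynthesis and scavenging predict (a redox-feedback reading).
Scavenging genes are driven by S_prog, so the computed
index I = B − w·S_prog = A, and the pipeline reproduces the planted
correlation structure end to end. S and S_prog both remain independent of
B, so corr(III, IV) stays ≈ 0.

**Archetype cohorts.** Eight cluster centroids are planted in 5-dim index
space (minimum pairwise distance 2, enforced by config validation), with
isotropic per-dimension noise (SD 0.4) added to each sample's target.
Because computed index I is functionally IV − w·III, only four coordinates
are free; a target is realized by honoring its I-coordinate exactly and
choosing the biosynthesis/scavenging programs closest (least squares) to
the target's III and IV coordinates:

    delta  = t_I − (t_IV − w·t_III)
    B      = t_IV  + delta/(1 + w²)
    S_prog = t_III − w·delta/(1 + w²)

This keeps the realized centroids at pairwise distance ≥ 2 (the naive
"drop the I-coordinate" realization collapses the closest pair to 1.8 and
destabilizes k selection; an unconstrained equal-weight projection shrinks
it further to 1.5). Cluster truth labels are the archetype assignments.

**Group cohorts.** 22 cancer types are assigned to 5 group templates
(sizes 6, 6, 2, 4, 4); each type's mean profile is its template plus
N(0, 0.2²) per dimension, and samples scatter around their type's profile
with SD 1.0 (a realistic within-type spread; with ≥ 100 samples per type
the type-mean standard error ≤ 0.1 keeps the planted 0.2 deviation
dominant). Archetype and group structures are deliberately *not*
superimposed in one cohort — both live in the same index coordinates, and
stacking them would destroy both recoveries; `simulate_cohort` exposes
them as separate `structure` modes.

**Survival.** Exponential event times with log-hazard linear in the true
indexes, cancer-type-specific coefficients (default: one driving index per
type, magnitude 0.5, sign alternating across types) and administrative
censoring at 3,000 days with baseline hazard 1/1,000 days (≈ 78% event
rate at neutral indexes). Exponential + fixed-horizon censoring is the
simplest model with exact Cox recovery semantics.

**Drug panel.** 1,066 cell lines × 251 drugs by default, mirroring a
GDSC-scale screen; 204 drugs (81.3%) are effective with
ln IC50 = a_d + b_d·z(index_{j(d)}) + N(0, 1), slope magnitude 0.5, driving
index cycling through I–V with alternating sign; the remainder are null.
One driving index per drug keeps the per-edge power analytic. AUC is a
monotone decreasing logistic transform of ln IC50, and the maximum
screening concentration defaults to ln 20 µM ≈ 3.0 on the ln-µM scale.

**Omics layers.** One planted feature per cluster per layer: mutations
Bernoulli(0.5) inside vs 0.05 outside; CNV amplification frequency 0.2
inside vs 0.02 outside (straddling the 10% characteristic rule);
continuous features shifted +1 SD inside. Remaining features are null.

All draws flow from one `numpy.random.Generator` seeded by the config:
identical config + seed ⇒ bit-identical cohorts.

## Clustering and k selection

Ward linkage on Euclidean distance over z-scored indexes (the linkage used
originally is not stated; Ward is markedly more stable for planted-cluster
recovery, and complete linkage remains available by flag). Cut labels are
relabeled 1..k in order of first appearance, so the partition is
order-stable. `select_k` maximizes mean silhouette over k = 2..12 on a
distance matrix computed once, ties going to the smaller k; a winning
silhouette below 0.25 is flagged low-confidence. Silhouette reliably
recovers the default 8-archetype geometry; note that it will merge a pair
of clusters sitting exactly at the generator's minimum-separation bound
(distance 2 with noise SD 0.4) when few clusters are present — k selection
on real data should always be read together with the silhouette trace.
Cancer-type grouping clusters the per-type arithmetic mean index vectors
with the same machinery. The 2-D embedding is t-SNE on the five indexes,
seeded, for visualization only.

## Statistics

- **Cox screens**: univariate proportional-hazards fits (partial
  likelihood, Efron tie handling, Wald inference) via lifelines, one fit
  per (unit, cancer type); strata with < 10 samples or < 3 events are
  skipped and recorded. Covariates are used continuously.
- **Multiple testing**: Benjamini–Hochberg within each screen (a
  Bonferroni switch exists). Headline counts use q < 0.05; significance
  stars follow raw p (0.05/0.01/0.001) to mirror the usual figure
  annotation.
- **HR display**: HR if HR ≥ 1 else −1/HR — an odd-symmetric encoding
  around ±1 that makes protective and risk effects visually comparable.
- **Cluster-vs-rest tests**: 2×2 chi-square without continuity correction,
  falling back to Fisher's exact test when any expected cell < 5; Welch
  (unequal-variance) t for continuous features, since cluster sizes and
  variances differ wildly. CNV characteristic calls use the strict > 10%
  frequency rule and no p-value, matching the published rule.
- **Drug network**: Spearman rank correlation (average ranks on ties)
  between each index and each drug's ln IC50, BH across all edges;
  network edges additionally require |rho| ≥ 0.3 — the operationalization
  of "moderate correlation", configurable because no cutoff was printed.
  Resistance is ln IC50 strictly above the ln maximum screening
  concentration (ties sensitive). When a resistant drug has both a
  positive index-I edge and a negative index-II edge, the index-I
  (scavenger) rule wins; the original presentation keeps the two panels
  disjoint and never defines the overlap, so the precedence is a
  documented package choice.
- **Biomarkers**: hubs are nodes with degree strictly above 1.5× the mean
  degree of their (per-index category sub)graph; biomarker records require
  |R| strictly above 0.2, Pearson by default with a Spearman flag,
  computed pan-cohort.

## What the synthetic tests do and do not show

Passing recovery tests shows the pipeline's machinery is correct and
calibrated under the generator's assumptions: log-normal expression with a
single latent program per category, independent gene noise, exponential
hazards, one driving index per drug, cluster-wise homogeneous omics
enrichment. Real tumors violate most of these (gene–gene covariance within
programs, batch and purity effects, non-proportional hazards, pleiotropic
drugs), so synthetic recovery quantifies *implementation* fidelity, not
biological validity. No attempt is made to reproduce dataset-specific
numbers that depend on the actual TCGA/GDSC downloads (mutation
frequencies, exact retained-sample counts, specific biomarker gene lists).

The gene-set collection shipped by the generator uses synthetic gene
symbols and is clearly non-canonical; real analyses must supply their own
GMT (with `category=` tags) — the published supplementary set membership
is not machine-readable.

## Problem sizes used in the checked examples

Correlation structure: n = 7,559 samples, 1,000 genes, 20 replicates.
Cluster recovery: 8 × 400 samples, 25 replicates. Group recovery: 22 types
× 200 samples, 25 replicates. Calibration: 200 Cox replicates at n = 500
(null) and n = 1,000 (coverage). These sizes give sampling error well
inside the asserted tolerances while keeping a full run of the suite in
the low minutes on one CPU.

## Known limitations

- GSVA's KDE-based scoring is deliberately not reimplemented; geometric
  means are used uniformly for every gene set (a documented deviation —
  the two scores are monotonically related on typical data but not equal).
- No batch correction, cross-cohort calibration, consensus clustering or
  cluster-stability bootstrap.
- Microenvironment scores (purity/immune/stromal) and PPI edges are
  consumed as inputs, never computed.
- The index formulas are a reconstruction; λ and the outlier policy are
  the two knobs whose published values are uncertain, and both are
  surfaced in the public API rather than buried.
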