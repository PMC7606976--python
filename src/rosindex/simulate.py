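"""Synthetic cohort generator with the statistical structure the pipeline assumes.

The generator plants, per sample, five latent redox programs

    B  biosynthesis        S  scavenging        R  oxidative stress
    M  mitochondrial source                     C  cytoplasmic source

(i.i.d. standard normal in the correlation-structure cohort) plus a derived
accumulation latent

    A = B - w*S + eps,        eps ~ Normal(0, sigma2),

with w = 0.5 and sigma2 = 0.274 by default, which fixes the planted
accumulation-biosynthesis correlation at 1/sqrt(1 + w^2 + sigma2) ~ 0.810.

Genes are emitted log-normally around their category's program:

    x_gs = exp( mu_g + loading * L_k(s) + Normal(0, gene_noise_sd^2) ).

The accumulation latent drives no genes of its own; it is only recoverable
through the index-I formula.  For A to be recoverable at all, the
disturbance eps must leave a transcriptional trace, so the *measured*
scavenging program carries a redox-feedback term:

    S_prog = S - eps / w,

i.e. scavenger transcription is read low when accumulation runs above what
biosynthesis and scavenging alone predict.  Then index I = B - w*S_prog = A
exactly, and the computed index correlations reproduce the planted ones
(r(I, IV) ~ 0.81, r(III, IV) = 0).

Planted cohort structures (one per cohort, not mixed -- superimposing both
in the same coordinates would destroy both recoveries):

* ``archetypes`` -- 8 cluster centroids in 5-dim index space with isotropic
  per-dimension noise; because computed index I is functionally
  IV - w*III, the I-coordinate of a centroid is realized through the
  formula rather than planted independently.
* ``groups`` -- 22 cancer types drawn from 5 template mean profiles; each
  type's profile is template + noise, samples scatter around their type.

Survival is exponential with log-hazard linear in the true indexes with
cancer-type-specific coefficients and fixed-horizon censoring.  Drug
response is ln IC50 linear in one driving index per drug, with a planted
fraction of null drugs.  Omics features are cluster-enriched Bernoulli
(mutations), categorical amp/del calls (CNV) and mean-shifted Gaussians
(miRNA/GO-like continuous scores).

All draws flow from a single ``numpy`` Generator seeded by the config, so
identical config + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneSet, GeneSetCollection, REQUIRED_CATEGORIES, ValidationError
from .scoring import INDEX_COLUMNS

#: Default 8 cluster archetypes (rows) in index space (I, II, III, IV, V).
DEFAULT_ARCHETYPES = np.array(
    [
        [2, 0, -1, 2, 0],    # high accumulation, enhanced biosynthesis
        [0, 2, 0, 0, 0],     # elevated oxidative stress
        [0, 0, 0, 0, 0],     # baseline metabolism
        [-1, 0, 2, 0, 0],    # reinforced scavenging
        [-2, -1, -1, -1, 0], # globally low ROS metabolism
        [0, -2, 0, 1, -1],   # low stress, cytoplasmic source
        [0, 0, 0, 0, 2],     # mitochondria-derived ROS
        [1, 1, 1, -1, 1],    # mixed high-turnover phenotype
    ],
    dtype=float,
)

#: Default 5 cancer-type group templates (rows) in index space.
DEFAULT_GROUP_TEMPLATES = np.array(
    [
        [0, 1.5, 0, 0, 0],      # elevated oxidative stress
        [0, 0, 1.5, 0, 0],      # increased scavenging
        [2, 0, -0.5, 2, 0],     # high accumulation / generation (CNS-like)
        [-1.5, -1, -1, -1, 0],  # low ROS metabolism
        [0, 0, 0, 0, 0],        # moderate
    ],
    dtype=float,
)

#: Number of cancer types assigned to each group template (22 types total).
DEFAULT_GROUP_SIZES = (6, 6, 2, 4, 4)

_CATEGORY_PREFIX = {
    "biosynthesis": "BIO",
    "scavenging": "SCAV",
    "stress_response": "STRESS",
    "mito_source": "MITO",
    "cyto_source": "CYTO",
}

#: Which latent program drives the genes of each category.
_CATEGORY_PROGRAM = {
    "biosynthesis": "B",
    "scavenging": "S_prog",
    "stress_response": "R",
    "mito_source": "M",
    "cyto_source": "C",
}

ROMAN = ("I", "II", "III", "IV", "V")


@dataclass
class SyntheticConfig:
    """All planted parameters of the generator (defaults = study conditions)."""

    seed: int = 13
    n_samples: int = 2000

    # expression model
    genes_per_category: int = 200
    sets_per_category: int = 2
    gene_loading: float = 1.0
    gene_noise_sd: float = 0.5
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 0.5

    # latent model
    accumulation_noise_var: float = 0.274
    scavenging_weight: float = 0.5

    # archetype (cluster) cohort
    archetype_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_ARCHETYPES.copy()
    )
    archetype_noise_sd: float = 0.4
    samples_per_archetype: int = 400

    # cancer-type group cohort
    group_templates: np.ndarray = field(
        default_factory=lambda: DEFAULT_GROUP_TEMPLATES.copy()
    )
    group_sizes: tuple = DEFAULT_GROUP_SIZES
    template_noise_sd: float = 0.2
    group_within_sd: float = 1.0
    samples_per_type: int = 100

    # survival model
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    censor_horizon: float = 3000.0  # days
    survival_beta_scale: float = 0.5
    survival_betas: Mapping[str, Sequence[float]] | None = None

    # drug panel (GDSC-like: 251 drugs x 1,066 cell lines)
    n_cell_lines: int = 1066
    n_drugs: int = 251
    n_effective_drugs: int = 204
    drug_slope: float = 0.5
    drug_noise_sd: float = 1.0
    drug_intercept_mean: float = 2.0
    drug_intercept_sd: float = 1.0
    max_screen_conc_ln: float = 3.0  # ln uM

    # omics layers
    n_mut_features: int = 50
    mut_p_high: float = 0.5
    mut_p_low: float = 0.05
    n_cnv_loci: int = 30
    cnv_freq_high: float = 0.2
    cnv_freq_low: float = 0.02
    n_cont_features: int = 40
    cont_shift: float = 1.0

    def __post_init__(self) -> None:
        self.archetype_matrix = np.asarray(self.archetype_matrix, dtype=float)
        self.group_templates = np.asarray(self.group_templates, dtype=float)
        for name in ("gene_noise_sd", "baseline_log_sd", "archetype_noise_sd",
                     "template_noise_sd", "group_within_sd", "drug_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.accumulation_noise_var < 0:
            raise ValidationError("accumulation_noise_var must be >= 0")
        if self.scavenging_weight < 0:
            raise ValidationError("scavenging_weight must be >= 0")
        k, d = self.archetype_matrix.shape
        if d != 5:
            raise ValidationError("archetype matrix must have 5 columns")
        for i in range(k):
            for j in range(i + 1, k):
                dist = np.linalg.norm(
                    self.archetype_matrix[i] - self.archetype_matrix[j]
                )
                if dist < 2 - 1e-9:
                    raise ValidationError(
                        f"archetype rows {i} and {j} closer than 2 ({dist:.3f})"
                    )
        if sum(self.group_sizes) != 22:
            raise ValidationError("group sizes must cover 22 cancer types")
        if len(self.group_sizes) != self.group_templates.shape[0]:
            raise ValidationError("one group size per template row required")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# closed forms documented by the generator (used by docs and property tests)

def expected_accumulation_biosynthesis_corr(config: SyntheticConfig) -> float:
    """Analytic Pearson corr(A, B) = 1/sqrt(1 + w^2 + sigma2)."""
    w, s2 = config.scavenging_weight, config.accumulation_noise_var
    return 1.0 / np.sqrt(1.0 + w * w + s2)


def expected_index_attenuation(config: SyntheticConfig) -> float:
    """Analytic corr(computed category score, its driving program).

    The category score averages gene_noise over genes_per_category genes,
    attenuating the correlation by 1/sqrt(1 + noise_var/(loading^2 * n)).
    """
    noise = config.gene_noise_sd**2 / (
        config.gene_loading**2 * config.genes_per_category
    )
    return 1.0 / np.sqrt(1.0 + noise)


# ---------------------------------------------------------------------------
# latents

def _finish_latents(df: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Add derived columns A and the realizable true indexes."""
    w = config.scavenging_weight
    df["A"] = df["B"] - w * df["S"] + df["eps"]
    df["index_I"] = df["B"] - w * df["S_prog"]
    df["index_II"] = df["R"]
    df["index_III"] = df["S_prog"]
    df["index_IV"] = df["B"]
    df["index_V"] = df["M"] - df["C"]
    return df


def simulate_latents(
    config: SyntheticConfig,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw i.i.d.-mode latents (the correlation-structure cohort).

    Columns: B, S, R, M, C (i.i.d. N(0,1)), eps, A = B - w*S + eps,
    S_prog = S - eps/w (the measured scavenging program; equal to S when
    w = 0, in which case eps leaves no trace), and the true index
    coordinates index_I..index_V the pipeline can recover.
    """
    n = n_samples if n_samples is not None else config.n_samples
    rng = rng if rng is not None else config.rng()
    w = config.scavenging_weight
    cols = {k: rng.standard_normal(n) for k in ("B", "S", "R", "M", "C")}
    eps = rng.standard_normal(n) * np.sqrt(config.accumulation_noise_var)
    df = pd.DataFrame(cols, index=_sample_ids(n))
    df["eps"] = eps
    df["S_prog"] = df["S"] - (eps / w if w > 0 else 0.0)
    return _finish_latents(df, config)


def _sample_ids(n: int, prefix: str = "S") -> pd.Index:
    width = max(4, len(str(n)))
    return pd.Index([f"{prefix}{i + 1:0{width}d}" for i in range(n)], name="sample")


def _latents_from_index_targets(
    targets: np.ndarray, index: pd.Index, config: SyntheticConfig
) -> pd.DataFrame:
    """Back out gene programs from 5-dim index-space targets.

    Only four coordinates are free (the programs S_prog, R, B and the M-C
    split); computed index I is always B - w*S_prog.  A target is realized
    by honoring its I-coordinate exactly -- I is the design's headline
    accumulation axis -- and choosing the biosynthesis/scavenging programs
    closest (least squares) to the target's III and IV coordinates under
    that constraint:

        delta  = t_I - (t_IV - w*t_III)
        B      = t_IV  + delta / (1 + w^2)
        S_prog = t_III - w*delta / (1 + w^2)

    which keeps the default archetype rows at pairwise distance >= 2 after
    realization.
    """
    w = config.scavenging_weight
    t1, t2, t3, t4, t5 = (targets[:, j] for j in range(5))
    delta = t1 - (t4 - w * t3)
    df = pd.DataFrame(index=index)
    df["B"] = t4 + delta / (1.0 + w * w)
    df["S_prog"] = t3 - w * delta / (1.0 + w * w)
    df["S"] = df["S_prog"]
    df["R"] = t2
    df["M"] = t5 / 2.0
    df["C"] = -t5 / 2.0
    df["eps"] = 0.0
    return _finish_latents(df, config)


def simulate_archetype_latents(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Archetype-mode latents: 8 planted clusters in index space.

    Returns the latent table with a 1-based ``cluster`` column.
    """
    rng = rng if rng is not None else config.rng()
    k = config.archetype_matrix.shape[0]
    labels = np.repeat(np.arange(1, k + 1), config.samples_per_archetype)
    targets = config.archetype_matrix[labels - 1] + rng.normal(
        0.0, config.archetype_noise_sd, size=(len(labels), 5)
    )
    df = _latents_from_index_targets(targets, _sample_ids(len(labels)), config)
    df["cluster"] = labels
    return df


def type_names(n: int = 22) -> list[str]:
    return [f"CT{i + 1:02d}" for i in range(n)]


def simulate_type_profiles(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw the 22 cancer-type mean index profiles from the 5 templates.

    Returns (profiles: 22 x 5 DataFrame, true group labels per type).
    """
    rng = rng if rng is not None else config.rng()
    groups = np.concatenate(
        [np.full(size, g + 1) for g, size in enumerate(config.group_sizes)]
    )
    names = type_names(len(groups))
    profiles = config.group_templates[groups - 1] + rng.normal(
        0.0, config.template_noise_sd, size=(len(groups), 5)
    )
    prof = pd.DataFrame(profiles, index=pd.Index(names, name="cancer_type"),
                        columns=list(INDEX_COLUMNS))
    return prof, pd.Series(groups, index=prof.index, name="group")


def simulate_group_latents(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Group-mode latents: samples scatter around their cancer type's profile.

    Returns (latent table with a ``cancer_type`` column, type -> group truth).
    """
    rng = rng if rng is not None else config.rng()
    profiles, groups = simulate_type_profiles(config, rng)
    n_types = len(profiles)
    labels = np.repeat(np.arange(n_types), config.samples_per_type)
    targets = profiles.to_numpy()[labels] + rng.normal(
        0.0, config.group_within_sd, size=(len(labels), 5)
    )
    df = _latents_from_index_targets(targets, _sample_ids(len(labels)), config)
    df["cancer_type"] = np.asarray(profiles.index)[labels]
    return df, groups


# ---------------------------------------------------------------------------
# expression

def make_collection(config: SyntheticConfig) -> GeneSetCollection:
    """Build the generator's gene-set collection (synthetic gene symbols)."""
    sets: list[GeneSet] = []
    for cat in REQUIRED_CATEGORIES:
        prefix = _CATEGORY_PREFIX[cat]
        genes = [f"{prefix}_G{i + 1:04d}" for i in range(config.genes_per_category)]
        chunks = np.array_split(np.array(genes), config.sets_per_category)
        for j, chunk in enumerate(chunks, start=1):
            sets.append(
                GeneSet(
                    name=f"{prefix}_SET{j}",
                    category=cat,
                    genes=tuple(chunk.tolist()),
                )
            )
    return GeneSetCollection(sets=sets, provenance="rosindex synthetic collection")


def simulate_expression(
    latents: pd.DataFrame,
    collection: GeneSetCollection,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emit a linear-scale genes x samples expression matrix.

    Every gene of category k is log-normal around its baseline plus
    ``gene_loading`` times the category's program value in that sample.
    """
    rng = rng if rng is not None else config.rng()
    n = len(latents)
    gene_rows: list[str] = []
    programs: list[str] = []
    for cat in REQUIRED_CATEGORIES:
        cat_sets = collection.by_category(cat)
        if not cat_sets:
            raise ValidationError(f"collection has no {cat} sets")
        seen: set[str] = set()
        for s in cat_sets:
            for g in s.genes:
                if g not in seen:
                    seen.add(g)
                    gene_rows.append(g)
                    programs.append(_CATEGORY_PROGRAM[cat])
    L = latents[programs].to_numpy(dtype=float).T  # genes x samples
    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                    size=len(gene_rows))
    noise = rng.normal(0.0, config.gene_noise_sd, size=(len(gene_rows), n))
    log_x = mu[:, None] + config.gene_loading * L + noise
    expr = pd.DataFrame(np.exp(log_x), index=pd.Index(gene_rows, name="gene"),
                        columns=latents.index)
    return expr


# ---------------------------------------------------------------------------
# survival

def default_survival_betas(config: SyntheticConfig,
                           types: Sequence[str]) -> dict[str, np.ndarray]:
    """One driving index per cancer type, alternating sign across types."""
    betas: dict[str, np.ndarray] = {}
    for i, t in enumerate(sorted(types)):
        beta = np.zeros(5)
        sign = 1.0 if (i // 5) % 2 == 0 else -1.0
        beta[i % 5] = sign * config.survival_beta_scale
        betas[t] = beta
    return betas


def simulate_survival(
    true_indexes: pd.DataFrame,
    cancer_type: pd.Series,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    betas: Mapping[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Exponential survival with log-hazard linear in the true indexes.

    Censoring is administrative at ``censor_horizon``.  Returns a clinical
    frame (sample index; cancer_type, time, event).
    """
    rng = rng if rng is not None else config.rng()
    if betas is None:
        betas = config.survival_betas or default_survival_betas(
            config, cancer_type.unique()
        )
    bmat = np.vstack([np.asarray(betas[t], dtype=float)
                      for t in cancer_type.to_numpy()])
    lp = (true_indexes.to_numpy() * bmat).sum(axis=1)
    rate = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    time = np.minimum(t_event, config.censor_horizon)
    event = (t_event <= config.censor_horizon).astype(int)
    return pd.DataFrame(
        {"cancer_type": cancer_type.to_numpy(), "time": time, "event": event},
        index=true_indexes.index,
    )


# ---------------------------------------------------------------------------
# cohort bundles

@dataclass
class CohortBundle:
    """Everything one synthetic cohort provides, truth included."""

    expression: pd.DataFrame
    collection: GeneSetCollection
    clinical: pd.DataFrame
    latents: pd.DataFrame
    true_indexes: pd.DataFrame
    cluster_labels: pd.Series | None = None
    type_groups: pd.Series | None = None
    config: SyntheticConfig | None = None


def simulate_cohort(
    config: SyntheticConfig,
    structure: str = "archetypes",
    rng: np.random.Generator | None = None,
) -> CohortBundle:
    """Generate a full cohort: expression + clinical + planted truth.

    structure:
        ``archetypes`` -- 8 planted index-space clusters (cancer types
        assigned independently of cluster);
        ``groups`` -- 22 cancer types from 5 planted group templates;
        ``iid`` -- unstructured latents (the correlation-structure cohort).
    """
    rng = rng if rng is not None else config.rng()
    type_groups: pd.Series | None = None
    cluster_labels: pd.Series | None = None

    if structure == "archetypes":
        latents = simulate_archetype_latents(config, rng)
        cluster_labels = latents["cluster"].astype(int)
        ctypes = pd.Series(
            rng.choice(type_names(), size=len(latents)),
            index=latents.index, name="cancer_type",
        )
    elif structure == "groups":
        latents, type_groups = simulate_group_latents(config, rng)
        ctypes = latents["cancer_type"]
    elif structure == "iid":
        latents = simulate_latents(config, rng=rng)
        ctypes = pd.Series(
            rng.choice(type_names(), size=len(latents)),
            index=latents.index, name="cancer_type",
        )
    else:
        raise ValidationError(f"unknown cohort structure {structure!r}")

    true_idx = latents[list(INDEX_COLUMNS)].copy()
    collection = make_collection(config)
    expression = simulate_expression(latents, collection, config, rng)
    clinical = simulate_survival(true_idx, ctypes, config, rng)
    return CohortBundle(
        expression=expression,
        collection=collection,
        clinical=clinical,
        latents=latents,
        true_indexes=true_idx,
        cluster_labels=cluster_labels,
        type_groups=type_groups,
        config=config,
    )


# ---------------------------------------------------------------------------
# drug panel

@dataclass
class DrugPanelBundle:
    """Synthetic GDSC-like screen: cell-line expression + responses + truth."""

    expression: pd.DataFrame
    collection: GeneSetCollection
    responses: pd.DataFrame  # cell lines x drugs, ln IC50 (ln uM)
    drug_meta: pd.DataFrame  # per drug: target, max_screen_conc, truth
    latents: pd.DataFrame
    true_indexes: pd.DataFrame


def simulate_drug_panel(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> DrugPanelBundle:
    """ln IC50_{d,c} = a_d + b_d * z(index_{j(d)}(c)) + noise.

    The first ``n_effective_drugs`` drugs cycle their driving index through
    I..V with alternating slope sign; the rest are null (b_d = 0).  AUC is a
    monotone decreasing logistic transform of ln IC50.
    """
    rng = rng if rng is not None else config.rng()
    latents = simulate_latents(config, n_samples=config.n_cell_lines, rng=rng)
    latents.index = _sample_ids(config.n_cell_lines, prefix="CL")
    true_idx = latents[list(INDEX_COLUMNS)].copy()
    z = (true_idx - true_idx.mean()) / true_idx.std(ddof=0)

    collection = make_collection(config)
    expression = simulate_expression(latents, collection, config, rng)

    drugs = [f"DRUG{i + 1:03d}" for i in range(config.n_drugs)]
    meta_rows = []
    resp = np.empty((config.n_cell_lines, config.n_drugs))
    intercepts = rng.normal(config.drug_intercept_mean, config.drug_intercept_sd,
                            size=config.n_drugs)
    for d in range(config.n_drugs):
        effective = d < config.n_effective_drugs
        idx_j = d % 5 if effective else -1
        slope = 0.0
        if effective:
            slope = config.drug_slope * (1.0 if d % 2 == 0 else -1.0)
        driver = z.iloc[:, idx_j].to_numpy() if effective else 0.0
        resp[:, d] = (
            intercepts[d]
            + slope * driver
            + rng.normal(0.0, config.drug_noise_sd, size=config.n_cell_lines)
        )
        meta_rows.append(
            {
                "drug": drugs[d],
                "target": f"TGT_{ROMAN[idx_j]}" if effective else "TGT_NULL",
                "max_screen_conc": config.max_screen_conc_ln,
                "true_index": f"index_{ROMAN[idx_j]}" if effective else "",
                "true_slope": slope,
            }
        )
    responses = pd.DataFrame(resp, index=latents.index, columns=drugs)
    drug_meta = pd.DataFrame(meta_rows).set_index("drug")
    return DrugPanelBundle(
        expression=expression,
        collection=collection,
        responses=responses,
        drug_meta=drug_meta,
        latents=latents,
        true_indexes=true_idx,
    )


def auc_from_ic50(ln_ic50: pd.DataFrame, max_conc_ln: float) -> pd.DataFrame:
    """Monotone decreasing transform of ln IC50 onto (0, 1)."""
    return 1.0 / (1.0 + np.exp(ln_ic50 - max_conc_ln))


# ---------------------------------------------------------------------------
# omics features

@dataclass
class OmicsBundle:
    mutations: pd.DataFrame  # features x samples, 0/1
    cnv: pd.DataFrame        # loci x samples, {"amp", "del", "neutral"}
    continuous: pd.DataFrame # features x samples, float
    truth: dict


def simulate_omics_features(
    cluster_labels: pd.Series,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> OmicsBundle:
    """Cluster-enriched binary, CNV-call and continuous feature layers.

    One planted feature per cluster and layer; remaining features are null.
    Planted CNV frequencies straddle the 10% characteristic-CNV rule
    (``cnv_freq_high`` above it, ``cnv_freq_low`` below).
    """
    rng = rng if rng is not None else config.rng()
    samples = cluster_labels.index
    labels = cluster_labels.to_numpy()
    clusters = sorted(pd.unique(labels).tolist())
    n = len(samples)

    def planted_name(layer: str, k) -> str:
        return f"{layer}_C{k}"

    # mutations
    mut_rows, mut_names = [], []
    for k in clusters:
        p = np.where(labels == k, config.mut_p_high, config.mut_p_low)
        mut_rows.append(rng.random(n) < p)
        mut_names.append(planted_name("MUT", k))
    for j in range(max(0, config.n_mut_features - len(clusters))):
        mut_rows.append(rng.random(n) < config.mut_p_low)
        mut_names.append(f"MUT_NULL{j + 1:03d}")
    mutations = pd.DataFrame(
        np.asarray(mut_rows, dtype=int), index=mut_names, columns=samples
    )

    # CNV calls: planted amp per cluster, plus null loci
    cnv_rows, cnv_names = [], []
    for k in clusters:
        p = np.where(labels == k, config.cnv_freq_high, config.cnv_freq_low)
        calls = np.where(rng.random(n) < p, "amp", "neutral")
        cnv_rows.append(calls)
        cnv_names.append(planted_name("CNV_AMP", k))
    for j in range(max(0, config.n_cnv_loci - len(clusters))):
        draw = rng.random(n)
        calls = np.where(draw < config.cnv_freq_low, "del", "neutral")
        cnv_rows.append(calls)
        cnv_names.append(f"CNV_NULL{j + 1:03d}")
    cnv = pd.DataFrame(np.asarray(cnv_rows), index=cnv_names, columns=samples)

    # continuous (miRNA/GO-like) features
    cont_rows, cont_names = [], []
    for k in clusters:
        shift = np.where(labels == k, config.cont_shift, 0.0)
        cont_rows.append(shift + rng.standard_normal(n))
        cont_names.append(planted_name("FT", k))
    for j in range(max(0, config.n_cont_features - len(clusters))):
        cont_rows.append(rng.standard_normal(n))
        cont_names.append(f"FT_NULL{j + 1:03d}")
    continuous = pd.DataFrame(
        np.asarray(cont_rows), index=cont_names, columns=samples
    )

    truth = {
        "planted_mutations": {k: planted_name("MUT", k) for k in clusters},
        "planted_cnv": {k: planted_name("CNV_AMP", k) for k in clusters},
        "planted_continuous": {k: planted_name("FT", k) for k in clusters},
    }
    return OmicsBundle(mutations=mutations, cnv=cnv, continuous=continuous,
                       truth=truth)
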