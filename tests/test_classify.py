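"""Hierarchical reclassification, k selection, composition and embedding."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from rosindex import classify as cl
from rosindex import io, scoring as sc
from rosindex import simulate as sim


def frame_of(X):
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(
        X, columns=list(sc.INDEX_COLUMNS)[: X.shape[1]],
        index=[f"s{i}" for i in range(len(X))],
    )


def blobs(centers, n_per, noise, seed=0):
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    rows, labels = [], []
    for k, c in enumerate(centers, start=1):
        rows.append(c + rng.normal(0, noise, size=(n_per, len(c))))
        labels += [k] * n_per
    return frame_of(np.vstack(rows)), np.array(labels)


def brute_force_ari(a, b):
    """ARI from the contingency table, straight from the definition."""
    from math import comb

    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ct = pd.crosstab(a, b).to_numpy()
    sum_comb = sum(comb(int(x), 2) for x in ct.ravel())
    sum_a = sum(comb(int(x), 2) for x in ct.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in ct.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)


class TestHierarchicalCluster:
    def test_two_point_masses_split_perfectly(self):
        X, labels = blobs([[0] * 5, [10] * 5], n_per=20, noise=0.1)
        a = cl.hierarchical_cluster(X, k=2)
        assert adjusted_rand_score(labels, a.labels) == 1.0

    def test_k_equals_n_gives_singletons(self):
        X, _ = blobs([[0] * 5], n_per=6, noise=1.0)
        a = cl.hierarchical_cluster(X, k=6)
        assert a.labels.nunique() == 6

    def test_k_above_n_rejected(self):
        X, _ = blobs([[0] * 5], n_per=4, noise=1.0)
        with pytest.raises(io.ValidationError):
            cl.hierarchical_cluster(X, k=5)

    def test_permutation_equivariant(self):
        X, _ = blobs([[0] * 5, [4] * 5, [-4] * 5], n_per=30, noise=0.5, seed=3)
        a1 = cl.hierarchical_cluster(X, k=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(X))
        a2 = cl.hierarchical_cluster(X.iloc[perm], k=3)
        parts1 = {frozenset(a1.labels.index[a1.labels == k])
                  for k in a1.labels.unique()}
        parts2 = {frozenset(a2.labels.index[a2.labels == k])
                  for k in a2.labels.unique()}
        assert parts1 == parts2

    def test_archetype_cohort_recovery(self, archetype_cohort):
        bundle = archetype_cohort["bundle"]
        a = cl.hierarchical_cluster(archetype_cohort["table"], k=8)
        ari = adjusted_rand_score(bundle.cluster_labels, a.labels)
        assert ari >= 0.9

    def test_ari_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, size=60)
            b = rng.integers(0, 3, size=60)
            assert adjusted_rand_score(a, b) == pytest.approx(
                brute_force_ari(a, b), abs=1e-12
            )


class TestSelectK:
    def test_two_blobs(self):
        X, _ = blobs([[0] * 5, [6] * 5], n_per=40, noise=0.5, seed=1)
        assert cl.select_k(X, k_range=range(2, 8)).k == 2

    # subsets of the default archetype rows with comfortable pairwise
    # separation (>= 2.8); silhouette merges pairs sitting exactly at the
    # generator's minimum-separation bound when k is small
    SUBSETS = {2: [0, 4], 3: [0, 3, 6], 5: [0, 1, 3, 4, 6], 8: list(range(8))}

    @pytest.mark.parametrize("planted_k", [2, 3, 5, 8])
    def test_recovers_planted_k(self, planted_k):
        centers = sim.DEFAULT_ARCHETYPES[self.SUBSETS[planted_k]]
        hits = 0
        reps = 10
        for i in range(reps):
            X, _ = blobs(centers, n_per=60, noise=0.4, seed=1000 * planted_k + i)
            hits += cl.select_k(X, k_range=range(2, 13)).k == planted_k
        assert hits >= int(0.9 * reps)

    def test_single_blob_flags_low_confidence(self):
        X, _ = blobs([[0] * 5], n_per=120, noise=1.0, seed=5)
        with pytest.warns(UserWarning, match="weak cluster structure"):
            a = cl.select_k(X, k_range=range(2, 8))
        assert a.low_confidence
        assert a.selection_trace["silhouette"].max() < cl.LOW_CONFIDENCE_SILHOUETTE

    def test_trace_covers_requested_range(self):
        X, _ = blobs([[0] * 5, [6] * 5], n_per=30, noise=0.5)
        a = cl.select_k(X, k_range=range(2, 6))
        assert list(a.selection_trace["k"]) == [2, 3, 4, 5]


class TestClusterComposition:
    def assignment_of(self, labels):
        s = pd.Series(labels, index=[f"s{i}" for i in range(len(labels))],
                      name="cluster")
        return cl.ClusterAssignment(labels=s, k=s.max(), linkage="ward",
                                    metric="euclidean")

    def test_pure_cluster_homogeneity_one(self):
        a = self.assignment_of([1, 1, 1])
        ann = pd.Series(["glioma"] * 3, index=a.labels.index)
        _, hom = cl.cluster_composition(a, ann)
        assert hom.loc[1] == 1.0

    def test_dominant_fraction(self):
        a = self.assignment_of([1] * 100)
        ann = pd.Series(["glioma"] * 79 + ["other"] * 21, index=a.labels.index)
        comp, hom = cl.cluster_composition(a, ann)
        assert hom.loc[1] == pytest.approx(0.79)
        glioma = comp[(comp["cluster"] == 1) & (comp["annotation"] == "glioma")]
        assert glioma["fraction"].iloc[0] == pytest.approx(0.79)

    def test_missing_annotation_rejected(self):
        a = self.assignment_of([1, 1])
        ann = pd.Series(["x"], index=["s0"])
        with pytest.raises(io.ValidationError):
            cl.cluster_composition(a, ann)


class TestGroupCancerTypes:
    def test_recovers_planted_templates(self):
        cfg = sim.SyntheticConfig(seed=31, samples_per_type=100)
        lat, groups = sim.simulate_group_latents(cfg)
        table = lat[list(sc.INDEX_COLUMNS)]
        ga = cl.group_cancer_types(table, lat["cancer_type"], g=None)
        assert ga.g == 5
        assert adjusted_rand_score(groups.loc[ga.groups.index], ga.groups) >= 0.9

    def test_single_type_mean_is_identity(self):
        X, _ = blobs([[1, 2, 3, 4, 5]], n_per=1, noise=0.0)
        X2 = pd.concat([X, X + 4])
        X2.index = ["a", "b"]
        ctype = pd.Series(["T1", "T2"], index=X2.index)
        ga = cl.group_cancer_types(X2, ctype, g=2)
        assert np.allclose(ga.type_means.loc["T1"], X2.loc["a"])

    def test_identical_means_warn_single_group(self):
        X = frame_of(np.tile([1.0, 2, 3, 4, 5], (6, 1)))
        ctype = pd.Series(["A", "A", "B", "B", "C", "C"], index=X.index)
        with pytest.warns(UserWarning, match="identical"):
            ga = cl.group_cancer_types(X, ctype, g=2)
        assert ga.g == 1


class TestDensitySummary:
    def test_archetype_cluster_signature(self, archetype_cohort):
        bundle = archetype_cohort["bundle"]
        a = cl.ClusterAssignment(
            labels=bundle.cluster_labels, k=8, linkage="ward", metric="euclidean"
        )
        summary = cl.index_density_summary(archetype_cohort["table"], a)
        c1 = summary[summary["cluster"] == 1].set_index("index")
        # archetype 1 = high accumulation/biosynthesis, low scavenging
        assert c1.loc["index_I", "mean"] > 0
        assert c1.loc["index_IV", "mean"] > 0
        assert c1.loc["index_III", "mean"] < 0

    def test_pooled_mean_identity(self):
        X, labels = blobs([[0] * 5, [3] * 5], n_per=10, noise=0.7, seed=2)
        s = pd.Series(labels, index=X.index, name="cluster")
        a = cl.ClusterAssignment(labels=s, k=2, linkage="ward", metric="euclidean")
        summary = cl.index_density_summary(X, a)
        for col in X.columns:
            sub = summary[summary["index"] == col]
            pooled = (sub["mean"] * sub["n"]).sum() / sub["n"].sum()
            assert pooled == pytest.approx(X[col].mean(), abs=1e-12)

    def test_constant_input_zero_sd(self):
        X = frame_of(np.ones((12, 5)))
        s = pd.Series([1] * 6 + [2] * 6, index=X.index, name="cluster")
        a = cl.ClusterAssignment(labels=s, k=2, linkage="ward", metric="euclidean")
        summary = cl.index_density_summary(X, a)
        assert (summary["sd"] == 0).all()


class TestEmbed2D:
    def test_three_points_distinct_finite(self):
        X = frame_of([[0] * 5, [5] * 5, [-5] * 5])
        coords = cl.embed_2d(X, seed=0)
        assert coords.shape == (3, 2)
        assert np.isfinite(coords.to_numpy()).all()
        assert len({tuple(r) for r in coords.to_numpy().round(6)}) == 3

    def test_deterministic_under_seed(self):
        X, _ = blobs([[0] * 5, [5] * 5], n_per=20, noise=0.3, seed=9)
        c1 = cl.embed_2d(X, seed=42)
        c2 = cl.embed_2d(X, seed=42)
        pd.testing.assert_frame_equal(c1, c2)

    def test_separated_blobs_stay_separated(self):
        X, labels = blobs([[0] * 5, [8] * 5, [-8] * 5], n_per=40, noise=0.4, seed=4)
        coords = cl.embed_2d(X, seed=1).to_numpy()
        centroids = np.array([coords[labels == k].mean(axis=0) for k in (1, 2, 3)])
        intra = np.mean(
            [
                np.linalg.norm(coords[labels == k] - centroids[k - 1], axis=1).mean()
                for k in (1, 2, 3)
            ]
        )
        inter = np.mean(
            [
                np.linalg.norm(centroids[i] - centroids[j])
                for i in range(3) for j in range(i + 1, 3)
            ]
        )
        assert inter > intra
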