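"""Geometric-mean scoring, index construction and outlier trimming."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rosindex import io, scoring as sc
from rosindex.simulate import SyntheticConfig, make_collection


def expr_of(values, genes=None, samples=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


def five_category_collection(n_genes=2):
    sets = []
    for cat in io.REQUIRED_CATEGORIES:
        genes = tuple(f"{cat[:3].upper()}{i}" for i in range(n_genes))
        sets.append(io.GeneSet(name=f"{cat}_set", category=cat, genes=genes))
    return io.GeneSetCollection(sets=sets)


class TestGeometricMeanScore:
    def test_two_genes(self):
        e = expr_of([[1.0], [4.0]])
        s = sc.geometric_mean_score(e, ["G0", "G1"], pseudocount=1e-300)
        assert s.iloc[0] == pytest.approx(2.0)

    def test_three_genes(self):
        e = expr_of([[2.0], [8.0], [4.0]])
        s = sc.geometric_mean_score(e, ["G0", "G1", "G2"], pseudocount=1e-300)
        assert s.iloc[0] == pytest.approx(4.0)

    def test_zero_with_pseudocount(self):
        e = expr_of([[0.0], [1.0]])
        s = sc.geometric_mean_score(e, ["G0", "G1"], pseudocount=0.01)
        assert s.iloc[0] == pytest.approx(np.sqrt(0.01 * 1.01))

    def test_matches_naive_loop_oracle(self, rng):
        X = rng.gamma(2.0, 3.0, size=(20, 10))
        e = expr_of(X)
        eps = 0.01
        s = sc.geometric_mean_score(e, list(e.index), pseudocount=eps)
        for j, col in enumerate(e.columns):
            acc = 0.0
            for i in range(20):
                acc += np.log(X[i, j] + eps)
            assert s[col] == pytest.approx(np.exp(acc / 20), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(c=st.floats(0.1, 10.0), seed=st.integers(0, 10_000))
    def test_scale_equivariance(self, c, seed):
        X = np.random.default_rng(seed).gamma(2.0, 3.0, size=(6, 4)) + 0.1
        tiny = 1e-300  # effectively eps = 0 on strictly positive data
        s1 = sc.geometric_mean_score(expr_of(X), [f"G{i}" for i in range(6)], tiny)
        s2 = sc.geometric_mean_score(expr_of(c * X), [f"G{i}" for i in range(6)], tiny)
        assert np.allclose(s2, c * s1, rtol=1e-9)

    def test_empty_mapped_set_rejected(self):
        with pytest.raises(io.ValidationError):
            sc.geometric_mean_score(expr_of([[1.0]]), ["NOT_THERE"])

    def test_nan_rejected(self):
        e = expr_of([[np.nan]])
        with pytest.raises(io.ValidationError):
            sc.geometric_mean_score(e, ["G0"])


class TestCategoryScore:
    def test_single_set_identity(self):
        coll = io.GeneSetCollection(
            sets=[io.GeneSet(name="S", category="scavenging", genes=("G0", "G1"))]
        )
        e = expr_of([[1.0], [4.0]])
        cs = sc.category_score(e, coll, "scavenging", pseudocount=1e-300)
        gm = sc.geometric_mean_score(e, ["G0", "G1"], pseudocount=1e-300)
        assert cs.iloc[0] == pytest.approx(np.log(gm.iloc[0]))

    def test_mean_of_set_log_scores(self):
        # one set scoring 1, another scoring e^2 -> category log-score 1
        coll = io.GeneSetCollection(
            sets=[
                io.GeneSet(name="A", category="scavenging", genes=("G0",)),
                io.GeneSet(name="B", category="scavenging", genes=("G1",)),
            ]
        )
        e = expr_of([[1.0], [np.exp(2.0)]])
        cs = sc.category_score(e, coll, "scavenging", pseudocount=1e-300)
        assert cs.iloc[0] == pytest.approx(1.0)

    def test_global_scaling_shifts_by_log_c(self):
        coll = five_category_collection()
        genes = [g for s in coll for g in s.genes]
        X = np.random.default_rng(0).gamma(3.0, 2.0, size=(len(genes), 5)) + 0.5
        e = expr_of(X, genes=genes)
        c = 3.7
        for cat in io.REQUIRED_CATEGORIES:
            s1 = sc.category_score(e, coll, cat, pseudocount=1e-300)
            s2 = sc.category_score(e * c, coll, cat, pseudocount=1e-300)
            assert np.allclose(s2 - s1, np.log(c), atol=1e-9)

    def test_missing_category_rejected(self):
        coll = five_category_collection()
        e = expr_of([[1.0]], genes=["BIO0"])
        with pytest.raises(io.ValidationError):
            sc.category_score(e, io.GeneSetCollection(sets=[]), "scavenging")


class TestComputeIndexes:
    def make_cohort(self, n_samples=6, seed=0):
        coll = five_category_collection()
        genes = [g for s in coll for g in s.genes]
        X = np.random.default_rng(seed).gamma(3.0, 2.0,
                                              size=(len(genes), n_samples)) + 0.5
        return expr_of(X, genes=genes), coll

    def test_biosynthesis_scaling_moves_only_I_and_IV(self):
        e, coll = self.make_cohort()
        params = sc.IndexParams(pseudocount=1e-300, standardize=False)
        t0 = sc.compute_indexes(e, coll, params)
        e2 = e.copy()
        bio_genes = [g for s in coll.by_category("biosynthesis") for g in s.genes]
        e2.loc[bio_genes, "s0"] *= np.e
        t1 = sc.compute_indexes(e2, coll, params)
        d = (t1.values - t0.values).loc["s0"]
        assert d["index_IV"] == pytest.approx(1.0, abs=1e-9)
        assert d["index_I"] == pytest.approx(1.0, abs=1e-9)
        for col in ("index_II", "index_III", "index_V"):
            assert d[col] == pytest.approx(0.0, abs=1e-9)

    def test_global_scaling_with_unit_coupling_fixes_index_I(self):
        e, coll = self.make_cohort()
        params = sc.IndexParams(pseudocount=1e-300, scavenging_coupling=1.0,
                                standardize=False)
        t0 = sc.compute_indexes(e, coll, params)
        t1 = sc.compute_indexes(e * 5.0, coll, params)
        # index I = B - S and index V = M - C: common log-shifts cancel
        assert np.allclose(t1.values["index_I"], t0.values["index_I"], atol=1e-9)
        assert np.allclose(t1.values["index_V"], t0.values["index_V"], atol=1e-9)

    def test_standardized_moments(self):
        e, coll = self.make_cohort(n_samples=40)
        t = sc.compute_indexes(e, coll)
        assert np.allclose(t.values.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(t.values.std(axis=0, ddof=0), 1.0, atol=1e-6)

    def test_single_sample_standardization_rejected(self):
        e, coll = self.make_cohort(n_samples=1)
        with pytest.raises(io.ValidationError):
            sc.compute_indexes(e, coll)

    def test_monotone_in_biosynthesis_and_scavenging_genes(self):
        e, coll = self.make_cohort()
        params = sc.IndexParams(pseudocount=1e-300, standardize=False)
        t0 = sc.compute_indexes(e, coll, params)
        up_bio = e.copy()
        up_bio.loc["BIO0", "s1"] *= 4.0
        t_bio = sc.compute_indexes(up_bio, coll, params)
        assert t_bio.values.loc["s1", "index_I"] >= t0.values.loc["s1", "index_I"]
        assert t_bio.values.loc["s1", "index_IV"] >= t0.values.loc["s1", "index_IV"]
        up_scav = e.copy()
        up_scav.loc["SCA0", "s1"] *= 4.0
        t_sc = sc.compute_indexes(up_scav, coll, params)
        assert t_sc.values.loc["s1", "index_I"] <= t0.values.loc["s1", "index_I"]
        assert t_sc.values.loc["s1", "index_III"] >= t0.values.loc["s1", "index_III"]

    def test_recovers_planted_latents(self, iid_cohort):
        table = iid_cohort["table"]
        latents = iid_cohort["latents"]
        planted = {
            "index_I": latents["A"],
            "index_II": latents["R"],
            "index_III": latents["S_prog"],
            "index_IV": latents["B"],
            "index_V": latents["M"] - latents["C"],
        }
        for col, truth in planted.items():
            r = np.corrcoef(table.values[col], truth)[0, 1]
            assert r >= 0.95, f"{col}: r={r:.3f}"


class TestFilterOutliers:
    def table_from(self, values: np.ndarray) -> sc.IndexTable:
        df = pd.DataFrame(
            np.column_stack([values] + [np.linspace(-1, 1, len(values))] * 4),
            columns=list(sc.INDEX_COLUMNS),
        )
        # only index_I varies freely; the others are identical gentle ramps
        return sc.IndexTable(values=df.copy(), raw=df.copy(), standardized=False)

    def test_quantile_removes_exactly_ten_of_hundred(self):
        rng = np.random.default_rng(3)
        v = rng.permutation(100).astype(float)
        df = pd.DataFrame({c: v for c in sc.INDEX_COLUMNS})
        t = sc.IndexTable(values=df.copy(), raw=df.copy(), standardized=False)
        retained, removed = sc.filter_outliers(
            t, sc.OutlierParams(mode="quantile", tail_fraction=0.05)
        )
        assert len(removed) == 10
        assert len(retained) == 90

    def test_constant_index_fences_removes_nothing(self):
        df = pd.DataFrame({c: np.ones(20) for c in sc.INDEX_COLUMNS})
        t = sc.IndexTable(values=df.copy(), raw=df.copy(), standardized=False)
        retained, removed = sc.filter_outliers(t, sc.OutlierParams(mode="fences"))
        assert removed == []
        assert len(retained) == 20

    def test_union_over_independent_uniform_indexes(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            rng.uniform(size=(10_000, 5)), columns=list(sc.INDEX_COLUMNS)
        )
        t = sc.IndexTable(values=df.copy(), raw=df.copy(), standardized=False)
        retained, _ = sc.filter_outliers(
            t, sc.OutlierParams(mode="quantile", tail_fraction=0.05)
        )
        frac = len(retained) / 10_000
        assert frac == pytest.approx(0.9**5, abs=0.02)

    def test_fences_idempotent_on_gaussian_data(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            rng.standard_normal((500, 5)), columns=list(sc.INDEX_COLUMNS)
        )
        t = sc.IndexTable(values=df.copy(), raw=df.copy(), standardized=False)
        once, removed1 = sc.filter_outliers(t, sc.OutlierParams(mode="fences"))
        twice, removed2 = sc.filter_outliers(once, sc.OutlierParams(mode="fences"))
        assert removed2 == []
        assert list(twice.sample_ids) == list(once.sample_ids)

    def test_restandardizes_retained_samples(self, iid_cohort):
        retained, removed = sc.filter_outliers(iid_cohort["table"])
        assert len(removed) > 0
        assert np.allclose(retained.values.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(retained.values.std(axis=0, ddof=0), 1.0, atol=1e-6)

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({c: np.arange(5.0) for c in sc.INDEX_COLUMNS})
        t = sc.IndexTable(values=df.copy(), raw=df.copy(), standardized=False)
        with pytest.raises(io.ValidationError):
            sc.filter_outliers(t)


class TestIndexCorrelations:
    def test_reproduces_planted_structure(self, iid_cohort):
        corr = sc.index_correlations(iid_cohort["table"])
        assert corr.loc["index_I", "index_IV"] == pytest.approx(0.810, abs=0.03)
        assert abs(corr.loc["index_III", "index_IV"]) < 0.05

    def test_spearman_flag(self, iid_cohort):
        corr = sc.index_correlations(iid_cohort["table"], method="spearman")
        assert corr.loc["index_I", "index_IV"] > 0.7
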