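"""Harmonization pipeline: transforms, imputation, normalization, PCA, tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from decaykit import compendium as cp


def meta(sid, study="s1", species="human", ct="HeLa", method="4sU",
         unit="hours", rate=False):
    return cp.SampleMeta(sid, study, species, ct, method,
                         unit=unit, is_degradation_rate=rate)


def to_stage(df, samples, stage):
    return cp.HalfLifeMatrix(values=df, samples=samples, stage=stage)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_pseudocount_forces_exact_zero_for_point_nine_hours(self):
        table = pd.DataFrame({"a": [0.9]}, index=["g1"])
        m = cp.preprocess_halflives(table, [meta("a", unit="hours")])
        assert m.values.loc["g1", "a"] == 0.0

    @pytest.mark.parametrize(
        "unit,value,expected",
        [("hours", 0.9, np.log10(1.0)), ("minutes", 99.0, np.log10(100.0))],
    )
    def test_pseudocount_depends_on_unit(self, unit, value, expected):
        table = pd.DataFrame({"a": [value]}, index=["g1"])
        m = cp.preprocess_halflives(table, [meta("a", unit=unit)])
        assert m.values.loc["g1", "a"] == pytest.approx(expected)

    def test_duplicate_gene_ids_averaged_after_transform(self):
        # transformed values 1.0 and 3.0 -> mean 2.0
        table = pd.DataFrame({"a": [10.0**1 - 0.1, 10.0**3 - 0.1]},
                             index=["g1", "g1"])
        m = cp.preprocess_halflives(table, [meta("a")])
        assert len(m.values) == 1
        assert m.values.loc["g1", "a"] == pytest.approx(2.0)

    def test_degradation_rates_negated_and_monotone_decreasing(self):
        table = pd.DataFrame({"a": [0.1, 0.5, 0.9]}, index=list("ghi"))
        m = cp.preprocess_halflives(
            table, [meta("a", unit=None, rate=True)]
        )
        col = m.values["a"]
        assert (np.diff(col) < 0).all()  # faster decay = shorter half-life

    def test_negative_halflife_dropped_with_warning(self):
        table = pd.DataFrame({"a": [1.0, -2.0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="negative"):
            m = cp.preprocess_halflives(table, [meta("a")])
        assert np.isnan(m.values.loc["g2", "a"])

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            meta("a", unit="fortnights")


# ---------------------------------------------------------------------------
# filtering and standardization
# ---------------------------------------------------------------------------

class TestFilterStandardize:
    def _matrix(self, counts, n_samples=60):
        """Genes with the requested non-missing counts."""
        rng = np.random.default_rng(1)
        rows = {}
        for i, c in enumerate(counts):
            v = np.full(n_samples, np.nan)
            v[rng.choice(n_samples, size=c, replace=False)] = rng.normal(size=c)
            rows[f"g{i}"] = v
        df = pd.DataFrame(rows).T
        df.columns = [f"s{j}" for j in range(n_samples)]
        samples = [meta(f"s{j}", study=f"st{j}") for j in range(n_samples)]
        return to_stage(df, samples, "transformed")

    def test_threshold_counts(self):
        m = cp.filter_genes(self._matrix([3, 5, 10, 12, 54]), min_samples=10)
        assert len(m.genes) == 3

    def test_below_threshold_gene_dropped(self):
        m = cp.filter_genes(self._matrix([9, 10]), min_samples=10)
        assert m.genes == ["g1"]

    def test_zero_threshold_is_identity_on_genes(self):
        base = self._matrix([3, 5, 10])
        m = cp.filter_genes(base, min_samples=0)
        assert m.genes == base.genes

    def test_threshold_above_sample_count_errors(self):
        with pytest.raises(ValueError):
            cp.filter_genes(self._matrix([3]), min_samples=61)

    def test_standardize_simple_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]}, index=list("xyz"))
        m = cp.standardize_samples(to_stage(df, [meta("a")], "filtered"))
        assert np.allclose(m.values["a"], [-1.0, 0.0, 1.0])

    def test_standardize_idempotent(self):
        df = pd.DataFrame({"a": [-1.0, 0.0, 1.0]}, index=list("xyz"))
        m = cp.standardize_samples(to_stage(df, [meta("a")], "filtered"))
        assert np.allclose(m.values["a"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_zero_variance_sample_named_in_error(self):
        df = pd.DataFrame({"bad": [2.0, 2.0, 2.0]}, index=list("xyz"))
        with pytest.raises(ValueError, match="bad"):
            cp.standardize_samples(to_stage(df, [meta("bad")], "filtered"))

    def test_zscores_independent_of_log_base(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.5, 20.0, size=50)
        z10 = stats.zscore(np.log10(x), ddof=1)
        zln = stats.zscore(np.log(x), ddof=1)
        assert np.abs(z10 - zln).max() < 1e-10


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

class TestImputation:
    def _standardized(self, X, miss_mask):
        Xm = X.copy()
        Xm[miss_mask] = np.nan
        df = pd.DataFrame(
            Xm, index=[f"g{i}" for i in range(X.shape[0])],
            columns=[f"s{j}" for j in range(X.shape[1])],
        )
        samples = [meta(f"s{j}", study=f"st{j}") for j in range(X.shape[1])]
        return cp.HalfLifeMatrix(values=df, samples=samples, stage="standardized")

    def test_no_missing_returned_unchanged(self):
        X = np.random.default_rng(0).normal(size=(8, 5))
        m = self._standardized(X, np.zeros_like(X, dtype=bool))
        out, ncp = cp.impute_iterative_pca(m, ncp_max=3)
        assert np.array_equal(out.values.to_numpy(), X)
        assert out.stage == "imputed"

    def test_rank1_recovery_matches_full_svd_oracle(self):
        rng = np.random.default_rng(42)
        u = rng.normal(size=8)
        v = rng.normal(size=5)
        X = np.outer(u, v)
        mask = rng.random(X.shape) < 0.2
        mask[:, mask.all(axis=0)] = False  # keep every column observed somewhere
        m = self._standardized(X, mask)
        # the EM contraction rate is close to 1 on this tiny problem, so a
        # tight step tolerance is needed for 1e-6 accuracy on the cells
        out, _ = cp.impute_iterative_pca(
            m, ncp_max=1, ncp=1, tol=1e-11, max_iter=50000
        )
        # oracle: rank-1 truncated SVD of the *unmasked* matrix is X itself
        U, s, Vt = np.linalg.svd(X)
        oracle = s[0] * np.outer(U[:, 0], Vt[0])
        assert np.abs(out.values.to_numpy() - oracle)[mask].max() < 1e-6

    def test_observed_cells_bit_identical(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 6))
        mask = rng.random(X.shape) < 0.25
        m = self._standardized(X, mask)
        out, _ = cp.impute_iterative_pca(m, ncp_max=2, seed=0)
        assert np.array_equal(out.values.to_numpy()[~mask], X[~mask])
        assert not np.isnan(out.values.to_numpy()).any()

    def test_all_missing_gene_errors(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        mask = np.zeros_like(X, dtype=bool)
        mask[2, :] = True
        with pytest.raises(ValueError, match="all values missing"):
            cp.impute_iterative_pca(self._standardized(X, mask), ncp_max=2)

    def test_ncp_bounds_validated(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.raises(ValueError, match="ncp_max"):
            cp.impute_iterative_pca(
                self._standardized(X, np.zeros_like(X, bool)), ncp_max=4
            )


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def _imputed(self, cols):
        df = pd.DataFrame(cols)
        df.index = [f"g{i}" for i in range(len(df))]
        samples = [meta(c, study=c) for c in df.columns]
        return cp.HalfLifeMatrix(values=df, samples=samples, stage="imputed")

    def test_two_column_mean_of_order_statistics(self):
        m = cp.quantile_normalize(
            self._imputed({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        )
        assert np.allclose(m.values["a"], [2.5, 3.5, 4.5])
        assert np.allclose(m.values["b"], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        m = cp.quantile_normalize(
            self._imputed({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        )
        assert np.allclose(m.values["a"], [3.0, 1.0, 2.0])

    def test_sorted_columns_exactly_identical(self):
        rng = np.random.default_rng(5)
        cols = {f"s{j}": rng.normal(size=40) for j in range(6)}
        m = cp.quantile_normalize(self._imputed(cols))
        X = m.values.to_numpy()
        ref = np.sort(X[:, 0])
        for j in range(X.shape[1]):
            assert np.array_equal(np.sort(X[:, j]), ref)

    def test_rank_order_preserved_within_column(self):
        rng = np.random.default_rng(6)
        cols = {f"s{j}": rng.normal(size=25) for j in range(4)}
        before = pd.DataFrame(cols)
        m = cp.quantile_normalize(self._imputed(cols))
        for c in before:
            assert (
                before[c].rank().to_numpy()
                == m.values[c].rank().to_numpy()
            ).all()


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------

def _normalized(X):
    df = pd.DataFrame(
        X, index=[f"g{i}" for i in range(X.shape[0])],
        columns=[f"s{j}" for j in range(X.shape[1])],
    )
    samples = [meta(f"s{j}", study=f"st{j}") for j in range(X.shape[1])]
    return cp.HalfLifeMatrix(values=df, samples=samples, stage="normalized")


class TestConsensusPCA:
    def test_exact_rank1_explains_all_variance(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.normal(size=30), rng.normal(size=5))
        cons = cp.consensus_pc1(_normalized(X))
        assert cons.variance_explained[0] == pytest.approx(1.0)

    def test_sign_anchor_follows_row_mean_orientation(self):
        # the anchor forces corr(scores, row means) > 0; negating every
        # column flips the row means, so the anchored scores flip with the
        # data's orientation (a rate-sense matrix yields rate-sense scores)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5)) + rng.normal(size=(30, 1))
        a = cp.consensus_pc1(_normalized(X)).gene_scores
        b = cp.consensus_pc1(_normalized(-X)).gene_scores
        assert np.allclose(a, -b, atol=1e-10)
        assert np.corrcoef(a, X.mean(axis=1))[0, 1] > 0
        assert np.corrcoef(b, (-X).mean(axis=1))[0, 1] > 0

    def test_scores_positively_correlate_with_row_means(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 8)) + 2 * rng.normal(size=(50, 1))
        cons = cp.consensus_pc1(_normalized(X))
        r = np.corrcoef(cons.gene_scores, X.mean(axis=1))[0, 1]
        assert r > 0

    def test_log_base_invariance_of_consensus_scores(self):
        # z-scoring removes the log-base scale factor, so consensus scores
        # from log10 and natural-log preprocessing agree elementwise
        rng = np.random.default_rng(11)
        raw = rng.uniform(0.2, 30.0, size=(60, 5))

        def pipeline(logged):
            z = stats.zscore(logged, axis=0, ddof=1)
            return cp.consensus_pc1(_normalized(z)).gene_scores.to_numpy()

        a = pipeline(np.log10(raw))
        b = pipeline(np.log(raw))
        assert np.abs(a - b).max() < 1e-8

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            cp.consensus_pc1(_normalized(np.random.default_rng(0).normal(size=(10, 1))))


class TestSamplePCA:
    def test_duplicated_samples_get_identical_coordinates(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=20)
        X = np.column_stack([col, col, rng.normal(size=20)])
        coords, _ = cp.sample_pca(_normalized(X))
        assert np.allclose(coords.iloc[0], coords.iloc[1], atol=1e-9)

    def test_variance_fractions_sum_to_at_most_one(self):
        X = np.random.default_rng(4).normal(size=(25, 6))
        _, var_frac = cp.sample_pca(_normalized(X))
        assert var_frac.sum() <= 1.0 + 1e-12
        assert (var_frac >= 0).all()


# ---------------------------------------------------------------------------
# statistical probes
# ---------------------------------------------------------------------------

def exact_twosided_ranksum_p(a, b):
    """Enumeration oracle: all C(n+m, n) group assignments of pooled values."""
    pooled = list(a) + list(b)
    n = len(a)

    def ustat(idx):
        aa = [pooled[i] for i in idx]
        bb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1 for x in aa for y in bb if x > y) + \
            0.5 * sum(1 for x in aa for y in bb if x == y)

    obs = ustat(range(n))
    us = [ustat(c) for c in itertools.combinations(range(len(pooled)), n)]
    mu = len(a) * len(b) / 2.0
    return sum(1 for u in us if abs(u - mu) >= abs(obs - mu) - 1e-12) / len(us)


class TestMethodBias:
    def _setup(self, pc2_by_sample, classes, studies):
        coords = pd.DataFrame(
            {"PC1": 0.0, "PC2": pc2_by_sample},
            index=[f"s{i}" for i in range(len(pc2_by_sample))],
        )
        samples = [
            meta(f"s{i}", study=studies[i],
                 method="4sU" if classes[i] == "p" else "ActD")
            for i in range(len(pc2_by_sample))
        ]
        return coords, samples

    def test_identical_distributions_give_p_one(self):
        coords, samples = self._setup(
            [1, 2, 3, 1, 2, 3], "pppsss", [f"st{i}" for i in range(6)]
        )
        rep = cp.method_bias_test(coords, samples)
        assert rep.p_value == pytest.approx(1.0)

    def test_complete_separation_three_vs_three(self):
        coords, samples = self._setup(
            [1, 2, 3, 4, 5, 6], "pppsss", [f"st{i}" for i in range(6)]
        )
        rep = cp.method_bias_test(coords, samples)
        assert rep.p_value == pytest.approx(0.1)
        # independent enumeration oracle over all 20 assignments
        assert exact_twosided_ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        assert rep.p_value == pytest.approx(
            exact_twosided_ranksum_p([1, 2, 3], [4, 5, 6])
        )

    def test_replicates_averaged_within_study(self):
        coords, samples = self._setup(
            [0.2, 0.4, 1.0, 2.0, 3.0, 4.0, 5.0],
            "ppsssss".replace("s", "s"),
            ["stA", "stA", "stB", "stC", "stD", "stE", "stF"],
        )
        # make the last five shutoff and give study A two pulse replicates;
        # need >=2 studies per class, so flip study B to pulse
        samples[2] = meta("s2", study="stB", method="4sU")
        rep = cp.method_bias_test(coords, samples)
        assert rep.group_a.loc["stA"] == pytest.approx(0.3)

    def test_single_study_class_rejected(self):
        coords, samples = self._setup(
            [1, 2, 3, 4], "psss", ["stA", "stB", "stC", "stD"]
        )
        with pytest.raises(ValueError, match="<2 study-level"):
            cp.method_bias_test(coords, samples)


class TestCelltypeSpecificity:
    def _matrix(self, n_genes=60, seed=0, samples=None):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=n_genes)
        cols = {}
        for s in samples:
            ct_shift = rng.normal(size=n_genes) * 0.0
            cols[s.sample_id] = base + rng.normal(size=n_genes)
        df = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])
        return cp.HalfLifeMatrix(values=df, samples=samples, stage="normalized")

    def test_single_study_has_no_cross_study_pairs(self):
        samples = [meta(f"s{i}", study="only") for i in range(4)]
        m = self._matrix(samples=samples)
        with pytest.raises(ValueError):
            cp.celltype_specificity_test(m)

    def test_pair_partition_counts(self):
        samples = [
            meta("s0", study="A", ct="HeLa"),
            meta("s1", study="B", ct="HeLa"),
            meta("s2", study="C", ct="K562"),
        ]
        m = self._matrix(samples=samples)
        rep = cp.celltype_specificity_test(m)
        assert len(rep.group_a) == 1      # one same-cell-type cross-study pair
        assert len(rep.group_b) == 2      # two different-cell-type pairs

    def test_planted_celltype_effect_detected(self):
        rng = np.random.default_rng(9)
        n = 400
        base = rng.normal(size=n)
        effect = {"HeLa": rng.normal(size=n), "K562": rng.normal(size=n)}
        samples, cols = [], {}
        for i in range(12):
            ct = "HeLa" if i % 2 == 0 else "K562"
            s = meta(f"s{i}", study=f"st{i}", ct=ct)
            samples.append(s)
            cols[s.sample_id] = base + effect[ct] + 0.5 * rng.normal(size=n)
        df = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
        m = cp.HalfLifeMatrix(values=df, samples=samples, stage="normalized")
        rep = cp.celltype_specificity_test(m)
        assert rep.p_value < 0.05


class TestStageContract:
    def test_stage_cannot_regress(self):
        df = pd.DataFrame({"a": [1.0, 2.0]}, index=["g1", "g2"])
        m = to_stage(df, [meta("a")], "filtered")
        with pytest.raises(ValueError, match="regress"):
            m._advance(df, "raw")

    def test_imputed_stage_forbids_missing(self):
        df = pd.DataFrame({"a": [1.0, np.nan]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="missing"):
            cp.HalfLifeMatrix(values=df, samples=[meta("a")], stage="imputed")
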