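"""Covariation analyses: pairwise correlations vs a per-entry oracle,
cosine clustering, concordance, singular-pair removal, gene-set nulls,
Jaccard overlap, and the mRNA/protein support filters."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

import scpquant as sq

from conftest import make_quant

nan = float("nan")


def oracle_corr(values: pd.DataFrame, method: str, min_pairs: int) -> pd.DataFrame:
    """Each entry computed independently over complete pairs."""
    n = len(values.index)
    out = pd.DataFrame(np.eye(n), index=values.index, columns=values.index)
    for i, fi in enumerate(values.index):
        for j, fj in enumerate(values.index):
            if i >= j:
                continue
            ok = values.loc[fi].notna() & values.loc[fj].notna()
            x, y = values.loc[fi, ok], values.loc[fj, ok]
            if ok.sum() < min_pairs or x.std() == 0 or y.std() == 0:
                r = np.nan
            elif method == "pearson":
                r = pearsonr(x, y).statistic
            else:
                r = spearmanr(x, y).statistic
            out.loc[fi, fj] = out.loc[fj, fi] = r
    return out


class TestPairwiseCorrelations:
    def test_self_is_one_and_antithetic_is_minus_one(self):
        x = np.arange(10, dtype=float)
        m = make_quant(np.vstack([x, -x + 3]))
        c = sq.pairwise_correlations(m.values)
        assert c.matrix.loc["f0", "f0"] == 1.0
        assert c.matrix.loc["f0", "f1"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_matches_per_entry_oracle_with_missingness(self, method):
        rng = np.random.default_rng(7)
        for _ in range(10):
            vals = rng.normal(size=(rng.integers(4, 15), rng.integers(6, 20)))
            vals[rng.random(vals.shape) < 0.3] = np.nan
            df = make_quant(vals).values
            c = sq.pairwise_correlations(df, method=method, min_pairs=3)
            expected = oracle_corr(df, method, 3)
            assert np.allclose(c.matrix, expected, equal_nan=True, atol=1e-10)
            # support counts complete pairs
            obs = df.notna().to_numpy(dtype=float)
            assert np.array_equal(c.support.to_numpy(), (obs @ obs.T).astype(int))

    def test_low_support_entries_missing(self):
        vals = np.array([[1.0, 2, 3, nan, nan], [1.0, 2, nan, 4, nan], [1, 2, 3, 4, 5]])
        c = sq.pairwise_correlations(make_quant(vals).values, min_pairs=3)
        assert np.isnan(c.matrix.loc["f0", "f1"])  # only 2 complete pairs
        assert not np.isnan(c.matrix.loc["f0", "f2"])

    def test_imputed_entries_excluded(self):
        m = sq.impute_knn(make_quant([[1.0, 2, 3, 4], [1, 2, 3, nan], [2, 1, 0, 4]]))
        c = sq.pairwise_correlations(m)
        # f0-f1 correlation must use only the 3 observed pairs
        r = pearsonr([1, 2, 3], [1, 2, 3]).statistic
        assert c.matrix.loc["f0", "f1"] == pytest.approx(r)


class TestClustering:
    def test_block_diagonal_recovered_exactly(self):
        R = np.full((6, 6), 0.0)
        R[:3, :3] = 0.9
        R[3:, 3:] = 0.9
        np.fill_diagonal(R, 1.0)
        c = sq.CorrelationResult(
            matrix=pd.DataFrame(R, index=list("abcdef"), columns=list("abcdef")),
            method="pearson",
            support=pd.DataFrame(10, index=list("abcdef"), columns=list("abcdef")),
            min_pairs=3,
        )
        labels = sq.cluster_correlation_vectors(c, n_clusters=2)
        l = labels.labels
        assert len(set(l[list("abc")])) == 1
        assert len(set(l[list("def")])) == 1
        assert l["a"] != l["f"]

    def test_identical_rows_have_zero_cosine_distance(self):
        from scpquant.covariation import _pairwise_cosine_rows

        R = np.array(
            [
                [1.0, 0.5, 0.3, 0.2],
                [0.5, 1.0, 0.3, 0.2],
                [0.3, 0.3, 1.0, 0.4],
                [0.2, 0.2, 0.4, 1.0],
            ]
        )
        # after excluding the self-entries, rows 0 and 1 reduce to the same
        # remaining vector (0.3, 0.2) -> cosine similarity 1, distance 0
        sim = _pairwise_cosine_rows(R)
        assert sim[0, 1] == pytest.approx(1.0)

    def test_module_recovery_from_simulated_truth(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = sq.SimulationConfig(
            n_sets=1, n_proteins=60, n_cells=120, n_modules=6,
            module_factor_sd=1.0, noise_sd=0.25, n_markers_per_direction=0, seed=3,
        )
        truth = sq.simulate_truth(cfg)
        corr = sq.pairwise_correlations(np.log2(truth.true_abundance))
        labels = sq.cluster_correlation_vectors(corr, n_clusters=6)
        ari = adjusted_rand_score(
            truth.module_assignment.loc[labels.labels.index], labels.labels
        )
        assert ari >= 0.9


class TestConcordance:
    @staticmethod
    def _corr_of(vals, seed=0):
        return sq.pairwise_correlations(vals)

    def test_self_concordance_exactly_one(self):
        rng = np.random.default_rng(2)
        c = self._corr_of(make_quant(rng.normal(size=(10, 30))).values)
        res = sq.concordance_of_correlations(c, c)
        assert np.allclose(res.concordance, 1.0)
        assert res.median == pytest.approx(1.0)

    def test_antithetic_concordance_minus_one(self):
        rng = np.random.default_rng(3)
        a = self._corr_of(make_quant(rng.normal(size=(8, 40))).values)
        neg = a.matrix.copy() * -1
        np.fill_diagonal(neg.values, 1.0)
        b = sq.CorrelationResult(matrix=neg, method="pearson",
                                 support=a.support, min_pairs=a.min_pairs)
        res = sq.concordance_of_correlations(a, b)
        assert np.allclose(res.concordance, -1.0)

    def test_independent_data_centered_at_zero(self):
        rng = np.random.default_rng(4)
        medians = []
        for _ in range(5):
            a = self._corr_of(make_quant(rng.normal(size=(50, 40))).values)
            b = self._corr_of(make_quant(rng.normal(size=(50, 40))).values)
            medians.append(sq.concordance_of_correlations(a, b).median)
        assert abs(np.mean(medians)) < 0.1

    def test_sparse_feature_gets_nan(self):
        vals = np.array(
            [[1.0, 2, 3, 4, 2], [2, 1, 4, 3, 5], [1, 3, 2, 5, 4], [5, nan, nan, nan, nan]]
        )
        a = sq.pairwise_correlations(make_quant(vals).values, min_pairs=3)
        res = sq.concordance_of_correlations(a, a)
        assert np.isnan(res.concordance["f3"])


class TestSingularPairRemoval:
    def test_rank_one_annihilated(self):
        u, v = np.arange(1, 7, dtype=float), np.arange(2, 10, dtype=float)
        X = pd.DataFrame(np.outer(u, v))
        Xp = sq.remove_first_singular_pair(X)
        s1 = np.linalg.svd(X.to_numpy(), compute_uv=False)[0]
        assert np.abs(Xp.to_numpy()).max() <= 1e-8 * s1

    def test_residual_orthogonal_and_norm_nonincreasing(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(15, 10)))
        U, s, Vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
        Xp = sq.remove_first_singular_pair(X).to_numpy()
        assert np.abs(U[:, 0] @ Xp).max() <= 1e-8 * s[0]
        assert np.abs(Xp @ Vt[0, :]).max() <= 1e-8 * s[0]
        assert np.linalg.norm(Xp) <= np.linalg.norm(X.to_numpy())

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            sq.remove_first_singular_pair(make_quant([[1.0, nan], [2.0, 3.0]]))

    def test_global_factor_removal_deflates_between_module_correlations(self):
        rng = np.random.default_rng(9)
        n_prot, n_cells = 48, 150
        modules = np.repeat(np.arange(8), 6)
        factors = rng.normal(size=(8, n_cells))
        g = rng.normal(size=n_cells)  # global trend hitting every protein
        load = 1.5 + 0.2 * rng.random(n_prot)
        X = load[:, None] * g[None, :] + 0.7 * factors[modules] + 0.4 * rng.normal(
            size=(n_prot, n_cells)
        )
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(n_prot)])

        def between_module_mean(mat):
            c = sq.pairwise_correlations(mat).matrix.to_numpy()
            mask = modules[:, None] != modules[None, :]
            return np.nanmean(c[mask])

        before = between_module_mean(df)
        after_df = sq.remove_first_singular_pair(df)
        after = between_module_mean(after_df)
        within_after = np.nanmean(
            sq.pairwise_correlations(after_df).matrix.to_numpy()[
                (modules[:, None] == modules[None, :]) & ~np.eye(n_prot, dtype=bool)
            ]
        )
        assert before > 0.4  # global factor dominates raw correlations
        assert abs(after) < 0.15  # between-module correlation shrinks toward 0
        assert within_after > 0.5  # within-module structure persists


class TestGeneSets:
    def _result(self, vals):
        return sq.pairwise_correlations(vals)

    def test_planted_module_shifted_above_null(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(30, 100))
        shared = rng.normal(size=100)
        base[:5] = 0.9 * shared + 0.4 * rng.normal(size=(5, 100))
        df = make_quant(base).values
        c = self._result(df)
        null = self._result(pd.DataFrame(
            sq.remove_first_singular_pair(df).to_numpy(), index=df.index, columns=df.columns
        ))
        sets = {"module": [f"f{i}" for i in range(5)]}
        dists, null_vals = sq.geneset_correlation_distributions(c, sets, null)
        assert dists[0].p_value < 1e-4
        assert np.median(dists[0].correlations) > np.median(null_vals)

    def test_two_member_set_gives_single_value(self):
        rng = np.random.default_rng(11)
        df = make_quant(rng.normal(size=(10, 30))).values
        c = self._result(df)
        dists, _ = sq.geneset_correlation_distributions(c, {"pair": ["f0", "f1"]}, c)
        assert len(dists[0].correlations) == 1

    def test_all_features_set_equals_null_source(self):
        rng = np.random.default_rng(12)
        df = make_quant(rng.normal(size=(12, 25))).values
        c = self._result(df)
        dists, null_vals = sq.geneset_correlation_distributions(
            c, {"all": list(df.index)}, c
        )
        assert np.allclose(np.sort(dists[0].correlations), np.sort(null_vals))

    def test_undersized_set_skipped(self):
        rng = np.random.default_rng(13)
        c = self._result(make_quant(rng.normal(size=(5, 20))).values)
        dists, _ = sq.geneset_correlation_distributions(c, {"solo": ["f0"]}, c)
        assert dists == []


class TestJaccardAndFilters:
    @staticmethod
    def _labels(d):
        return sq.ClusterLabels(
            labels=pd.Series(d), linkage_matrix=np.empty((0, 4)), leaf_order=list(d)
        )

    def test_identical_disjoint_and_partial(self):
        a = self._labels({"A": 1, "B": 1, "C": 2})
        b = self._labels({"A": 1, "B": 2, "C": 2})
        J = sq.jaccard_cluster_overlap(a, a)
        assert J.loc[1, 1] == 1.0 and J.loc[1, 2] == 0.0
        # {A,B} vs {B,C}: one shared of three total
        J2 = sq.jaccard_cluster_overlap(a, b)
        assert J2.loc[1, 2] == pytest.approx(1 / 3)

    def test_jaccard_symmetric_and_bounded(self):
        rng = np.random.default_rng(14)
        la = self._labels({f"g{i}": int(x) for i, x in enumerate(rng.integers(1, 4, 30))})
        lb = self._labels({f"g{i}": int(x) for i, x in enumerate(rng.integers(1, 4, 30))})
        J_ab = sq.jaccard_cluster_overlap(la, lb)
        J_ba = sq.jaccard_cluster_overlap(lb, la)
        assert np.allclose(J_ab.to_numpy(), J_ba.to_numpy().T)
        assert ((J_ab >= 0) & (J_ab <= 1)).all().all()

    def test_mrna_filter_inclusive_at_threshold(self):
        counts = pd.DataFrame(
            {"c1": [5, 0, 1], "c2": [0, 0, 2]}, index=["g_at", "g_zero", "g_below"]
        )
        # g_at mean 2.5 kept (inclusive); all-zero dropped; 1.5 dropped
        out = sq.filter_mrna(counts, min_mean_reads=2.5)
        assert list(out.index) == ["g_at"]
        assert sq.filter_mrna(counts, min_mean_reads=0).equals(counts)

    def test_protein_support_filter_counts_observed_not_imputed(self):
        vals = np.full((3, 14), np.nan)
        vals[0, :] = 1.0 + np.arange(14) * 0.1  # 14 observed
        vals[1, :12] = 2.0 + np.arange(12) * 0.1  # exactly 12 -> kept (inclusive)
        vals[2, :5] = 3.0  # 5 observed -> dropped
        m = sq.impute_knn(make_quant(vals))
        out = sq.filter_protein_support(m, min_cells=12)
        assert list(out.values.index) == ["f0", "f1"]
        assert sq.filter_protein_support(m, min_cells=0).values.shape[0] == 3
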