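import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

from dosewise.io import CountMatrix
from dosewise.pseudobulk import (
    aggregate_pseudobulk,
    call_degs,
    classify_dose_response,
    deg_burden,
    design_matrix,
    estimate_dispersions,
    estimate_size_factors,
    fit_nb_glm,
    lrt_test,
    normalized_dose_means,
    run_dose_lrt,
    run_pairwise_wald,
    wald_test,
)


def ones(index):
    return pd.Series(1.0, index=index)


class TestAggregate:
    def test_sums_within_combination(self):
        cm = CountMatrix(
            sp.csr_matrix(np.array([[2, 1], [3, 0], [7, 7]])),
            ["c1", "c2", "c3"],
            ["g1", "g2"],
        )
        cells = pd.DataFrame(
            {"cluster": ["A", "A", "B"], "sample": ["s1", "s1", "s1"], "dose": [2, 2, 2]},
            index=cm.cells,
        )
        pb = aggregate_pseudobulk(cm, cells)
        assert pb.counts.loc["g1", "A|s1"] == 5
        assert pb.counts.loc["g2", "A|s1"] == 1
        assert pb.counts.loc["g1", "B|s1"] == 7

    def test_one_cell_per_combination_is_identity(self, sim_small):
        _, counts, cells, _ = sim_small
        solo = cells.copy()
        solo["sample"] = np.arange(len(solo)).astype(str)
        pb = aggregate_pseudobulk(counts, solo)
        assert pb.counts.to_numpy().sum() == counts.matrix.sum()
        assert pb.counts.shape[1] == len(solo)

    def test_total_conservation(self, sim_small, pseudobulk_small=None):
        _, counts, cells, _ = sim_small
        pb = aggregate_pseudobulk(counts, cells)
        assert pb.counts.to_numpy().sum() == counts.matrix.sum()
        # per-column totals equal summed per-cell depths
        depths = pd.Series(counts.umis_per_cell(), index=counts.cells)
        key = cells["cluster"].astype(str) + "|" + cells["sample"].astype(str)
        expected = depths.groupby(key).sum()
        got = pb.counts.sum(axis=0)
        assert (expected.sort_index() == got.sort_index()).all()


class TestSizeFactors:
    def test_two_gene_fixture(self):
        counts = pd.DataFrame({"s1": [2, 4], "s2": [8, 16]}, index=["g1", "g2"])
        s = estimate_size_factors(counts)
        assert np.allclose(s.to_numpy(), [0.5, 2.0])

    def test_identical_columns_give_unity(self):
        counts = pd.DataFrame({"a": [3, 9, 1], "b": [3, 9, 1], "c": [3, 9, 1]})
        assert np.allclose(estimate_size_factors(counts), 1.0)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(20, size=(100, 4)) + 1)
        s0 = estimate_size_factors(counts)
        scaled = counts.copy()
        scaled[2] = counts[2] * 3
        s1 = estimate_size_factors(scaled)
        ratio = (s1 / s0).to_numpy()
        # column 2 scales by 3 relative to the rest (geometric mean renorm)
        assert ratio[2] / ratio[0] == pytest.approx(3.0, rel=1e-9)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(30, size=(200, 6)) + 1)
        s = estimate_size_factors(counts)
        assert np.exp(np.mean(np.log(s))) == pytest.approx(1.0, abs=1e-12)

    def test_no_all_nonzero_gene_errors(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="fallback"):
            estimate_size_factors(counts)


class TestDispersions:
    def test_poisson_counts_near_zero(self):
        rng = np.random.default_rng(7)
        Y = pd.DataFrame(rng.poisson(100, size=(300, 20)))
        a = estimate_dispersions(Y, ones(Y.columns))
        assert np.median(a) < 0.02

    def test_nb_alpha_half_recovered(self):
        rng = np.random.default_rng(8)
        lam = rng.gamma(1 / 0.5, 50 * 0.5, size=(300, 50))
        Y = pd.DataFrame(rng.poisson(lam))
        a = estimate_dispersions(Y, ones(Y.columns))
        assert ((a >= 0.3) & (a <= 0.7)).mean() >= 0.8

    def test_constant_gene_at_floor(self):
        Y = pd.DataFrame([[5] * 10, [3] * 10])
        a = estimate_dispersions(Y, ones(Y.columns))
        assert (a <= 1e-7).all()

    def test_all_zero_gene_excluded(self):
        Y = pd.DataFrame([[0] * 6, [4] * 6])
        a = estimate_dispersions(Y, ones(Y.columns))
        assert np.isnan(a.iloc[0])
        assert np.isfinite(a.iloc[1])


class TestGlm:
    def test_identical_groups_beta_zero(self):
        Y = pd.DataFrame([[12, 12, 12, 12]], index=["g"], columns=list("abcd"))
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        fit = fit_nb_glm(Y, X, ones(Y.columns), pd.Series(0.01, index=Y.index))
        assert fit.beta.iloc[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_weighted_mean(self):
        s = pd.Series([0.5, 1.0, 2.0, 1.5], index=list("abcd"))
        Y = pd.DataFrame([[3, 5, 9, 7]], index=["g"], columns=list("abcd"))
        fit = fit_nb_glm(Y, np.ones((4, 1)), s, pd.Series(1e-12, index=Y.index))
        mu = 2.0 ** fit.beta.iloc[0, 0]
        assert mu == pytest.approx(Y.iloc[0].sum() / s.sum(), rel=1e-6)

    def test_poisson_limit_closed_form(self):
        Y = pd.DataFrame(
            [[10, 10, 10, 40, 40, 40]], index=["g"], columns=list("abcdef")
        )
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = fit_nb_glm(
            Y, X, ones(Y.columns), pd.Series(1e-12, index=Y.index), coef_names=["i", "grp"]
        )
        assert fit.beta["grp"].iloc[0] == pytest.approx(2.0, abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        Y = pd.DataFrame([[1, 2, 3]], index=["g"])
        X = np.column_stack([np.ones(3), np.ones(3)])
        with pytest.raises(ValueError, match="rank"):
            fit_nb_glm(Y, X, ones(Y.columns), pd.Series(0.1, index=Y.index))


class TestWald:
    @pytest.fixture
    def two_group_fit(self):
        rng = np.random.default_rng(0)
        Y = pd.DataFrame(rng.poisson(50, size=(50, 8)))
        X = np.column_stack([np.ones(8), [0] * 4 + [1] * 4])
        s = ones(Y.columns)
        a = estimate_dispersions(Y, s, design=X)
        return fit_nb_glm(Y, X, s, a, coef_names=["i", "grp"])

    def test_zero_contrast_gives_p_one(self, two_group_fit):
        res = wald_test(two_group_fit, [0.0, 0.0])
        assert np.allclose(res["stat"].dropna(), 0.0)
        assert np.allclose(res["pvalue"].dropna(), 1.0)

    def test_z_1p96_gives_p05(self):
        assert 2 * scipy.stats.norm.sf(1.96) == pytest.approx(0.05, abs=1e-3)

    def test_contrast_length_checked(self, two_group_fit):
        with pytest.raises(ValueError, match="contrast length"):
            wald_test(two_group_fit, [1.0])

    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        lam = rng.gamma(1 / 0.05, 100 * 0.05, size=(2000, 12))
        Y = pd.DataFrame(rng.poisson(lam))
        X = np.column_stack([np.ones(12), [0] * 6 + [1] * 6])
        s = estimate_size_factors(Y)
        a = estimate_dispersions(Y, s, design=X)
        fit = fit_nb_glm(Y, X, s, a, coef_names=["i", "grp"])
        res = wald_test(fit, [0, 1])
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08


class TestLrt:
    def test_full_equals_reduced(self):
        Y = pd.DataFrame([[5, 6, 7, 8]], index=["g"])
        X = np.ones((4, 1))
        s = ones(Y.columns)
        a = pd.Series(0.1, index=Y.index)
        fit = fit_nb_glm(Y, X, s, a)
        res = lrt_test(fit, fit)
        assert res["stat"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res["pvalue"].iloc[0] == 1.0

    def test_null_added_covariate_is_chi2_1(self):
        rng = np.random.default_rng(9)
        lam = rng.gamma(1 / 0.05, 100 * 0.05, size=(1500, 20))
        Y = pd.DataFrame(rng.poisson(lam))
        Xr = np.ones((20, 1))
        Xf = np.column_stack([np.ones(20), [0, 1] * 10])
        s = ones(Y.columns)
        a = estimate_dispersions(Y, s, design=Xf)
        full = fit_nb_glm(Y, Xf, s, a)
        red = fit_nb_glm(Y, Xr, s, a)
        res = lrt_test(full, red)
        assert res["df"].iloc[0] == 1
        ks = scipy.stats.kstest(res["stat"].dropna(), "chi2", args=(1,))
        assert ks.pvalue > 0.01

    def test_interaction_df_one(self):
        coldata = pd.DataFrame(
            {
                "dose": [0, 0, 2, 2, 0, 0, 2, 2],
                "age": ["E14"] * 4 + ["P1"] * 4,
            }
        )
        Xf, _ = design_matrix(coldata, ["age", "dose", "age:dose"])
        Xr, _ = design_matrix(coldata, ["age", "dose"])
        assert np.linalg.matrix_rank(Xf) - np.linalg.matrix_rank(Xr) == 1

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(1)
        Y = pd.DataFrame(rng.poisson(20, size=(5, 6)))
        s = ones(Y.columns)
        a = pd.Series(0.1, index=Y.index)
        f1 = fit_nb_glm(Y, np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]]), s, a)
        f2 = fit_nb_glm(Y, np.column_stack([[1, 1, 0, 0, 1, 1], [0, 0, 1, 1, 0, 0]]), s, a)
        with pytest.raises(ValueError, match="nested"):
            lrt_test(f1, f2)


class TestCallAndClassify:
    def test_lfc_gate(self):
        res = pd.DataFrame(
            {"pvalue": [1e-6, 1e-6], "log2fc": [0.1, -0.5]}, index=["a", "b"]
        )
        out = call_degs(res)
        assert not out.loc["a", "called"]  # fails LFC
        assert out.loc["b", "called"] and out.loc["b", "direction"] == "down"

    def test_classification(self):
        lrt = pd.DataFrame({"qvalue": [0.001, 0.001, 0.001, 0.5]}, index=list("abcd"))
        means = pd.DataFrame(
            {0: [40.0, 10, 25, 10], 1: [20.0, 38, 30, 10], 2: [10.0, 40, 20, 10]},
            index=list("abcd"),
        )
        klass = classify_dose_response(lrt, means)
        assert klass["a"] == "repressed"
        assert klass["b"] == "activated"
        assert klass["c"] == "non-monotone"
        assert klass["d"] == "ns"

    def test_missing_dose_errors(self):
        lrt = pd.DataFrame({"qvalue": [0.001]}, index=["a"])
        means = pd.DataFrame({0: [1.0], 1: [2.0]}, index=["a"])
        with pytest.raises(ValueError, match="dose level 2"):
            classify_dose_response(lrt, means)


class TestRecovery:
    def test_planted_classes_recovered(self, sim_default, pseudobulk_default):
        _, _, _, truth = sim_default
        pb = pseudobulk_default
        res = run_dose_lrt(pb.counts, pb.coldata)
        rep = truth.genes_of_class("repressed")
        act = truth.genes_of_class("activated")
        assert (res.loc[rep, "class"] == "repressed").mean() >= 0.8
        assert (res.loc[act, "class"] == "activated").mean() >= 0.8

    def test_het_asymmetry(self, sim_default, pseudobulk_default):
        # dose-sensitive repressed genes are called at Het more often than
        # threshold-like activated genes
        _, _, _, truth = sim_default
        pb = pseudobulk_default
        res = run_pairwise_wald(pb.counts, pb.coldata, dose_a=2, dose_b=1)
        frac_rep = res.loc[truth.genes_of_class("repressed"), "called"].mean()
        frac_act = res.loc[truth.genes_of_class("activated"), "called"].mean()
        assert frac_rep > frac_act

    def test_wald_lrt_asymptotic_agreement(self):
        # 1-df contrasts at n=50: median |z^2 - lambda| / lambda < 0.05
        rng = np.random.default_rng(3)
        mu = np.where(np.arange(50) < 25, 50, 90)
        lam = rng.gamma(1 / 0.05, mu * 0.05, size=(300, 50))
        Y = pd.DataFrame(rng.poisson(lam))
        X = np.column_stack([np.ones(50), (np.arange(50) >= 25).astype(float)])
        s = ones(Y.columns)
        a = estimate_dispersions(Y, s, design=X)
        full = fit_nb_glm(Y, X, s, a, coef_names=["i", "grp"])
        red = fit_nb_glm(Y, np.ones((50, 1)), s, a)
        z = wald_test(full, [0, 1])["stat"]
        lam_stat = lrt_test(full, red)["stat"]
        rel = ((z**2 - lam_stat).abs() / lam_stat).dropna()
        assert rel.median() < 0.05


class TestBurden:
    def test_undersized_cluster_is_na(self, sim_small):
        _, counts, cells, _ = sim_small
        res = deg_burden(counts, cells, n_cells=700, reps=2, seed=0)
        assert (res.table["status"] == "N/A").all()

    def test_null_no_cluster_flagged(self, sim_null):
        _, counts, cells, _ = sim_null
        res = deg_burden(counts, cells, n_cells=300, reps=10, seed=4)
        ok = res.table[res.table["status"] == "ok"]
        assert len(ok) == 5
        assert (ok["qvalue"] >= 0.05).all()

    def test_planted_cluster_has_max_burden(self, sim_null):
        # inject a strong effect only in cluster T3 of the null data
        _, counts, cells, _ = sim_null
        dense = counts.to_dense().copy()
        rng = np.random.default_rng(2)
        target_genes = rng.choice(dense.shape[1], 150, replace=False)
        target_cells = (cells["cluster"] == "T3") & (cells["dose"] == 0)
        rows = np.flatnonzero(target_cells.to_numpy())
        dense[np.ix_(rows, target_genes)] *= 4
        spiked = CountMatrix(sp.csr_matrix(dense), counts.cells, counts.genes)
        res = deg_burden(spiked, cells, n_cells=300, reps=5, seed=4)
        ok = res.table[res.table["status"] == "ok"]
        assert ok["burden"].idxmax() == "T3"
        assert ok.loc["T3", "qvalue"] < 0.05

    def test_deterministic(self, sim_small):
        _, counts, cells, _ = sim_small
        r1 = deg_burden(counts, cells, n_cells=150, reps=3, seed=9)
        r2 = deg_burden(counts, cells, n_cells=150, reps=3, seed=9)
        pd.testing.assert_frame_equal(r1.table, r2.table)
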