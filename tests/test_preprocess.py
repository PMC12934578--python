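"""Missingness classification, KNN-TN / down-shift imputation, VSN."""

import numpy as np
import pandas as pd
import pytest

import methylworm as mw
from tests.conftest import make_matrix

NA = np.nan


class TestClassify:
    CFG = mw.ImputeConfig()

    def classify(self, row_vals):
        mat = make_matrix([row_vals])
        return mw.classify_missingness(mat.values.iloc[0], mat.design, self.CFG)

    def test_whole_group_missing_is_mnar(self):
        assert self.classify([1, 1, 1, 1, 1, 1, NA, NA, NA]) == "MNAR"

    def test_single_scattered_missing_is_mar(self):
        assert self.classify([1, 1, 1, 1, NA, 1, 1, 1, 1]) == "MAR"

    def test_no_missing_is_complete(self):
        assert self.classify([1] * 9) == "complete"

    def test_two_missing_in_one_group_without_full_loss_drops(self):
        assert self.classify([1, 1, 1, NA, NA, 1, 1, 1, 1]) == "drop"

    def test_partition_counts_sum_to_input(self, default_study):
        mat = default_study["peptide_matrix"]
        classes = mw.preprocess_matrix(mat, normalize=False)["classes"]
        assert classes.value_counts().sum() == len(mat.values)


class TestKnnTn:
    def test_duplicate_neighbor_recovers_value(self):
        base = np.arange(9, dtype=float) + 20
        rows = [base, base.copy(), base + 5, base - 3, base * 0 + 22]
        rows[1][4] = NA
        mat = make_matrix(rows)
        out, fallback = mw.impute_knn_tn(mat, mw.ImputeConfig(knn_k=1))
        assert fallback == []
        assert out.values.iloc[1, 4] == pytest.approx(base[4], abs=0.3)

    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        mat = make_matrix(rng.normal(25, 2, (20, 9)))
        out, _ = mw.impute_knn_tn(mat)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(25, 2, (30, 9))
        vals[rng.random((30, 9)) < 0.1] = NA
        mat = make_matrix(vals)
        out, _ = mw.impute_knn_tn(mat)
        obs = ~np.isnan(vals)
        np.testing.assert_array_equal(out.values.to_numpy()[obs], vals[obs])

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(25, 2, (30, 9))
        vals[rng.random((30, 9)) < 0.1] = NA
        mat = make_matrix(vals)
        a, _ = mw.impute_knn_tn(mat)
        b, _ = mw.impute_knn_tn(mat)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_beats_mean_imputation_rmse(self):
        """KNN-TN should beat the naive column-mean oracle on correlated MAR
        data: 500 features, 10% dropout, 20 seeds."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            profile = rng.normal(0, 2, 9)
            truth = (25 + rng.normal(0, 2, (500, 1))
                     + np.outer(rng.normal(1, 0.3, 500), profile)
                     + rng.normal(0, 0.4, (500, 9)))
            vals = truth.copy()
            mask = rng.random((500, 9)) < 0.1
            vals[mask] = NA
            mat = make_matrix(vals)
            out, _ = mw.impute_knn_tn(mat)
            imputed = out.values.to_numpy()
            col_means = np.nanmean(vals, axis=0)
            mean_filled = np.where(np.isnan(vals), col_means[None, :], vals)
            rmse_knn = np.sqrt(np.nanmean((imputed[mask] - truth[mask]) ** 2))
            rmse_mean = np.sqrt(np.nanmean((mean_filled[mask] - truth[mask]) ** 2))
            wins += rmse_knn < rmse_mean
        assert wins == 20


class TestDownshift:
    def test_monte_carlo_moments(self):
        """Draws follow Normal(mu - 1.8 sd, (0.3 sd)^2): with mu=20, sd=2 the
        mean of 1e5 draws is 16.4 within Monte-Carlo error."""
        rng = np.random.default_rng(0)
        n = 100000
        obs = rng.normal(20, 2, (n, 1))
        vals = np.hstack([obs, np.full((n, 1), NA)])
        design = pd.DataFrame({"genotype": ["WT", "WT"], "replicate": [1, 2]},
                              index=["a", "b"])
        mat = mw.AbundanceMatrix(
            pd.DataFrame(vals, columns=["a", "b"]), design)
        out = mw.impute_downshift(mat, mw.ImputeConfig(seed=1),
                                  reference=mat)
        draws = out.values["b"].to_numpy()
        mu, sd = obs.mean(), obs.std(ddof=1)
        assert draws.mean() == pytest.approx(mu - 1.8 * sd, abs=0.02)
        assert draws.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.02)

    def test_constant_column_imputes_at_mean(self):
        vals = np.array([[20.0, 20.0, 20.0, NA, 20.0, 20.0, 20.0, 20.0, 20.0]])
        mat = make_matrix(vals)
        out = mw.impute_downshift(mat, mw.ImputeConfig(seed=0))
        assert out.values.iloc[0, 3] == pytest.approx(20.0, abs=1e-9)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(25, 2, (20, 9))
        vals[rng.random((20, 9)) < 0.2] = NA
        mat = make_matrix(vals)
        a = mw.impute_downshift(mat, mw.ImputeConfig(seed=5))
        b = mw.impute_downshift(mat, mw.ImputeConfig(seed=5))
        pd.testing.assert_frame_equal(a.values, b.values)


class TestVsn:
    def test_identical_samples_identical_transforms(self):
        rng = np.random.default_rng(0)
        col = rng.lognormal(15, 2, 200)
        mat = make_matrix(np.tile(col[:, None], (1, 9)), scale="linear")
        out, params = mw.vsn_normalize(mat)
        assert params["a"].std() < 1e-9 and params["b"].std() / params["b"].mean() < 1e-9
        H = out.values.to_numpy()
        assert np.allclose(H, H[:, :1])

    def test_large_intensity_glog_limit(self):
        rng = np.random.default_rng(1)
        mat = make_matrix(rng.lognormal(15, 1, (100, 9)), scale="linear")
        _, params = mw.vsn_normalize(mat)
        a, b = params.iloc[0]["a"], params.iloc[0]["b"]
        h = lambda x: np.arcsinh(a + b * x) / np.log(2)
        x = 1000.0 / b
        assert h(2 * x) - h(x) == pytest.approx(1.0, abs=1e-3)

    def test_variance_stabilization_slope(self):
        """Multiplicative + additive noise: the SD-vs-mean trend after the
        transform is <= 0.1x the trend before."""
        rng = np.random.default_rng(2)
        n, m = 400, 9
        mu = rng.lognormal(8, 2, n)
        X = mu[:, None] * np.exp(rng.normal(0, 0.15, (n, m))) \
            + rng.normal(0, 50, (n, m))
        X = np.clip(X, 1, None)
        mat = make_matrix(X, scale="linear")
        out, _ = mw.vsn_normalize(mat)
        slope = lambda V: abs(np.polyfit(V.mean(axis=1), V.std(axis=1), 1)[0])
        assert slope(out.values.to_numpy()) <= 0.1 * slope(X)

    def test_rank_preserving_within_sample(self):
        rng = np.random.default_rng(3)
        mat = make_matrix(rng.lognormal(14, 2, (100, 9)), scale="linear")
        out, _ = mw.vsn_normalize(mat)
        for j in range(9):
            x = mat.values.iloc[:, j].to_numpy()
            h = out.values.iloc[:, j].to_numpy()
            assert (np.argsort(x, kind="stable") == np.argsort(h, kind="stable")).all()

    def test_incomplete_matrix_rejected(self):
        vals = np.full((3, 9), 20.0)
        vals[0, 0] = NA
        with pytest.raises(ValueError):
            mw.vsn_normalize(make_matrix(vals))


class TestFullPreprocess:
    def test_observed_cells_survive_imputation(self, default_study):
        mat = default_study["peptide_matrix"]
        res = mw.preprocess_matrix(mat, normalize=False)
        filled = res["imputed_matrix"].values
        for f in filled.index:
            row = mat.values.loc[f]
            obs = row.notna()
            np.testing.assert_array_equal(filled.loc[f][obs.to_numpy()],
                                          row[obs.to_numpy()])

    def test_provenance_matches_mask(self, default_study):
        mat = default_study["peptide_matrix"]
        res = mw.preprocess_matrix(mat, normalize=False)
        prov = res["provenance"]
        mask = mat.values.loc[prov.index].isna()
        assert ((prov == "observed") == ~mask).all().all()
        assert set(np.unique(prov.values)) <= {"observed", "knn-tn", "downshift"}

    def test_mnar_rows_get_downshift_mar_rows_get_knn(self, default_study):
        mat = default_study["peptide_matrix"]
        res = mw.preprocess_matrix(mat, normalize=False)
        prov, classes = res["provenance"], res["classes"]
        for f in prov.index:
            kinds = set(prov.loc[f].unique()) - {"observed"}
            if classes[f] == "MNAR":
                assert kinds <= {"downshift"}
            elif classes[f] == "MAR":
                assert kinds <= {"knn-tn", "downshift"}

    def test_observed_ablated_peptides_called_down(self, default_study):
        """The attainable end-to-end power property: ablated peptides whose
        knockout values survive censoring are recovered as down-regulated."""
        truth = default_study["truth"]
        mat = default_study["peptide_matrix"]
        res = mw.preprocess_matrix(mat)
        pep = res["matrix"]
        sites = truth.sites.set_index("site_id")
        protein_of = pd.Series({f: sites.loc[f, "protein"]
                                for f in pep.values.index})
        prot = mw.preprocess_matrix(default_study["protein_matrix"])["matrix"]
        diff = mw.run_differential(pep, ("KO1", "WT"), prot, protein_of)
        ko1 = mat.samples_for("KO1")
        observed = [
            sid for sid in sites.query(
                "ko1_dependent and ablation_log2fc <= -5").index
            if sid in diff.index and mat.values.loc[sid, ko1].notna().all()
        ]
        assert len(observed) >= 3
        calls = diff.loc[observed, "call"]
        assert (calls == "down").mean() >= 0.9
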