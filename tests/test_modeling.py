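"""Residualization, rank alignment, fold machinery and group regressions."""

import numpy as np
import pandas as pd
import pytest

from tauspread.modeling import (RegressionResult, compare_folds,
                                evaluate_model, fit_group_model,
                                fit_interaction_model, rank_align,
                                rank_align_and_average, residualize_tpi,
                                stratified_kfold)


class TestResidualize:
    def test_null_covariates_preserve_signal(self):
        """When the generator's covariate effects are all zero the
        residuals correlate with raw TPI at r > 0.99."""
        from tauspread import GeneratorConfig, generate_cohort
        from tauspread.mixtures import build_tpi_table, fit_region_models
        cfg = GeneratorConfig(
            n_subjects=60, seed=21,
            covariate_effects={k: 0.0 for k in
                               ["age", "sex_male", "education", "race",
                                "study_adni", "scan_interval"]})
        c = generate_cohort(cfg)
        models = fit_region_models(c.suvr_baseline, seed=0)
        tpi = build_tpi_table(c.suvr_baseline, models)
        adj = residualize_tpi(tpi, c.metadata)
        r = np.corrcoef(tpi.to_numpy().ravel(), adj.to_numpy().ravel())[0, 1]
        assert r > 0.99

    def test_age_translation_invariance(self, small_cohort, small_tpi):
        meta = small_cohort.metadata
        a = residualize_tpi(small_tpi, meta)
        shifted = meta.copy()
        shifted["age"] = shifted["age"] + 10.0
        b = residualize_tpi(small_tpi, shifted)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)

    def test_missing_covariate_named(self, small_cohort, small_tpi):
        meta = small_cohort.metadata.copy()
        meta.loc[meta.index[0], "education"] = np.nan
        with pytest.raises(ValueError, match="education"):
            residualize_tpi(small_tpi, meta)

    def test_fixed_effects_fallback_available(self, small_cohort, small_tpi):
        adj = residualize_tpi(small_tpi, small_cohort.metadata,
                              method="fixed")
        assert adj.shape == small_tpi.shape


class TestRankAlignment:
    def test_sorting_order(self):
        row = pd.Series([0.2, 0.9, -0.5], index=["r1", "r2", "r3"])
        perm = rank_align(row)
        assert list(row.index[perm]) == ["r2", "r1", "r3"]

    def test_ties_broken_by_label(self):
        row = pd.Series([0.5, 0.5, 0.1], index=["b", "a", "c"])
        perm = rank_align(row)
        assert list(row.index[perm]) == ["a", "b", "c"]

    def test_same_permutation_applied_to_all_matrices(self):
        regions = ["r1", "r2", "r3"]
        tpi = pd.DataFrame([[0.2, 0.9, -0.5]], index=["s"], columns=regions)
        dist = pd.DataFrame([[5.0, 1.0, 9.0]], index=["s"], columns=regions)
        mean_tpi, mean_dist = rank_align_and_average(
            tpi, tpi, {"IE-IC": dist})
        assert list(mean_tpi) == [0.9, 0.2, -0.5]
        assert list(mean_dist["IE-IC"]) == [1.0, 5.0, 9.0]

    def test_mirrored_vectors_average_to_constant(self):
        regions = ["r1", "r2", "r3"]
        tpi = pd.DataFrame([[3.0, 2.0, 1.0], [1.0, 2.0, 3.0]],
                           index=["a", "b"], columns=regions)
        v = np.array([2.0, 5.0, 8.0])
        dist = pd.DataFrame([v, v[::-1]], index=["a", "b"], columns=regions)
        # a's rank order keeps v; b's reversal restores v -> mean == v
        _, mean_dist = rank_align_and_average(tpi, tpi, {"IE-IC": dist})
        assert np.allclose(mean_dist["IE-IC"], v)

    def test_rank_mean_raw_tpi_non_increasing(self, small_cohort, small_tpi):
        mean_tpi, _ = rank_align_and_average(
            small_tpi, small_tpi,
            {"IE-IC": small_tpi * 0})  # dummy profile
        assert np.all(np.diff(mean_tpi.to_numpy()) <= 1e-12)

    def test_subject_with_missing_profile_excluded(self, caplog):
        regions = ["r1", "r2", "r3"]
        tpi = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
                           index=["a", "b"], columns=regions)
        dist = pd.DataFrame([[1.0, 2.0, 3.0], [np.nan, 2.0, 1.0]],
                            index=["a", "b"], columns=regions)
        mean_tpi, _ = rank_align_and_average(tpi, tpi, {"IE-IC": dist})
        assert list(mean_tpi) == [3.0, 2.0, 1.0]  # only subject a


class TestStratifiedKFold:
    def test_partition_and_balance(self, small_cohort):
        meta = small_cohort.metadata
        folds = stratified_kfold(meta, k=5, seed=17)
        assert set(folds.unique()) == set(range(5))
        assert len(folds) == len(meta)
        overall = meta["amyloid_positive"].mean()
        for f in range(5):
            sub = meta.loc[folds[folds == f].index, "amyloid_positive"]
            assert abs(sub.sum() - overall * len(sub)) <= 1.0

    def test_deterministic_given_seed(self, small_cohort):
        meta = small_cohort.metadata
        a = stratified_kfold(meta, k=5, seed=17)
        b = stratified_kfold(meta, k=5, seed=17)
        assert a.equals(b)
        assert not a.equals(stratified_kfold(meta, k=5, seed=18))

    def test_k_too_small_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            stratified_kfold(small_cohort.metadata, k=1)

    def test_small_stratum_rejected(self):
        meta = pd.DataFrame({"amyloid_positive": [True] * 2 + [False] * 10},
                            index=[f"s{i}" for i in range(12)])
        with pytest.raises(ValueError, match="stratum"):
            stratified_kfold(meta, k=5)


class TestGroupModel:
    def _series(self, vals):
        return pd.Series(vals, index=range(1, len(vals) + 1))

    def test_perfect_negative_line(self):
        d = self._series(np.linspace(0, 1, 64))
        t = 1.0 - d
        res = fit_group_model(t, d, "IE-IC", 0)
        assert res.beta_std == pytest.approx(-1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.rmse == pytest.approx(0.0, abs=1e-12)
        assert res.df == 62

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_group_model(self._series(np.arange(10.0)),
                            self._series(np.ones(10)))

    def test_beta_sign_invariant_under_affine_distance_rescale(self, rng):
        d = self._series(rng.random(64))
        t = self._series(-0.5 * d.to_numpy() + rng.normal(0, 0.1, 64))
        a = fit_group_model(t, d)
        b = fit_group_model(t, 3.0 * d + 7.0)
        assert np.sign(a.beta_std) == np.sign(b.beta_std)
        assert a.beta_std == pytest.approx(b.beta_std, abs=1e-12)

    def test_resubstitution_identity(self, rng):
        d = self._series(rng.random(64))
        t = self._series(-0.8 * d.to_numpy() + rng.normal(0, 0.05, 64))
        train = fit_group_model(t, d)
        test = evaluate_model(train, t, d)
        assert test.r2 == pytest.approx(train.r2, abs=1e-12)
        assert test.beta_std > 0  # measured-on-predicted orientation

    def test_constant_prediction_rejected(self):
        train = RegressionResult(0.0, 1.0, 0.0, 0.0, 1.0, 8, 0.0, 0.0,
                                 1.0, 10)
        with pytest.raises(ValueError, match="constant predictions"):
            evaluate_model(train, self._series(np.arange(10.0)),
                           self._series(np.arange(10.0)))

    def test_interaction_model_detects_group_difference(self, rng):
        d = np.linspace(0, 1, 64)
        tpi_pos = pd.Series(1.0 - 1.5 * d, index=range(64))
        tpi_neg = pd.Series(1.0 - 0.2 * d + rng.normal(0, 0.01, 64),
                            index=range(64))
        dist = pd.Series(d, index=range(64))
        out = fit_interaction_model({"abpos": tpi_pos, "abneg": tpi_neg},
                                    {"abpos": dist, "abneg": dist}, "IE-IC")
        assert out["interaction_p"] < 1e-6


class TestCompareFolds:
    def test_identical_vectors_null(self):
        table = pd.DataFrame({"IE-IC": [0.8] * 5, "GE-GC": [0.8] * 5})
        out = compare_folds(table)
        assert out.loc[0, "t"] == 0.0 and out.loc[0, "p"] == 1.0

    def test_df_is_folds_minus_one(self, rng):
        table = pd.DataFrame(rng.random((5, 4)),
                             columns=["IE-IC", "IE-GC", "GE-IC", "GE-GC"])
        out = compare_folds(table)
        assert (out["df"] == 4).all()
        assert len(out) == 6

    def test_constant_difference_guard(self):
        table = pd.DataFrame({"A": [0.5, 0.6, 0.7, 0.8, 0.9],
                              "B": [0.4, 0.5, 0.6, 0.7, 0.8]})
        out = compare_folds(table)
        assert np.isinf(out.loc[0, "t"]) and out.loc[0, "t"] > 0
        assert out.loc[0, "p"] == 0.0

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            compare_folds(pd.DataFrame({"A": [0.5], "B": [0.4]}))
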