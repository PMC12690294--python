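"""Subject-level effect sizes and longitudinal change models."""

import numpy as np
import pandas as pd
import pytest

from tauspread.longitudinal import (PooledModel, annualize_change,
                                    average_fold_models,
                                    compare_effect_sizes,
                                    compare_longitudinal_models,
                                    fit_longitudinal_group_model,
                                    subject_effect_size)
from tauspread.modeling import RegressionResult
from tauspread.stats import hittner_z


def _train_result(variant, fold, intercept, slope):
    return RegressionResult(-0.5, intercept, slope, -3.0, 0.01, 62,
                            0.5, 0.49, 0.05, 64, variant, fold, "train")


class TestPooling:
    def test_identical_folds_idempotent(self):
        res = [_train_result("IE-IC", f, 1.0, -2.0) for f in range(5)]
        pooled = average_fold_models(res, "IE-IC")
        assert pooled.intercept == 1.0 and pooled.slope == -2.0

    def test_arithmetic_mean(self):
        slopes = [-1.0, -1.0, -1.0, -1.0, -2.0]
        res = [_train_result("IE-IC", f, 0.0, s)
               for f, s in enumerate(slopes)]
        assert average_fold_models(res, "IE-IC").slope == pytest.approx(-1.2)

    def test_duplicate_folds_rejected(self):
        res = [_train_result("IE-IC", 0, 0.0, -1.0)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            average_fold_models(res, "IE-IC")

    def test_pooled_prediction_equals_mean_of_fold_predictions(self, rng):
        folds = [(rng.normal(), rng.normal()) for _ in range(5)]
        res = [_train_result("IE-IC", f, a, b)
               for f, (a, b) in enumerate(folds)]
        pooled = average_fold_models(res, "IE-IC")
        x = rng.random(10)
        per_fold = np.mean([a + b * x for a, b in folds], axis=0)
        assert np.allclose(pooled.intercept + pooled.slope * x, per_fold)


class TestSubjectEffect:
    def _profile(self, rng, n=64):
        idx = [f"r{i}" for i in range(n)]
        return pd.Series(rng.random(n), index=idx)

    def test_exact_affine_subject_scores_one(self, rng):
        prof = self._profile(rng)
        pooled = PooledModel("IE-IC", 0.5, -0.8, 5)
        measured = pd.Series(2.0 * (pooled.intercept
                                    + pooled.slope * prof.to_numpy()) + 1.0,
                             index=prof.index)
        eff = subject_effect_size(measured, prof, pooled, subject="s")
        assert eff.beta_std == pytest.approx(1.0)
        assert eff.n_regions == 64

    def test_permutation_null_centered(self, rng):
        """Randomly shuffled profiles give effect sizes centered at zero
        (|mean| < 0.02 over 1,000 permutations)."""
        prof = self._profile(rng)
        pooled = PooledModel("IE-IC", 0.0, 1.0, 5)
        measured = pd.Series(rng.random(64), index=prof.index)
        vals = []
        for _ in range(1000):
            perm = rng.permutation(64)
            shuffled = pd.Series(prof.to_numpy()[perm], index=prof.index)
            vals.append(subject_effect_size(measured, shuffled, pooled,
                                            subject="s").beta_std)
        assert abs(np.mean(vals)) < 0.02

    def test_zero_variance_prediction_recorded_missing(self, rng):
        prof = pd.Series(np.ones(10), index=[f"r{i}" for i in range(10)])
        pooled = PooledModel("IE-IC", 0.0, 1.0, 5)
        eff = subject_effect_size(pd.Series(rng.random(10),
                                            index=prof.index),
                                  prof, pooled, subject="s")
        assert eff.beta_std is None
        assert "zero-variance" in eff.missing_reason

    def test_longitudinal_controls_baseline(self, rng):
        prof = self._profile(rng)
        base = pd.Series(rng.random(64), index=prof.index)
        pooled = PooledModel("IE-IC", 0.0, 1.0, 5)
        outcome = pd.Series(0.5 * prof.to_numpy() + 2.0 * base.to_numpy(),
                            index=prof.index)
        eff = subject_effect_size(outcome, prof, pooled, baseline=base,
                                  subject="s", analysis="longitudinal")
        assert eff.analysis == "longitudinal"
        assert eff.beta_std is not None and eff.beta_std > 0.2


class TestCompareEffects:
    def test_identical_variants_give_zero_f(self):
        df = pd.DataFrame({"IE-IC": [0.4, 0.5, 0.6],
                           "IE-GC": [0.4, 0.5, 0.6],
                           "GE-IC": [0.4, 0.5, 0.6],
                           "GE-GC": [0.4, 0.5, 0.6]})
        res = compare_effect_sizes(df)
        assert res.f == 0.0

    def test_df_structure_matches_cohort_sizes(self, rng):
        df = pd.DataFrame(rng.random((76, 4)),
                          columns=["IE-IC", "IE-GC", "GE-IC", "GE-GC"])
        res = compare_effect_sizes(df)
        assert (res.df1, res.df2) == (3, 225)

    def test_matches_decomposition_oracle(self, rng):
        x = rng.random((5, 4))
        df = pd.DataFrame(x, columns=["IE-IC", "IE-GC", "GE-IC", "GE-GC"])
        res = compare_effect_sizes(df)
        n, k = x.shape
        grand = x.mean()
        ss_s = k * ((x.mean(1) - grand) ** 2).sum()
        ss_c = n * ((x.mean(0) - grand) ** 2).sum()
        ss_e = ((x - grand) ** 2).sum() - ss_s - ss_c
        f = (ss_c / (k - 1)) / (ss_e / ((k - 1) * (n - 1)))
        assert res.f == pytest.approx(f, abs=1e-9)


class TestAnnualize:
    def _tables(self, b, f):
        idx, cols = ["s1"], ["r1"]
        return (pd.DataFrame([[b]], index=idx, columns=cols),
                pd.DataFrame([[f]], index=idx, columns=cols))

    def test_arithmetic(self):
        base, fu = self._tables(0.2, 0.4)
        out = annualize_change(base, fu, pd.Series({"s1": 2.0}))
        assert out.loc["s1", "r1"] == pytest.approx(0.1)

    def test_no_change_is_zero(self):
        base, fu = self._tables(0.3, 0.3)
        out = annualize_change(base, fu, pd.Series({"s1": 1.7}))
        assert out.loc["s1", "r1"] == 0.0

    def test_doubling_interval_halves_rate(self):
        base, fu = self._tables(0.2, 0.6)
        a = annualize_change(base, fu, pd.Series({"s1": 1.0}))
        b = annualize_change(base, fu, pd.Series({"s1": 2.0}))
        assert a.loc["s1", "r1"] == pytest.approx(2 * b.loc["s1", "r1"])

    def test_nonpositive_interval_rejected(self):
        base, fu = self._tables(0.2, 0.4)
        with pytest.raises(ValueError, match="interval"):
            annualize_change(base, fu, pd.Series({"s1": 0.0}))


class TestLongitudinalGroupModel:
    def _ranks(self, n=64):
        return pd.RangeIndex(1, n + 1)

    def test_constructed_pure_distance_fit(self, rng):
        idx = self._ranks()
        d = pd.Series(np.linspace(1, 10, 64), index=idx)
        base = pd.Series(rng.random(64), index=idx)
        y = pd.Series(-0.5 * d.to_numpy(), index=idx)
        fit = fit_longitudinal_group_model(y, base, d, "IE-IC")
        assert fit.beta_std_distance == pytest.approx(-1.0, abs=1e-9)
        assert fit.beta_std_baseline == pytest.approx(0.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.df == 61

    def test_collinear_predictors_rejected(self):
        idx = self._ranks()
        d = pd.Series(np.linspace(1, 10, 64), index=idx)
        with pytest.raises(ValueError, match="collinear"):
            fit_longitudinal_group_model(d, 2 * d + 1, d)

    def test_ci_contains_point_estimate(self, rng):
        idx = self._ranks()
        d = pd.Series(rng.random(64), index=idx)
        base = pd.Series(rng.random(64), index=idx)
        y = pd.Series(-0.3 * d.to_numpy() + 0.5 * base.to_numpy()
                      + rng.normal(0, 0.1, 64), index=idx)
        fit = fit_longitudinal_group_model(y, base, d)
        assert fit.ci_low < fit.beta_std_distance < fit.ci_high


class TestCompareLongitudinal:
    def _vectors(self, rng):
        idx = pd.RangeIndex(1, 65)
        ref = pd.Series(rng.random(64), index=idx)
        other = pd.Series(0.5 * ref.to_numpy() + 0.5 * rng.random(64),
                          index=idx)
        base = pd.Series(rng.random(64), index=idx)
        y = pd.Series(-0.6 * ref.to_numpy() + 0.3 * base.to_numpy()
                      + rng.normal(0, 0.1, 64), index=idx)
        return ref, other, base, y

    def test_identical_vectors_give_zero_z(self, rng):
        ref, _, base, y = self._vectors(rng)
        out = compare_longitudinal_models(
            {"IE-IC": ref, "IE-GC": ref.copy()}, y, base)
        assert out.loc[0, "z"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_hittner_call(self, rng):
        import statsmodels.api as sm
        ref, other, base, y = self._vectors(rng)
        out = compare_longitudinal_models({"IE-IC": ref, "GE-GC": other},
                                          y, base)
        resid = sm.OLS(y.to_numpy(),
                       sm.add_constant(base.to_numpy())).fit().resid
        expect = hittner_z(np.corrcoef(resid, ref)[0, 1],
                           np.corrcoef(resid, other)[0, 1],
                           np.corrcoef(ref, other)[0, 1], 64)
        assert out.loc[0, "z"] == pytest.approx(expect.z, abs=1e-9)

    def test_antisymmetric_under_swap(self, rng):
        ref, other, base, y = self._vectors(rng)
        a = compare_longitudinal_models({"IE-IC": ref, "GE-GC": other},
                                        y, base, reference="IE-IC")
        b = compare_longitudinal_models({"IE-IC": ref, "GE-GC": other},
                                        y, base, reference="GE-GC")
        assert a.loc[0, "z"] == pytest.approx(-b.loc[0, "z"], abs=1e-12)
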