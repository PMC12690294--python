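"""Subject-level prediction and longitudinal change modeling.

The group models are taken to the single-subject level by pooling the
amyloid-positive training fits (mean intercept/slope across folds),
predicting each subject's regional TPI from their own distance profile,
and summarizing the fit with a standardized beta per subject; a one-way
repeated-measures ANOVA with Bonferroni pairwise tests compares the four
variants. Longitudinally, annualized TPI change is modeled from baseline
distance with baseline TPI as a covariate, and the distance terms of the
four variants are compared with the Hittner-modified Dunn–Clark Z for
dependent overlapping correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .graph import VARIANTS
from .modeling import RegressionResult
from .stats import RMAnovaResult, hittner_z, rm_anova_oneway

logger = logging.getLogger(__name__)

__all__ = [
    "PooledModel",
    "SubjectEffect",
    "average_fold_models",
    "subject_effect_size",
    "compare_effect_sizes",
    "annualize_change",
    "fit_longitudinal_group_model",
    "compare_longitudinal_models",
]


@dataclass(frozen=True)
class PooledModel:
    variant: str
    intercept: float
    slope: float
    n_folds: int


@dataclass(frozen=True)
class SubjectEffect:
    subject: str
    variant: str
    beta_std: float | None
    n_regions: int
    analysis: str = "cross-sectional"
    missing_reason: str = ""


def average_fold_models(train_results: list[RegressionResult],
                        variant: str) -> PooledModel:
    """Arithmetic mean of intercepts and slopes across the training folds."""
    results = [r for r in train_results if r.variant == variant
               and r.role == "train"]
    if not results:
        raise ValueError(f"no training fits for variant {variant!r}")
    folds = {r.fold for r in results}
    if len(folds) != len(results):
        raise ValueError("duplicate folds in training results")
    return PooledModel(
        variant=variant,
        intercept=float(np.mean([r.intercept for r in results])),
        slope=float(np.mean([r.slope for r in results])),
        n_folds=len(results),
    )


def _standardized_coefs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardized coefficients of a multiple OLS fit (no intercept term
    returned): b_j * sd(x_j) / sd(y)."""
    Xc = sm.add_constant(X)
    fit = sm.OLS(y, Xc).fit()
    return fit.params[1:] * X.std(axis=0, ddof=1) / y.std(ddof=1)


def subject_effect_size(
    measured: pd.Series,
    profile: pd.Series,
    pooled: PooledModel,
    baseline: pd.Series | None = None,
    subject: str = "",
    analysis: str = "cross-sectional",
) -> SubjectEffect:
    """Goodness-of-fit of a pooled group model within one subject.

    Cross-sectional: regress the subject's measured TPI on the
    model-predicted TPI; the standardized beta is the effect size.
    Longitudinal (``baseline`` given): regress annualized TPI change on
    predicted change with baseline TPI as covariate and report the
    predicted-term standardized beta. Zero-variance predictions yield a
    missing effect with a reason rather than an error.
    """
    if not measured.index.equals(profile.index):
        raise ValueError("measured and profile region sets differ")
    pred = pooled.intercept + pooled.slope * profile.to_numpy(dtype=float)
    y = measured.to_numpy(dtype=float)
    if np.std(pred, ddof=1) == 0:
        return SubjectEffect(subject, pooled.variant, None, len(y), analysis,
                             missing_reason="zero-variance predictions")
    if baseline is None:
        X = pred[:, None]
    else:
        base = baseline.to_numpy(dtype=float)
        if base.std(ddof=1) > 0:
            r_pb = np.corrcoef(pred, base)[0, 1]
            if abs(r_pb) > 0.995:
                return SubjectEffect(
                    subject, pooled.variant, None, len(y), analysis,
                    missing_reason="predictions collinear with baseline")
        X = np.column_stack([pred, base])
    if y.std(ddof=1) == 0:
        return SubjectEffect(subject, pooled.variant, None, len(y), analysis,
                             missing_reason="zero-variance outcome")
    beta = _standardized_coefs(X, y)[0]
    return SubjectEffect(subject, pooled.variant, float(beta), len(y),
                         analysis)


def compare_effect_sizes(
    effects: pd.DataFrame,
    bonferroni: bool = True,
) -> RMAnovaResult:
    """Repeated-measures ANOVA across model variants on subject effect
    sizes (subjects x variants table; incomplete rows dropped listwise)."""
    cols = [c for c in VARIANTS if c in effects.columns] or list(
        effects.columns)
    return rm_anova_oneway(effects[cols].to_numpy(), condition_names=cols,
                           pairwise=bonferroni)


def annualize_change(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    intervals: pd.Series,
) -> pd.DataFrame:
    """Element-wise (follow-up − baseline) / interval, in units per year."""
    if not baseline.columns.equals(followup.columns):
        raise ValueError("baseline/follow-up regions differ")
    common = baseline.index.intersection(followup.index)
    iv = intervals.loc[common]
    if (iv <= 0).any():
        bad = iv.index[iv <= 0][0]
        raise ValueError(f"non-positive interval for subject {bad!r}")
    return (followup.loc[common] - baseline.loc[common]).div(iv, axis=0)


@dataclass(frozen=True)
class LongitudinalGroupFit:
    variant: str
    r2: float
    beta_std_distance: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    beta_std_baseline: float
    df: int
    n: int


def fit_longitudinal_group_model(
    mean_dchange: pd.Series,
    mean_baseline: pd.Series,
    mean_dist: pd.Series,
    variant: str = "",
) -> LongitudinalGroupFit:
    """Two-predictor OLS: annualized TPI change ~ distance + baseline TPI.

    Vectors are rank-aligned group means over retained regions. The
    distance term's standardized beta (with 95% CI) is the quantity of
    interest. Near-collinear predictors (|r| > 0.999) raise.
    """
    y = mean_dchange.to_numpy(dtype=float)
    d = mean_dist.to_numpy(dtype=float)
    b = mean_baseline.to_numpy(dtype=float)
    if not (len(y) == len(d) == len(b)):
        raise ValueError("vector length mismatch")
    if d.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise ValueError("degenerate fit: zero-variance predictor")
    r_db = np.corrcoef(d, b)[0, 1]
    if abs(r_db) > 0.999:
        raise ValueError(f"predictors nearly collinear (r={r_db:.4f})")

    X = sm.add_constant(np.column_stack([d, b]))
    fit = sm.OLS(y, X).fit()
    # standardized fit for beta_std and its CI
    zd = (d - d.mean()) / d.std(ddof=1)
    zb = (b - b.mean()) / b.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    zfit = sm.OLS(zy, sm.add_constant(np.column_stack([zd, zb]))).fit()
    ci = zfit.conf_int(alpha=0.05)[1]
    return LongitudinalGroupFit(
        variant=variant,
        r2=float(fit.rsquared),
        beta_std_distance=float(zfit.params[1]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        t=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        beta_std_baseline=float(zfit.params[2]),
        df=int(fit.df_resid),
        n=len(y),
    )


def compare_longitudinal_models(
    dist_vectors: dict[str, pd.Series],
    outcome: pd.Series,
    baseline: pd.Series,
    reference: str = "IE-IC",
) -> pd.DataFrame:
    """Hittner Z comparison of each variant's distance association with
    the baseline-adjusted outcome, against a reference variant.

    The outcome is residualized on baseline TPI (OLS); each variant's
    correlation with that residual, together with the inter-variant
    distance correlation, feeds the dependent-correlation Z test.
    """
    y = outcome.to_numpy(dtype=float)
    b = baseline.to_numpy(dtype=float)
    resid = sm.OLS(y, sm.add_constant(b)).fit().resid
    n = len(resid)
    r_ref = np.corrcoef(resid, dist_vectors[reference].to_numpy())[0, 1]
    rows = []
    for variant, vec in dist_vectors.items():
        if variant == reference:
            continue
        r_v = np.corrcoef(resid, vec.to_numpy())[0, 1]
        r_12 = np.corrcoef(dist_vectors[reference].to_numpy(),
                           vec.to_numpy())[0, 1]
        # identical distance vectors: Z is 0 by antisymmetry; clip the
        # inter-variant correlation away from +-1 so the test stays
        # defined
        r_12 = float(np.clip(r_12, -1 + 1e-12, 1 - 1e-12))
        cmp = hittner_z(r_ref, r_v, r_12, n)
        rows.append({"reference": reference, "variant": variant,
                     "r_reference": r_ref, "r_variant": r_v,
                     "r_between": r_12, "z": cmp.z, "p": cmp.p, "n": n})
    return pd.DataFrame(rows)
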