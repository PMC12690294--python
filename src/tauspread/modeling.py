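"""Rank-aligned group regression of regional tau burden on epicenter
distance.

Subjects differ in which regions carry tau, so before group averaging
each subject's regions are re-ordered from highest to lowest TPI and the
same permutation is applied to that subject's covariate-adjusted TPI and
to each variant's distance-from-epicenter profile. Averaging at each
rank across subjects yields 64-length group vectors on which ordinary
least squares relates mean TPI to mean distance for the four variants
(IE-IC, IE-GC, GE-IC, GE-GC), with stratified 5-fold train/test
validation and paired-t comparison of fold-wise fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "residualize_tpi",
    "rank_align",
    "rank_align_and_average",
    "stratified_kfold",
    "fit_group_model",
    "fit_interaction_model",
    "evaluate_model",
    "compare_folds",
]

COVARIATE_FORMULA = ("age + C(sex) + education + C(race) + C(study) "
                     "+ scan_interval")


@dataclass(frozen=True)
class RegressionResult:
    """Outputs of a (possibly standardized) linear fit."""

    beta_std: float
    intercept: float
    slope: float
    t: float
    p: float
    df: int
    r2: float
    adj_r2: float
    rmse: float
    n: int
    variant: str = ""
    fold: int = -1
    role: str = "train"


def residualize_tpi(
    tpi: pd.DataFrame,
    metadata: pd.DataFrame,
    method: str = "mixed",
) -> pd.DataFrame:
    """Regress subject-level covariates out of TPI.

    One model over all region-level observations with fixed effects for
    age, sex, education, race, study and PET–dMRI scan interval and a
    random intercept per participant; returns conditional residuals
    (observed − fixed prediction − participant intercept). ``method=
    "fixed"`` (also the fallback when the mixed fit fails) uses plain OLS
    residuals.
    """
    needed = ["age", "sex", "education", "race", "study", "scan_interval"]
    missing = [c for c in needed if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing covariates: {missing}")
    for c in needed:
        bad = metadata.loc[list(tpi.index), c].isna()
        if bad.any():
            raise ValueError(
                f"missing covariate {c!r} for subject {bad.idxmax()!r}")

    long = tpi.stack().rename("tpi").reset_index()
    long.columns = ["subject_id", "region", "tpi"]
    long = long.merge(metadata[needed], left_on="subject_id",
                      right_index=True)

    if method == "mixed":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(f"tpi ~ {COVARIATE_FORMULA}", long,
                                    groups=long["subject_id"])
                fit = model.fit(reml=True, method="lbfgs")
            fixed_pred = fit.predict(long)
            rand = {k: float(v.iloc[0]) for k, v in fit.random_effects.items()}
            resid = (long["tpi"] - fixed_pred
                     - long["subject_id"].map(rand).astype(float))
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("mixed-model residualization failed (%s); "
                           "falling back to fixed-effects OLS", exc)
            method = "fixed"
    if method == "fixed":
        fit = smf.ols(f"tpi ~ {COVARIATE_FORMULA}", long).fit()
        resid = fit.resid
    long["resid"] = np.asarray(resid, dtype=float)
    out = long.pivot(index="subject_id", columns="region", values="resid")
    return out.loc[tpi.index, tpi.columns]


def rank_align(tpi_raw_row: pd.Series) -> np.ndarray:
    """Permutation ordering a subject's regions by descending raw TPI
    (ties broken by region label, ascending)."""
    labels = np.asarray(tpi_raw_row.index, dtype=str)
    values = tpi_raw_row.to_numpy(dtype=float)
    return np.lexsort((labels, -values))


def rank_align_and_average(
    tpi_raw: pd.DataFrame,
    tpi_adjusted: pd.DataFrame,
    profiles: dict[str, pd.DataFrame],
    subjects=None,
) -> tuple[pd.Series, dict[str, pd.Series]]:
    """Group vectors by TPI rank: mean adjusted TPI and, per variant,
    mean distance from epicenters at each rank.

    Rank is computed on raw TPI and the same per-subject permutation is
    applied to adjusted TPI and to every distance profile. Subjects with
    a missing (NaN) profile under any variant are excluded with a
    warning.
    """
    if subjects is None:
        subjects = list(tpi_raw.index)
    usable = []
    for s in subjects:
        if any(profiles[v].loc[s].isna().any() for v in profiles):
            logger.warning("rank_align_and_average: excluding %r "
                           "(missing distance profile)", s)
            continue
        usable.append(s)
    if not usable:
        raise ValueError("no subjects with complete profiles")

    n_regions = tpi_raw.shape[1]
    tpi_stack = np.empty((len(usable), n_regions))
    dist_stack = {v: np.empty((len(usable), n_regions)) for v in profiles}
    for i, s in enumerate(usable):
        perm = rank_align(tpi_raw.loc[s])
        tpi_stack[i] = tpi_adjusted.loc[s].to_numpy(dtype=float)[perm]
        for v in profiles:
            dist_stack[v][i] = profiles[v].loc[s].to_numpy(dtype=float)[perm]
    ranks = pd.RangeIndex(1, n_regions + 1, name="rank")
    mean_tpi = pd.Series(tpi_stack.mean(axis=0), index=ranks)
    mean_dist = {v: pd.Series(dist_stack[v].mean(axis=0), index=ranks)
                 for v in profiles}
    return mean_tpi, mean_dist


def stratified_kfold(
    metadata: pd.DataFrame,
    k: int = 5,
    stratify_on: str = "amyloid_positive",
    seed: int = 17,
) -> pd.Series:
    """Deterministic stratified fold assignment (fold = test split)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    strata = metadata[stratify_on].to_numpy()
    for value, count in zip(*np.unique(strata, return_counts=True)):
        if count < k:
            raise ValueError(f"stratum {value!r} has {count} < k subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = pd.Series(-1, index=metadata.index, name="fold")
    for f, (_, test_ix) in enumerate(skf.split(np.zeros(len(strata)), strata)):
        fold.iloc[test_ix] = f
    return fold


def _ols_summary(x: np.ndarray, y: np.ndarray, variant="", fold=-1,
                 role="train") -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std(ddof=1) == 0:
        raise ValueError("degenerate fit: zero-variance predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    beta_std = float(fit.params[1] * x.std(ddof=1) / y.std(ddof=1))
    resid = y - fit.fittedvalues
    return RegressionResult(
        beta_std=beta_std,
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        t=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        df=int(fit.df_resid),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=len(y),
        variant=variant, fold=fold, role=role,
    )


def fit_group_model(
    mean_tpi: pd.Series,
    mean_dist: pd.Series,
    variant: str = "",
    fold: int = -1,
) -> RegressionResult:
    """OLS of rank-averaged TPI on rank-averaged epicenter distance."""
    if len(mean_tpi) != len(mean_dist):
        raise ValueError("vector length mismatch")
    return _ols_summary(mean_dist.to_numpy(), mean_tpi.to_numpy(),
                        variant=variant, fold=fold, role="train")


def fit_interaction_model(
    mean_tpi_by_group: dict[str, pd.Series],
    mean_dist_by_group: dict[str, pd.Series],
    variant: str = "",
) -> dict:
    """Distance x group interaction on stacked group-wise rank averages.

    Fits ``TPI ~ distance * group`` on the concatenated per-group rank
    vectors (2 x 64 points for an amyloid +/- split) and reports the
    interaction coefficient's t and p.
    """
    groups = sorted(mean_tpi_by_group)
    if len(groups) != 2:
        raise ValueError("interaction model needs exactly 2 groups")
    y = np.concatenate([mean_tpi_by_group[g].to_numpy() for g in groups])
    d = np.concatenate([mean_dist_by_group[g].to_numpy() for g in groups])
    g = np.concatenate([np.full(len(mean_tpi_by_group[gr]), i)
                        for i, gr in enumerate(groups)])
    X = sm.add_constant(np.column_stack([d, g, d * g]))
    fit = sm.OLS(y, X).fit()
    return {
        "variant": variant,
        "groups": tuple(groups),
        "interaction_coef": float(fit.params[3]),
        "interaction_t": float(fit.tvalues[3]),
        "interaction_p": float(fit.pvalues[3]),
        "r2": float(fit.rsquared),
        "n": int(len(y)),
    }


def evaluate_model(
    train: RegressionResult,
    test_tpi: pd.Series,
    test_dist: pd.Series,
) -> RegressionResult:
    """Apply a trained model to held-out rank vectors.

    Predicted TPI = intercept + slope * test distance; measured TPI is
    regressed on predicted TPI (positive standardized beta = successful
    prediction).
    """
    if len(test_tpi) != len(test_dist):
        raise ValueError("test vector length mismatch")
    pred = train.intercept + train.slope * test_dist.to_numpy()
    if np.std(pred, ddof=1) == 0:
        raise ValueError("degenerate fit: constant predictions "
                         "(zero train slope)")
    res = _ols_summary(pred, test_tpi.to_numpy(), variant=train.variant,
                       fold=train.fold, role="test")
    return res


def compare_folds(r2_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise paired t-tests on per-fold R² between variants.

    ``r2_table`` is folds x variants. df = folds − 1. Constant nonzero
    differences produce an unbounded t (reported as inf, p=0, warning).
    """
    from .stats import paired_t

    if r2_table.shape[0] < 2:
        raise ValueError("need >= 2 folds")
    rows = []
    variants = list(r2_table.columns)
    for i, va in enumerate(variants):
        for vb in variants[i + 1:]:
            t, df, p = paired_t(r2_table[va].to_numpy(),
                                r2_table[vb].to_numpy())
            rows.append({"variant_a": va, "variant_b": vb,
                         "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)
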