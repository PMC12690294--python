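"""Statistical primitives used across the pipeline.

Self-contained implementations of the dependent-correlation comparison
(Dunn–Clark Z with Hittner's backtransformed-mean modification), the
two-way random-effects intraclass correlation ICC(2,1), one-way
repeated-measures ANOVA with Bonferroni-corrected pairwise paired
t-tests, and standardized regression coefficients.

Every primitive is written from its ANOVA/Fisher-z definition so that
independent oracles (brute-force sum-of-squares, simulation) can verify
it; none delegates the core formula to an external package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationComparison",
    "hittner_z",
    "icc_2_1",
    "rm_anova_oneway",
    "paired_t",
    "standardized_beta",
]


@dataclass(frozen=True)
class CorrelationComparison:
    """Comparison of two dependent, overlapping correlations.

    ``r_y1`` and ``r_y2`` are correlations of a shared outcome with two
    predictors whose mutual correlation is ``r_12``; ``n`` is the common
    sample size.
    """

    r_y1: float
    r_y2: float
    r_12: float
    n: int
    z: float
    p: float
    method: str = "hittner-dunn-clark"


def hittner_z(r_y1: float, r_y2: float, r_12: float, n: int) -> CorrelationComparison:
    """Test equality of two overlapping dependent correlations.

    Uses Dunn and Clark's Z on Fisher-transformed correlations with the
    covariance term evaluated at the backtransformed mean Fisher z of the
    two outcome correlations (Hittner's modification).

    Parameters
    ----------
    r_y1, r_y2
        Correlation of the shared variable with predictor 1 and 2.
    r_12
        Correlation between the two predictors.
    n
        Sample size (must be >= 4).

    Returns
    -------
    CorrelationComparison
        Z statistic (positive when ``r_y1 > r_y2``) and two-sided p.
    """
    for name, r in (("r_y1", r_y1), ("r_y2", r_y2), ("r_12", r_12)):
        if not np.isfinite(r) or abs(r) >= 1.0:
            raise ValueError(f"{name}={r} must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError(f"n={n} too small; need n >= 4")

    z1 = np.arctanh(r_y1)
    z2 = np.arctanh(r_y2)
    # backtransformed average Fisher z (Hittner's choice of pooled r)
    rm = np.tanh(0.5 * (z1 + z2))
    cov = (
        r_12 * (1.0 - 2.0 * rm**2)
        - 0.5 * rm**2 * (1.0 - 2.0 * rm**2 - r_12**2)
    ) / (1.0 - rm**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - cov)))
    p = 2.0 * sps.norm.sf(abs(z))
    logger.debug(
        "hittner_z: r_y1=%.4f r_y2=%.4f r_12=%.4f n=%d rm=%.4f cov=%.4f z=%.4f",
        r_y1, r_y2, r_12, n, rm, cov, z,
    )
    return CorrelationComparison(r_y1, r_y2, r_12, n, float(z), float(p))


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_targets: int
    n_raters: int


def icc_2_1(ratings: np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is a targets x raters matrix with no missing cells.

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    where MSR, MSC, MSE are the row (target), column (rater) and residual
    mean squares of the two-way ANOVA decomposition.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D targets x raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >=2 targets and >=2 raters, got {n}x{k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings contain missing or non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_error = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    logger.debug("icc_2_1: MSR=%.6g MSC=%.6g MSE=%.6g", msr, msc, mse)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 0 and mse <= 0:
        raise ValueError(
            "ICC undefined: ratings matrix has no between-target variance "
            "(all targets identical)"
        )
    if denom == 0:
        raise ValueError("ICC undefined: zero denominator (constant ratings)")
    return ICCResult(float((msr - mse) / denom), float(msr), float(msc),
                     float(mse), n, k)


@dataclass(frozen=True)
class PairwiseComparison:
    level_a: str
    level_b: str
    t: float
    df: int
    p_uncorrected: float
    p_bonferroni: float


@dataclass(frozen=True)
class RMAnovaResult:
    f: float
    df1: int
    df2: int
    p: float
    ms_condition: float
    ms_error: float
    n_subjects: int
    n_conditions: int
    pairwise: tuple[PairwiseComparison, ...] = field(default=())


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test returning (t, df, p).

    A constant nonzero difference vector has zero variance; its t is
    reported as signed infinity with p = 0 (and a warning is logged)
    rather than NaN so that downstream tables stay interpretable.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t requires two equal-length 1-D arrays")
    if a.size < 2:
        raise ValueError("paired_t requires at least 2 pairs")
    d = a - b
    df = d.size - 1
    sd = d.std(ddof=1)
    # constant differences up to float representation
    if sd <= 1e-9 * max(1.0, float(np.abs(d).mean())):
        if d.mean() == 0:
            return 0.0, df, 1.0
        logger.warning("paired_t: constant nonzero differences; t unbounded")
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def rm_anova_oneway(
    data: np.ndarray,
    condition_names: list[str] | None = None,
    pairwise: bool = True,
) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    F = MS_condition / MS_error with df = (k−1, (k−1)(n−1)); rows with any
    missing cell are dropped listwise. Pairwise paired t-tests are
    Bonferroni-corrected by the number of pairs actually compared.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be subjects x conditions")
    keep = np.all(np.isfinite(x), axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("rm_anova_oneway: listwise deletion of %d subjects", dropped)
    x = x[keep]
    n, k = x.shape
    if n < 3:
        raise ValueError(f"need >=3 complete subjects, got {n}")
    if k < 2:
        raise ValueError(f"need >=2 conditions, got {k}")
    if condition_names is None:
        condition_names = [f"cond{i}" for i in range(k)]

    grand = x.mean()
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = max(ss_total - ss_subj - ss_cond, 0.0)
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    logger.debug("rm_anova: SScond=%.6g SSerr=%.6g MScond=%.6g MSerr=%.6g",
                 ss_cond, ss_err, ms_cond, ms_err)
    tiny = 1e-12 * max(ss_total, 1.0)  # float dust from the decomposition
    if ss_err <= tiny:
        f = 0.0 if ss_cond <= tiny else float("inf")
        p = 1.0 if ss_cond <= tiny else 0.0
    else:
        f = ms_cond / ms_err
        p = float(sps.f.sf(f, df1, df2))

    comparisons: list[PairwiseComparison] = []
    if pairwise:
        n_pairs = k * (k - 1) // 2
        for i in range(k):
            for j in range(i + 1, k):
                t, df, p_unc = paired_t(x[:, i], x[:, j])
                comparisons.append(PairwiseComparison(
                    condition_names[i], condition_names[j],
                    t, df, p_unc, min(1.0, p_unc * n_pairs),
                ))
    return RMAnovaResult(float(f), df1, df2, float(p), float(ms_cond),
                         float(ms_err), n, k, tuple(comparisons))


def standardized_beta(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized slope of the simple regression of y on x.

    Equals the Pearson correlation for a single predictor; raises on a
    zero-variance predictor or outcome.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("standardized_beta undefined for zero-variance input")
    return float(np.cov(x, y, ddof=1)[0, 1] / (sx * sy))
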