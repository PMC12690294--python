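"""Gaussian-mixture modeling of regional SUVR and the tau pathology index.

Flortaucipir PET shows off-target ("non-specific") binding in several
regions. Pooling each region's SUVR values over all subjects, regions are
fit with a single Gaussian and a two-component Gaussian mixture; regions
better fit by the single Gaussian are treated as non-specific-binding and
excluded. For retained regions, the higher-mean component is the
pathologic distribution and the lower-mean one the non-pathologic
distribution, and SUVR x maps to the tau pathology index

    TPI(x) = F_p(x) + F_n(x) - 1

where F_p, F_n are the component Gaussian CDFs. TPI is strictly
increasing in x and bounded in (-1, 1): -1 means clearly non-pathologic
signal, +1 clearly pathologic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianFit",
    "MixtureFit",
    "RegionMixtureModel",
    "fit_gaussian_mixture",
    "select_binding_model",
    "fit_region_models",
    "tpi_transform",
    "build_tpi_table",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GaussianFit:
    """Single-Gaussian MLE: mean, SD, log-likelihood, n, BIC."""

    mu: float
    sigma: float
    loglik: float
    n: int

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + 2.0 * np.log(self.n)


@dataclass(frozen=True)
class MixtureFit:
    """Two-component Gaussian mixture fit (components sorted by mean)."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sigmas: tuple[float, float]
    loglik: float
    n: int
    n_iter: int
    converged: bool
    variance_floored: bool = False

    @property
    def bic(self) -> float:
        # 5 free parameters: 2 means, 2 SDs, 1 mixing weight
        return -2.0 * self.loglik + 5.0 * np.log(self.n)


@dataclass(frozen=True)
class RegionMixtureModel:
    """Per-region model-selection verdict and component labels.

    ``retained`` is True when the two-component model wins; the pathologic
    component is always the higher-mean one (index 1 after sorting).
    """

    region: str
    one: GaussianFit
    two: MixtureFit
    retained: bool

    @property
    def mu_n(self) -> float:
        return self.two.means[0]

    @property
    def sigma_n(self) -> float:
        return self.two.sigmas[0]

    @property
    def mu_p(self) -> float:
        return self.two.means[1]

    @property
    def sigma_p(self) -> float:
        return self.two.sigmas[1]

    def to_dict(self) -> dict:
        d = {
            "region": self.region,
            "retained": self.retained,
            "one": asdict(self.one) | {"bic": self.one.bic},
            "two": asdict(self.two) | {"bic": self.two.bic},
        }
        return d


def _loglik_k1(x: np.ndarray, mu: float, sigma: float) -> float:
    z = (x - mu) / sigma
    return float(-0.5 * np.sum(z * z) - x.size * (np.log(sigma) + 0.5 * _LOG2PI))


def fit_gaussian_mixture(
    values: np.ndarray,
    k: int,
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
    seed: int = 0,
    min_obs: int = 20,
    var_floor_frac: float = 1e-6,
) -> GaussianFit | MixtureFit:
    """Fit a 1- or 2-component Gaussian model by maximum likelihood.

    k=1 is the closed-form sample MLE. k=2 runs EM initialized by a
    median split, with ``n_restarts`` mean-perturbed restarts keeping the
    best log-likelihood. Component variances are floored at
    ``var_floor_frac`` times the sample variance to prevent singular
    collapse; if every restart collapses the floored fit is returned with
    a warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < min_obs:
        raise ValueError(f"insufficient data: n={x.size} < min_obs={min_obs}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")

    n = x.size
    sample_var = float(np.var(x))
    var_floor = max(var_floor_frac * sample_var, 1e-24)
    sd_floor = np.sqrt(var_floor)

    if k == 1:
        mu = float(np.mean(x))
        sigma = max(float(np.sqrt(sample_var)), sd_floor)
        return GaussianFit(mu, sigma, _loglik_k1(x, mu, sigma), n)

    rng = np.random.default_rng(seed)
    xs = np.sort(x)
    lo, hi = xs[: n // 2], xs[n // 2:]
    base_means = np.array([lo.mean(), hi.mean()])
    spread = max(float(x.std()), sd_floor)

    means0 = np.empty((n_restarts, 2))
    means0[0] = base_means
    for restart in range(1, n_restarts):
        means0[restart] = base_means + rng.normal(0.0, 0.25 * spread, size=2)
    sigmas0 = np.full((n_restarts, 2), max(0.5 * spread, sd_floor))
    weights0 = np.full((n_restarts, 2), 0.5)
    fits = _em_two_component_batch(
        np.broadcast_to(x, (n_restarts, n)), weights0, means0, sigmas0,
        tol, max_iter, np.full(n_restarts, var_floor))
    best = max(fits, key=lambda f: f.loglik)
    if best.variance_floored:
        logger.warning("fit_gaussian_mixture: variance floor active in the "
                       "best 2-component fit (near-singular component)")
    return best


def _em_two_component_batch(
    X: np.ndarray,        # (C, n) data per chain
    weights: np.ndarray,  # (C, 2)
    means: np.ndarray,    # (C, 2)
    sigmas: np.ndarray,   # (C, 2)
    tol: float,
    max_iter: int,
    var_floor: np.ndarray,  # (C,)
    trace_out: list | None = None,
) -> list[MixtureFit]:
    """Run many independent 2-component EM chains in lock-step.

    Converged chains are frozen (their parameters no longer update) while
    the rest continue; per-chain log-likelihood is non-decreasing. When
    ``trace_out`` is a list, the full (C,) log-likelihood vector is
    appended each iteration (frozen chains repeat their last value).
    """
    C, n = X.shape
    weights = weights.copy().astype(float)
    means = means.copy().astype(float)
    sigmas = sigmas.copy().astype(float)
    prev_ll = np.full(C, -np.inf)
    ll = prev_ll.copy()
    n_iter = np.zeros(C, dtype=int)
    floored = np.zeros(C, dtype=bool)
    active = np.ones(C, dtype=bool)
    vf = var_floor[:, None]

    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        x = X[idx]                                   # (c, n)
        w, mu, sg = weights[idx], means[idx], sigmas[idx]
        logp = (np.log(w)[:, :, None] - np.log(sg)[:, :, None]
                - 0.5 * _LOG2PI
                - 0.5 * ((x[:, None, :] - mu[:, :, None])
                         / sg[:, :, None]) ** 2)     # (c, 2, n)
        m = logp.max(axis=1)
        lse = m + np.log(np.exp(logp - m[:, None, :]).sum(axis=1))
        ll_new = lse.sum(axis=1)
        resp = np.exp(logp - lse[:, None, :])

        nk = np.maximum(resp.sum(axis=2), 1e-12)     # (c, 2)
        w_new = nk / n
        mu_new = (resp * x[:, None, :]).sum(axis=2) / nk
        var = (resp * (x[:, None, :] - mu_new[:, :, None]) ** 2
               ).sum(axis=2) / nk
        low = var < vf[idx]
        if low.any():
            floored[idx[low.any(axis=1)]] = True
            var = np.maximum(var, vf[idx])

        weights[idx], means[idx], sigmas[idx] = w_new, mu_new, np.sqrt(var)
        ll[idx] = ll_new
        n_iter[idx] = it
        done = np.abs(ll_new - prev_ll[idx]) < tol
        prev_ll[idx] = ll_new
        active[idx[done]] = False
        if trace_out is not None:
            trace_out.append(ll.copy())

    fits = []
    for c in range(C):
        order = np.argsort(means[c])
        fits.append(MixtureFit(
            weights=tuple(float(v) for v in weights[c][order]),
            means=tuple(float(v) for v in means[c][order]),
            sigmas=tuple(float(v) for v in sigmas[c][order]),
            loglik=float(ll[c]),
            n=n,
            n_iter=int(n_iter[c]),
            converged=bool(not active[c]),
            variance_floored=bool(floored[c]),
        ))
    return fits


def em_loglik_trace(
    values: np.ndarray,
    *,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
    var_floor_frac: float = 1e-6,
) -> np.ndarray:
    """Per-iteration log-likelihoods of the 2-component EM restarts.

    Returns an (n_iterations, n_restarts) array; each column is
    non-decreasing (EM ascent property). Intended for diagnostics and
    invariant checks.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    rng = np.random.default_rng(seed)
    var_floor = max(var_floor_frac * float(np.var(x)), 1e-24)
    sd_floor = np.sqrt(var_floor)
    xs = np.sort(x)
    base_means = np.array([xs[: n // 2].mean(), xs[n // 2:].mean()])
    spread = max(float(x.std()), sd_floor)
    means0 = np.empty((n_restarts, 2))
    means0[0] = base_means
    for r in range(1, n_restarts):
        means0[r] = base_means + rng.normal(0.0, 0.25 * spread, size=2)
    trace: list = []
    _em_two_component_batch(
        np.broadcast_to(x, (n_restarts, n)),
        np.full((n_restarts, 2), 0.5), means0,
        np.full((n_restarts, 2), max(0.5 * spread, sd_floor)),
        tol, max_iter, np.full(n_restarts, var_floor), trace_out=trace)
    return np.asarray(trace)


def select_binding_model(one: GaussianFit, two: MixtureFit) -> bool:
    """Return True (retained) iff the two-component model wins on BIC.

    A tie in BIC, or a two-component fit whose component means coincide
    (effectively unimodal), is excluded.
    """
    if one.n != two.n:
        raise ValueError(f"fits disagree on n: {one.n} vs {two.n}")
    if two.means[1] <= two.means[0]:
        return False
    return bool(two.bic < one.bic)


def fit_region_models(
    suvr: pd.DataFrame,
    *,
    seed: int = 0,
    min_obs: int = 20,
    **fit_kwargs,
) -> dict[str, RegionMixtureModel]:
    """Fit and select 1- vs 2-component models for every region column.

    ``suvr`` is a subjects x regions table pooled over the cohort (the
    fitting cohort may be larger than the analysis cohort).
    """
    tol = fit_kwargs.pop("tol", 1e-8)
    max_iter = fit_kwargs.pop("max_iter", 500)
    n_restarts = fit_kwargs.pop("n_restarts", 5)
    var_floor_frac = fit_kwargs.pop("var_floor_frac", 1e-6)
    if fit_kwargs:
        raise TypeError(f"unexpected arguments: {sorted(fit_kwargs)}")

    regions = [str(r) for r in suvr.columns]
    n = suvr.shape[0]
    if n < min_obs:
        raise ValueError(f"insufficient data: n={n} < min_obs={min_obs}")
    X = suvr.to_numpy(dtype=float).T  # (R, n)
    if not np.all(np.isfinite(X)):
        raise ValueError("SUVR table contains non-finite values")
    R = len(regions)

    ones = [fit_gaussian_mixture(X[i], 1, min_obs=min_obs) for i in range(R)]

    # all regions share n, so the 2-component fits (with all restarts)
    # run as one lock-step EM batch
    var_floor = np.maximum(var_floor_frac * X.var(axis=1), 1e-24)
    spread = np.maximum(X.std(axis=1), np.sqrt(var_floor))
    Xs = np.sort(X, axis=1)
    base_means = np.column_stack([Xs[:, : n // 2].mean(axis=1),
                                  Xs[:, n // 2:].mean(axis=1)])
    chains_x = np.repeat(X, n_restarts, axis=0)
    means0 = np.empty((R * n_restarts, 2))
    for i in range(R):
        rng = np.random.default_rng(seed + i)
        for rs in range(n_restarts):
            c = i * n_restarts + rs
            if rs == 0:
                means0[c] = base_means[i]
            else:
                means0[c] = base_means[i] + rng.normal(
                    0.0, 0.25 * spread[i], size=2)
    sigmas0 = np.repeat(np.maximum(0.5 * spread, np.sqrt(var_floor)),
                        n_restarts)[:, None].repeat(2, axis=1)
    weights0 = np.full((R * n_restarts, 2), 0.5)
    fits = _em_two_component_batch(
        chains_x, weights0, means0, sigmas0, tol, max_iter,
        np.repeat(var_floor, n_restarts))

    models: dict[str, RegionMixtureModel] = {}
    for i, region in enumerate(regions):
        cand = fits[i * n_restarts:(i + 1) * n_restarts]
        two = max(cand, key=lambda f: f.loglik)
        models[region] = RegionMixtureModel(
            region=region, one=ones[i], two=two,
            retained=select_binding_model(ones[i], two),
        )
    n_kept = sum(m.retained for m in models.values())
    logger.info("fit_region_models: %d/%d regions retained", n_kept, len(models))
    return models


def tpi_transform(x, model: RegionMixtureModel):
    """Map SUVR to the tau pathology index for a retained region.

    TPI(x) = F_p(x) + F_n(x) - 1, with F_p/F_n the CDFs of the
    pathologic (higher-mean) and non-pathologic components.
    """
    if not model.retained:
        raise ValueError(f"region {model.region} was excluded "
                         "(single-Gaussian fit preferred); TPI undefined")
    return (norm.cdf(x, model.mu_p, model.sigma_p)
            + norm.cdf(x, model.mu_n, model.sigma_n) - 1.0)


def build_tpi_table(
    suvr: pd.DataFrame,
    models: dict[str, RegionMixtureModel],
) -> pd.DataFrame:
    """Convert a subjects x regions SUVR table to TPI over retained regions.

    Excluded regions are dropped (and logged); a missing SUVR value in a
    retained region raises, naming the subject and region.
    """
    retained = [r for r in suvr.columns if r in models and models[r].retained]
    dropped = [r for r in suvr.columns if r not in retained]
    if dropped:
        logger.info("build_tpi_table: dropping %d excluded regions", len(dropped))
    out = {}
    for region in retained:
        col = suvr[region]
        if col.isna().any():
            subj = col.index[col.isna()][0]
            raise ValueError(f"missing SUVR for subject {subj!r}, "
                             f"region {region!r}")
        out[region] = tpi_transform(col.to_numpy(dtype=float), models[region])
    return pd.DataFrame(out, index=suvr.index)


def save_models(models: dict[str, RegionMixtureModel], path) -> None:
    with open(path, "w") as fh:
        json.dump({r: m.to_dict() for r, m in models.items()}, fh, indent=1)


def load_models(path) -> dict[str, RegionMixtureModel]:
    with open(path) as fh:
        raw = json.load(fh)
    models = {}
    for region, d in raw.items():
        one = GaussianFit(d["one"]["mu"], d["one"]["sigma"],
                          d["one"]["loglik"], d["one"]["n"])
        t = d["two"]
        two = MixtureFit(tuple(t["weights"]), tuple(t["means"]),
                         tuple(t["sigmas"]), t["loglik"], t["n"],
                         t["n_iter"], t["converged"],
                         t.get("variance_floored", False))
        models[region] = RegionMixtureModel(region, one, two, d["retained"])
    return models
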