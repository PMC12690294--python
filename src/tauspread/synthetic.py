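"""Synthetic cohort generator with known ground truth.

Real tau-PET/dMRI cohorts of this kind are access-controlled, so every
downstream stage is exercised on synthetic cohorts that reproduce the
qualitative structure the analysis assumes:

* a 104-region parcellation, 40 of whose regions carry only
  non-specific binding (unimodal SUVR) while 64 carry a two-component
  mixture of non-pathologic and pathologic signal;
* dense, heavy-tailed structural connectomes: log-normal edge weights
  with exponential decay in a latent 3-D embedding, clipped to [0, 1],
  individually perturbed per subject by multiplicative log-normal noise;
* subject-specific epicenters drawn from a pool in which a small
  "limbic-like" subset (entorhinal, amygdala, hippocampal,
  parahippocampal labels) is strongly favored, with 1–7 epicenters per
  subject;
* a distance-graded pathologic occupancy: a subject draws region r's
  SUVR from the pathologic component with probability
  severity * logistic(a − b * d̄_r), where d̄_r is the mean shortest-path
  distance of r from the subject's epicenters on the subject's own
  connectome;
* amyloid-status severity differences (amyloid-negative subjects sample
  the lower third of the severity scale, so individualized-epicenter
  models remain informative in that group), small linear covariate
  effects, and longitudinal accumulation proportional to connectome
  proximity to epicenters.

All randomness flows through one ``numpy.random.default_rng(seed)``;
identical configs give bit-identical cohorts.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticCohort",
    "default_region_labels",
    "generate_connectomes",
    "generate_regional_suvr",
    "generate_longitudinal",
    "generate_cohort",
]

#: Limbic-like labels that seed the epicenter pool and carry the
#: canonical bilateral-entorhinal group epicenter.
LIMBIC_LABELS = (
    "ERC_L", "ERC_R", "Amygdala_L", "Amygdala_R",
    "Hippocampus_L", "Hippocampus_R",
    "Parahippocampal_L", "Parahippocampal_R",
)


def default_region_labels(n_regions: int = 104) -> tuple[str, ...]:
    """Region labels: 8 named limbic-like regions, then generic cortex."""
    if n_regions < len(LIMBIC_LABELS):
        raise ValueError("need at least 8 regions for the limbic labels")
    generic = tuple(f"ctx_{i:03d}" for i in range(len(LIMBIC_LABELS), n_regions))
    return LIMBIC_LABELS + generic


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Defaults emulate the study's data structure: 104 regions, 40
    non-specific; ~36% amyloid-positive; inter-scan intervals around
    3.18 ± 1.35 years. Mixture parameters are drawn per region from the
    stated ranges (well separated, Δμ/σ >= ~4) unless ``mixture_truth``
    supplies explicit per-region (μ_n, σ_n, μ_p, σ_p) rows.
    """

    n_subjects: int = 200
    n_regions: int = 104
    n_nonspecific_regions: int = 40
    mixture_truth: np.ndarray | None = None
    mu_n_range: tuple[float, float] = (1.0, 1.25)
    sigma_n_range: tuple[float, float] = (0.05, 0.08)
    delta_mu_range: tuple[float, float] = (0.45, 0.65)
    sigma_p_range: tuple[float, float] = (0.06, 0.10)
    # connectome weight law: w = scale * exp(-decay * ||x_i - x_j||) * LN(0, sigma)
    weight_scale: float = 0.5
    weight_decay: float = 6.0
    weight_sigma: float = 0.6
    subject_noise_sd: float = 1.0
    # epicenters
    limbic_pool_weight: float = 10.0
    epicenter_count_range: tuple[int, int] = (1, 7)
    # pathologic occupancy p_r = severity * logistic(a - b * dbar_r)
    distance_effect: tuple[float, float] = (1.0, 0.25)
    # pathologic draws sit at mu_n + (mu_p - mu_n) * (1 - g + g * logistic)
    # with g = depth_grading: burden within affected regions is itself
    # graded by connectome proximity (0 -> pure binary occupancy)
    depth_grading: float = 0.7
    # sub-threshold grading of the non-pathologic mean in mixture regions:
    # mu_n + sub_grading * (mu_p - mu_n) * logistic (0 -> flat non-path)
    sub_grading: float = 0.12
    # pathologic depth also scales with subject severity:
    # depth multiplier = (1 - severity_depth) + severity_depth * severity,
    # so only severe subjects reach the top of the pooled pathologic
    # distribution (0 -> severity-independent depth)
    severity_depth: float = 0.4
    # seed (epicenter) regions draw this many pathologic SDs above their
    # graded component mean: the source regions carry the deepest burden
    epicenter_boost_sd: float = 1.5
    severity_range_abpos: tuple[float, float] = (0.55, 1.0)
    severity_range_abneg: tuple[float, float] = (0.15, 0.35)
    amyloid_positive_fraction: float = 0.36
    # subject-level linear covariate effects on SUVR (standardized-small)
    covariate_effects: dict = field(default_factory=lambda: {
        "age": 0.0015,        # per year from age 71
        "sex_male": 0.010,
        "education": -0.0020,  # per year from 16
        "race": 0.005,         # non-white indicator
        "study_adni": 0.005,
        "scan_interval": 0.005,  # per year of PET-dMRI gap
    })
    # longitudinal spread: a baseline-non-pathologic mixture region
    # converts to the pathologic component with per-year hazard
    # severity * conversion_hazard * logistic(a - b * dbar_r); converted
    # regions redraw from the (graded) pathologic component, all regions
    # additionally drift by N(0, drift_sd * sqrt(years)) on the SUVR scale
    conversion_hazard: float = 0.35
    drift_sd: float = 0.005
    interval_mean: float = 3.18
    interval_sd: float = 1.35
    suvr_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0 or self.n_regions <= 0:
            raise ValueError("n_subjects and n_regions must be positive")
        if not 0 <= self.n_nonspecific_regions < self.n_regions:
            raise ValueError("n_nonspecific_regions must be < n_regions")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be >= 0")
        if self.distance_effect[1] < 0:
            raise ValueError("distance effect slope b must be >= 0")
        if self.weight_scale <= 0 or self.weight_scale > 1:
            raise ValueError("weight_scale must be in (0, 1]")

    @property
    def region_labels(self) -> tuple[str, ...]:
        return default_region_labels(self.n_regions)

    @property
    def n_mixture_regions(self) -> int:
        return self.n_regions - self.n_nonspecific_regions


@dataclass(frozen=True)
class GroundTruth:
    """Recovery targets for tests: everything the generator knows."""

    epicenters: dict[str, tuple[str, ...]]
    severity: dict[str, float]
    amyloid_positive: dict[str, bool]
    unimodal: pd.Series            # region -> bool
    mixture_params: pd.DataFrame   # region x (mu_n, sigma_n, mu_p, sigma_p)
    distance_effect: tuple[float, float]
    distance_profiles: pd.DataFrame  # subject x region mean epicenter distance
    pathologic_draws: pd.DataFrame   # subject x region bool
    annualized_rates: pd.DataFrame | None = None  # realized SUVR change/yr
    conversions: pd.DataFrame | None = None  # subject x region bool

    def __post_init__(self):
        for s, e in self.epicenters.items():
            if len(e) == 0:
                raise ValueError(f"subject {s} has an empty epicenter set")


@dataclass(frozen=True)
class SyntheticCohort:
    config: GeneratorConfig
    template_adjacency: np.ndarray
    subject_adjacencies: dict[str, np.ndarray]
    suvr_baseline: pd.DataFrame
    suvr_followup: pd.DataFrame
    intervals: pd.Series
    metadata: pd.DataFrame
    truth: GroundTruth

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.template_adjacency.tobytes())
        for s in sorted(self.subject_adjacencies):
            h.update(self.subject_adjacencies[s].tobytes())
        for df in (self.suvr_baseline, self.suvr_followup):
            h.update(df.to_numpy().tobytes())
        h.update(self.intervals.to_numpy().tobytes())
        h.update(self.metadata.to_csv().encode())
        return h.hexdigest()


def _subject_ids(n: int) -> list[str]:
    return [f"sub-{i:03d}" for i in range(n)]


def generate_connectomes(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Template + per-subject structural connectivity matrices.

    The template places regions uniformly in a unit cube and draws
    undirected weights ``scale * exp(-decay * distance) * LogNormal(0, σ)``
    clipped to [0, 1] — dense (every off-diagonal weight positive) and
    heavy-tailed, mimicking distance-corrected tractography proportions.
    Subject matrices multiply the template by log-normal noise
    ``exp(N(0, subject_noise_sd))`` edge-wise and re-clip.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_regions
    coords = rng.uniform(0.0, 1.0, size=(n, 3))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    noise = np.exp(rng.normal(0.0, config.weight_sigma, size=(n, n)))
    noise = np.triu(noise, 1)
    noise = noise + noise.T
    template = config.weight_scale * np.exp(-config.weight_decay * dist) * noise
    template = np.clip(template, 0.0, 1.0)
    np.fill_diagonal(template, 0.0)

    subjects = {}
    for sid in _subject_ids(config.n_subjects):
        if config.subject_noise_sd == 0:
            adj = template.copy()
        else:
            pert = np.exp(rng.normal(0.0, config.subject_noise_sd, size=(n, n)))
            pert = np.triu(pert, 1)
            pert = pert + pert.T
            adj = np.clip(template * pert, 0.0, 1.0)
            np.fill_diagonal(adj, 0.0)
        subjects[sid] = adj
    return template, subjects


def _draw_mixture_params(config: GeneratorConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    labels = config.region_labels
    if config.mixture_truth is not None:
        arr = np.asarray(config.mixture_truth, dtype=float)
        if arr.shape != (config.n_regions, 4):
            raise ValueError("mixture_truth must be n_regions x 4")
        df = pd.DataFrame(arr, index=list(labels),
                          columns=["mu_n", "sigma_n", "mu_p", "sigma_p"])
    else:
        mu_n = rng.uniform(*config.mu_n_range, size=config.n_regions)
        sigma_n = rng.uniform(*config.sigma_n_range, size=config.n_regions)
        mu_p = mu_n + rng.uniform(*config.delta_mu_range, size=config.n_regions)
        sigma_p = rng.uniform(*config.sigma_p_range, size=config.n_regions)
        df = pd.DataFrame({"mu_n": mu_n, "sigma_n": sigma_n,
                           "mu_p": mu_p, "sigma_p": sigma_p},
                          index=list(labels))
    if not (df["mu_p"] > df["mu_n"]).all():
        raise ValueError("mixture truth requires mu_p > mu_n in every region")
    return df


def _draw_metadata(config: GeneratorConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    ids = _subject_ids(config.n_subjects)
    n = config.n_subjects
    n_pos = int(round(config.amyloid_positive_fraction * n))
    ab = np.zeros(n, dtype=bool)
    ab[rng.choice(n, size=n_pos, replace=False)] = True
    # diagnosis mix conditional on amyloid status (CU-heavy cohort)
    diag = np.empty(n, dtype=object)
    for i in range(n):
        probs = (0.43, 0.46, 0.11) if ab[i] else (0.83, 0.16, 0.01)
        diag[i] = rng.choice(["CU", "MCI", "Dementia"], p=probs)
    meta = pd.DataFrame({
        "age": np.clip(rng.normal(71.0, 8.0, n), 50, 90),
        "sex": rng.choice(["F", "M"], size=n, p=[0.6, 0.4]),
        "education": np.clip(rng.normal(16.0, 2.5, n), 9, 20).round(),
        "race": rng.choice(["White", "Black", "Asian", "Multiple"],
                           size=n, p=[0.79, 0.19, 0.01, 0.01]),
        "study": rng.choice(["ABC", "ADNI"], size=n, p=[0.35, 0.65]),
        "scan_interval": rng.uniform(0.0, 1.5, n),
        "amyloid_positive": ab,
        "diagnosis": diag,
    }, index=ids)
    meta.index.name = "subject_id"
    return meta


def _draw_epicenters_and_severity(
    config: GeneratorConfig, metadata: pd.DataFrame, rng: np.random.Generator
) -> tuple[dict[str, tuple[str, ...]], dict[str, float]]:
    labels = config.region_labels
    mixture_ix = np.arange(config.n_mixture_regions)  # first regions are mixture
    weights = np.ones(mixture_ix.size)
    weights[: len(LIMBIC_LABELS)] = config.limbic_pool_weight
    weights /= weights.sum()
    lo, hi = config.epicenter_count_range
    epicenters, severity = {}, {}
    for sid, row in metadata.iterrows():
        count = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(mixture_ix, size=count, replace=False, p=weights)
        epicenters[sid] = tuple(labels[i] for i in sorted(chosen))
        rng_range = (config.severity_range_abpos if row["amyloid_positive"]
                     else config.severity_range_abneg)
        severity[sid] = float(rng.uniform(*rng_range))
    return epicenters, severity


def _true_distance_profiles(
    config: GeneratorConfig,
    subject_adjacencies: dict[str, np.ndarray],
    epicenters: dict[str, tuple[str, ...]],
) -> pd.DataFrame:
    """Mean shortest-path distance of every region from each subject's
    epicenters, on the subject's own (unthresholded) connectome.

    Only the epicenter source rows of the distance matrix are needed, so
    Dijkstra runs from those sources alone."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import dijkstra as _dijkstra

    labels = list(config.region_labels)
    ix = {lab: i for i, lab in enumerate(labels)}
    rows = {}
    for sid, adj in subject_adjacencies.items():
        a = np.asarray(adj, dtype=float)
        mask = a > 0
        costs = np.zeros_like(a)
        costs[mask] = 1.0 / a[mask]
        sources = [ix[e] for e in epicenters[sid]]
        d = _dijkstra(csr_matrix(costs), directed=False, indices=sources)
        rows[sid] = d.mean(axis=0)
    return pd.DataFrame(rows, index=labels).T


def generate_regional_suvr(
    config: GeneratorConfig,
    subject_adjacencies: dict[str, np.ndarray],
    epicenters: dict[str, tuple[str, ...]],
    severity: dict[str, float],
    mixture_params: pd.DataFrame,
    metadata: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Baseline SUVR table plus the distance profiles and pathologic-draw
    indicators that constitute its ground truth.

    Unimodal (non-specific) regions draw N(μ_n, σ_n) for everyone;
    mixture regions draw the pathologic component with probability
    ``severity * logistic(a − b·d̄_r)``, and within the pathologic
    component the mean is graded toward μ_p by the same logistic
    (``depth_grading``): affected regions close to the epicenters carry
    deeper pathology. Subject-level covariate effects shift each
    subject's whole row linearly. All SUVR stay positive.
    """
    for sid in subject_adjacencies:
        if not epicenters.get(sid):
            raise ValueError(f"subject {sid} has no epicenters")
    labels = list(config.region_labels)
    unimodal = pd.Series([False] * config.n_mixture_regions
                         + [True] * config.n_nonspecific_regions,
                         index=labels)
    dbar = _true_distance_profiles(config, subject_adjacencies, epicenters)
    a, b = config.distance_effect
    g = config.depth_grading
    eff = config.covariate_effects

    label_ix = {lab: i for i, lab in enumerate(labels)}
    suvr_rows, draw_rows = {}, {}
    for sid in subject_adjacencies:
        logit = 1.0 / (1.0 + np.exp(-(a - b * dbar.loc[sid].to_numpy())))
        # the seed regions themselves are maximally and certainly affected
        epi_ix = [label_ix[e] for e in epicenters[sid]]
        logit[epi_ix] = 1.0
        p = severity[sid] * logit
        p[epi_ix] = 1.0
        is_path = rng.random(config.n_regions) < p
        is_path[unimodal.to_numpy()] = False
        sep = mixture_params["mu_p"] - mixture_params["mu_n"]
        sd_ = config.severity_depth
        depth = (((1.0 - g) + g * logit)
                 * ((1.0 - sd_) + sd_ * severity[sid]))
        mu_path = mixture_params["mu_n"] + sep * depth
        mu_path = mu_path.copy()
        mu_path.iloc[epi_ix] += (config.epicenter_boost_sd
                                 * mixture_params["sigma_p"].iloc[epi_ix])
        mu_nonpath = mixture_params["mu_n"] + config.sub_grading * sep * logit
        mu_nonpath = np.where(unimodal.to_numpy(), mixture_params["mu_n"],
                              mu_nonpath)
        mu = np.where(is_path, mu_path, mu_nonpath)
        sd = np.where(is_path, mixture_params["sigma_p"],
                      mixture_params["sigma_n"])
        vals = rng.normal(mu, sd)
        row = metadata.loc[sid]
        shift = (
            eff["age"] * (row["age"] - 71.0)
            + eff["sex_male"] * (row["sex"] == "M")
            + eff["education"] * (row["education"] - 16.0)
            + eff["race"] * (row["race"] != "White")
            + eff["study_adni"] * (row["study"] == "ADNI")
            + eff["scan_interval"] * row["scan_interval"]
        )
        suvr_rows[sid] = np.maximum(vals + shift, config.suvr_floor)
        draw_rows[sid] = is_path
    suvr = pd.DataFrame(suvr_rows, index=labels).T
    draws = pd.DataFrame(draw_rows, index=labels).T
    suvr.index.name = draws.index.name = "subject_id"
    return suvr, dbar, draws


def generate_longitudinal(
    baseline: pd.DataFrame,
    dbar: pd.DataFrame,
    pathologic_draws: pd.DataFrame,
    severity: dict[str, float],
    mixture_params: pd.DataFrame,
    unimodal: pd.Series,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.DataFrame]:
    """Follow-up SUVR as a distance-graded conversion (spread) process.

    Over an inter-scan interval of t years, a mixture region that was
    non-pathologic at baseline converts to the pathologic component with
    probability ``1 − exp(−t · severity · conversion_hazard ·
    logistic(a − b·d̄_r))``: spread reaches connectome-near regions first.
    Converted regions redraw SUVR from the (distance-graded) pathologic
    component; every region additionally drifts by
    ``N(0, drift_sd · sqrt(t))``. Intervals are Normal(interval_mean,
    interval_sd), resampled until positive.

    Returns follow-up SUVR, intervals (years), realized annualized SUVR
    rates, and the boolean conversion indicator table.
    """
    a, b = config.distance_effect
    g = config.depth_grading
    sd_ = config.severity_depth
    intervals = {}
    followup_rows, rate_rows, conv_rows = {}, {}, {}
    uni = unimodal.to_numpy()
    for sid in baseline.index:
        t = rng.normal(config.interval_mean, config.interval_sd)
        while t <= 0:
            t = rng.normal(config.interval_mean, config.interval_sd)
        intervals[sid] = float(t)
        d = dbar.loc[sid].to_numpy()
        logit = 1.0 / (1.0 + np.exp(-(a - b * d)))
        hazard = severity[sid] * config.conversion_hazard * logit
        q = 1.0 - np.exp(-t * hazard)
        eligible = ~pathologic_draws.loc[sid].to_numpy() & ~uni
        convert = eligible & (rng.random(len(d)) < q)
        sep = (mixture_params["mu_p"] - mixture_params["mu_n"]).to_numpy()
        depth = (((1.0 - g) + g * logit)
                 * ((1.0 - sd_) + sd_ * severity[sid]))
        mu_path = mixture_params["mu_n"].to_numpy() + sep * depth
        new_vals = rng.normal(mu_path, mixture_params["sigma_p"].to_numpy())
        x0 = baseline.loc[sid].to_numpy()
        x1 = np.where(convert, new_vals, x0)
        x1 = x1 + rng.normal(0.0, config.drift_sd * np.sqrt(t), size=len(d))
        x1 = np.maximum(x1, config.suvr_floor)
        followup_rows[sid] = x1
        rate_rows[sid] = (x1 - x0) / t
        conv_rows[sid] = convert
    followup = pd.DataFrame(followup_rows, index=baseline.columns).T
    rates = pd.DataFrame(rate_rows, index=baseline.columns).T
    conversions = pd.DataFrame(conv_rows, index=baseline.columns).T
    followup.index.name = rates.index.name = conversions.index.name = \
        "subject_id"
    return (followup, pd.Series(intervals, name="interval_years"), rates,
            conversions)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a complete, internally consistent synthetic cohort."""
    rng = np.random.default_rng(config.seed)
    mixture_params = _draw_mixture_params(config, rng)
    template, subject_adj = generate_connectomes(config, rng)
    metadata = _draw_metadata(config, rng)
    epicenters, severity = _draw_epicenters_and_severity(config, metadata, rng)
    suvr, dbar, draws = generate_regional_suvr(
        config, subject_adj, epicenters, severity, mixture_params,
        metadata, rng)
    labels = list(config.region_labels)
    unimodal = pd.Series([False] * config.n_mixture_regions
                         + [True] * config.n_nonspecific_regions,
                         index=labels, name="unimodal")
    followup, intervals, rates, conversions = generate_longitudinal(
        suvr, dbar, draws, severity, mixture_params, unimodal, config, rng)

    truth = GroundTruth(
        epicenters=epicenters,
        severity=severity,
        amyloid_positive={s: bool(v) for s, v in
                          metadata["amyloid_positive"].items()},
        unimodal=unimodal,
        mixture_params=mixture_params,
        distance_effect=config.distance_effect,
        distance_profiles=dbar,
        pathologic_draws=draws,
        annualized_rates=rates,
        conversions=conversions,
    )
    logger.info("generated cohort: %d subjects, %d regions, %d Aβ+",
                config.n_subjects, config.n_regions,
                int(metadata["amyloid_positive"].sum()))
    return SyntheticCohort(config, template, subject_adj, suvr, followup,
                           intervals, metadata, truth)
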