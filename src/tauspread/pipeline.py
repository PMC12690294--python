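"""End-to-end orchestration of the tau-spread analysis.

Stages, in order: per-region mixture fitting and exclusion → TPI
conversion → individualized epicenter detection (+ canonical bilateral
entorhinal set) → connectome thresholding, shortest-path distances and
group connectome → four-variant distance profiles → covariate
residualization, stratified k-fold rank-aligned group regressions with
train/test evaluation and fold comparisons → pooled amyloid-positive
models applied per subject with repeated-measures comparison →
longitudinal annualized-change models with dependent-correlation
comparison of the variants.

Zero-epicenter subjects are excluded from all statistical stages but
still contribute to the group connectome when they are cognitively
unimpaired and amyloid-negative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import graph, io, longitudinal as lng, mixtures, modeling
from .epicenters import (DEFAULT_Z_THRESHOLD, canonical_epicenters,
                         detect_epicenters)
from .graph import VARIANTS

logger = logging.getLogger(__name__)

__all__ = ["AnalysisSettings", "AnalysisResults", "run_analysis",
           "run_pipeline_from_dir", "simulate_to_dir"]


@dataclass(frozen=True)
class AnalysisSettings:
    z_threshold: float = DEFAULT_Z_THRESHOLD
    connectome_threshold: float = 0.10
    erc_labels: tuple[str, str] = ("ERC_L", "ERC_R")
    n_folds: int = 5
    fold_seed: int = 17
    residualization: str = "mixed"
    gmm_seed: int = 0
    min_obs: int = 20


@dataclass
class AnalysisResults:
    settings: AnalysisSettings
    models: dict
    retained_regions: list[str]
    tpi: pd.DataFrame
    tpi_adjusted: pd.DataFrame
    epicenter_sets: dict
    excluded_subjects: list[str]
    folds: pd.Series
    profiles: dict[str, pd.DataFrame]
    group_results: pd.DataFrame
    fold_comparisons_train: pd.DataFrame
    fold_comparisons_test: pd.DataFrame
    interactions: pd.DataFrame
    stratified_results: pd.DataFrame | None = None
    subject_effects: pd.DataFrame | None = None
    subject_rm_anova: object = None
    longitudinal_fits: pd.DataFrame | None = None
    longitudinal_comparisons: pd.DataFrame | None = None
    longitudinal_subject_effects: pd.DataFrame | None = None
    longitudinal_rm_anova: object = None
    manifest: dict = field(default_factory=dict)


def _results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def run_analysis(
    adjacencies: dict[str, np.ndarray],
    region_labels,
    suvr_baseline: pd.DataFrame,
    metadata: pd.DataFrame,
    suvr_followup: pd.DataFrame | None = None,
    intervals: pd.Series | None = None,
    settings: AnalysisSettings = AnalysisSettings(),
) -> AnalysisResults:
    """Run the full analysis on in-memory inputs. See module docstring."""
    labels = list(map(str, region_labels))
    missing_conn = [s for s in suvr_baseline.index if s not in adjacencies]
    if missing_conn:
        raise ValueError(
            f"distance stage: no connectome for subject(s) {missing_conn}")

    # 1-2: mixture fitting, exclusion, TPI
    models = mixtures.fit_region_models(
        suvr_baseline, seed=settings.gmm_seed, min_obs=settings.min_obs)
    retained = [r for r in labels if models[r].retained]
    if len(retained) < 3:
        raise ValueError("fewer than 3 retained regions; cannot continue")
    tpi = mixtures.build_tpi_table(suvr_baseline, models)

    # 3: epicenters
    epicenter_sets = {
        s: detect_epicenters(tpi.loc[s], settings.z_threshold, subject=s)
        for s in tpi.index}
    excluded = [s for s, e in epicenter_sets.items() if len(e) == 0]
    if excluded:
        logger.info("excluding %d zero-epicenter subjects from statistics",
                    len(excluded))
    canonical = canonical_epicenters(retained, settings.erc_labels)

    # 4: connectomes and distances; 5: four-variant profiles.
    # Individual-connectome profiles need distances from the epicenter
    # sources only, so Dijkstra runs source-restricted per subject.
    group_conn = graph.group_connectome(
        adjacencies, metadata,
        exclude_bottom_fraction=settings.connectome_threshold, labels=labels)
    group_dmat = graph.shortest_path_distances(group_conn)
    nan_profile = pd.Series(np.nan, index=retained)
    rows = {v: {} for v in graph.VARIANTS}
    for sid in suvr_baseline.index:
        conn = graph.prepare_adjacency(
            adjacencies[sid], labels, settings.connectome_threshold,
            provenance=sid)
        epi = list(epicenter_sets[sid].regions)
        for variant in graph.VARIANTS:
            e = epi if variant.startswith("IE") else list(canonical.regions)
            if not e:
                rows[variant][sid] = nan_profile
            elif variant.endswith("IC"):
                rows[variant][sid] = graph.epicenter_mean_distances(
                    conn, e, retained)
            else:
                rows[variant][sid] = graph.average_epicenter_distance(
                    group_dmat, e, retained)
    profiles = {v: pd.DataFrame(r).T.loc[list(suvr_baseline.index)]
                for v, r in rows.items()}

    # 6: residualization and folds over included subjects
    included = [s for s in tpi.index if s not in excluded]
    tpi_adj = modeling.residualize_tpi(tpi, metadata,
                                      method=settings.residualization)
    folds = modeling.stratified_kfold(
        metadata.loc[included], k=settings.n_folds, seed=settings.fold_seed)

    abpos = metadata["amyloid_positive"].astype(bool)
    group_results: list[modeling.RegressionResult] = []
    strat_results: list[modeling.RegressionResult] = []
    interactions = []
    for f in range(settings.n_folds):
        train = [s for s in included if folds[s] != f]
        test = [s for s in included if folds[s] == f]
        tr_tpi, tr_dist = modeling.rank_align_and_average(
            tpi, tpi_adj, profiles, train)
        te_tpi, te_dist = modeling.rank_align_and_average(
            tpi, tpi_adj, profiles, test)
        for v in VARIANTS:
            fit = modeling.fit_group_model(tr_tpi, tr_dist[v], v, f)
            group_results.append(fit)
            group_results.append(modeling.evaluate_model(fit, te_tpi,
                                                         te_dist[v]))
        # amyloid-stratified fits + interaction on the training split
        by_group_tpi, by_group_dist = {}, {}
        for gname, mask in (("abpos", abpos), ("abneg", ~abpos)):
            g_train = [s for s in train if mask[s]]
            g_test = [s for s in test if mask[s]]
            if len(g_train) < 2 or len(g_test) < 2:
                continue
            g_tr_tpi, g_tr_dist = modeling.rank_align_and_average(
                tpi, tpi_adj, profiles, g_train)
            g_te_tpi, g_te_dist = modeling.rank_align_and_average(
                tpi, tpi_adj, profiles, g_test)
            by_group_tpi[gname] = g_tr_tpi
            by_group_dist[gname] = g_tr_dist
            for v in VARIANTS:
                fit = modeling.fit_group_model(g_tr_tpi, g_tr_dist[v], v, f)
                fit = modeling.RegressionResult(
                    **{**vars(fit), "variant": f"{v}:{gname}"})
                strat_results.append(fit)
                ev = modeling.evaluate_model(fit, g_te_tpi, g_te_dist[v])
                strat_results.append(ev)
        if len(by_group_tpi) == 2:
            for v in VARIANTS:
                interactions.append(modeling.fit_interaction_model(
                    by_group_tpi,
                    {g: by_group_dist[g][v] for g in by_group_dist}, v)
                    | {"fold": f})

    group_df = _results_to_frame(group_results)
    strat_df = (_results_to_frame(strat_results) if strat_results else None)

    def r2_table(df, role):
        sub = df[df["role"] == role]
        return sub.pivot(index="fold", columns="variant", values="r2")

    cmp_train = modeling.compare_folds(r2_table(group_df, "train"))
    cmp_test = modeling.compare_folds(r2_table(group_df, "test"))

    results = AnalysisResults(
        settings=settings, models=models, retained_regions=retained,
        tpi=tpi, tpi_adjusted=tpi_adj, epicenter_sets=epicenter_sets,
        excluded_subjects=excluded, folds=folds, profiles=profiles,
        group_results=group_df, fold_comparisons_train=cmp_train,
        fold_comparisons_test=cmp_test,
        interactions=pd.DataFrame(interactions),
        stratified_results=strat_df,
    )

    # 7: subject-level prediction in amyloid-positive subjects
    _subject_level(results, abpos, included, strat_df if strat_df is not None
                   else group_df)

    # 8: longitudinal
    if suvr_followup is not None and intervals is not None:
        _longitudinal(results, suvr_followup, intervals, abpos, included)

    results.manifest = {
        "n_subjects": int(len(suvr_baseline)),
        "n_regions": len(labels),
        "n_retained": len(retained),
        "n_excluded_subjects": len(excluded),
        "settings": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in vars(settings).items()},
    }
    return results


def _subject_level(results, abpos, included, source_df):
    """Pooled amyloid-positive training models applied per subject."""
    fits = source_df[source_df["role"] == "train"]
    pos_subjects = [s for s in included if abpos[s]]
    if len(pos_subjects) < 3:
        logger.warning("too few amyloid-positive subjects for subject-level "
                       "analysis")
        return
    rows = []
    for v in VARIANTS:
        tagged = fits[fits["variant"] == f"{v}:abpos"]
        if tagged.empty:
            tagged = fits[fits["variant"] == v]
        pooled = lng.PooledModel(v, float(tagged["intercept"].mean()),
                                 float(tagged["slope"].mean()), len(tagged))
        for s in pos_subjects:
            eff = lng.subject_effect_size(
                results.tpi.loc[s], results.profiles[v].loc[s], pooled,
                subject=s)
            rows.append(vars(eff))
    df = pd.DataFrame(rows)
    results.subject_effects = df
    wide = df.pivot(index="subject", columns="variant", values="beta_std")
    wide = wide[[v for v in VARIANTS if v in wide.columns]]
    if wide.dropna().shape[0] >= 3:
        results.subject_rm_anova = lng.compare_effect_sizes(wide)


def _longitudinal(results, suvr_followup, intervals, abpos, included):
    tpi_fu = mixtures.build_tpi_table(suvr_followup, results.models)
    dtpi = lng.annualize_change(results.tpi, tpi_fu, intervals)
    subjects = [s for s in included
                if abpos[s] and s in dtpi.index]
    if len(subjects) < 3:
        logger.warning("too few longitudinal amyloid-positive subjects")
        return
    # rank alignment by baseline TPI; same permutation for change,
    # baseline and distances
    n_regions = results.tpi.shape[1]
    stacks = {"dchange": [], "baseline": []}
    dist_stacks = {v: [] for v in VARIANTS}
    for s in subjects:
        perm = modeling.rank_align(results.tpi.loc[s])
        stacks["dchange"].append(dtpi.loc[s].to_numpy()[perm])
        stacks["baseline"].append(results.tpi.loc[s].to_numpy()[perm])
        for v in VARIANTS:
            dist_stacks[v].append(
                results.profiles[v].loc[s].to_numpy()[perm])
    ranks = pd.RangeIndex(1, n_regions + 1, name="rank")
    mean_dchange = pd.Series(np.mean(stacks["dchange"], axis=0), index=ranks)
    mean_baseline = pd.Series(np.mean(stacks["baseline"], axis=0), index=ranks)
    mean_dist = {v: pd.Series(np.mean(dist_stacks[v], axis=0), index=ranks)
                 for v in VARIANTS}

    fits = {v: lng.fit_longitudinal_group_model(
        mean_dchange, mean_baseline, mean_dist[v], v) for v in VARIANTS}
    results.longitudinal_fits = pd.DataFrame([vars(f) for f in fits.values()])
    results.longitudinal_comparisons = lng.compare_longitudinal_models(
        mean_dist, mean_dchange, mean_baseline)

    rows = []
    identity = {v: lng.PooledModel(v, 0.0, 1.0, 1) for v in VARIANTS}
    for v in VARIANTS:
        f = fits[v]
        for s in subjects:
            d = results.profiles[v].loc[s]
            base = results.tpi.loc[s]
            # group-model prediction of annualized change for this subject
            pred = pd.Series(
                _predict_long(f, d.to_numpy(), base.to_numpy(),
                              mean_dchange, mean_baseline, mean_dist[v]),
                index=d.index)
            eff = lng.subject_effect_size(
                dtpi.loc[s], pred, identity[v],
                baseline=base, subject=s, analysis="longitudinal")
            rows.append(vars(eff))
    df = pd.DataFrame(rows)
    results.longitudinal_subject_effects = df
    wide = df.pivot(index="subject", columns="variant", values="beta_std")
    wide = wide[[v for v in VARIANTS if v in wide.columns]]
    if wide.dropna().shape[0] >= 3:
        results.longitudinal_rm_anova = lng.compare_effect_sizes(wide)


def _predict_long(f, dist, base, mean_dchange, mean_baseline, mean_dist):
    """Unstandardized group-model prediction of annualized change from a
    subject's distance profile and baseline TPI."""
    sd_y = mean_dchange.std(ddof=1)
    b_d = f.beta_std_distance * sd_y / mean_dist.std(ddof=1)
    b_b = f.beta_std_baseline * sd_y / mean_baseline.std(ddof=1)
    a = (mean_dchange.mean() - b_d * mean_dist.mean()
         - b_b * mean_baseline.mean())
    return a + b_d * dist + b_b * base


def simulate_to_dir(config, out_dir) -> None:
    from .synthetic import generate_cohort

    cohort = generate_cohort(config)
    io.write_cohort(cohort, out_dir)


def run_pipeline_from_dir(
    in_dir,
    out_dir,
    settings: AnalysisSettings = AnalysisSettings(),
) -> AnalysisResults:
    """File-based pipeline: read a cohort directory (as written by
    ``simulate``), run the analysis, write result CSVs and a manifest."""
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    adjacencies, labels = io.read_connectome_dir(in_dir)
    suvr = io.read_suvr_long(in_dir / "suvr_baseline.csv")
    metadata = pd.read_csv(in_dir / "metadata.csv", index_col=0)
    followup = intervals = None
    fu_path = in_dir / "suvr_followup.csv"
    if fu_path.exists() and "interval_years" in metadata.columns:
        followup = io.read_suvr_long(fu_path)[list(labels)]
        intervals = metadata["interval_years"]
    suvr = suvr[list(labels)]

    results = run_analysis(adjacencies, labels, suvr, metadata,
                           followup, intervals, settings)

    out_dir.mkdir(parents=True, exist_ok=True)
    results.tpi.to_csv(out_dir / "tpi.csv")
    results.group_results.to_csv(out_dir / "group_results.csv", index=False)
    results.fold_comparisons_train.to_csv(
        out_dir / "fold_comparisons_train.csv", index=False)
    results.fold_comparisons_test.to_csv(
        out_dir / "fold_comparisons_test.csv", index=False)
    if not results.interactions.empty:
        results.interactions.to_csv(out_dir / "interactions.csv", index=False)
    if results.subject_effects is not None:
        results.subject_effects.to_csv(out_dir / "subject_effects.csv",
                                       index=False)
    if results.longitudinal_fits is not None:
        results.longitudinal_fits.to_csv(out_dir / "longitudinal_fits.csv",
                                         index=False)
        results.longitudinal_comparisons.to_csv(
            out_dir / "longitudinal_comparisons.csv", index=False)
    io.write_epicenters_json(out_dir / "epicenters.json",
                             results.epicenter_sets)
    mixtures.save_models(results.models, out_dir / "models.json")
    (out_dir / "manifest.json").write_text(json.dumps(results.manifest,
                                                      indent=1))
    return results
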