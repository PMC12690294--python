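# Methods

This note documents the models implemented in `tauspread`, the design
choices made where the methodology was genuinely open, the synthetic
cohort that stands in for access-controlled tau-PET/dMRI data, and what
the test suite does and does not establish.

## Tau pathology index

Flortaucipir SUVR mixes specific tau signal with off-target binding.
Pooling each region's SUVR across subjects, we fit a one-component
Gaussian (closed-form MLE) and a two-component Gaussian mixture by EM:

- initialization splits the sorted sample at the median; 5 restarts
  perturb the initial means by 0.25 sample SD; the best log-likelihood
  wins;
- convergence at |Δ log-likelihood| < 1e-8, max 500 iterations;
- component variances are floored at 1e-6 × sample variance to prevent
  singular collapse (a floored best fit is reported with a warning);
- all regions share the subject count, so `fit_region_models` runs every
  region's restarts as one lock-step vectorized EM batch; the update
  rule is identical to the single-vector API.

**Exclusion rule.** "Better fit" is decided by BIC (2 parameters for the
single Gaussian, 5 for the mixture). Ties, and mixtures whose component
means coincide, are excluded. BIC was chosen over AIC because the extra
3 parameters should pay for themselves only when a region is genuinely
bimodal; at 300 subjects the rule separates the generator's 40
non-specific regions from its 64 mixture regions exactly, and at 60
subjects a handful of borderline regions flip (the tests encode both
scales).

**Transform.** With F_p, F_n the CDFs of the higher-/lower-mean
components, TPI(x) = F_p(x) + F_n(x) − 1. "Percentile on a component" is
read as the component's own CDF, not the posterior membership
probability: it is strictly increasing in x, maps the non-pathologic
bulk toward −1 and the pathologic bulk toward +1, and is insensitive to
the mixing weights. Mixtures may be fit on a larger cohort than the one
analyzed; `build_tpi_table` accepts any fitted model set.

## Epicenters

TPI is z-scored within subject (sample SD, n−1 denominator — the
conventional unbiased form) over the retained regions only, and regions
with z ≥ threshold are epicenters. The inclusive ≥ is used at the
default 1.645 (95th percentile of a standard normal); 1.96 and 2.32 are
supported for sensitivity analyses. A zero-variance row yields an empty,
flagged set rather than an error; zero-epicenter subjects are excluded
from all statistical stages but still contribute to the group connectome
when cognitively unimpaired and amyloid-negative. Fold agreement of
epicenter frequency uses ICC(2,1) — two-way random effects, absolute
agreement, single measures — both pairwise between folds and between
each fold and the pooled frequency vector.

## Connectome distances

Raw connectivity matrices (nonnegative, in [0, 1]) are symmetrized by
the arithmetic mean of (i, j) and (j, i) — order-independent and
standard for seed-based tractography proportions — the diagonal is
zeroed, and the weakest floor(fraction × count) strictly positive
undirected edges are removed (default fraction 0.10; ties broken by
row-major position so re-runs are identical). Zero-weight pairs are
non-edges, not infinite-cost edges. Edge cost is 1/weight; all-pairs
distances come from Dijkstra (scipy's csgraph), verified element-wise
against a brute-force Floyd–Warshall oracle in the tests. Unreachable
pairs are recorded as infinity and reported, never raised.

The graph keeps all 104 parcellation regions — excluded-binding regions
may lie on shortest paths — while distance profiles are reported for
retained regions only. The group connectome averages the raw matrices of
all cognitively unimpaired amyloid-negative subjects before
thresholding, computed once (not per fold; a fold-wise recomputation
would only perturb it by sampling noise). d̄_r is the mean of each
retained region's distance to the epicenter set, with the 0 self-term
included when the region is itself an epicenter and infinite entries
dropped from the mean. The four variants cross individualized vs
canonical (bilateral entorhinal) epicenters with individual vs group
connectomes: IE-IC, IE-GC, GE-IC, GE-GC. Profiles are computed by
source-restricted Dijkstra from the epicenter nodes, which is
numerically identical to slicing the full distance matrix.

## Group models

Rank alignment sorts each subject's regions by raw TPI, descending, ties
broken by region label; the same permutation is applied to the
covariate-adjusted TPI and to all four distance profiles, and vectors
are averaged across subjects at each rank. Ranking on raw (not
adjusted) TPI keeps the ordering interpretable as tau burden; since the
covariate model is subject-level, the adjustment cannot reorder regions
within a subject anyway.

Covariate adjustment fits one linear mixed model over all region-level
observations — fixed effects for age, sex, education, race, study and
PET–dMRI scan interval, random intercept per participant — and takes
conditional residuals (observed − fixed prediction − participant
intercept). When the mixed fit is singular (common in small cohorts
where the participant variance estimate collapses) the code falls back
to fixed-effects OLS residuals with a warning; a `method="fixed"` flag
selects that path directly.

Each variant's model is OLS of rank-averaged adjusted TPI on
rank-averaged distance; standardized β is the coefficient after
z-scoring predictor and outcome (for one predictor, the Pearson r).
Validation uses stratified 5-fold splits (amyloid status balanced within
one subject, shuffled with a fixed documented seed, 17); the trained
coefficients predict the held-out fold's rank-averaged TPI and measured
is regressed on predicted, so a successful prediction has positive β.
Fold-wise R² values are compared between variants with paired t-tests
(df = folds − 1); exactly constant differences are reported as infinite
t with p = 0 and a warning. The amyloid interaction stacks the two
groups' rank-averaged vectors (2 × regions points) and fits
TPI ~ distance × group.

## Subject level and longitudinal

The per-variant amyloid-positive training fits are pooled by averaging
intercepts and slopes across folds; applying the pooled model to a
subject's own distance profile gives predicted TPI, and the standardized
β from regressing measured on predicted is that subject's effect size.
Effects are compared across the four variants by one-way
repeated-measures ANOVA (F = MS_condition/MS_error, df (k−1, (k−1)(n−1)),
no sphericity correction) with Bonferroni-corrected pairwise paired
t-tests (factor = number of pairs actually tested, 6).

Longitudinally, annualized change is (follow-up − baseline)/interval on
the TPI scale. Rank alignment uses baseline TPI. The group model per
variant is a two-predictor OLS of mean annualized change on mean
distance and mean baseline TPI; the distance term's standardized β with
95% CI is the quantity of interest, and near-collinear predictors
(|r| > 0.999) raise. Variants are compared against IE-IC with the
Hittner-modified Dunn–Clark Z applied to correlations between each
variant's distance vector and the outcome residualized on baseline TPI
(the full dataset is used, no train/test split, matching the small
longitudinal sample). Subject-level longitudinal effects regress a
subject's annualized change on the group model's prediction with
baseline TPI as covariate; predictions collinear with baseline or of
zero variance are recorded as missing with a reason.

## Statistical primitives

All four primitives are implemented from their definitions and verified
against independent oracles in the tests:

- **Hittner Z** (dependent overlapping correlations): Fisher-transform
  both outcome correlations, evaluate the Dunn–Clark covariance at the
  backtransformed mean Fisher z, Z = (z₁ − z₂)·√((n−3)/(2(1−c))).
  Monte-Carlo calibration: type-I error at α = 0.05 within [0.04, 0.06]
  and null Z consistent with N(0,1) (10⁴ trivariate-normal replicates,
  n = 64).
- **ICC(2,1)**: (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) from the
  two-way ANOVA decomposition; cross-checked against pingouin's
  ICC(A,1) and a hand decomposition.
- **One-way RM-ANOVA**: sum-of-squares decomposition with listwise
  deletion; equals the squared paired t at k = 2; permutation-null p
  values are uniform.

p-values are two-sided throughout.

## Synthetic cohort

No public data with this structure exists, so the generator defines the
study conditions. Defaults (all in `GeneratorConfig`):

- **Parcellation**: 104 regions; 8 named limbic-like regions (bilateral
  entorhinal, amygdala, hippocampus, parahippocampal) plus generic
  cortex; the last 40 regions are non-specific (unimodal SUVR).
- **Connectomes**: regions embedded uniformly in a unit cube; undirected
  weight = 0.5·exp(−6·distance)·LogNormal(0, 0.6), clipped to [0, 1] —
  dense and heavy-tailed. The decay of 6 makes shortest paths traverse
  chains of spatial neighbors, producing a broad graded
  distance-from-epicenter field; with weak decay the dense graph is
  "small-world flat" (everything ≈ 2 hops away) and there is no distance
  structure for the analysis to recover. Subject matrices multiply the
  template edge-wise by exp(N(0, 1.0)) and re-clip; this noise level
  leaves subject distance profiles correlated ~0.6 with the template, so
  individual connectomes are genuinely informative without being
  unrecognizable.
- **Epicenters**: 1–7 per subject, sampled without replacement from the
  mixture regions with 10× weight on the limbic-like pool.
- **Baseline SUVR**: per-region mixture truth drawn from μ_n ∈ [1.0,
  1.25], σ_n ∈ [0.05, 0.08], Δμ ∈ [0.45, 0.65], σ_p ∈ [0.06, 0.10]
  (well separated, Δμ/σ ≥ ~4). A subject draws region r from the
  pathologic component with probability severity · logistic(1.0 −
  0.25·d̄_r), where d̄_r is computed on the subject's own unthresholded
  connectome. Within the pathologic component the mean is graded toward
  μ_p by the same logistic (depth grading 0.7), scaled by subject
  severity (severity-depth 0.4), and the non-pathologic mean carries a
  small sub-threshold gradient (0.12 of the separation): tau burden, not
  just tau presence, declines with connectome distance, which is the
  gradient the regressions measure. Seed regions are certainly affected
  and draw ~1.5 pathologic SDs above the graded mean — the sources carry
  the deepest burden, which is what makes them recoverable as
  within-subject outliers. Severity is U(0.55, 1.0) for
  amyloid-positive and U(0.15, 0.35) for amyloid-negative subjects
  (lower third, so individualized-epicenter models remain informative in
  that group); ~36% of subjects are amyloid-positive. Subject-level
  covariate effects are small (≤0.01 SUVR per SD) so residualization is
  exercised but never dominant.
- **Longitudinal**: inter-scan intervals N(3.18, 1.35²) years, resampled
  positive. Follow-up is a spread process: each baseline-non-pathologic
  mixture region converts to the pathologic component with per-year
  hazard severity · 0.35 · logistic(1.0 − 0.25·d̄_r); converted regions
  redraw from the graded pathologic component and all regions drift by
  N(0, 0.005·√years) SUVR. An additive "annualized SUVR change linear in
  distance" law was evaluated first and rejected: after the TPI
  measurement transform its mid-rank hump (CDF slope vanishes at the TPI
  plateaus) correlates positively with distance and reverses the
  measured effect at any rate scale. The conversion process is the
  mechanism the framework is about — spread reaching connectome-near
  regions first — and reproduces the qualitative longitudinal results.
- **Occupancy ceiling**: the logistic intercept 1.0 keeps even severe
  subjects at ~15–20 pathologic regions. Near-saturating occupancy would
  put half a subject's regions in the high block and destroy z-outlier
  epicenter detection entirely.

Determinism: one `numpy.random.default_rng(seed)` drives everything in a
fixed order; identical configs are bit-identical (hash-checked).

### What the synthetic cohort does not emulate

Spatial autocorrelation of PET signal between anatomically adjacent
regions; hemispheric symmetry; off-target binding structure beyond
unimodality; scanner/site batch effects beyond a scalar study covariate;
atrophy-driven SUVR decline; informative dropout in the longitudinal
subset. Passing tests therefore establish that the pipeline recovers the
structure this generative model encodes — not that real cohorts would
show the same effect sizes. In particular, generated effect magnitudes
(training R² ≈ 0.5–0.65 for IE-IC) are deliberate qualitative
surrogates, not calibrated to any real cohort's values.

### Recovery margins

Measured during design at 200 subjects per cohort: the IE-IC training R²
exceeds all other variants in ≥95% of seeds and its distance β is
negative in ~100%; the longitudinal IE-IC distance β is negative in
~100% of seeds and the most negative of the four variants in ~85–90% —
the regression test bounds this at 14/20 seeds. Seeded epicenters are
recovered at z = 1.645 with mean Jaccard ≈ 0.4–0.55 among high-severity
(≥0.7) subjects, roughly ten times the permutation-chance overlap; the
test asserts > 0.35 plus the chance comparison. Perfect recovery is not
expected: detection is defined on measured TPI outliers, and pathologic
neighbors of the seeds legitimately compete.

## Numerical choices

Variance floor 1e-6 × sample variance in EM; BIC with 2 vs 5 parameters;
inclusive z-threshold comparisons; sample SD (n−1) everywhere;
rank ties broken by region label; threshold ties broken row-major;
paired-t differences constant up to 1e-9 relative treated as exact
(infinite t guard); RM-ANOVA sums of squares clipped at float dust;
inter-variant correlations clipped to ±(1 − 1e-12) before the Z test;
degenerate fits (zero-variance predictor, collinearity |r| > 0.999)
raise rather than return garbage. Problem sizes in the test suite — 60-
to 300-subject cohorts, 100-seed sweeps at 200 subjects — were chosen to
make the stochastic claims statistically stable while keeping the suite
fast.

## Known limitations

- The paper-style headline magnitudes from real cohorts are not
  reproducible here by construction; only orderings and signs are.
- The mixed-model residualization falls back to OLS when the
  participant-variance estimate is singular, which is the norm rather
  than the exception at small cohort sizes (the two residual sets are
  nearly identical there).
- Hittner's Z assumes jointly normal ranks-free correlations; with 64
  regions the normal approximation is adequate (verified by simulation)
  but small retained-region counts would not be.
- The CLI writes one TSV per subject connectome; at thousands of
  subjects an HDF5-backed store would be preferable.
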