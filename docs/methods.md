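# Methods

This note documents the statistical procedures, the synthetic-data
generator, and the numerical/design choices made where the analysis design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Events, effort, and RAI

A record opens a new independent event iff its gap to the **previous
record** of the same (camera, species) stream strictly exceeds the merge
window (default 30 min). The boundary is inclusive: a gap of exactly 30 min
still merges. An alternative anchoring — gap to the *first record of the
current event* — would split long bursts more aggressively; we chose
gap-to-previous because it is the common behavior of camera-trap packages
and is idempotent under record duplication (tested).

Effective effort counts calendar days with any operational coverage;
partial days count as one day. `RAI = 100 · events / effective days`.

The species inclusion filter retains a species only if it has ≥ 30
independent events **and** was detected at ≥ 10 cameras ("fewer than" is
strict, so 30 events at 10 sites passes). The source phrasing is
grammatically ambiguous between AND- and OR-exclusion; we exclude on either
failure (the stricter, conventional reading). Both thresholds are
configurable.

Detection histories use consecutive occasions (default 14 days) counted
from one **global** survey start shared by all cameras, so occasion j is
the same calendar block everywhere; `workday_ij` is the number of
operational days of site i in occasion j, and occasions with zero workday
are structurally missing. Per-camera occasion alignment would inflate
effort in early occasions and break the shared occasion index the detection
model assumes.

## Beta diversity and the swap null

Pairwise (not multiple-site) Jaccard partition: for sites sharing `a`
species with `b`, `c` unique, `jac = (b+c)/(a+b+c)`,
`jtu = 2min(b,c)/(a+2min(b,c))`, `jne = jac − jtu`. `jtu + jne = jac` holds
exactly and is asserted at 1e−12. The summary `turnover_fraction` is the
ratio of the mean turnover to the mean total dissimilarity.

The null model is a sequential checkerboard swap on the binary site ×
species matrix: a random 2×2 submatrix of the form [[1,0],[0,1]] or
[[0,1],[1,0]] is flipped, preserving all row and column sums. Chain
settings: burn-in = 10× the matrix fill in successful swaps, thinning = one
fill between samples. The p-value is two-sided with add-one correction,
`2·min(P(null ≥ obs), P(null ≤ obs))` capped at 1, each tail estimated as
(count+1)/(n+1); two-sided because deviation in either direction
(aggregation or segregation) is interpretable. SES = (obs − null mean)/null
SD. Note that on strongly gradient-structured data (including the default
synthetic scenario) |SES| is large; the original field system reported a
near-zero SES, which reflects that survey's weaker structure, not a
different statistic.

## Species similarity, silhouettes, Δ

Species distances are Jaccard on occurrence profiles and Bray–Curtis on
RAI profiles across sites (sites as dimensions). Clustering for this
screening uses **average linkage** — the linkage for this step is not
prescribed by the study design (Ward is specified only for the coefficient
clustering), and average linkage is the common default for ecological
dissimilarities; it is configurable. Trees are cut with `cut_tree` (merge
order), which is robust to tied merge heights. Mean silhouette uses
`s(i) = (b_i − a_i)/max(a_i, b_i)` with singletons scored 0.

Δ = mean between-group − mean within-group dissimilarity. The null permutes
labels with group sizes fixed; the test is one-sided for large Δ (more
structure), add-one corrected. Calibration (uniform p under random labels)
and the exact block-matrix value Δ = 0.6 are asserted in the acceptance
suite.

## NMDS and envfit

NMDS minimizes Kruskal stress-1,
`sqrt(Σ(d − d̂)² / Σ d²)`, alternating a Guttman (SMACOF) update of the
configuration with an isotonic regression of configuration distances on the
dissimilarity order (pool-adjacent-violators via scikit-learn). Ties are
handled in the *primary* manner: within tied dissimilarities, points are
ordered by current configuration distance, so ties impose no constraint.
The raw-stress objective is provably non-increasing across iterations and
the trace is asserted monotone in tests. Starts: one classical-scaling
start plus random starts (default 20); the best solution is centered and
rotated to principal axes with a deterministic sign convention.

Convergence is declared when a second start reproduces the best
configuration (Procrustes RMSE < 1e−4 after centering, unit-RMS scaling and
orthogonal alignment) — or, when best stress < 1e−3, when a second start
merely reproduces the (effectively perfect) stress, because a zero-stress
nonmetric solution constrains only the rank order and the configuration
itself is not unique. Degenerate all-equal dissimilarity matrices are
flagged and returned with stress 0.

`envfit` regresses a covariate on the 2-D scores; the arrow is the unit
coefficient vector, r² the coefficient of determination, and p the
one-sided add-one permutation fraction with r² at least the observed.
Because ordination points are **species**, each environmental variable
needs one value per species: we use the RAI-weighted mean of the site
covariate over the species' sites (occurrence-weighted mean available via
`envfit_weighting="occurrence"`). How the species-level values were derived
in the motivating analysis is unstated; this is the largest interpretive
gap in the pipeline and both options are exposed.

## Occupancy models

Per species, the single-season marginal likelihood

    L_i = ψ_i · Π_j p_ij^{y_ij}(1−p_ij)^{1−y_ij}   +   (1−ψ_i)·I(all y_ij = 0)

over surveyed occasions only, with `logit ψ` linear in the 13 standardized
predictors and `logit p` linear in standardized workday, standardized water
distance, and a binary camera-type indicator. The likelihood is verified
against brute-force enumeration of all latent-state vectors (≤ 10 sites,
1e−10).

Fits are **independent across species** — the source model indexes every
parameter by species with no shared hyperprior stated — with independent
Normal(0, 2.5²) priors on all logit-scale coefficients (weakly informative;
configurable). Sampling: posterior mode by L-BFGS, finite-difference
curvature at the mode, then random-walk Metropolis with a multivariate
normal proposal scaled by 2.38²/d and inflated ×1.3 (the curvature
understates the spread of this skewed posterior; an independence-type
proposal at the mode was evaluated and rejected — its acceptance rate
collapses in 18 dimensions). Chains ≥ 2, default 2 × (1000 warmup +
1200 stored draws thinned ×16). Split-R̂ is computed per parameter
(cross-checked against ArviZ) with a desk-scale convergence threshold of
1.01; exceeding it flags the fit with a warning but still returns it.
Typical max split-R̂ at the default settings is ≈ 1.01–1.03.

Summaries: posterior mean/SD, 90% equal-tailed credible interval,
significance = CrI excluding 0, direction probability P(β > 0) with
directional calls at > 0.9 / < 0.1. Elevational response classification:
quadratic term clearly negative → hump-shaped (skew from the linear sign);
clearly positive → U-shaped; quadratic uncertain → monotone by the linear
sign; both uncertain → flat.

## Shrinkage and response clustering

Each occupancy coefficient is multiplied by `τ²_v/(τ²_v + σ²_iv)`, with
σ²_iv the posterior variance and τ²_v the across-species sample variance of
the posterior means for predictor v — computed once, no iteration. This is
a post-hoc empirical-Bayes-style damping, not a re-estimation: it never
flips a sign and never grows a magnitude (property-tested). If τ²_v = 0
(all species identical), coefficients collapse to the common value with a
warning. Only the 13 occupancy-level environmental coefficients enter
clustering; the intercept and detection parameters do not (the intercept is
not an environmental response).

Order of operations: shrink → column standardize → 1 − Pearson correlation
between species rows → Ward clustering (scipy's Ward on the condensed
distance, the Ward.D2 update) → k selected as the highest mean silhouette
over k = 2..min(16, n−1), ties to the smaller k → PERMANOVA on the same
distance at the selected labels, with `SS_total = Σ_{i<j} d²/n`, group-wise
within sums, `F = (SS_b/(k−1))/(SS_w/(n−k))`, label-permutation p with
add-one correction.

## Mantel concordance

Pearson correlation over upper-triangle entries; the null permutes rows and
columns of one matrix simultaneously; one-sided for positive association
(concordance), add-one corrected; a Spearman variant and a two-sided
alternative are available but off by default, matching the concordance
interpretation of positive r.

## The synthetic generator

What it emulates: 109 sites with elevation uniform on 1330–4551 m;
correlated Gaussian terrain/vegetation covariates (NDVI–EVI r = 0.85,
slope–TRI r = 0.7); lognormal land-cover distances; composite water
distance from two sources; 17 species assigned round-robin to two guild
archetypes with opposite signs on elevation and forest/shrub distances
(scatter SD 0.3 around the archetype); single-season Bernoulli occupancy
from the same 13-predictor logit model the analysis fits; detection per
14-day occasion from effort, water distance and camera type; detected
occasions emit 1 + Poisson(event_rate − 1) bursts of 1–3 records within
5 min (exercising the 30-min merge without affecting occasion-level
detection); staggered deployment starts/ends produce partial-effort
occasions; and human/livestock pseudo-species are Poisson streams from a
latent site-level disturbance intensity (mean `disturbance_rate` = 4
events/100 days — a free parameter, as no field rate is stated), so the
disturbance covariate is *measured* downstream by the same RAI operation as
on real data.

What it does not emulate: spatial autocorrelation and the 800-m spacing
design, animal movement and home ranges, seasonal/diel activity cycles,
species misidentification, and unmodeled detection heterogeneity.
Consequently, passing tests demonstrate internal statistical correctness
and recoverability under the model's own assumptions — not robustness to
the violations real surveys exhibit. Synthetic communities are *cleaner*
than field data: envfit r² for elevation is ≈ 0.9 here versus ≈ 0.4 in
typical field systems, and the swap-null SES is far from zero because the
two-guild truth imposes strong coherent structure.

## Problem sizes and defaults

Permutation counts default to 9999 in `PipelineConfig` (the full design);
the analysis drivers and the acceptance script run at 999 permutations and
999 swap randomizations — the package's desk-scale choice, which leaves
Monte-Carlo error on p well below the decision thresholds used anywhere in
the pipeline. MCMC defaults (2 chains × 1000 + 1200×16 thinned) put max
split-R̂ near 1.01 per species at about 8 s/species. The acceptance-suite
recovery experiments use 40 replicates (occupancy coverage, 200 sites × 10
occasions, reduced sampler settings) and 50 replicates (guild recovery); in
the guild-recovery experiment the occupancy-fit output is emulated by
drawing posterior means around the generator's true coefficients with SD
0.3 and matching posterior variance — the clustering, shrinkage, PERMANOVA
and Mantel machinery is exercised end-to-end, while the full
MCMC-to-clustering path is run (once per seed) by the pipeline itself.

## Known limitations

- The sampler is random-walk Metropolis; at desk scale split-R̂ lands near
  1.01 rather than the ~1.001 a long HMC run would give. Posterior means
  and 90% intervals are stable to this (coverage is asserted at the nominal
  rate in the acceptance suite), but extreme tail quantiles would not be.
- Species are fit independently; a community (shared-hyperprior) model
  would pool information and shrink more adaptively than the post-hoc
  factor.
- `ele2` is the square of standardized elevation and is deliberately not
  re-standardized, preserving the sign-based response classification.
- VIF screening reports and drops collinear candidates, but the occupancy
  predictor set itself is fixed by configuration (13 predictors), mirroring
  a design where TRI and EVI were dropped a priori by screening on the real
  covariate rasters; on synthetic covariates the screen typically drops
  nothing, and the report makes the outcome inspectable.
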