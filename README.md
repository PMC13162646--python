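# trapcomm

Community-structure analysis for camera-trap surveys of terrestrial mammals
and ground-dwelling birds. The package asks two linked questions about a
multi-species survey: **is the community organized into discrete site-level
modules, or does it vary continuously along environmental gradients?** and
**do species differ in their responses to those gradients (niche
differentiation)?** It is aimed at ecologists analyzing detection/
non-detection data from camera grids in heterogeneous landscapes (e.g.
mountain reserves with strong elevational zonation and diffuse human
disturbance).

## What it computes

Starting from timestamped detection records, camera deployments, and a
per-site environmental table:

1. **Events and effort** — consecutive records of a species at a camera
   within 30 min collapse into one *independent event* (gap measured to the
   previous record). The relative abundance index is
   `RAI = 100 · events / effective camera-days`. Species with < 30 events or
   detected at < 10 cameras are excluded.
2. **Beta diversity** — pairwise Jaccard dissimilarity among sites,
   partitioned into turnover and nestedness:
   `β_jac = (b+c)/(a+b+c)`, `β_jtu = 2min(b,c)/(a+2min(b,c))`,
   `β_jne = β_jac − β_jtu`, tested against a fixed-fixed checkerboard-swap
   null (row and column sums preserved) via a standardized effect size.
3. **Species similarity** — Jaccard (occurrence) and Bray–Curtis (RAI)
   distances among species; hierarchical clustering screened over k = 2–16
   by mean silhouette; a permutation Δ statistic (mean between-group minus
   mean within-group dissimilarity) tests non-randomness of any grouping.
4. **Ordination** — two-dimensional NMDS minimizing Kruskal stress-1, with
   environmental vectors fitted by permutation (`envfit`-style r²).
5. **Occupancy models** — per species, a single-season model with imperfect
   detection, marginalizing the latent occupancy state:
   `logit(ψ_si) = α_s + Σ_v β_sv Z_iv` over 13 standardized predictors
   (linear + quadratic elevation, slope, northness, TWI, NDVI, six
   land-cover distances, disturbance), and
   `logit(p_sij) = γ_0s + γ_1s·workday_ij + γ_2s·dist_water_i + γ_3s·cam_type_i`.
   Posteriors are sampled by preconditioned random-walk Metropolis (≥ 2
   chains, split-R̂ diagnostics), summarized by 90% credible intervals and
   direction probabilities P(β > 0), and elevational response curves are
   classified (monotone, hump-shaped, U-shaped, flat) from the signs of the
   elevation terms.
6. **Response clustering** — posterior-mean coefficients are damped by the
   uncertainty-weighted shrinkage factor `τ²_v / (τ²_v + σ²_iv)`, column
   standardized, converted to 1 − Pearson-correlation distances, Ward
   clustered with silhouette k-selection, and tested with PERMANOVA.
7. **Concordance** — Mantel tests among the three species-level distance
   matrices (occurrence, activity, environmental response).

Because surveys of this kind are rarely deposited publicly, the package
includes a first-class synthetic-survey generator (`trapcomm.synth`) whose
default scenario mirrors the motivating study design: 109 sites across a
1330–4551 m gradient, 17 species in two response guilds with opposite
elevation and habitat preferences, 14-day occasions, effort-, water- and
camera-type-dependent detection, and human/livestock records that define
the disturbance covariate. Every number below is computed from that
generator; see `docs/methods.md` for what it does and does not emulate.

## Worked example

Run the numbered drivers in order (they share `--out`; each stage reads the
previous stage's files):

```bash
python analysis/01_simulate_survey.py --out results/run --seed 1
python analysis/02_build_events.py    --out results/run --seed 1
python analysis/04_beta_diversity.py  --out results/run --seed 1
```

which prints

```
simulated 109 sites x 17 species: 42032 raw records -> results/run/survey
42032 records -> 21631 independent events over 36238 camera-days at 109 cameras; 17 species retained; 24 occasions from 2017-10-01
mean Jaccard 0.6068 = turnover 0.5020 + nestedness 0.1049 (turnover share 82.72%)
swap null: observed 0.6068, null mean 0.6179, SES -45.0069, p = 0.0020
```

Read: site-to-site community differences are dominated by species
*turnover* (82.7% of total beta diversity), not nestedness — sites replace
species along the gradient rather than losing subsets. The large negative
SES says sites share more species than the fixed-fixed null expects: the
two guilds respond coherently to the same gradient, so co-occurrence is
aggregated. Continuing,

```
jaccard: best k = 2 (mean silhouette 0.3074), Delta p at best k = 0.0010
jaccard: stress 0.0697 (converged=True); strongest vector ele, elevation r2 = 0.9766
fit 17 species; max split-Rhat 1.0141; 17 species with >=1 significant effect
selected k = 3 (mean silhouette 0.3479), cluster sizes [8, 4, 5]
PERMANOVA: r2 = 0.6336, F = 12.1060, p = 0.0010
jac_beta: r = 0.6056, p = 0.0010
```

Elevation is the strongest correlate of the species ordination; occupancy
models recover mixed elevational response types (monotone, hump-shaped,
U-shaped); shrinkage clustering separates the montane guild cleanly (the
third cluster is a split of the valley guild — at other seeds k = 2 is
selected); and occurrence structure concords positively with environmental
response structure (Mantel r = 0.61).

The same pipeline runs in one call — `python -m trapcomm all --out results/run`
— or stage by stage with the verbs `simulate`, `events`, `covariates`,
`beta`, `structure`, `ordinate`, `occupancy`, `responses`, `mantel`.

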