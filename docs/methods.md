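# Methods

`somexposure` implements an end-to-end analysis for classifying binary
respiratory outcomes (asthma vs non-asthma presentations) from
multidimensional exposure and demographic data with Kohonen self-organizing
maps (SOMs). This note records the models, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical conventions.

## The self-organizing map

A SOM is a K × J lattice of nodes, each holding a codebook vector
w_kj ∈ R^I in the input space. Nodes are reported in reading order: node 1
is the bottom-left node, increasing left to right and then bottom to top.
Training is online competitive learning: for each scaled input pattern z_p,
the best-matching unit (BMU) is the node with the smallest Euclidean
distance to z_p, and every codebook moves toward the pattern,

    w(t+1) = w(t) + h(t) [z_p − w(t)],

with a Gaussian neighbourhood around the BMU,

    h(t) = η(t) · exp(−d_grid² / 2σ(t)²),
    η(t) = η₀ e^(−t/τ₂),   σ(t) = σ₀ e^(−t/τ₁),

where t counts pattern presentations and d_grid is the Euclidean distance
between nodes in grid units (hexagonal maps offset odd rows by half a
column and compress row spacing by √3/2, giving six unit-distance
neighbours).

Defaults (all exposed in `TrainingConfig`):

| parameter | default | rationale |
|---|---|---|
| η₀ | 0.05 | small enough not to thrash late training, large enough to converge in ≤100 epochs on z-scored data |
| τ₂ | n_epochs·n_patterns / 4 | learning rate falls to e⁻⁴ ≈ 2% of η₀ by the end of training |
| σ₀ | max(K, J)/2 | neighbourhood initially spans half the map |
| τ₁ | total_iterations / ln σ₀ | radius decays to ~1 grid unit by the end (for σ₀ ≤ 1, radius is effectively frozen) |
| n_epochs | 100 | with early stopping, rarely reached |
| stop_tol | 1e-5 | stop when the relative per-epoch QE improvement falls below this; 0 disables early stopping |

When σ(t) underflows to zero the update collapses to the BMU only; this is
defined behaviour, not an error.

**Quantization error (QE)** is reported both as the sum over patterns of the
squared distance to the BMU codebook and, as the headline number, the mean
over patterns — the per-object scale is the one on which node-quality
thresholds are meaningful. **Topographic error** is the fraction of patterns
whose best and second-best nodes are not direct lattice neighbours
(4-neighbourhood on rectangular maps, 6 on hexagonal).

**Supervised variant.** A second codebook layer is attached over the one-hot
coded binary outcome. During training the BMU minimizes
x_weight·d_X² + (1 − x_weight)·d_Y² (default x_weight = 0.5); both layers are
updated with the same neighbourhood weights, which keeps every Y row on the
probability simplex (convex updates of simplex points). At prediction time
the BMU is found on the X layer only — labels are unknown for new patients —
and the predicted class is the argmax of the node's Y codebook, ties going
to class 0. With x_weight = 1 the X layer trains exactly as an unsupervised
map with the same seed (the three RNG streams — X init, Y init, shuffle —
are split from one seed so the reduction is bitwise).

Tie-breaking everywhere is toward the lowest linear node index.

## Ward clustering of codebooks and the U-matrix

Cluster boundaries on the trained map are drawn by agglomerative Ward
clustering of the codebook vectors. The merge cost between clusters r and s
is

    d_rs = n_r n_s / (n_r + n_s) · ‖w_r − w_s‖²,

the increase in within-cluster sum of squares caused by the merge; centroids
are updated as pooled means. The squared-centroid-distance form is the
standard Ward objective; an unsquared variant is available via
`squared=False` for comparison. Merge ties break toward the pair with the
smallest member node indices. The number of clusters is user-chosen
(default 4 in the pipeline); nothing in the method selects it automatically.
Tests verify the merge sequence against an independent hierarchical
clustering oracle (heights h relate to the cost by h² = 2·d_rs).

The U-matrix alternative assigns each node the mean Euclidean distance
between its codebook and its lattice neighbours' codebooks. Code-plot data
rescales each feature's codebook component to [0, 1] across the map
(constant features get 0.5) for per-node fan displays.

## Exposure assembly

Station measurements are carried to patient coordinates by inverse-distance
weighting: a convex combination with weights ∝ distance^(−power), default
power 2 — the minimal standard interpolator for sparse station networks
(kriging is out of scope). Distances are equirectangular planar
approximations (adequate at metropolitan scale); a station within 1 m of the
target returns its value exactly. The exposure used for each patient is the
interpolated value on presentation_date − lag, default lag 2 days, matching
the inflammatory delay that typically precedes an acute presentation; a
single lagged day is used rather than a window. Patients with no reporting
station for some pollutant on their lagged day are dropped and listed in an
exclusion report, so profiles + exclusions always partition the cohort.

## Imputation, scaling, coding

Missing measurements are completed *before* interpolation by
chained-equation imputation on the date × (station, pollutant) matrix:
columns initialize at their means; then for 10 sweeps each incomplete column
is regressed (OLS) on all others and its missing cells refilled with the
prediction plus a Gaussian draw at the residual standard deviation. A single
completed dataset is used (no multiple-imputation pooling): one map is
trained on one completed dataset, and a SOM has no pooling rule for
codebooks. Observed cells are never altered; imputed concentrations are
clipped at zero.

Continuous features (pollutants, and the ordinal age category) are z-scored
so that no variable dominates the Euclidean BMU search by scale alone.
Gender and race are expanded to full one-hot blocks — including an explicit
missing-gender indicator, since missingness of gender is itself informative
structure — while age enters as one ordinal column (categories 1–5) so code
plots show a single age segment. Age categories are: infants [0, 1],
children (1, 9], adolescents (9, 19], adults (19, 65], elderly over 65; ages
strictly between 1 and 2 years go to the children category, the only
gap-free completion of the published labels.

## The synthetic study generator

No real cohort or monitoring data ship with the package, so a seeded
generator produces study inputs with the statistical structure the analysis
assumes:

- **Stations** are placed by a scrambled Halton sequence (quasi-uniform, as
  a deliberately sited network would be).
- **Pollutant fields** are a regional baseline plus isotropic Gaussian
  source plumes — the simplest spatial model with smooth gradients, so
  interpolation has something real to recover. Defaults are
  Highveld-like magnitudes: NO₂ 25, SO₂ 15, PM₁₀ 45 µg/m³ baselines with
  one plume each. Daily variation is a shared lognormal AR(1) factor per
  pollutant (ρ = 0.6) times independent lognormal station noise, both with
  log-sd 0.3; setting the noise scale to zero recovers the deterministic
  field exactly.
- **Missingness** at rate 0.15 by default: MCAR uniformly, or MAR with
  probability proportional to the value's rank (high readings drop out
  more), a concrete, testable mechanism for informative missingness.
- **Cohort** (default 483 patients): ages gamma(2, 16) clipped to
  [4 months, 86 years] (right-skewed, mostly adults); 53% male with a 1.5%
  missing-gender fraction; race proportions (0.72, 0.14, 0.08, 0.06) for
  categories 0–3; coordinates uniform in the region or drawn from
  configurable Gaussian population centres (two-city structure);
  presentation dates leave room for the lag.
- **Outcomes**: P(asthma) = logistic(intercept + β·x) with exposures
  standardized and demographic terms mean-centred, so the intercept
  logit(0.19) keeps prevalence near 19%. Default effects β_SO2 = 0.9 >
  β_PM10 = 0.45 ≥ β_NO2 = 0.3, β_age = 0.35 > 0, β_male = 0.15 — SO₂ the
  strongest pollutant and risk rising with age. The outcome is driven by the
  *deterministic* field at the patient's address, so the pipeline's
  imputation + interpolation is genuinely recovering a signal, not noise.

What the generator does **not** emulate: real atmospheric dispersion
(plumes are static and isotropic), street-level geocoding error, seasonal
or weekday structure in pollution or presentations, correlated pollutant
chemistry, or clinical label noise. Passing recovery tests therefore show
the pipeline is correct and sensitive under its own assumptions — not that
any particular real-data accuracy is attainable.

## Canonical experiment conditions

- `separable_config`: two population centres (one inside the plumes), 36
  stations, near-noiseless fields (log-sd 0.01), 5% missingness, large
  pollutant effects (β_SO2 = 12 > β_PM10 = 6 > β_NO2 = 4) and a balanced
  intercept. Outcomes are an essentially deterministic function of exposure
  with a clear between-class margin, so a correct pipeline must reach
  held-out accuracy ≥ 0.95 (and the SO₂ codebook contrast between
  majority-case and majority-control nodes must be positive).
- `null_config`: every outcome coefficient zero with balanced classes;
  held-out accuracy should hover around 0.5. This control is run at a
  reduced per-seed size (800 patients, 6 stations, 60 days, a 4×4 map,
  30 epochs) so a 20-seed replication remains a quick desk-scale check.

The evaluation stage reports accuracy, sensitivity and specificity (class 1
= asthma positive; undefined rates are NaN, never 0), both in-sample and on
a seeded 70/30 held-out split — the appropriate mode for a claim about new
patients, but both are reported. Per-node quality is the mean Euclidean
distance of a node's mapped objects to its codebook, with a configurable
threshold (default 0.05; its meaning depends on the feature scaling, which
is why it is a parameter and not a constant).

## Numerical conventions and edge cases

- All randomness flows from explicit seeds through split `SeedSequence`
  streams; every pipeline artifact (fixed-format CSV, sorted-key JSON) is
  byte-identical across reruns with the same config.
- Degenerate feature range [v, v] initializes that codebook component to v
  exactly; a zero-variance column is a named error at scaling time; an
  entirely missing column is an error at imputation time; a single-class
  training set is an error for the supervised map.
- BMU and merge ties break deterministically (lowest index); class ties
  predict 0.
- "Linear" map topology is recognised in config and rejected as
  unimplemented; use a 1-row rectangular grid.

## Known limitations

- Online (per-pattern) training only; no batch SOM, growing maps, or
  hierarchical variants.
- IDW ignores anisotropy and elevation; no kriging or land-use regression.
- The chained-equation engine is linear-Gaussian; no predictive-mean
  matching, and no Rubin-rules pooling across multiple imputations.
- Exposure is a single lagged day (default 2); multi-day windows are a
  config hook, not implemented behaviour.
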