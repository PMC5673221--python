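# Methods

This document states the models, conventions and numerical choices used in
`tgbrt`, in enough detail to re-derive every number the package produces.

## 1. Pseudo-absence schemes

A *target group* is a set of ≥ 2 species' occurrence records assumed to share
survey effort; `D` is the total record count. Cell membership is computed on
the analysis grid (half-open cells, points on a boundary belong to the cell
above/right).

- **UTGB.** Background for focal species `k` = all records of the other
  group members whose cell is not occupied by the focal species. Its size is
  `a_k = D − p_k` when no cross-species records share focal cells (cells are
  distinct in the synthetic generator by construction, so the identity is
  exact there); shared cells reduce `a_k` and are reported. All weights are 1.
- **WTGB.** Same points; each background row gets weight `p_k / a_k`, so the
  summed background weight equals `p_k` exactly (one multiplication and one
  division per set — conservation holds to ≤ 1e−9 relative error, limited
  only by floating-point summation).
- **RDM.** `p_k` cells drawn uniformly without replacement from the cells not
  occupied by the focal species, independently per replicate; replicate `r`
  of a run seeded `s` uses generator seed `s + r`, so replicates are distinct
  but individually reproducible. Requesting more cells than are free is an
  error.

## 2. Boosting engine

Weighted stochastic gradient boosting for a Bernoulli response, matching the
classical gbm formulation:

- Weights are normalized to mean 1 (`w ← w / mean(w)`) on entry: only weight
  *ratios* matter, and the loss becomes invariant to rescaling all weights by
  a constant.
- Intercept `F₀ = logit(Σwy / Σw)`.
- Per iteration: `p = σ(F)`, residual `z = y − p`, Hessian `h = w·p(1−p)`.
  A regression tree is fitted to `z` on a bagged subsample
  (`max(2, round(bag_fraction·n))` rows drawn without replacement).
- **Split rule**: weighted least-squares gain
  `(Σ_L wz)²/Σ_L w + (Σ_R wz)²/Σ_R w − (Σ wz)²/Σ w`, candidate thresholds at
  midpoints of consecutive distinct feature values (falling back to the left
  value when the midpoint is not representable between adjacent floats).
  Ties break to the lowest feature index, then the lowest threshold.
- **Growth**: best-first; the frontier leaf with the highest gain is split
  next (earliest-created node on exact ties), up to `2^tree_complexity`
  leaves, with every leaf holding ≥ `min_obs` rows and depth ≤
  `tree_complexity`. `tree_complexity` is therefore the maximum interaction
  order a single tree can express.
- **Leaf values**: one Newton step, `Σ wz / (Σ h + 1e−6)`; the 1e−6
  stabilizer guards empty-curvature leaves.
- Update `F ← F + learning_rate · tree(x)`.

`gbm_step_fit` reproduces the `gbm.step` protocol: stratified seeded CV
folds; within each fold the booster grows in `step_size` blocks; the
held-out deviance trace is averaged over folds; boosting stops after
`patience` non-improving blocks; the selected tree count is the trace argmin
(fewest trees on ties); a final model with that many trees is refitted on
all rows. Bag-fraction selection refits the whole procedure per candidate
and keeps the lowest mean CV deviance (lowest fraction on ties).

All random streams derive from `numpy.random.default_rng` with composite
keys (`[seed, 17]` for folds, `[seed, 100+f]` for fold boosters,
`[seed, 999]` for the refit), so every stage is independently reproducible.

## 3. Evaluation conventions

- **AUC**: weighted Mann–Whitney form with midrank tie handling — equal to
  trapezoidal integration of the ROC curve, and to replicating rows by
  integer weights.
- **Deviance**: `−2 Σ w·[y log p + (1−y) log(1−p)] / N`. Two conventions for
  `N` coexist in the literature and both are provided:
  - `normalization="weights"` (`N = Σw`, the default of
    `weighted_deviance`): invariant to rescaling all weights; baseline
    `2·log 2` for `p = 0.5`.
  - `normalization="observations"` (`N = n_obs`, the gbm/dismo reporting
    convention): this is what the CV traces and per-fold CV deviances
    report. Under it, a weighted background carries less total loss mass
    per row, which is precisely why the weighted target-group scheme is
    structurally better calibrated — the convention is stated here so the
    reported numbers are interpretable.
- **TSS**: sensitivity + specificity − 1 at the 101 thresholds 0.00…1.00
  (prediction positive when `score ≥ t`). Reported operating points: the
  lowest threshold attaining the maximum TSS, and the 10th percentile of
  presence scores (linear interpolation).
- **Scheme comparison cascade**: Shapiro–Wilk on both samples and Levene
  (mean-centered) on the pair; if all three p-values exceed 0.05, a pooled
  two-sample t-test, otherwise a two-sided Wilcoxon–Mann–Whitney; α = 0.05.
  The cascade's empirical type-I error rate is checked by simulation in the
  test suite (500 null seeds; observed rate ≈ 0.058).
- **CV metric samples**: target-group schemes contribute the per-fold
  held-out values of the selected model (n = folds); RDM contributes the
  per-replicate mean CV values (n = replicates) and also exposes the raw
  per-replicate fold values.
- **Deviance spread**: compared like-for-like at the fold level — the SD of
  held-out fold deviances, pooling the replicates' folds for RDM (e.g.
  4 × 10 = 40 values) against each target-group scheme's fold values.
  Comparing RDM's replicate-mean SD against raw fold values would average
  RDM's noise down fourfold and bias the comparison.

## 4. Interpretation

- **Relative influence**: per-predictor sum of split gains across the used
  trees, normalized to percentages (ties ordered by predictor name).
- **Partial dependence** is computed by *exact* tree traversal: each node
  carries the training rows that reach it, and the recursion clamps only the
  target predictor(s), so the result equals the brute-force "clamp the
  column, average the raw prediction over the training rows (training
  weights)" definition to machine precision, on the logit scale
  (transformed to probability on request).
- **Interaction size** for a predictor pair: 2-D partial dependence on a
  `g × g` quantile lattice (levels `(k+0.5)/g`), fit of the best additive
  (row + column) surface on the logit scale, and
  `1000 × mean squared residual`. Stump ensembles are exactly additive and
  score ~0; the statistic is nonnegative by construction.

## 5. Synthetic landscape and virtual species

- Smooth fields: white noise convolved with a Gaussian kernel
  (`σ = max(2, min(nrows, ncols)/6)`, long-range autocorrelation comparable
  to kilometre-scale climate surfaces), plus a random planar trend of
  amplitude 0.35, standardized per field.
- Correlation control: `n_layers + 1` latent fields are drawn, the centered
  cell × field matrix is orthogonalized by QR, and layer `i` is built as
  `√ρ · shared + √(1−ρ) · own_i`. Because the latents are exactly orthonormal
  in-sample, the requested pairwise correlation ρ between climatic layers is
  exact, not approximate. (Without the orthogonalization, heavily smoothed
  fields have only ~36 effective spatial degrees of freedom and independent
  draws correlate spuriously by ~0.2–0.3.)
- Topography: `SLOPE = 12·|own|` (half-normal, like slope magnitudes) and
  `ASPECT = (120·own + 180) mod 360` (degrees); both derive nonlinearly from
  their own latent, so they are only weakly correlated with the climatic
  layers.
- Virtual species: logistic suitability
  `σ(intercept + Σ βᵢ·layerᵢ + Σ γ·layerᵢ·layerⱼ)` on standardized layers;
  presences are sampled without replacement with probability proportional to
  suitability (zero-suitability cells excluded). A target group places each
  species' presences in distinct cells.
- Generator realism and limits: the landscapes have realistic spatial
  autocorrelation and collinearity but no elevation model, no survey bias,
  and no observation error; species are equilibrium logistic responders.
  Conclusions drawn from these landscapes are about the *schemes'* relative
  behavior, not about any real fauna.

## 6. Study pipeline

One seeded config drives: landscape + target-group generation (or CSV/ASCII
file input), Moran's I screening of each species and the pooled records,
then per species × scheme: background generation, CV-fitted BRT (bag
fraction selected from the configured candidates), CV metrics, TSS
operating points, top-k contributions and pairwise interactions, projection
(replicate-averaged for RDM) and five-class areas; finally all pairwise
scheme comparisons per species and metric. Failures are isolated per
combination and recorded in the report. Sub-seeds are derived as
`seed·1000 + 10·species_index + scheme_index` (RDM replicates further
multiply by 10), keeping streams disjoint across combinations.

Two presets exist: a full-scale configuration (40×40 grid, 14 layers,
learning rate 0.001, tree complexity 5, 10-fold CV, bag fraction from
{0.5, 0.75}, up to 10 000 trees) and a desk-scale one (20×20 grid, 7 layers,
learning rate 0.02, tree complexity 3, 10-fold CV, ≤ 500 trees, `min_obs`
5 — gbm's default 10 would forbid any split for the smallest species after
50 % bagging).

## 7. Numerical choices

- Vectorized cumulative-sum split scanning; the independent test oracle
  accumulates left sums in the same (running) order so near-tied gains round
  identically and tie-breaks agree bitwise.
- Sigmoids are evaluated in the numerically stable branch-free form.
- Moran's I uses the analytic Cliff–Ord randomization variance for z-scores,
  with an optional permutation p-value; `E[I] = −1/(n−1)`.
- Class discretization uses half-open intervals
  [0, .2), [.2, .4), [.4, .6), [.6, .8), [.8, 1] via `np.digitize`.

## 8. Limitations

- Raster I/O is ESRI ASCII only (plain text); no GeoTIFF/projection
  metadata.
- The engine is single-threaded, dense, in-memory; it is sized for
  thousands of rows, not millions.
- `tree_complexity` caps leaves at `2^tc` under best-first growth — a
  *depth/interaction-order* reading; R `gbm`'s `interaction.depth` counts
  splits instead, so tree shapes differ from R for `tc ≥ 2` even though the
  loss, shrinkage and CV protocol match.
- The 10th-percentile threshold uses linear interpolation of presence
  scores; other percentile definitions shift it slightly.
- The comparison cascade treats fold/replicate metric values as independent
  samples; CV folds share training data, so its p-values are approximate,
  as they are in the practice it mirrors.
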