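# Methods

## Effect-size conversion

All effects are analysed on the correlation scale (`r`), deliberately *not*
Fisher z-transformed: a dataset mixing Pearson r with biserial r_bis cannot
be combined on the z scale because the two require different stabilizing
transforms. `fisher_z_guard` therefore hard-errors on a z request unless all
origins are genuine Pearson correlations (reported r, or r derived from t);
homogeneous-r sensitivity runs remain possible with `z = atanh(r)`,
`v_z = 1/(n−3)`.

Conversions, per origin:

* **means-SD-n → biserial r_bis.** The standardized difference
  `d = (x̄_D − x̄_L)/s_pooled`,
  `s_pooled = √(((n_L−1)SD_L² + (n_D−1)SD_D²)/(n_L+n_D−2))`, is mapped to the
  point-biserial with `r_pb = d/√(d² + h)`, `h = m(1/n_D + 1/n_L)`,
  `m = n_D + n_L − 2`, then ascended to the biserial with
  `√(pq)/φ(Φ⁻¹(p))` at the observed dark-group proportion `p`. The variance
  is Soper's large-sample biserial approximation. This chain reproduces
  `metafor::escalc(measure="RBIS")` exactly (worked example: r = 0.127124,
  v = 0.080561), which we treat as the reference behaviour; biserial values
  may exceed |1| and are propagated unclipped. A `variant="buggy"` path
  reproduces the documented missing-parentheses denominator
  `√((n_L−1)SD_L² + (n_D−1)SD_D²/(n_L+n_D−2))` for audit simulations only.
* **t → r.** `r = t/√(t² + df)`, sign carried by t; `v = (1−r²)²/(n−1)` with
  `n = df + 2` unless the table provides `n_total`.
* **χ² → Cramér's V.** `V = √(χ²/(n(min(rows, cols) − 1)))` ∈ [0, 1],
  supporting tables larger than 2×2.
* **F → η².** `η² = F·df1/(F·df1 + df2)`, `r_magnitude = √η²`; for df1 = 1
  this equals the t-route on `t = √F`.

V- and η²-derived effects carry the correlation-scale large-sample variance
`(1−r²)²/(n−1)`. That is a declared convention (no published variance
formula exists for these routes in this context); it is consistent with the
t and Pearson routes and keeps all origins on one variance scale.

**Sign policy.** F and χ² are inherently unsigned. Their direction must be
supplied by the extraction table (`direction` column); records with unknown
direction are flagged (`sign_source = flagged_unknown`) and excluded from
fits by default — defaulting them to positive is exactly the bias the
`sign_distribution_audit` is designed to expose. The audit warns when an
unsigned origin's percent-positive exceeds the signed origins' average by
more than 25 percentage points (configurable). Reversed-scale traits (e.g.
latency, where larger values mean less aggression) flip the sign before it
is recorded, for inherent and assigned signs alike.

## Phylogenetic correlation

Trees are read from Newick (dendropy behind `parse_newick`; polytomies
allowed, duplicate tips rejected). Grafen heights — node height =
(descendant tips − 1)^power, scaled to root height 1 — give an ultrametric
unit-depth tree; the power defaults to 1, the cited method's own convention.
`A[i, j]` is the root-to-MRCA depth of tips i and j, the Brownian-motion
correlation on a unit-depth tree. Species labels are matched
case-insensitively with space/underscore folding; dataset species missing
from the tree are a hard error, because silently dropping rows changes k.

## REML engine

The marginal covariance is
`Σ(θ) = V + σ²_study Z_sZ_sᵀ + σ²_species Z_pZ_pᵀ + σ²_phylo Z_pAZ_pᵀ + σ²_unit I`,
with `V` the block sampling VCV (`ρ√(v_i v_j)` within study; ρ = 0.5
default). The REML objective
`−½[log|Σ| + log|XᵀΣ⁻¹X| + rᵀΣ⁻¹r]` (+ constant) is maximized over
log-variances with L-BFGS-B using the analytic gradient
`∂l/∂σ²_j = −½[tr(P G_j) − yᵀP G_j P y]`, three seeded starts, bounds
log σ² ∈ [−30, 4], `ftol = 1e−13`, `gtol = 1e−8`. The log parameterization
sends boundary solutions smoothly to −∞; estimates below 1e−8 are snapped to
zero on report. Likelihood evaluation is Cholesky-based with escalating PSD
jitter (1e−10 → 1e−6) on factorization failure. The engine reproduces
`metafor::rma.mv` on the same instance to ~1e−4 in β, SE and log-likelihood
(metafor's REML log-likelihood differs by the constant `+½log|XᵀX|`), and
matches a brute-force grid/Nelder-Mead maximization of the same objective on
small instances.

Inference uses the normal (z) reference by default — the magnitude of the
reported CIs is consistent with z — with a t(k−p) reference available as a
sensitivity flag. Cochran's Q uses diagonal weights `w_i = 1/v_i` against
the weighted-least-squares fixed-effect fit. Categorical moderators are
coded without intercept so coefficients are per-level pooled means; missing
moderator values are dropped listwise, never imputed.

## Heterogeneity and small-study effects

The typical sampling variance `v̄ = (k−1)Σw/((Σw)² − Σw²)` uses the diagonal
variances of all retained effects (VCV off-diagonals ignored, matching the
multilevel-I² convention). `I²_level = 100·σ²_level/(Σσ² + v̄)`; levels sum
exactly to the total. The 95% prediction interval is
`β̂ ± z·√(SE² + Σσ²)`, so PI ⊇ CI always. Marginal R² =
`100·var(Xβ̂)/(var(Xβ̂) + Σσ²)` (sample variance, ddof = 1).

The small-study test fits the full phylogenetic multilevel meta-regression
on a precision moderator. Two moderator kinds are first-class, because both
appear in practice: `inv_sqrt_n_eff` (`√(1/ñ)`, `ñ = 4n₁n₂/(n₁+n₂)` for
two-group designs, `ñ = n` otherwise) and the standard-error variants
(`se_of_r`, `se_of_z`). Neither is endorsed over the other; the choice is
explicit and recorded in output metadata. The slope measures funnel
asymmetry; the intercept is the pooled mean at infinite precision.

## Synthetic data

`simulate_rbis_comparison` draws both groups from the configured normals
(defaults: dark 2.40 ± 0.80, light 2.25 ± 0.75, n = 10 per group — the
motivating dataset's first-quartile group size; 70 its maximum) and applies
both conversion variants to each replicate. The replicate count defaults to
10,000; published summaries of this design carry an unstated replicate
count, so comparisons use Monte-Carlo tolerances.

`simulate_meta_dataset` draws true correlations
`ρ_i = clamp(μ + u_study + u_species + u_phylo + u_unit, ±0.97)` (clamping
keeps finite-sample statistics defined; events are counted in the truth
record) with defaults shaped like the empirical dataset: 74 studies, 54
species, 1–4 effects per study (~170 effects), group sizes 10–70, origin
mixture (r .15, means-SD-n .25, t .25, F .20, χ² .15), variance components
(study .05, species .02, phylogeny .08, unit .10), grand mean 0.2. Raw
statistics are generated per origin so that each origin's conversion
consistently estimates ρ_i: bivariate-normal samples for r; median-style
dichotomization of a latent bivariate normal for the biserial; a
standardized difference `δ = ρ/√(pq(1−ρ²))` for t and F (two-group one-way
layouts; the converter also handles multi-df F, the generator does not emit
them); and 2×2 multinomial tables with φ = ρ for χ² (larger tables are
supported by the converter but not generated). Real data offer no such
estimand alignment across origins — that mismatch is what the origin
moderator analysis detects — so recovery tests validate the estimator, not
the comparability of real-world conversions.

`simulate_r_scale_dataset` is the estimator-level fast path: effects drawn
directly on the r scale with sampling errors from the block VCV and
variances that depend on sample size only (`v = (1−μ²)²/(n−1)`), satisfying
the model's known-variance assumption. The raw-statistic generator instead
keeps the realistic coupling of `v̂` to the observed effect, which induces
the familiar mild weight-effect correlation of r-scale meta-analysis; the
full-pipeline recovery test uses a correspondingly looser bound.
`apply_selection_bias` censors negative effects from small samples, the
simplest publication-selection mechanism adequate for directional tests.

## Problem sizes used by the test suite

Estimator recovery and small-study calibration run 200 replicates at a
reduced design (40 studies, 24 species, k ≈ 80), a size at which the REML
surface is well-behaved and the suite completes quickly; full-pipeline
recovery runs 25 replicates at the empirical scale (74/54/~170). Recovery is
judged against each replicate's realized grand mean (the mean of the drawn
ρ_i), since clamping makes the nominal μ and the generator's realized mean
differ by design.

## Known limitations

* The sampling-variance conventions for V- and η²-derived effects are
  declared, not literature-fixed; sensitivity to them is not explored.
* Wald/z inference can be mildly anticonservative at small k; the t flag is
  a partial remedy, cluster-robust or Bayesian alternatives are out of
  scope, as are trim-and-fill and selection models.
* σ²_species and σ²_phylo are only weakly separable on trees with little
  depth structure; only their sum should be interpreted on small datasets
  (with A = I they are exchangeable and only the sum is identified).
* The generator does not emulate correlated moderators, unequal reporting
  quality, or origin-dependent extraction error; conclusions about those
  failure modes come from the injected-bias scenarios, not from defaults.
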