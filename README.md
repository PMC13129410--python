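# badgemeta

Phylogenetic multilevel meta-analysis of aggression–coloration effect sizes,
built around a corrected effect-size conversion pipeline.

## The problem

Meta-analyses of the *badge of status* hypothesis — that the size or darkness
of a color patch signals an animal's fighting ability — must pool evidence
reported in incompatible currencies: Pearson correlations, dark/light group
means with SDs, and inferential statistics (t, F, χ²). Getting from those to
a common correlation scale is error-prone in ways that materially change the
conclusions: a single missing pair of parentheses in a custom biserial
formula attenuates a quarter of a typical dataset, inherently unsigned
statistics (F, χ²) can silently default to "positive", and mixing Fisher
z-transformed Pearson r with biserial r_bis is statistically invalid.
`badgemeta` implements the corrected pipeline end to end, with every failure
mode it guards against reproducible from synthetic data.

## The model

Each converted effect `y_i` (correlation scale, sampling variance `v_i`)
enters the multilevel model

    y = Xβ + u_study + u_species + u_phylo + u_unit + e

with marginal covariance

    Σ(θ) = V + σ²_study Z_s Z_sᵀ + σ²_species Z_p Z_pᵀ + σ²_phylo Z_p A Z_pᵀ + σ²_unit I

where `V` is a block sampling VCV (`V_ij = ρ √(v_i v_j)` for effects of the
same study, ρ = 0.5 by default) and `A` is the phylogenetic correlation
matrix from a Newick tree with Grafen branch lengths. Variance components
are estimated by REML; the package derives Wald CIs, Cochran's Q, multilevel
I² (level-wise shares that sum exactly to the total), 95% prediction
intervals, marginal R² for moderators, and an Egger-type small-study test
(effect size regressed on `√(1/ñ)` with `ñ = 4n₁n₂/(n₁+n₂)`, or on the
standard error; the intercept is the precision-adjusted pooled mean).

## Worked example

```python
from badgemeta.effect_sizes import GroupSummary, rbis_from_group_summary, \
    standardized_difference

g = GroupSummary(mean_dark=2.40, mean_light=2.25, sd_dark=0.80,
                 sd_light=0.75, n_dark=10, n_light=10)
for variant in ("fixed", "buggy"):
    d = standardized_difference(g, variant)
    r, v = rbis_from_group_summary(g, variant)
    print(f"{variant:5s}: d = {d:.5f}, r_bis = {r:.5f} (v = {v:.5f})")
```

prints

```
fixed: d = 0.19345, r_bis = 0.12712 (v = 0.08056)
buggy: d = 0.06465, r_bis = 0.04268 (v = 0.08243)
```

The corrected conversion divides the mean difference by the pooled SD
√(((n_L−1)SD_L² + (n_D−1)SD_D²)/(n_L+n_D−2)) ≈ 0.775; the erroneous variant
applies the division to the last summand only, inflating the denominator to
2.32 and attenuating d three-fold. The `r_bis` values match
`metafor::escalc(measure="RBIS")` on the same inputs.

A full synthetic re-analysis (74 studies, 54 species, ~185 mixed-origin
effects with true grand mean 0.2 and total heterogeneity σ² = 0.25):

```
python analysis/02_synthetic_reanalysis.py
```

```
pooled r = 0.359, 95% CI = [0.083, 0.635], p = 0.0108
sigma2 = 0.197, Q = 25433 (p = 0), I2_total = 99.8%
I2 by level: study 25.1%, species 0.0%, phylogeny 29.9%, unit 44.9%
95% PI = [-0.553, 1.272]
small-study slope = 0.28 (CI [-1.48, 2.03], p = 0.756); adjusted mean = 0.326
```

The pooled mean lands near the realized grand mean of that draw, the
prediction interval is far wider than the CI (high heterogeneity), and the
small-study slope is null, as it should be for an uncensored generator. The
other numbered scripts under `analysis/` demonstrate the parentheses bug
(`01`), the origin-moderator and default-positive sign artifact (`03`), and
small-study calibration plus an injected censoring mechanism (`04`); each
writes its tables under `results/`.

A CLI mirrors the library: `badgemeta convert|fit|bias|simulate|run`
(see `badgemeta run --help`).

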