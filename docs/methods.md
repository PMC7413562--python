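# Methods

This note documents the models, algorithms, defaults and numerical
choices behind `holcbirths`, and what the synthetic study does and does
not establish about real data.

## Study design being implemented

The unit of exposure is a HOLC-graded neighborhood polygon; the unit of
outcome is a birth. A birth inherits the grade of the polygon containing
its residence. Adjacent grades only are compared (B vs A, C vs B,
D vs C): non-adjacent contrasts violate positivity in practice, because
almost no grade-A neighborhood had any realistic chance of being graded
D given its 1940 characteristics. Confounding control uses 1940 census
measures exclusively, on the argument that present-day neighborhood
measures are mediators of any grade effect and would bias it toward
zero if adjusted for.

## Synthetic city and cohort

### Geometry

The city is an `n_cols x n_rows` grid of unit-square HOLC cells split
into contiguous metro bands (default LA/OAK/SF at 60/25/15% of columns),
each band's bounding rectangle serving as its explicit map boundary —
this is what makes the NG-versus-outside distinction decidable. The
1940 tract layer is the same grid shifted diagonally by `tract_offset`
(default 0.5 cells, any value strictly between 0 and 1 is valid; 0 or 1
raise a "degenerate overlay" error) and extended one cell outward, so
every HOLC cell is fully covered and every interior cell is cut by four
tracts. All geometry is planar in arbitrary units; no CRS handling, as
every method step is projection-invariant.

### Grades

Cell grades are drawn i.i.d. from `grade_probs` (default A/B/C/D/NG =
.10/.20/.35/.30/.05) and then spatially smoothed by greedy pair swaps
that increase same-grade adjacency. Swaps permute the sampled vector, so
marginal grade frequencies remain exactly multinomial — the smoothing
adds spatial realism without distorting the grade mix.

### 1940 tract metrics

Each tract's mean vector is the intersection-area-weighted mix of
per-grade means (defaults follow the historical direction: worse grades
have lower median home value, more non-White residents, more homes
needing major repairs, fewer radios/refrigerators, less schooling).
Totals are gamma-distributed with coefficient of variation `metric_cv`
(default 0.15) and rounded; every subcount is binomial in its total, so
logical bounds (subcount ≤ total) hold by construction.

On top of the grade gradients, metric means are modulated by smooth
Gaussian random surfaces (random Fourier features, correlation length 3
cells): one shared "wealth" field plus one independent field per metric,
mixed half-and-half, with per-metric loadings (`FIELD_SPECS`). This
creates large, spatially correlated *within-grade* heterogeneity.  It is
essential for realism: without it the 1940 covariates jointly determine
the grade almost perfectly, adjacent-grade propensity distributions
separate, and matching degenerates — whereas real cities vary far more
within a grade than adjacent grade means differ, and published
adjacent-grade propensity distributions overlap substantially. With the
default fields, the D-vs-C standardized difference is about 0.6–0.8 for
median home value and percent non-White (pre-match t-tests significant
in most 200-neighborhood cities) while the propensity model retains
genuine overlap.

### Births and outcomes

Births land uniformly within a neighborhood chosen with probability
proportional to area times a per-grade intensity (worse grades denser,
calibrated to the published cohort's grade totals). Configurable
fractions fall outside every boundary (2%), below 24 weeks (0.5%), or
have missing birth weight (0.2%), to exercise the inclusion flow; a
small fraction are flagged elective abortions to exercise the mortality
exclusion.

Outcome indicators come first, from logistic models; the raw fields are
then synthesized to encode them:

    logit P(outcome) = α_outcome + Σ_contrasts θ·[grade at/below cut]
                       + Σ_m γ_m (x_m − x̄_m) + maternal terms

* **Injected effects** accumulate down the grade ladder (B gets the
  B-vs-A effect, C adds C-vs-B, D adds D-vs-C), so each adjacent
  contrast's conditional log-OR equals exactly its injected value. NG
  carries no grade effect.
* **Confounders** `γ` act on the polygon's centered areal-weighted
  metrics — the same quantities the analysis adjusts for — with defaults
  −0.05 per $1000 of median home value and +0.012 per point of percent
  non-White. The crude and conditional contrast odds ratios therefore
  genuinely differ (for D vs C by roughly +0.10 on the log scale).
* **Maternal covariates** have grade-dependent distributions (younger,
  more often Hispanic/Black, less often college-educated mothers in
  worse grades, patterned on the published descriptive table) but by
  default do not enter the outcome logits (`maternal_coefs = {}`): the
  field does not establish which maternal variables confound versus
  mediate, so the simulator exposes the role through configuration
  rather than fixing it, and the default keeps the injected conditional
  effect identified by metric adjustment alone.
* **Couplings** make short gestations lighter and riskier (LBW logit
  +2.5 if preterm, VLBW +1.5 if very preterm, mortality +1.5 if
  preterm), giving realistic cross-outcome structure. Severe-variant
  intercepts are conditional (very-preterm given preterm, etc.).

Gestational age in days is then drawn in the band matching the
indicators (very preterm 168–223, preterm 224–258, term ≈ N(276, 9)
clipped to 259–293); birth weight in the matching gram bin, with the
non-LBW branch increasing in gestational age (+15 g/day) with a male
shift (+120 g). SGA is not injected directly; it emerges from the weight
model and is coded downstream against the cohort's own empirical
percentile reference. Death ages are drawn inside/outside the 28-day
window according to the neonatal indicator.

All randomness flows through `numpy.random.default_rng` seeded as
`[seed, stage]`; fixed seeds give byte-identical GeoJSON/CSV outputs.

## Areal apportionment

Weights divide the intersection area by the *HOLC polygon* area — the
method's stated rule — rather than by the source-tract area as classic
dasymetric interpolation would; the divergence is deliberate and not
"corrected". One rule is applied to every metric, including median home
value (yielding a weighted mean of tract medians) and population density
(tract residents per tract area, then weighted). Derived rates are
ratios of weighted numerators to weighted denominators; a zero weighted
denominator records the rate as missing with a warning. Intersections
below 1e-10 of the polygon area are dropped as floating-point slivers.
Partial coverage is not renormalized; a per-polygon `coverage` column
reports the weight sum instead.

## Outcome coding

Thresholds are strict inequalities at 259/224 days, 2500/1500 g, and 28
days; "within the first 28 days" is read as strictly fewer than 28
completed days, and weight exactly at the SGA percentile is not SGA.
Records under 168 days must be excluded upstream; the coders refuse
them. The empirical SGA reference takes the linear-interpolation 10th
percentile per (sex, completed week) cell with at least 100 births,
makes the curve non-decreasing across weeks by isotonic regression, and
strictly increasing by a 1e-6 g tie-break; under-filled cells are
unsupported and yield missing SGA. A loader accepts any user-supplied
`(sex, week, p10_grams)` CSV for use with an external reference table.
Perinatal mortality is implemented literally as any non-elective-abortion
death, unbounded in age.

## Propensity ensemble

Five deterministic learner families stand in for the published ensemble
menu: grand mean; unpenalized linear logistic; ridge logistic (the
Bayesian-GLM slot — an equivalent shrinkage function class with a
deterministic fit); an adaptive piecewise-linear learner (hinge bases at
the 25/50/75% quantiles of each standardized covariate, selected by
L1-penalized logistic regression — the MARS slot); and an additive
smooth-spline logistic (cubic B-spline basis, ridge penalty — the GAM
slot). Out-of-fold predictions from stratified k-fold CV (default k=10,
seed-controlled) are blended by non-negative weights summing to one that
minimize CV log-loss (SLSQP on the simplex); final scores come from
refit learners under those weights, clipped to [1e-6, 1−1e-6].
Separation in a learner is harmless (clipping); an all-one-arm input is
an error.

## Trimming and full matching

Support bounds are the 1st percentile of the propensity in the
better-graded arm and the 99th percentile in the worse-graded arm
(linear-interpolation quantiles); exclusions are logged with their
scores, and `--no-trim` reproduces the unrestricted analysis.

Matching is exact optimal full matching with replacement, solved as a
minimum-cost flow: treated-control pairs within the caliper (0.2 × SD of
the propensity on the trimmed sample, raw scale) are edges costed by the
Mahalanobis distance on (percent non-White, median home value) under the
pooled on-support covariance with a 1e-8 ridge; every unit with at least
one admissible partner must be used at least once (units without one are
discarded and logged); each pair can be used once. Costs are scaled by
1e6, rounded to integers, and incremented by 1, so among equal-cost
solutions the one with fewest pairs is preferred; with strictly positive
edge costs any optimal flow is automatically a union of stars (an edge
joining two nodes that both have other edges could be removed, reducing
cost while preserving feasibility), so the flow solution *is* a valid
full match — each subclass one treated with m controls or m treated with
one control. Treated neighborhoods get weight 1; each control's weight
is its subclass's treated count divided by its control count. Birth
weights are inherited by residence and rescaled so the mean nonzero
weight is 1, which stabilizes the weighted GLM without changing point
estimates.

The brute-force oracle in the test suite enumerates every admissible
edge subset covering all retained units on instances up to 4+4 and
agrees with the flow solution's total distance on 100 random instances.

## Weighted inference

Balance uses a Welch-type t-test with reliability weights: weighted
means, unbiased weighted variances, effective sample sizes
`(Σw)²/Σw²`, Welch–Satterthwaite degrees of freedom; it is invariant to
weight rescaling and reduces to the classical Welch test at unit
weights.

Outcome models are weighted logistic regressions (score equations
`Σ w_i (y_i − p_i) x_i = 0`) of each outcome on the worse-grade
indicator plus the four fixed 1940 covariates; the Spearman screen
(average-rank ties) is reported as a diagnostic but does not alter the
fixed covariate set. The sensitivity variant adds maternal age, parity
and birth year. No multiple-testing adjustment is applied, matching the
design; the number of tests is recorded in the run metadata.

### Variance estimation

Births sharing a neighborhood share exposure and weight, so
neighborhood-clustered sandwich errors are the natural default. Full
matching, however, concentrates weight on few neighborhoods (effective
cluster counts of 15–50 are routine), a regime in which the plain
empirical cluster meat is badly behaved: in fixed-design replications
its average fell ~20% below the true sampling standard deviation while
the *analytic working-model independence sandwich* — bread⁻¹
`Σ w_i² p̂_i(1−p̂_i) x_i x_i'` bread⁻¹, the exact score variance when
observations are independent given covariates — matched it exactly.
Since non-negative within-cluster correlation can only raise the true
variance above that analytic floor, the default estimator is:

1. compute the CR2 (Bell–McCaffrey) leverage-adjusted cluster meat,
   via low-rank `(I − H_cc)^{−1/2}` identities (verified equal to HC2 in
   the singleton-cluster limit);
2. use it, with a t quantile on `effG − 1` degrees of freedom
   (`effG = (Σ_c w_c)²/Σ_c w_c²` over cluster weight totals), only when
   it exceeds the analytic floor by more than its own chi-square noise
   (relative excess `2·sqrt(2/effG)`);
3. otherwise use the floor with a normal quantile — an analytic
   variance needs no degrees-of-freedom penalty.

Model-based (nonrobust) Wald errors remain available through
`cov_type="nonrobust"` for comparison. Cells with |log OR| > 15 or
SE > 50 are reported unavailable (separation), as are strata with an
empty weighted arm; the run continues.

## Problem sizes

The simulation-based contracts run at the scale the design prescribes:
parameter recovery uses 200 neighborhoods × 100 000 births × 50 seeds;
null calibration and the balance contract use 100 seeds of the default
city (200 neighborhoods; 20 000 births for calibration, no births needed
for balance); the matching oracle enumerates 100 random ≤4+4 instances.

## What passing tests do and do not show

The generator reproduces the *structure* the methods rely on —
misaligned tessellations, grade-correlated confounders with within-grade
spatial heterogeneity, adjacent-grade effects, an inclusion flow — so
passing tests show the pipeline estimates what it claims under that
structure (correctly specified outcome logits, no unmeasured
confounding, no residential mobility, independent births given the
neighborhood). Real data violate several of these: multiple births per
parent, geocoding error, digitization artifacts in historical polygons,
unmeasured neighborhood-level risk (which the pretest estimator would
then pick up through the cluster meat), and confounder-model
misspecification. Results on the synthetic study therefore validate the
machinery, not the substantive conclusions one would draw from the real
cohort.

## Known limitations

* Rectangular tessellations only in the generator; the apportionment and
  assignment code paths accept arbitrary (multi)polygons but are tested
  on grids plus small hand-built cases.
* SGA effects cannot be injected directly; they arise through the weight
  model.
* The empirical SGA reference is cohort-relative; absolute SGA
  prevalence is ~10% by construction.
* Elective abortions are represented only as a record flag with a death
  date; no gestational-age structure is simulated for them.
* Birth year carries no secular trend by default.
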