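# Methods

This note documents the models, the defaults and the design choices behind
`otosr`, in the order the pipeline runs.

## Geology covariates

A watershed is described by mapped geologic units, each with an age range
(Ma), a broad rock class (intrusive / extrusive / other) and an outcrop
area (km²). The continuous age of a unit is the midpoint of its range —
map codes carry ranges, not point ages — and the covariates of a watershed
are its per-age-class and per-rock-class area fractions plus the
area-weighted mean age. Fractions are dimensionless in [0, 1] throughout
the package (readers convert "21%" cells on input); age is always in Ma.
Only the intrusive and extrusive fractions enter the candidate set: with
three rock classes the third fraction is the complement of the other two
and would be exactly collinear. Age-class bounds live in an editable
bundled table (`data/age_class_bounds.csv`) because chronostratigraphic
chart revisions move boundary ages; the composite "precambrian" class
spans 541–4000 Ma (midpoint 2270.5 Ma).

Two invariants pin the construction down: fractions and weighted mean age
are unchanged by splitting a unit into same-class pieces of the same total
area, and by rescaling all areas by a common factor (units of area cancel).

## Isoscape regression

The response is a river's baseline ⁸⁷Sr/⁸⁶Sr; candidates are the watershed
covariates and, optionally, all pairwise products. Models are ordinary
least squares with an intercept. The intercept matters on this data type:
⁸⁷Sr/⁸⁶Sr has a physical floor near 0.704–0.710 set by mantle-derived and
marine sources, so a through-the-origin fit has no sensible meaning, and a
without-intercept R² (computed against an uncentered total sum of squares)
would be uninformatively close to 1.

Model search minimises AICc, `AIC + 2k(k+1)/(n−k−1)`, with Gaussian
profile log-likelihood and k counting coefficients, intercept and residual
variance. Term subsets are limited to four (plus the intercept): with ~20
observations and two dozen candidates plus interactions, anything larger
invites over-parameterisation. The search is exhaustive whenever the model
space has at most 2000 members — with the bundled baseline's four
covariates there are only 385 models, so selection there is fully
enumerated and deterministic — and otherwise a seeded genetic algorithm
over term subsets (population 50, generations 200, mutation rate 0.1,
elitism 2, plus a ~10% quota of random immigrants per generation; the
immigrants keep the population from collapsing onto one local optimum in
small, plateau-rich model spaces). The GA is a search heuristic for the
same criterion, never a different criterion: wherever enumeration is
feasible the two must agree, and the tests assert exactly that.

A validation fraction (default one third when requested) is drawn by the
seeded generator *before* any search, withheld from selection, and
reported as held-out residuals of the chosen model. The final model is
refit on every supplied row before being used for prediction, so the
published coefficients use all usable data. On the bundled baseline the
package's convention is to select with no validation split (the model
space is enumerable, and selection is then a deterministic function of the
data); the split machinery exists for larger candidate sets and is
property-tested.

Prediction for an unsampled watershed uses the prediction interval for a
new observation, `t·√(s²(1 + x′(X′X)⁻¹x))` — wider than the confidence
interval for the mean, and monotonically growing with the covariate
vector's leverage. A fitted model serialises to JSON with its
`(X′X)⁻¹`, so stored models predict with exact intervals.

On the bundled baseline (23 sampled, non-outlier sites) the AICc-best
model is `{precambrian, carboniferous:mean_age, mean_age:precambrian,
precambrian:tertiary}` with adjusted R² 0.938; it predicts the unsampled
lower Jari watershed at 0.73644 ± 0.00611 (95% PI). The one flagged
outlier site is excluded by flag only — the package never auto-detects
outliers.

## River-group discrimination

With ⁸⁷Sr/⁸⁶Sr as the single predictor, each of the three river groups is
modelled as a Gaussian with its own mean and (unbiased) variance; priors
are equal by default because a fish's prior location is unknown. The
discriminant score is `−½ log σₖ² − (x−μₖ)²/(2σₖ²) + log πₖ`; posteriors
are normalised exponentiated scores; argmax ties break by the model's
fixed group order. Regression-predicted baseline sites join the training
set by default (a flag excludes them), and a site sampled repeatedly over
time enters once with its single reported mean, not as replicates.

Two error rates are reported and deliberately kept distinct:

* `apparent_error` — the fitted discriminant's classification error on its
  own training set. On the bundled 28-site baseline this is 1/28 (3.6%):
  the lone misassignment is the *predicted* Amazon-mouth site, whose ratio
  (0.71625) sits in the Beni-Madeira score region.
* `loocv_error` — leave-one-out cross-validation, refitting without each
  site before classifying it. On the same baseline this is 3/28 (10.7%):
  two genuine boundary sites (one high Negro-basin site in each of the
  two upper groups) flip in addition. LOO is the honest out-of-sample
  figure; the apparent error is the optimistic companion and is what a
  training-set classification table reports.

## Transect segmentation

A transect is a strictly increasing distance grid (μm from the otolith
core) with one ratio per laser integration point; points are ~7.86 μm
apart (30 μm/s scan speed × 0.262 s integration). Segmentation minimises

    Σ_segments cost(segment) + penalty × (#changepoints)

exactly, by PELT: a dynamic program over change positions that prunes any
candidate start `s` once `F(s) + C(s, t) > F(t)`, which is loss-free for
additive, split-non-increasing costs (pruning constant K = 0). The tests
hold PELT to exact index agreement with an unpruned O(n²) dynamic program.

The default cost is the raw within-segment sum of squared errors and the
default penalty is 1e-4. These two defaults are calibrated to each other
*for ratio-scale Sr data*: with instrument noise around 1e-3, a spurious
split gains SSE of order 1e-6–1e-5, while a real signature shift of ≥
3e-3 sustained for ≥ 10 points gains ≥ 1e-4. On a variance-scaled cost
(`cost_kind="scaled_sse"`, SSE divided by a robust noise variance
estimated from the median absolute first difference,
σ̂ = median|Δx|/0.95387) the same penalty would be absurdly small — a
pure-noise segment of m points then costs ≈ m — so that mode expects a
BIC-style penalty of order 2·log n. A per-segment Gaussian mean+variance
cost (`normal_meanvar`) is also provided, with a variance floor of 1e-16
against degenerate constant segments.

Fragments — segments shorter than `min_segment_points` (default 10, ≈ 80
μm of otolith, a run shorter than any plausible residence) — are merged
iteratively, shortest first, into the neighbour with the closer mean,
recomputing means from the data each time; a segment exactly at the
threshold is kept. The output always tiles the transect. This codifies a
step that is otherwise done by eye, trading judgement for
reproducibility. Transects shorter than twice the threshold are returned
whole with a warning; transects need at least 10 points at all.

Each retained segment's mean is classified with the discriminant. A
*signature move* is any changepoint (n_segments − 1); a *group move*
counts only adjacent segments assigned to different river groups, so
group moves ≤ signature moves, and movement within a group (e.g. between
distinct tributary signatures of the mainstem group) is visible as
signature movement without group movement.

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes, with truth records for recovery tests; all are pure functions of
(configuration, seed).

* Geology: per watershed, 3–8 units drawn from a 22-class age pool with
  log-normal areas and random rock classes — sized so the candidate set
  spans the two dozen variables the covariate construction is designed
  around.
* Water: ratios are a known ("truth") isoscape model's predictions plus
  Gaussian noise (default SD 2e-3, the scale of within-river temporal
  SDs in the baseline); group labels cut the noise-free predictions into
  three equal-count bands, mirroring the low/middle/high structure of the
  real groups.
* Transects: piecewise-constant means with i.i.d. Gaussian noise (default
  SD 1e-3 — an order of magnitude above the aggregate standard error of a
  marine-shell reference standard, approximating per-integration scatter)
  on the 7.86 μm grid. Segment means are drawn from the per-group
  empirical pools of the bundled baseline rather than invented, with
  consecutive means forced ≥ 3e-3 apart (a "move" smaller than instrument
  noise is not a signal; where a pool cannot satisfy the gap the most
  separated value is used). Pools keep only values that the
  baseline-fitted discriminant assigns back to their own group — without
  that, a simulated truth could label a segment with a group whose own
  classifier provably disagrees, and no segmentation could recover it.
* The default cohort fixes 22 fish (14 dourada, 5 piramutaba, 3 piraíba)
  with prescribed movement histories: 10/14 dourada multi-segment, 2 of
  them crossing river groups; 2/5 piramutaba moving within the mainstem
  group; 2/3 piraíba crossing between Beni-Madeira and the mainstem.

What the simulator does **not** emulate: otolith growth rate (distance is
not calendar time), element-incorporation kinetics, estuarine
salinity-mixing gradients, autocorrelated instrument drift, and gradual
(non-step) transitions during equilibration. Passing recovery tests
therefore show the algorithms are correct on step-plus-noise data, not
that real transects are step-plus-noise.

## Numerical choices

* OLS is delegated to statsmodels; selection, AICc and interval machinery
  are package code. Rank-deficient designs are rejected with the collinear
  terms named (smallest-singular-vector support).
* AICc requires n − k − 1 > 0 and is an error otherwise, never ±inf.
* Interaction names are canonical (`a:b` with factors sorted), so a term
  set is order-free.
* All delimited files are written with `repr(float)` cells and read back
  with round-trip float parsing, so read → write → read is value-identical.
* Determinism: GA and validation splits take explicit seeds; PELT,
  selection-by-enumeration, QDA and LOO are deterministic; argmax ties
  break by fixed group order.

## Known limitations

* The mainstem/estuary ambiguity is structural: the estuary's mixed
  signature falls inside the mainstem group's range, so "no group move"
  cannot distinguish estuary residence from mainstem residence.
* One-dimensional discrimination cannot separate groups whose ratio
  ranges overlap; boundary sites are genuinely ambiguous, as the LOO rate
  shows. Multi-element discrimination is out of scope.
* The fragment rule is a surrogate for expert judgement; its threshold is
  a length heuristic, not a significance test.
* Baseline sampling is sparse and temporally uneven (per-site SDs span
  2.5e-4 to 7.4e-3); the regression treats each site as one exchangeable
  observation and models no spatial autocorrelation.
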