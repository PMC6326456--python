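# Methods

This note documents the models, algorithms and numerical choices behind
`maternut`, in the order the pipeline runs them.

## Outcome: severe child undernutrition

Each under-five child contributes three anthropometric indicators
computed against an LMS growth reference (Box-Cox power *L*, median *M*,
coefficient of variation *S*, tabulated per sex over an age or height
grid):

- weight-for-age and height-for-age, indexed by age in months;
- weight-for-height, indexed by height in cm (age enters only through
  which reference table — recumbent vs standing — a configuration would
  select; the reference itself stays one-dimensional).

The z-score of measurement *x* is `((x/M)^L − 1)/(L·S)` (the log form
`ln(x/M)/S` when `L = 0`). Numerically both the forward and the inverse
transform use `expm1`/`log1p` forms, and `|L| < 1e-12` is treated as
`L = 0`: the naive power form cancels catastrophically for small *L*.
Parameters are interpolated linearly between tabulated rows; queries
outside the grid flag the child and mark that indicator missing.

The binary outcome follows the severe-anthropometric-failure rule: a
child is severely undernourished iff **any** non-missing indicator falls
strictly below −3 SD of the reference median. Two quality rules apply
before classification: `|z| > 6` is flagged biologically implausible and
excluded, and a child with no usable indicator is flagged
unclassifiable and excluded from the analysis (counts are logged). The
WHO "restricted application" adjustment for extreme weight-based scores
is deliberately not implemented; the simpler flag rule is documented
here instead. Severe sanitation deprivation is a covariate: no toilet
access of any kind.

## Conflict exposure

Conflict events (point locations, month, best-estimate battle deaths)
are treated as draws from a latent spatial point process. For a
reference month *t*, events of the 12 completed months strictly before
*t* (the closed window `[t−12, t−1]`) are smoothed with an isotropic
Gaussian kernel in locally projected kilometres (equirectangular
projection about the grid-centre latitude), each event weighted by its
deaths. Because the kernel is separable, the integral over each grid
cell is exact — a product of 1-D normal CDF differences across the cell
edges — and the surface is rescaled so that its total mass equals total
window deaths. A cell value therefore reads as *expected deaths in this
cell over the window*. Values below 1e-9 are floored to exactly zero so
"no exposure" is a sharp statement rather than a denormal float.

Defaults: bandwidth 30 km (wider than the ≤ 20 km anonymisation
displacement of cluster coordinates, so a displaced cluster still sits
under the kernel mass of nearby events), cell size 0.1°. Cells are
half-open (`[lon, lon+Δ)`), so a point exactly on an interior boundary
belongs to the east/north cell. Exposure surfaces are exactly invariant
under joint longitude translations of events and grid; latitude
translations change the projection scale by `cos(lat)` and are only
approximately invariant — a property of any fixed local projection.

Each child's exposure is the value of the cell containing its cluster
location, for the surface of its own interview month. The subgroup
contrast splits children into exposure exactly 0 versus exposure above
a threshold (default 10 expected deaths per cell; the band in between
belongs to neither group).

Flood and drought covariates are the max (surface runoff, mm/day) and
min (drought index, %) over the same 12-month retrospective window,
skipping missing months.

## Survey-constrained partition

A high-resolution spatial control is built by tessellating the region
into Voronoi cells seeded at survey-cluster locations and merging cells
into contiguous areas until every area contains clusters from **both**
survey rounds. The number of areas is maximised exactly: any contiguous
area containing both rounds must contain an adjacent mixed-round pair
of cells (walk a within-area path from a 2008 cell to a 2013 cell; the
round switches at some edge), so the achievable count is bounded by the
maximum bipartite matching over mixed-round adjacent pairs, and seeding
one area per matched pair then attaching leftover cells to adjacent
areas attains the bound. Attachment is deterministic (lowest-index cell
first, smallest adjacent area, ties to the lowest id). Unbounded
Voronoi cells are closed by extending ridges far beyond the region
before clipping; with fewer than four (or collinear) seeds, where a
proper tessellation does not exist, all seeds are treated as mutually
adjacent.

## Probit BART

The outcome model is a sum of *m* shallow regression trees under a
probit link:

    P(Y = 1 | x) = Φ( Σ_{j=1}^m g(x; T_j, M_j) + c₀ )

with `c₀ = Φ⁻¹(ȳ)` an offset at the sample prevalence. Fitting uses
Albert–Chib latent augmentation: `z_i ~ N(η_i, 1)` truncated to the
positive half-line when `y_i = 1` and to the non-positive half-line
otherwise, drawn by inverse CDF. Each backfitting sweep updates every
tree against the partial residuals of the latents (residual variance
fixed at 1 on the probit scale), proposes one structural move —
grow (p = 0.28), prune (0.28) or change (0.44) — accepted by
Metropolis–Hastings under the depth prior
`p(split at depth d) = α(1+d)^(−β)` (α = 0.95, β = 2) and the conjugate
marginal likelihood with leaf prior `μ ~ N(0, (3/(k√m))²)`, k = 2; then
redraws all leaf values from their normal conditionals and all latents.
A single-leaf tree proposes grow with probability 1 when `p_grow > 0`
(with the proposal asymmetry accounted for in the acceptance ratio);
with `p_grow = 0` trees stay single leaves and the model degenerates to
an intercept-only probit — a closed-form limit used as a test.

Split candidates are the distinct observed values of each column with
the minimum dropped (a cut at the minimum routes nothing left);
proposals that would create an empty leaf are rejected outright, which
keeps every leaf conditional proper. Categorical covariates are one-hot
encoded; the treatment (education level) enters as a single ordered
numeric column so trees can split the level axis anywhere.

The inner loop is compiled with numba; the ensemble lives in flat
preallocated arrays and pruned children become unreachable dead slots.
One internal PRNG stream is seeded per fit from the configuration seed,
making every chain — and the whole pipeline — exactly reproducible.
Prediction matrices passed at fit time are *tracked*: their per-tree
leaf assignments are updated incrementally during sampling, so
posterior predictive draws for counterfactual designs are recorded at
essentially zero extra cost and are bit-identical to post-hoc
evaluation of the retained states (a tested invariant).

Defaults follow the canonical regularisation (200 trees, 1,000 burn-in,
1,000 retained draws); tests and the acceptance runs use scaled-down
settings (50 trees, 200/200, and 25/150/150 for the null-calibration
suite) chosen to exercise the same code paths at desk scale.

## Counterfactual CATE

Treatment is the mother's education level, an ordinal coding of years
of schooling: 1 = none, 2 = 1–6 y, 3 = 7–8 y, 4 = 9 y (the compulsory
mark), 5 = 10–12 y, 6 = > 12 y. One 70/30 train/test split is drawn
(test share rounded up, which reproduces the 18,141 / 7,776 split of a
25,917-child sample). The fitted model predicts each test child twice:
at the observed level (factual) and with the level replaced (the
counterfactual), all other covariates bit-identical.

Per child, both arms' probit draws are averaged through Φ first:
`p̄_i = mean_s Φ(draw_{s,i})`; the individual treatment effect is
`θ_i = p̄_i(treated) − p̄_i(control)`, so a negative value is protective.
For the per-level analyses (children observed at level L vs a
no-education counterfactual) the factual arm is the treated arm; for
the untreated analysis (children observed at level 1, counterfactual at
the 9-year policy level) the counterfactual is the treated arm. The
CATE is the mean of θ_i over the (sub)group; the subgroup decomposition
is an exact weighted mean.

Uncertainty comes from bootstrapping the training set only: each of
`n_boot` iterations resamples training rows with replacement, refits
the model (fresh chain seed from a spawned sequence), and predicts the
*fixed* test design. The point estimate is the mean of bootstrap CATEs
and the credible region their 2.5–97.5 percentile band, clamped to
bracket the point estimate (with `n_boot = 1` the region degenerates to
a point). A resample that loses one outcome class entirely falls back
to the original training set for that iteration. Per-child reported
ITEs are bootstrap averages, so the reported CATE equals the mean of
reported ITEs exactly. Per-iteration posterior spread is averaged into
p̄_i before the CATE is formed; mixing posterior and bootstrap
variability differently is a documented alternative, not the default.
All per-level and conflict-subgroup estimates share one set of
bootstrap refits (the subgroup CATE is a restricted average of the same
θ_i), which is statistically identical to running them separately and
several times cheaper.

Covariates passed to the model: child age and sex, mother's age,
religion, native language, relation to household head, breastfeeding,
urban residence, household wealth (IWI), electricity, sanitation
deprivation, administrative region, partition area, survey round (time
as a control), conflict intensity, and the flood/drought window
extrema.

## Classifier diagnostics

Sensitivity, specificity, ROC and AUC are computed on the held-out test
set's factual predictions from a single reference fit on the full
training set (scikit-learn's ROC machinery; AUC by trapezoid equals the
midrank Mann–Whitney concordance, a tested equivalence). The operating
cutoff maximises Youden's J with ties broken towards the lower cutoff
and the convention `score ≥ cutoff ⇒ predicted positive`; the selection
rule is configurable since it is a reporting choice, not part of the
estimand.

## Synthetic data generator

The generator emulates the study design, not any real dataset: two
repeated cross-sectional rounds (field-work windows June–November 2008
and February–July 2013) of spatially clustered surveys in a
Nigeria-sized bounding box; household wealth drawn from a scaled Beta
distribution with an urban premium; education levels drawn with
probabilities shifting upward in wealth (the confounding path); and a
probit outcome

    η_i = c + β_w·wealth + β_s·no_sanitation + β_u·urban + β_a·age
          + γ·conflict_exposure + δ_{L(i)},
    y_i ~ Bernoulli(Φ(η_i))

with default intercept −1.0 (prevalence ≈ 0.19), wealth slope −0.35 per
wealth SD, and true education effects
δ = (0, −0.05, −0.07, −0.05, −0.12, −0.15) on the probit scale — a
threshold shape in which material protection appears only beyond the
compulsory 9 years. Conflict events follow a clustered spatial Poisson
process around three persistent hotspots biased towards the north-east
(12 events/month, ~40 deaths each, hotspot scatter 0.1°), and ~15% of
survey clusters are co-located with hotspot towns: conflict and surveys
both concentrate where people live. These rates make the exposure
distribution span exact zeros, a moderate band, and cells above the
subgroup threshold of 10.

Anthropometry is realised outcome-first: y is drawn from the probit
model, then target z-scores consistent with y are sampled (for y = 1
one of height-for-age / weight-for-height is pushed below −3, capped at
−5.5 to stay clear of the implausibility flag) and inverted through the
LMS reference into height and weight; a rejection loop (≤ 100 draws,
then a deterministic fallback) guarantees the anthropometry module
reproduces y for every child. The synthetic reference defines the
weight-for-age median as the weight-for-height median evaluated at the
height-for-age median, so the three indicators are mutually consistent
at the median up to the linear interpolation of the tables.

Ground truth (per-child `η_base` excluding the education term, the δ
vector, exposures) is emitted as a separate artefact never read by the
analysis stages; `true_cate` evaluates any contrast exactly as
`mean Φ(η_base + δ_t) − Φ(η_base + δ_c)`.

What the generator does **not** emulate: survey sampling weights,
stratification and non-response; displaced-population undercoverage;
measurement error in anthropometry; within-conflict temporal
escalation. Passing tests therefore show that the pipeline recovers
known effects under clustered, confounded, spatially exposed data — not
that any particular real-world estimate is correct.

## Problem sizes used in the standard runs

The standard validation scenario runs n = 4,000 children with 50 trees,
200 burn-in, 200 retained draws and 50 bootstrap refits (about 80 s per
seed on one CPU); the null-calibration suite runs 20 replicates at
n = 2,000 with 25 trees and 25 refits. These sizes were chosen so the
whole battery completes at desk scale while leaving the estimators'
statistical behaviour visible; all are configurable upward to the
canonical defaults.

## Known limitations

- The bootstrap credible region reflects refitting variability around a
  fixed split; it does not propagate split-to-split variance.
- The latitude-translation approximation above; negligible at
  country scale with a 30 km bandwidth.
- The partition maximises the number of areas but not any balance
  criterion; areas can differ greatly in cluster count.
- Intensity surfaces are estimated independently per month (no
  spatio-temporal smoothing), exactly as specified by the 12-month
  retrospective window design.
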