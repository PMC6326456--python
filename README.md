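# maternut

Heterogeneous treatment effects of maternal education on severe child
undernutrition under armed-conflict exposure.

`maternut` is a tested, reusable implementation of a causal pipeline
for repeated cross-sectional household surveys (DHS-style data) in a
conflict setting. It is aimed at epidemiologists and applied causal
inference researchers who want to estimate how many years of maternal
schooling protect under-five children from severe undernutrition, and
whether that protection survives exposure to armed conflict — without
access to the restricted microdata such studies normally require. A
first-class synthetic-data generator with known ground truth makes
every stage testable end to end.

## What it computes

**Outcome.** For each child, WHO-style LMS z-scores for weight-for-age,
height-for-age and weight-for-height,
`z = ((x/M)^L − 1)/(L·S)`, and the Bristol severe-undernutrition
binary: `y = 1` iff any indicator falls below −3 SD of the reference
median.

**Exposure.** Conflict events are smoothed into monthly intensity
surfaces (Gaussian kernel in projected km, events weighted by battle
deaths, exact per-cell integrals); each child is assigned the expected
deaths in its grid cell over the 12 months preceding its interview.
A Voronoi partition of survey clusters, merged into the maximum number
of contiguous areas containing both survey rounds, provides a
high-resolution spatial control.

**Model.** A from-scratch probit Bayesian Additive Regression Trees
sampler:

    P(Y=1 | d, x) = Φ( Σ_{j=1}^m g(d, x; T_j, M_j) )

with Albert–Chib latent augmentation, grow/prune/change
Metropolis–Hastings tree moves under the canonical regularisation prior
(α = 0.95, β = 2, leaf sd 3/(k√m)), and a numba-compiled inner loop.

**Estimand.** Each held-out child is predicted at its observed
education level and at a counterfactual level; the individual effect is
θ_i = p̄(treated) − p̄(control) where p̄ averages Φ over posterior draws,
and the CATE is the subgroup mean of θ_i (negative = protective).
Education is a six-level ordinal treatment (1 = none … 4 = the 9-year
compulsory mark … 6 = more than 12 years). Credible regions come from
bootstrapping the training set and refitting the model. Diagnostics
(ROC/AUC, Youden cutoff) are computed out-of-sample.

## Worked example

```python
from maternut import synthetic_data, cate_pipeline
from maternut.data_model_io import StudyConfig

cfg = synthetic_data.SimulationConfig(n_children=1500,
                                      n_clusters_per_round=20, seed=7)
children, clusters, events, series, truth = \
    synthetic_data.generate_population(cfg)

sc = StudyConfig(seed=7, num_trees=50, burn_in=200, num_draws=200,
                 n_bootstrap=25)
res = cate_pipeline.run_analysis(
    sc, children, events, synthetic_data.generate_reference(7),
    clusters=clusters, series=series, grid_spec=cfg.grid_spec)
for line in res.log_lines:
    print(line)
```

prints (about 30 s on one CPU):

```
outcomes: 1500 children, prevalence 0.1760
exposures: conflict intensity median 0.000, max 39.341
partition: 17 areas from 40 clusters
split: 1050 train / 450 test
diagnostics: AUC 0.655, cutoff 0.182
untreated analysis: CATE -0.0222 [-0.0728, +0.0289]
cate level 2: -0.0072 [-0.0467, +0.0047] n=106
cate level 3: -0.0170 [-0.0605, +0.0135] n=56
cate level 4: -0.0150 [-0.0495, +0.0184] n=52
cate level 5: -0.0144 [-0.0547, +0.0420] n=59
cate level 6: -0.0126 [-0.0400, +0.0213] n=43
```

Reading the output: prevalence is the share of children classified
severely undernourished; each `cate level L` line is the estimated
change in that probability had the mothers observed at level L instead
had no education, with its bootstrap 95% region — e.g. level 3 mothers'
education lowers their children's risk by an estimated 1.7 percentage
points, but the region includes 0. The `untreated analysis` line asks
the converse: how much would children of uneducated mothers gain if
their mothers had completed the 9-year compulsory level. At this small
n the regions are wide; the generator's true subgroup effects here are
−0.026 (level 5) and −0.029 (level 6), recovered tightly in the
standard n = 4,000 runs (see below). `res.cate_by_level`, `res.ite`,
`res.subgroups`, `res.metrics` hold the same results as data frames,
and `res.write(out_dir)` exports them as CSV/JSON.

A command-line interface mirrors the stages
(`maternut simulate | outcomes | exposures | evaluate | run-all`):

```bash
maternut run-all --seed 7 --n-children 1500 --n-boot 25 \
    --trees 50 --draws 200 --burn-in 200 --out-dir results/
```

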