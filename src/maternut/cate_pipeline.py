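"""Counterfactual CATE estimation for maternal-education effects.

Treatment is the mother's education level, a six-level ordinal coding of
years of schooling (1 = none ... 6 = more than 12 years).  Following the
potential-outcomes setup, the fitted probit ensemble predicts each
held-out child twice — once at the observed education level and once
with the level replaced by a counterfactual, all other covariates held
fixed.  Per child,

    theta_i = mean_s Phi(draw_treated_{s,i}) - mean_s Phi(draw_control_{s,i})

is the individual treatment effect on the probability scale, and the
conditional average treatment effect is the mean of theta_i over the
(sub)group of interest.  A negative value is protective: the child is
less likely to be severely undernourished under the treated level.

Uncertainty comes from bootstrapping the training set: the model is
refitted on each resample (the 70/30 split and the test-set
counterfactual design stay fixed), and the credible region is the
2.5-97.5 percentile band of the bootstrap CATE distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from maternut import anthropometry, evaluation, spatial_exposures
from maternut.data_model_io import (ChildRecord, ConflictEvent, StudyConfig,
                                    SurveyCluster, children_to_frame)
from maternut.probit_bart import (BartConfig, fit_probit_bart,
                                  posterior_mean_probability)

logger = logging.getLogger(__name__)

EDUCATION_LEVELS = (1, 2, 3, 4, 5, 6)

#: education level coded as treatment in the untreated analysis
#: (compulsory schooling: 9 completed years)
POLICY_LEVEL = 4

TREATMENT_COLUMN = "education_level"


def bin_education(years: int) -> int:
    """Six-level ordinal coding of years of schooling.

    1 = no education (0 y), 2 = up to and including primary (1-6 y),
    3 = lower secondary (7 - <9 y), 4 = completed lower secondary (9 y,
    the compulsory-education mark), 5 = up to and including higher
    secondary (10-12 y), 6 = college and higher (> 12 y).
    """
    if years < 0:
        raise ValueError(f"negative education years: {years}")
    if years == 0:
        return 1
    if years <= 6:
        return 2
    if years <= 8:
        return 3
    if years == 9:
        return 4
    if years <= 12:
        return 5
    return 6


def split_train_test(items: Sequence, fraction_train: float = 0.7,
                     seed: int = 0) -> tuple[list, list]:
    """Random disjoint exhaustive split; test share rounded up.

    ``ceil`` on the test share reproduces e.g. 18,141 / 7,776 for
    n = 25,917 at 70/30.  Reproducible for a fixed seed.
    """
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    if not 0.0 < fraction_train < 1.0:
        raise ValueError("fraction_train must be in (0, 1)")
    _, n_test = split_sizes(n, fraction_train)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [items[i] for i in range(n) if i not in test_idx]
    test = [items[i] for i in range(n) if i in test_idx]
    return train, test


def split_sizes(n: int, fraction_train: float = 0.7) -> tuple[int, int]:
    """(train, test) sizes under the ceil-on-test-share convention.

    Computed as ``train = floor(fraction * n)`` (equivalently ceil on
    the test share) with a small epsilon so binary fractions like 0.7
    do not tip an exact product over an integer boundary.
    """
    n_train = math.floor(fraction_train * n + 1e-9)
    return n_train, n - n_train


@dataclass
class TreatmentSpec:
    """Treatment coding for one counterfactual analysis."""

    variable: str = TREATMENT_COLUMN
    counterfactual_level: int = 1

    def __post_init__(self) -> None:
        if self.counterfactual_level not in EDUCATION_LEVELS:
            raise ValueError(
                f"counterfactual level {self.counterfactual_level} "
                f"not in {EDUCATION_LEVELS}")


@dataclass
class CounterfactualDesign:
    """Factual and counterfactual test matrices, paired by child_id.

    Identical except for the treatment column; combined row count is
    twice the test size.
    """

    factual: pd.DataFrame
    counterfactual: pd.DataFrame
    child_ids: list[str]

    def __post_init__(self) -> None:
        if list(self.factual.columns) != list(self.counterfactual.columns):
            raise ValueError("design halves must share a schema")
        if len(self.factual) != len(self.counterfactual):
            raise ValueError("design halves must have equal row counts")

    @property
    def n_rows_combined(self) -> int:
        return 2 * len(self.factual)


def build_counterfactual_design(test_X: pd.DataFrame,
                                spec: TreatmentSpec,
                                child_ids: Sequence[str] | None = None
                                ) -> CounterfactualDesign:
    """Duplicate the test matrix with the treatment column replaced."""
    if spec.variable not in test_X.columns:
        raise ValueError(f"treatment column {spec.variable!r} missing")
    cf = test_X.copy()
    cf[spec.variable] = float(spec.counterfactual_level)
    ids = list(child_ids) if child_ids is not None \
        else [str(i) for i in range(len(test_X))]
    return CounterfactualDesign(factual=test_X.copy(), counterfactual=cf,
                                child_ids=ids)


@dataclass
class CateEstimate:
    """Individual effects plus their (sub)group average and uncertainty."""

    theta: np.ndarray
    cate: float
    ci_low: float | None = None
    ci_high: float | None = None
    subgroup: str | None = None
    n_children: int = 0
    child_ids: list[str] | None = None
    bootstrap_cates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.n_children == 0:
            self.n_children = len(self.theta)
        if abs(self.cate - float(self.theta.mean())) > 1e-9:
            raise ValueError("CATE must equal the mean of theta")
        if np.any(np.abs(self.theta) > 1.0 + 1e-12):
            raise ValueError("theta outside [-1, 1]")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low - 1e-12 <= self.cate <= self.ci_high + 1e-12):
                raise ValueError("credible region must bracket the estimate")


def estimate_cate_from_draws(factual_draws: np.ndarray,
                             counterfactual_draws: np.ndarray,
                             treated_is_factual: bool = True,
                             child_ids: Sequence[str] | None = None
                             ) -> CateEstimate:
    """ITEs and CATE from probit-scale posterior draw matrices (S x n).

    Each child's probability per arm is the draw-average of Phi; theta_i
    is treated-arm minus control-arm.  For per-level treated analyses
    the factual matrix is the treated arm; for the untreated analysis
    (counterfactual = policy level) it is the control arm.
    """
    f = np.asarray(factual_draws, dtype=float)
    c = np.asarray(counterfactual_draws, dtype=float)
    if f.shape != c.shape:
        raise ValueError(f"draw shape mismatch: {f.shape} vs {c.shape}")
    if f.ndim != 2 or f.shape[0] < 1 or f.shape[1] < 1:
        raise ValueError("draws must be a non-empty S x n matrix")
    p_fact = ndtr(f).mean(axis=0)
    p_cf = ndtr(c).mean(axis=0)
    theta = p_fact - p_cf if treated_is_factual else p_cf - p_fact
    return CateEstimate(theta=theta, cate=float(theta.mean()),
                        child_ids=list(child_ids) if child_ids else None)


def subgroup_cate(estimate: CateEstimate,
                  mask: np.ndarray,
                  label: str | None = None) -> CateEstimate:
    """Restrict the ITE average to children selected by ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != estimate.theta.shape:
        raise ValueError("mask must align with theta")
    if not mask.any():
        raise ValueError(f"empty subgroup {label!r}")
    theta = estimate.theta[mask]
    ids = ([cid for cid, m in zip(estimate.child_ids, mask) if m]
           if estimate.child_ids else None)
    return CateEstimate(theta=theta, cate=float(theta.mean()),
                        subgroup=label, child_ids=ids)


def conflict_subgroup_masks(intensity: np.ndarray,
                            threshold: float = 10.0
                            ) -> dict[str, np.ndarray]:
    """Built-in conflict-exposure contrast: zero vs above-threshold.

    Children with intensity in (0, threshold] belong to neither group
    (the band between is excluded from the contrast).
    """
    intensity = np.asarray(intensity, dtype=float)
    return {"no_conflict": intensity == 0.0,
            f"conflict_gt_{threshold:g}": intensity > threshold}


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def bootstrap_cate(train_X: pd.DataFrame, train_y: np.ndarray,
                   design: CounterfactualDesign,
                   bart_config: BartConfig,
                   n_boot: int = 1000, seed: int = 0,
                   treated_is_factual: bool = True,
                   subgroup_masks: Mapping[str, np.ndarray] | None = None
                   ) -> dict[str, CateEstimate]:
    """Bootstrap credible regions by refitting the model on resamples.

    Each iteration resamples the training rows with replacement, refits
    probit BART, predicts the fixed factual/counterfactual test design,
    and records the CATE (overall and per requested subgroup).  Point
    estimate = mean of bootstrap CATEs; credible region = (2.5, 97.5)
    percentiles.  ``n_boot = 1`` degenerates to a single fit with a
    zero-width region.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n_train = len(train_X)
    y = np.asarray(train_y)
    masks = dict(subgroup_masks or {})
    for label, m in masks.items():
        if not np.asarray(m).any():
            raise ValueError(f"empty subgroup {label!r}")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_boot + 1)
    resample_rng = np.random.default_rng(child_seeds[0])
    labels = ["overall"] + list(masks)
    boot_cates: dict[str, list[float]] = {lab: [] for lab in labels}
    theta_sum = np.zeros(len(design.factual))
    Xt = train_X.to_numpy(dtype=float)
    cols = list(train_X.columns)
    for b in range(n_boot):
        idx = resample_rng.integers(0, n_train, size=n_train)
        if len(np.unique(y[idx])) < 2:
            idx = np.arange(n_train)      # degenerate resample: keep original
        cfg_b = BartConfig(**{**bart_config.__dict__,
                              "seed": _derive_seed(child_seeds[b + 1]),
                              "keep_states": False})
        post = fit_probit_bart(
            pd.DataFrame(Xt[idx], columns=cols), y[idx], cfg_b,
            tracked={"factual": design.factual,
                     "counterfactual": design.counterfactual})
        est = estimate_cate_from_draws(
            post.tracked_draws["factual"],
            post.tracked_draws["counterfactual"],
            treated_is_factual=treated_is_factual)
        theta_sum += est.theta
        boot_cates["overall"].append(est.cate)
        for label, m in masks.items():
            boot_cates[label].append(float(est.theta[np.asarray(m, bool)].mean()))
    theta_mean = theta_sum / n_boot
    out: dict[str, CateEstimate] = {}
    for label in labels:
        dist = np.asarray(boot_cates[label])
        lo, hi = np.percentile(dist, [2.5, 97.5])
        point = float(dist.mean())
        theta = theta_mean if label == "overall" \
            else theta_mean[np.asarray(masks[label], bool)]
        # the reported theta is the bootstrap-averaged ITE; its mean equals
        # the mean of bootstrap CATEs by exchange of summation order
        out[label] = CateEstimate(
            theta=theta, cate=point,
            ci_low=float(min(lo, point)), ci_high=float(max(hi, point)),
            subgroup=None if label == "overall" else label,
            child_ids=design.child_ids if label == "overall" else None,
            bootstrap_cates=dist)
    return out


# ---------------------------------------------------------------------------
# end-to-end analysis
# ---------------------------------------------------------------------------

CATEGORICAL_COVARIATES = ("relation_to_head", "breastfed", "religion",
                          "native_language", "region", "partition_area_id")


def build_design_matrix(children: Sequence[ChildRecord],
                        conflict_intensity: np.ndarray,
                        flood: np.ndarray | None = None,
                        drought: np.ndarray | None = None,
                        area_ids: Sequence[str] | None = None
                        ) -> pd.DataFrame:
    """Model matrix: ordinal treatment + encoded covariates + exposures.

    The treatment (education level) enters as a single ordered numeric
    column so trees can split the level axis anywhere; unordered
    categoricals are one-hot encoded.
    """
    frame = children_to_frame(children)
    if area_ids is not None:
        frame["partition_area_id"] = list(area_ids)
    X = pd.DataFrame(index=frame.index)
    X[TREATMENT_COLUMN] = frame["mother_education_years"].map(
        bin_education).astype(float)
    X["age_months"] = frame["age_months"].astype(float)
    X["sex_female"] = (frame["sex"] == "female").astype(float)
    X["mother_age_years"] = frame["mother_age_years"].astype(float)
    X["urban"] = frame["urban"].astype(float)
    X["iwi"] = frame["iwi"].astype(float)
    X["electricity"] = frame["electricity"].astype(float)
    X["sanitation_deprived"] = (~frame["sanitation_access"]).astype(float)
    X["survey_round_2013"] = (frame["survey_round"] == 2013).astype(float)
    X["conflict_intensity"] = np.asarray(conflict_intensity, dtype=float)
    if flood is not None:
        X["flood_runoff_max"] = np.asarray(flood, dtype=float)
    if drought is not None:
        X["drought_index_min"] = np.asarray(drought, dtype=float)
    for col in CATEGORICAL_COVARIATES:
        if col not in frame.columns or frame[col].isna().all():
            continue
        dummies = pd.get_dummies(frame[col].astype(str), prefix=col,
                                 dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return X


@dataclass
class AnalysisResult:
    """Everything `run_analysis` computes, ready for export."""

    cate_by_level: pd.DataFrame
    untreated: CateEstimate | None
    subgroups: pd.DataFrame
    ite: pd.DataFrame
    metrics: dict
    roc: pd.DataFrame
    config_echo: dict
    log_lines: list[str]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = lambda df, name: df.to_csv(out / name, index=False,
                                         float_format="%.10g")
        fmt(self.cate_by_level, "cate_by_level.csv")
        fmt(self.subgroups, "subgroup_cate.csv")
        fmt(self.ite, "ite.csv")
        fmt(self.roc, "roc.csv")
        if len(self.ite):
            summary = evaluation.summarize_ite(self.ite["theta"].to_numpy())
            fmt(pd.DataFrame({
                "bin_left": summary.bin_edges[:-1],
                "bin_right": summary.bin_edges[1:],
                "count": summary.counts}), "ite_hist.csv")
        with open(out / "metrics.json", "w", encoding="utf-8") as fh:
            import json
            json.dump(self.metrics, fh, indent=2, sort_keys=True)
        with open(out / "run_log.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.log_lines) + "\n")


def run_analysis(config: StudyConfig,
                 children: Sequence[ChildRecord],
                 events: Sequence[ConflictEvent],
                 reference: anthropometry.GrowthReference,
                 clusters: Sequence[SurveyCluster] | None = None,
                 series: Mapping[str, dict[str, spatial_exposures.MonthlySeries]]
                 | None = None,
                 grid_spec: spatial_exposures.GridSpec | None = None
                 ) -> AnalysisResult:
    """Execute the full pipeline on validated inputs.

    Stages: outcome construction -> exposure assignment -> treatment
    coding -> 70/30 split -> bootstrap CATE per education level (levels
    2-6 against a no-education counterfactual, plus the untreated
    analysis contrasting observed no-education with the 9-year policy
    level) -> conflict-exposure subgroup contrast -> classifier
    diagnostics on the held-out factual rows.  Deterministic for a fixed
    ``config.seed``.
    """
    log: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log.append(msg)

    # -- stage 1: outcomes ------------------------------------------------
    kept: list[ChildRecord] = []
    outcomes: list[int] = []
    n_excluded = 0
    for child in children:
        res = anthropometry.compute_indicators(child, reference)
        if res.severe_undernutrition is None:
            n_excluded += 1
            continue
        kept.append(child)
        outcomes.append(int(res.severe_undernutrition))
    if n_excluded:
        note(f"outcomes: excluded {n_excluded} unclassifiable children")
    note(f"outcomes: {len(kept)} children, "
         f"prevalence {np.mean(outcomes):.4f}")
    y = np.asarray(outcomes, dtype=np.int8)

    # -- stage 2: exposures ----------------------------------------------
    if grid_spec is None:
        lons = [c.location.lon for c in kept]
        lats = [c.location.lat for c in kept]
        grid_spec = spatial_exposures.GridSpec(
            lon_min=min(lons) - 0.5, lat_min=min(lats) - 0.5,
            lon_max=max(lons) + 0.5, lat_max=max(lats) + 0.5,
            cell_deg=config.grid_cell_deg)
    intensity = spatial_exposures.assign_intensities(
        kept, events, config.conflict_window_months, grid_spec,
        config.kernel_bandwidth_km)
    note(f"exposures: conflict intensity median {np.median(intensity):.3f}, "
         f"max {intensity.max():.3f}")
    flood = drought = None
    if series is not None:
        flood = np.array([spatial_exposures.window_extremum(
            series[c.cluster_id]["flood"], c.interview_month,
            config.conflict_window_months, "max") for c in kept])
        drought = np.array([spatial_exposures.window_extremum(
            series[c.cluster_id]["drought"], c.interview_month,
            config.conflict_window_months, "min") for c in kept])
    area_ids = None
    if clusters is not None:
        partition = spatial_exposures.build_partition(clusters)
        lookup = partition.cluster_to_area()
        area_ids = [lookup[c.cluster_id] for c in kept]
        note(f"partition: {len(partition.areas)} areas from "
             f"{len(clusters)} clusters")

    # -- stage 3: design matrix and split --------------------------------
    X = build_design_matrix(kept, intensity, flood, drought, area_ids)
    ss = np.random.SeedSequence(config.seed)
    split_seed, fit_seed, boot_seed = (_derive_seed(s) for s in ss.spawn(3))
    idx_train, idx_test = split_train_test(
        list(range(len(kept))), config.split_fraction_train, split_seed)
    note(f"split: {len(idx_train)} train / {len(idx_test)} test")
    X_train, X_test = X.iloc[idx_train], X.iloc[idx_test].reset_index(drop=True)
    y_train, y_test = y[idx_train], y[np.asarray(idx_test)]
    test_children = [kept[i] for i in idx_test]
    test_ids = [c.child_id for c in test_children]
    test_levels = X_test[TREATMENT_COLUMN].to_numpy()
    test_intensity = intensity[np.asarray(idx_test)]

    bart_cfg = BartConfig(num_trees=config.num_trees, burn_in=config.burn_in,
                          num_draws=config.num_draws, seed=fit_seed,
                          keep_states=False)

    # -- stage 4: reference fit for diagnostics --------------------------
    post = fit_probit_bart(X_train, y_train, bart_cfg,
                           tracked={"test": X_test})
    test_prob = posterior_mean_probability(post.tracked_draws["test"])
    if len(np.unique(y_test)) == 2:
        curve = evaluation.roc_auc(y_test, test_prob)
        metrics = {"auc": curve.auc, "cutoff": curve.cutoff,
                   "sensitivity": curve.sensitivity,
                   "specificity": curve.specificity}
        roc_df = pd.DataFrame({"threshold": curve.thresholds,
                               "fpr": curve.fpr, "tpr": curve.tpr})
        note(f"diagnostics: AUC {curve.auc:.3f}, cutoff {curve.cutoff:.3f}")
    else:
        metrics = {}
        roc_df = pd.DataFrame(columns=["threshold", "fpr", "tpr"])
        note("diagnostics: single-class test outcome, ROC skipped")

    # -- stage 5: bootstrap counterfactual analyses ----------------------
    design_cf1 = build_counterfactual_design(
        X_test, TreatmentSpec(counterfactual_level=1), test_ids)
    treated_mask = test_levels > 1
    subgroup_masks: dict[str, np.ndarray] = {}
    for lev in (2, 3, 4, 5, 6):
        m = test_levels == lev
        if m.any():
            subgroup_masks[f"level_{lev}"] = m
        else:
            note(f"cate: no test children at level {lev}; analysis skipped")
    for label, m in conflict_subgroup_masks(
            test_intensity, config.conflict_threshold).items():
        mm = m & treated_mask
        if mm.any():
            subgroup_masks[label] = mm
        else:
            note(f"cate: empty conflict subgroup {label}; skipped")
    results = bootstrap_cate(X_train, y_train, design_cf1, bart_cfg,
                             n_boot=config.n_bootstrap, seed=boot_seed,
                             treated_is_factual=True,
                             subgroup_masks=subgroup_masks)

    untreated = None
    level1_mask = test_levels == 1
    if level1_mask.any():
        design_cf4 = CounterfactualDesign(
            factual=X_test[level1_mask].reset_index(drop=True),
            counterfactual=X_test[level1_mask].reset_index(drop=True).assign(
                **{TREATMENT_COLUMN: float(POLICY_LEVEL)}),
            child_ids=[cid for cid, m in zip(test_ids, level1_mask) if m])
        untreated_res = bootstrap_cate(
            X_train, y_train, design_cf4, bart_cfg,
            n_boot=config.n_bootstrap, seed=boot_seed,
            treated_is_factual=False)   # counterfactual (policy) is treated
        untreated = untreated_res["overall"]
        note(f"untreated analysis: CATE {untreated.cate:+.4f} "
             f"[{untreated.ci_low:+.4f}, {untreated.ci_high:+.4f}]")
    else:
        note("untreated analysis skipped: no level-1 test children")

    rows = []
    for lev in (2, 3, 4, 5, 6):
        key = f"level_{lev}"
        if key not in results:
            continue
        est = results[key]
        rows.append({"level": lev, "delta_probability": est.cate,
                     "ci_2.5": est.ci_low, "ci_97.5": est.ci_high,
                     "n": est.n_children})
        note(f"cate level {lev}: {est.cate:+.4f} "
             f"[{est.ci_low:+.4f}, {est.ci_high:+.4f}] n={est.n_children}")
    cate_by_level = pd.DataFrame(rows)

    sub_rows = []
    for label in list(conflict_subgroup_masks(test_intensity,
                                              config.conflict_threshold)):
        if label in results:
            est = results[label]
            sub_rows.append({"subgroup": label,
                             "delta_probability": est.cate,
                             "ci_2.5": est.ci_low, "ci_97.5": est.ci_high,
                             "n": est.n_children})
    subgroups = pd.DataFrame(sub_rows)

    overall = results["overall"]
    ite = pd.DataFrame({"child_id": overall.child_ids,
                        "theta": overall.theta})

    config_echo = {"seed": config.seed, "num_trees": config.num_trees,
                   "burn_in": config.burn_in, "num_draws": config.num_draws,
                   "n_bootstrap": config.n_bootstrap,
                   "split_fraction_train": config.split_fraction_train,
                   "conflict_window_months": config.conflict_window_months,
                   "conflict_threshold": config.conflict_threshold}
    return AnalysisResult(cate_by_level=cate_by_level, untreated=untreated,
                          subgroups=subgroups, ite=ite, metrics=metrics,
                          roc=roc_df, config_echo=config_echo, log_lines=log)
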