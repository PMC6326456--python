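"""Synthetic survey populations with known causal ground truth.

The generator emulates the statistical structure of the study design —
two spatially clustered cross-sectional survey rounds, household wealth
confounding the mother's education, a probit outcome with an
education-level threshold effect, spatial Poisson conflict events, and
monthly environmental series — without reproducing any real data
source.

The binary outcome is generated first and the anthropometry realised
afterwards: for each child a set of target z-scores consistent with the
drawn outcome is sampled and converted to weight/height through the
inverse LMS transform, so the anthropometry stage reproduces the
generated outcome for every child by construction.  Ground truth
(per-child probit index without the education effect, plus the true
effect vector) is emitted separately and never consumed by the analysis
stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.special import ndtr

from maternut import anthropometry, spatial_exposures
from maternut.data_model_io import (ChildRecord, ConflictEvent, GeoPoint,
                                    SurveyCluster, month_index)
from maternut.spatial_exposures import GridSpec, MonthlySeries

#: probit-scale education effects per level; the threshold shape (material
#: protection only beyond the compulsory 9 years, levels 5-6) mirrors the
#: finding the pipeline is meant to recover
DEFAULT_DELTA = (0.0, -0.05, -0.07, -0.05, -0.12, -0.15)

RELIGIONS = ("christian", "muslim", "traditional")
LANGUAGES = ("hausa", "yoruba", "igbo", "other")
RELATIONS = ("child", "grandchild", "other")
BREASTFED = ("never", "ever", "current")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic population."""

    n_children: int = 4000
    n_clusters_per_round: int = 40
    lon_min: float = 3.0
    lat_min: float = 4.0
    lon_max: float = 14.0
    lat_max: float = 14.0
    #: wealth -> education confounding (logit slope on level choice)
    confound_wealth_education: float = 1.0
    #: wealth -> outcome (probit slope per wealth SD; negative = protective)
    confound_wealth_outcome: float = -0.35
    baseline_intercept: float = -1.0
    delta: tuple[float, ...] = DEFAULT_DELTA
    #: conflict events per month over the whole region
    event_rate_per_month: float = 12.0
    mean_deaths_per_event: float = 40.0
    #: probit shift per unit of assigned conflict intensity
    conflict_effect: float = 0.005
    grid_cell_deg: float = 0.1
    kernel_bandwidth_km: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children < self.n_clusters_per_round:
            raise ValueError("need n_children >= clusters per round")
        if len(self.delta) != 6 or self.delta[0] != 0.0:
            raise ValueError("delta must have 6 entries with delta[0] == 0")

    @property
    def grid_spec(self) -> GridSpec:
        return GridSpec(self.lon_min, self.lat_min, self.lon_max,
                        self.lat_max, self.grid_cell_deg)


@dataclass
class GroundTruth:
    """Per-child potential-outcome structure, for validation only."""

    child_ids: list[str]
    eta_base: np.ndarray          # probit index excluding the education term
    delta: np.ndarray             # education effects, levels 1..6
    observed_level: np.ndarray
    conflict_exposure: np.ndarray

    def prob_at_level(self, level: int) -> np.ndarray:
        return ndtr(self.eta_base + self.delta[level - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "child_id": self.child_ids,
            "eta_base": self.eta_base,
            "observed_level": self.observed_level,
            "conflict_exposure": self.conflict_exposure,
        })


def true_cate(truth: GroundTruth, contrast: tuple[int, int],
              mask: np.ndarray | None = None) -> float:
    """Exact CATE for (treated level, control level) over a subgroup."""
    level_t, level_c = contrast
    diff = truth.prob_at_level(level_t) - truth.prob_at_level(level_c)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty subgroup")
        diff = diff[mask]
    return float(diff.mean())


def generate_reference(seed: int = 0) -> anthropometry.GrowthReference:
    """Smooth synthetic LMS curves for the three indicators and both sexes.

    Median curves are monotone in the index; the weight-for-age median
    is defined as the weight-for-height median evaluated at the
    height-for-age median, so a child at the median of both height and
    weight-for-height is also exactly at the weight-for-age median.
    Coefficients of variation sit in [0.08, 0.15] and Box-Cox powers in
    [-1.5, 1.5].  Deterministic for a fixed seed (small sex-specific
    perturbations are drawn from it).
    """
    rng = np.random.default_rng(seed)
    rows = []
    ages = np.arange(0, 60, dtype=float)
    heights = np.arange(45.0, 121.0, 1.0)
    for sex in ("male", "female"):
        bump = 1.0 + 0.02 * rng.uniform(-1.0, 1.0)
        m_ha = 50.0 * bump + 60.0 * (ages / 59.0) ** 0.8

        def m_wh(h: np.ndarray) -> np.ndarray:
            return 3.3 * bump * (np.asarray(h) / (50.0 * bump)) ** 2.1

        m_wa = m_wh(m_ha)
        for age, M in zip(ages, m_ha):
            rows.append(("height_for_age", sex, age, 1.0, M, 0.08))
        for age, M in zip(ages, m_wa):
            rows.append(("weight_for_age", sex, age, 0.3, M, 0.12))
        for h, M in zip(heights, m_wh(heights)):
            rows.append(("weight_for_height", sex, h, 0.5, M, 0.11))
    table = pd.DataFrame(rows, columns=["indicator", "sex", "index_value",
                                        "L", "M", "S"])
    return anthropometry.GrowthReference(table)


def _education_years(levels: np.ndarray, rng: np.random.Generator
                     ) -> np.ndarray:
    years = np.zeros(len(levels), dtype=int)
    years[levels == 2] = rng.integers(1, 7, size=int((levels == 2).sum()))
    years[levels == 3] = rng.integers(7, 9, size=int((levels == 3).sum()))
    years[levels == 4] = 9
    years[levels == 5] = rng.integers(10, 13, size=int((levels == 5).sum()))
    years[levels == 6] = rng.integers(13, 19, size=int((levels == 6).sum()))
    return years


def _draw_levels(wealth_std: np.ndarray, strength: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Education level 1..6, probability shifting upward with wealth."""
    base = np.array([1.0, 0.9, 0.2, 0.3, 0.3, 0.0])
    slope = strength * np.array([-0.8, -0.3, 0.0, 0.2, 0.5, 0.9])
    logits = base[None, :] + wealth_std[:, None] * slope[None, :]
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(wealth_std))
    return 1 + (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def _realize_anthropometry(child: ChildRecord, y: int,
                           ref: anthropometry.GrowthReference,
                           rng: np.random.Generator) -> None:
    """Draw (height, weight) so the Bristol classifier reproduces ``y``."""
    sex, age = child.sex, float(child.age_months)
    for attempt in range(100):
        if attempt == 99:                       # deterministic fallback
            z_ha, z_wh = (-1.0, -3.5) if y == 1 else (0.0, 0.0)
        elif y == 1:
            if rng.random() < 0.5:
                z_ha = max(-5.5, -3.05 - rng.exponential(0.5))
                z_wh = float(np.clip(rng.normal(-1.0, 0.8), -2.7, 3.0))
            else:
                z_wh = max(-5.5, -3.05 - rng.exponential(0.5))
                z_ha = float(np.clip(rng.normal(-1.0, 0.8), -2.7, 3.0))
        else:
            z_ha = float(np.clip(rng.normal(-0.7, 1.0), -2.7, 3.5))
            z_wh = float(np.clip(rng.normal(-0.5, 1.0), -2.7, 3.5))
        L, M, S = anthropometry.interpolate_reference(
            ref, sex, "height_for_age", age)
        height = anthropometry.invert_lms(z_ha, L, M, S)
        lo, hi = ref.bounds(sex, "weight_for_height")
        if not lo <= height <= hi:
            continue
        L, M, S = anthropometry.interpolate_reference(
            ref, sex, "weight_for_height", height)
        weight = anthropometry.invert_lms(z_wh, L, M, S)
        child.height_cm = height
        child.weight_kg = weight
        result = anthropometry.compute_indicators(child, ref)
        if result.severe_undernutrition is not None \
                and int(result.severe_undernutrition) == y:
            return
    raise RuntimeError(
        f"could not realise anthropometry for child {child.child_id}")


def generate_population(cfg: SimulationConfig
                        ) -> tuple[list[ChildRecord], list[SurveyCluster],
                                   list[ConflictEvent],
                                   dict[str, dict[str, MonthlySeries]],
                                   GroundTruth]:
    """Draw a full synthetic study: children, clusters, events, series, truth."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    ref = generate_reference(cfg.seed)

    # conflict hotspots: a few persistent population centres (biased
    # towards the north-east of the region) around which both armed
    # violence and a share of survey clusters concentrate — conflict
    # happens where people live, and surveys sample them
    n_hotspots = 3
    hotspot_lon = rng.uniform(cfg.lon_min + 0.6 * (cfg.lon_max - cfg.lon_min),
                              cfg.lon_max, n_hotspots)
    hotspot_lat = rng.uniform(cfg.lat_min + 0.6 * (cfg.lat_max - cfg.lat_min),
                              cfg.lat_max, n_hotspots)

    # -- clusters: mostly uniform, ~15% near hotspot towns ----------------
    clusters: list[SurveyCluster] = []
    cluster_month: dict[str, int] = {}
    for survey_round in (2008, 2013):
        lo, hi = {2008: (month_index(2008, 6), month_index(2008, 11)),
                  2013: (month_index(2013, 2), month_index(2013, 7))}[survey_round]
        for i in range(cfg.n_clusters_per_round):
            cid = f"C{survey_round}_{i:03d}"
            if rng.random() < 0.15:
                h = int(rng.integers(n_hotspots))
                lon = float(np.clip(rng.normal(hotspot_lon[h], 0.1),
                                    cfg.lon_min, cfg.lon_max - 1e-6))
                lat = float(np.clip(rng.normal(hotspot_lat[h], 0.1),
                                    cfg.lat_min, cfg.lat_max - 1e-6))
            else:
                lon = float(rng.uniform(cfg.lon_min, cfg.lon_max))
                lat = float(rng.uniform(cfg.lat_min, cfg.lat_max))
            clusters.append(SurveyCluster(
                cluster_id=cid, survey_round=survey_round,
                location=GeoPoint(lon=lon, lat=lat),
                urban=bool(rng.random() < 0.4)))
            cluster_month[cid] = int(rng.integers(lo, hi + 1))

    # -- conflict events: clustered spatial Poisson process ---------------
    # the kernel-estimated surface then shows high-exposure cells near
    # hotspots and exact zeros far from them
    months = range(month_index(2007, 6), month_index(2013, 8))
    events: list[ConflictEvent] = []
    for m in months:
        for _ in range(rng.poisson(cfg.event_rate_per_month)):
            h = int(rng.integers(n_hotspots))
            events.append(ConflictEvent(
                location=GeoPoint(
                    lon=float(np.clip(rng.normal(hotspot_lon[h], 0.1),
                                      cfg.lon_min, cfg.lon_max - 1e-6)),
                    lat=float(np.clip(rng.normal(hotspot_lat[h], 0.1),
                                      cfg.lat_min, cfg.lat_max - 1e-6))),
                month=m,
                deaths=int(1 + rng.poisson(cfg.mean_deaths_per_event - 1.0))))

    # -- environmental series per cluster ---------------------------------
    series: dict[str, dict[str, MonthlySeries]] = {}
    month_arr = np.array(list(months))
    for c in clusters:
        seasonal = 2.0 + 1.5 * np.sin(2 * math.pi * (month_arr % 12) / 12.0)
        flood = np.maximum(0.0, seasonal + rng.gamma(2.0, 1.0, len(month_arr)))
        drought = np.clip(60.0 + 25.0 * np.sin(
            2 * math.pi * ((month_arr + 6) % 12) / 12.0)
            + rng.normal(0.0, 10.0, len(month_arr)), 0.0, 100.0)
        series[c.cluster_id] = {
            "flood": MonthlySeries(c.cluster_id, month_arr, flood),
            "drought": MonthlySeries(c.cluster_id, month_arr, drought)}

    # -- children: covariates, confounded education -----------------------
    n = cfg.n_children
    assigned = rng.integers(0, len(clusters), size=n)
    urban = np.array([clusters[i].urban for i in assigned])
    iwi = np.clip(100.0 * rng.beta(2.0, 3.0, n) + 12.0 * urban, 0.0, 100.0)
    wealth_std = (iwi - 50.0) / 25.0
    levels = _draw_levels(wealth_std, cfg.confound_wealth_education, rng)
    years = _education_years(levels, rng)
    age_months = rng.integers(0, 60, size=n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    sanitation = rng.random(n) < (0.45 + 0.35 * (wealth_std > 0))
    electricity = rng.random(n) < (0.3 + 0.4 * (wealth_std > 0))
    mother_age = rng.integers(16, 46, size=n)
    lon_mid = 0.5 * (cfg.lon_min + cfg.lon_max)
    lat_mid = 0.5 * (cfg.lat_min + cfg.lat_max)

    children: list[ChildRecord] = []
    for i in range(n):
        c = clusters[assigned[i]]
        region = ("north" if c.location.lat >= lat_mid else "south") + \
                 ("east" if c.location.lon >= lon_mid else "west")
        children.append(ChildRecord(
            child_id=f"K{i:06d}",
            cluster_id=c.cluster_id,
            survey_round=c.survey_round,
            interview_month=cluster_month[c.cluster_id],
            age_months=int(age_months[i]),
            sex=str(sex[i]),
            weight_kg=None, height_cm=None,       # realised below
            relation_to_head=RELATIONS[rng.integers(0, len(RELATIONS))],
            breastfed=BREASTFED[rng.integers(0, len(BREASTFED))],
            mother_age_years=int(mother_age[i]),
            religion=RELIGIONS[rng.integers(0, len(RELIGIONS))],
            native_language=LANGUAGES[rng.integers(0, len(LANGUAGES))],
            mother_education_years=int(years[i]),
            urban=bool(urban[i]),
            iwi=float(iwi[i]),
            electricity=bool(electricity[i]),
            sanitation_access=bool(sanitation[i]),
            region=region,
            location=c.location))

    # -- outcome model ----------------------------------------------------
    exposure = spatial_exposures.assign_intensities(
        children, events, 12, cfg.grid_spec, cfg.kernel_bandwidth_km)
    delta = np.asarray(cfg.delta)
    eta_base = (cfg.baseline_intercept
                + cfg.confound_wealth_outcome * wealth_std
                + 0.15 * (~sanitation)
                - 0.10 * urban
                + 0.08 * (age_months - 30.0) / 30.0
                + cfg.conflict_effect * exposure)
    eta = eta_base + delta[levels - 1]
    p = ndtr(eta)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("config produces degenerate outcome probabilities")
    y = (rng.random(n) < p).astype(np.int8)

    # -- anthropometry consistent with the outcome ------------------------
    for child, yi in zip(children, y):
        _realize_anthropometry(child, int(yi), ref, rng)

    truth = GroundTruth(
        child_ids=[c.child_id for c in children],
        eta_base=eta_base,
        delta=delta,
        observed_level=levels,
        conflict_exposure=exposure)
    return children, clusters, events, series, truth
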