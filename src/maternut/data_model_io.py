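"""Record schema shared by all pipeline stages, plus tabular/geospatial I/O.

Children, survey clusters and conflict events are plain dataclasses with
explicit validation; on disk they are RFC-4180 CSV (UTF-8, header row) or
GeoJSON FeatureCollections of Points.  Months are a single integer index
``year * 12 + (month - 1)`` so that retrospective-window arithmetic never
has to reason about year boundaries.  Missing values in CSV are the empty
string or ``"NA"``; in memory they are ``None``.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
import yaml

SCHEMA_VERSION = 1

#: interview-month ranges implied by each survey round (field-work windows
#: June-November 2008 and February-July 2013)
ROUND_MONTH_RANGES: dict[int, tuple[int, int]] = {
    2008: (2008 * 12 + 5, 2008 * 12 + 10),
    2013: (2013 * 12 + 1, 2013 * 12 + 6),
}

SEXES = ("male", "female")


def month_index(year: int, month: int) -> int:
    """Calendar month as a single integer, ``year*12 + (month-1)``."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return year * 12 + (month - 1)


def month_index_to_ym(idx: int) -> tuple[int, int]:
    """Inverse of :func:`month_index`; returns ``(year, month)``."""
    return idx // 12, idx % 12 + 1


@dataclass(frozen=True)
class GeoPoint:
    """WGS84 coordinate in decimal degrees."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon out of range: {self.lon}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat out of range: {self.lat}")


@dataclass
class ChildRecord:
    """One under-five child with mother/household covariates and location.

    Coordinates are cluster-level (survey releases displace them by up to
    20 km for anonymity); children inherit their cluster's displaced
    location.  ``weight_kg`` / ``height_cm`` may be ``None`` (missing),
    never 0.  ``partition_area_id`` is assigned downstream by the
    spatial-partition stage.
    """

    child_id: str
    cluster_id: str
    survey_round: int
    interview_month: int
    age_months: int
    sex: str
    weight_kg: float | None
    height_cm: float | None
    relation_to_head: str
    breastfed: str
    mother_age_years: int
    religion: str
    native_language: str
    mother_education_years: int
    urban: bool
    iwi: float
    electricity: bool
    sanitation_access: bool
    region: str
    location: GeoPoint
    partition_area_id: str | None = None


@dataclass(frozen=True)
class SurveyCluster:
    """Survey sampling cluster: one (displaced) location per round."""

    cluster_id: str
    survey_round: int
    location: GeoPoint
    urban: bool


@dataclass(frozen=True)
class ConflictEvent:
    """Georeferenced conflict event with best-estimate fatalities.

    The source dataset's 25-battle-death threshold applies at conflict
    level, not per event, and is therefore not re-applied here.
    """

    location: GeoPoint
    month: int
    deaths: int

    def __post_init__(self) -> None:
        if self.deaths < 0:
            raise ValueError(f"negative deaths: {self.deaths}")


@dataclass
class StudyConfig:
    """Run configuration: paths, column mappings and model hyperparameters."""

    schema_version: int = SCHEMA_VERSION
    children_path: str | None = None
    events_path: str | None = None
    reference_path: str | None = None
    column_mapping: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    # probit BART
    num_trees: int = 200
    burn_in: int = 1000
    num_draws: int = 1000
    # causal pipeline
    split_fraction_train: float = 0.7
    n_bootstrap: int = 1000
    # conflict exposure
    conflict_window_months: int = 12
    conflict_threshold: float = 10.0
    kernel_bandwidth_km: float = 30.0
    grid_cell_deg: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction_train < 1.0:
            raise ValueError("split_fraction_train must be in (0, 1)")
        for name in ("num_trees", "burn_in", "num_draws", "n_bootstrap",
                     "conflict_window_months"):
            value = getattr(self, name)
            if name != "burn_in" and value < 1:
                raise ValueError(f"{name} must be a positive integer")
            if name == "burn_in" and value < 0:
                raise ValueError("burn_in must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version {version}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(schema_version=version, **raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass(frozen=True)
class RejectedRow:
    row_index: int
    reason: str


@dataclass
class ReadResult:
    """Accepted records plus per-row rejection report.

    ``len(records) + len(rejected)`` always equals the raw row count.
    """

    records: list
    rejected: list[RejectedRow]


CHILD_COLUMNS = (
    "child_id", "cluster_id", "survey_round", "interview_month",
    "age_months", "sex", "weight_kg", "height_cm", "relation_to_head",
    "breastfed", "mother_age_years", "religion", "native_language",
    "mother_education_years", "urban", "iwi", "electricity",
    "sanitation_access", "region", "lon", "lat",
)

_MISSING_TOKENS = ("", "NA")


def _parse_optional_float(token: str) -> float | None:
    if token in _MISSING_TOKENS:
        return None
    return float(token)


def _parse_bool(token: str) -> bool:
    if token in ("1", "true", "True"):
        return True
    if token in ("0", "false", "False"):
        return False
    raise ValueError(f"not a boolean: {token!r}")


def _child_from_row(row: Mapping[str, str]) -> ChildRecord:
    """Parse and validate one CSV row; raises ValueError with a reason."""
    age = int(row["age_months"])
    if not 0 <= age <= 59:
        raise ValueError(f"age_months outside under-five range: {age}")
    sex = row["sex"]
    if sex not in SEXES:
        raise ValueError(f"unknown sex: {sex!r}")
    weight = _parse_optional_float(row["weight_kg"])
    if weight is not None and weight <= 0:
        raise ValueError("non-positive weight")
    height = _parse_optional_float(row["height_cm"])
    if height is not None and height <= 0:
        raise ValueError("non-positive height")
    survey_round = int(row["survey_round"])
    if survey_round not in ROUND_MONTH_RANGES:
        raise ValueError(f"unknown survey_round: {survey_round}")
    interview_month = int(row["interview_month"])
    lo, hi = ROUND_MONTH_RANGES[survey_round]
    if not lo <= interview_month <= hi:
        raise ValueError(
            f"interview_month {interview_month} outside round "
            f"{survey_round} field-work window [{lo}, {hi}]")
    education = int(row["mother_education_years"])
    if education < 0:
        raise ValueError(f"negative mother_education_years: {education}")
    iwi = float(row["iwi"])
    if not 0.0 <= iwi <= 100.0:
        raise ValueError(f"iwi outside [0, 100]: {iwi}")
    return ChildRecord(
        child_id=row["child_id"],
        cluster_id=row["cluster_id"],
        survey_round=survey_round,
        interview_month=interview_month,
        age_months=age,
        sex=sex,
        weight_kg=weight,
        height_cm=height,
        relation_to_head=row["relation_to_head"],
        breastfed=row["breastfed"],
        mother_age_years=int(row["mother_age_years"]),
        religion=row["religion"],
        native_language=row["native_language"],
        mother_education_years=education,
        urban=_parse_bool(row["urban"]),
        iwi=iwi,
        electricity=_parse_bool(row["electricity"]),
        sanitation_access=_parse_bool(row["sanitation_access"]),
        region=row["region"],
        location=GeoPoint(float(row["lon"]), float(row["lat"])),
    )


def read_children(path: str | Path,
                  config: StudyConfig | None = None) -> ReadResult:
    """Read child records from CSV, validating every row.

    ``config.column_mapping`` maps canonical column names to the names
    used in the file (``{"weight_kg": "wt"}`` reads column ``wt``).
    Rows violating an invariant are reported, not silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping = dict(config.column_mapping) if config is not None else {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"empty file: {path}")
        header = set(reader.fieldnames)
        missing = [c for c in CHILD_COLUMNS if mapping.get(c, c) not in header]
        if missing:
            raise ValueError(f"missing mapped columns: {missing}")
        records: list[ChildRecord] = []
        rejected: list[RejectedRow] = []
        for i, raw in enumerate(reader):
            row = {c: raw[mapping.get(c, c)] for c in CHILD_COLUMNS}
            try:
                records.append(_child_from_row(row))
            except (ValueError, KeyError) as exc:
                rejected.append(RejectedRow(row_index=i, reason=str(exc)))
    return ReadResult(records=records, rejected=rejected)


def write_children(records: Iterable[ChildRecord], path: str | Path) -> None:
    """Write child records as canonical CSV (round-trips with read_children)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CHILD_COLUMNS)
        for r in records:
            writer.writerow([
                r.child_id, r.cluster_id, r.survey_round, r.interview_month,
                r.age_months, r.sex,
                "" if r.weight_kg is None else repr(float(r.weight_kg)),
                "" if r.height_cm is None else repr(float(r.height_cm)),
                r.relation_to_head, r.breastfed, r.mother_age_years,
                r.religion, r.native_language, r.mother_education_years,
                int(r.urban), repr(float(r.iwi)), int(r.electricity),
                int(r.sanitation_access), r.region,
                repr(float(r.location.lon)), repr(float(r.location.lat)),
            ])


def _event_from_fields(lon: str | float, lat: str | float,
                       month: str | int, deaths: str | int) -> ConflictEvent:
    d = int(deaths)
    if d < 0:
        raise ValueError(f"negative deaths: {d}")
    return ConflictEvent(location=GeoPoint(float(lon), float(lat)),
                         month=int(month), deaths=d)


def read_events(path: str | Path) -> ReadResult:
    """Read conflict events from CSV (lon, lat, month, deaths) or GeoJSON.

    GeoJSON input must be a FeatureCollection of Points with ``month``
    and ``deaths`` properties.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".geojson", ".json"):
        return _read_events_geojson(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            # an entirely empty file carries zero events
            return ReadResult(records=[], rejected=[])
        required = {"lon", "lat", "month", "deaths"}
        if not required <= set(reader.fieldnames):
            raise ValueError(
                f"event file must have columns {sorted(required)}")
        records: list[ConflictEvent] = []
        rejected: list[RejectedRow] = []
        for i, row in enumerate(reader):
            try:
                records.append(_event_from_fields(
                    row["lon"], row["lat"], row["month"], row["deaths"]))
            except ValueError as exc:
                rejected.append(RejectedRow(row_index=i, reason=str(exc)))
    return ReadResult(records=records, rejected=rejected)


def _read_events_geojson(path: Path) -> ReadResult:
    with open(path, "r", encoding="utf-8") as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise ValueError("GeoJSON events must be a FeatureCollection")
    records: list[ConflictEvent] = []
    rejected: list[RejectedRow] = []
    for i, feature in enumerate(collection.get("features", [])):
        try:
            geom = feature["geometry"]
            if geom["type"] != "Point":
                raise ValueError(f"geometry type {geom['type']} is not Point")
            lon, lat = geom["coordinates"][:2]
            props = feature.get("properties", {})
            records.append(_event_from_fields(
                lon, lat, props["month"], props["deaths"]))
        except (ValueError, KeyError, TypeError) as exc:
            rejected.append(RejectedRow(row_index=i, reason=str(exc)))
    return ReadResult(records=records, rejected=rejected)


def write_events(events: Iterable[ConflictEvent], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lon", "lat", "month", "deaths"])
        for e in events:
            writer.writerow([repr(float(e.location.lon)),
                             repr(float(e.location.lat)), e.month, e.deaths])


def read_clusters_geojson(path: str | Path) -> list[SurveyCluster]:
    """Read survey clusters from a GeoJSON FeatureCollection of Points."""
    with open(path, "r", encoding="utf-8") as fh:
        collection = json.load(fh)
    clusters = []
    for feature in collection["features"]:
        lon, lat = feature["geometry"]["coordinates"][:2]
        props = feature["properties"]
        clusters.append(SurveyCluster(
            cluster_id=str(props["cluster_id"]),
            survey_round=int(props["survey_round"]),
            location=GeoPoint(float(lon), float(lat)),
            urban=bool(props["urban"])))
    return clusters


def write_clusters_geojson(clusters: Iterable[SurveyCluster],
                           path: str | Path) -> None:
    features = [{
        "type": "Feature",
        "geometry": {"type": "Point",
                     "coordinates": [c.location.lon, c.location.lat]},
        "properties": {"cluster_id": c.cluster_id,
                       "survey_round": c.survey_round,
                       "urban": c.urban},
    } for c in clusters]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


@dataclass
class ValidationReport:
    """Dataset-level audit: missingness, range violations, duplicates."""

    n_records: int
    missing_counts: dict[str, int]
    out_of_range_counts: dict[str, int]
    duplicate_child_ids: list[str]

    @property
    def passed(self) -> bool:
        return (not self.duplicate_child_ids
                and sum(self.out_of_range_counts.values()) == 0)


def validate_dataset(children: Sequence[ChildRecord]) -> ValidationReport:
    """Audit a record collection; report-only, raises nothing.

    Duplicate ``child_id`` is a hard violation because downstream
    counterfactual pairing keys on it.
    """
    missing = {"weight_kg": 0, "height_cm": 0}
    out_of_range = {"age_months": 0, "iwi": 0, "lon": 0, "lat": 0,
                    "interview_month": 0}
    seen: set[str] = set()
    duplicates: list[str] = []
    for r in children:
        if r.child_id in seen:
            duplicates.append(r.child_id)
        seen.add(r.child_id)
        if r.weight_kg is None or (isinstance(r.weight_kg, float)
                                   and math.isnan(r.weight_kg)):
            missing["weight_kg"] += 1
        if r.height_cm is None or (isinstance(r.height_cm, float)
                                   and math.isnan(r.height_cm)):
            missing["height_cm"] += 1
        if not 0 <= r.age_months <= 59:
            out_of_range["age_months"] += 1
        if not 0.0 <= r.iwi <= 100.0:
            out_of_range["iwi"] += 1
        if not -180.0 <= r.location.lon <= 180.0:
            out_of_range["lon"] += 1
        if not -90.0 <= r.location.lat <= 90.0:
            out_of_range["lat"] += 1
        lo, hi = ROUND_MONTH_RANGES.get(r.survey_round, (None, None))
        if lo is None or not lo <= r.interview_month <= hi:
            out_of_range["interview_month"] += 1
    return ValidationReport(
        n_records=len(children),
        missing_counts=missing,
        out_of_range_counts=out_of_range,
        duplicate_child_ids=duplicates,
    )


def children_to_frame(children: Sequence[ChildRecord]) -> pd.DataFrame:
    """Tabular view of a record collection (one row per child)."""
    rows: list[dict[str, Any]] = []
    for r in children:
        d = dataclasses.asdict(r)
        loc = d.pop("location")
        d["lon"] = loc["lon"]
        d["lat"] = loc["lat"]
        rows.append(d)
    return pd.DataFrame(rows)
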