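"""Shared fixtures: small synthetic study objects, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from maternut import synthetic_data
from maternut.data_model_io import ChildRecord, GeoPoint


@pytest.fixture(scope="session")
def reference():
    return synthetic_data.generate_reference(seed=0)


@pytest.fixture(scope="session")
def small_population():
    """One modest population shared across read-only tests."""
    cfg = synthetic_data.SimulationConfig(
        n_children=600, n_clusters_per_round=12, seed=42)
    return synthetic_data.generate_population(cfg)


@pytest.fixture()
def make_child():
    """Factory for a valid child record with overridable fields."""

    def _make(**kwargs) -> ChildRecord:
        defaults = dict(
            child_id="K000001", cluster_id="C2008_000", survey_round=2008,
            interview_month=2008 * 12 + 6, age_months=24, sex="female",
            weight_kg=10.0, height_cm=85.0, relation_to_head="child",
            breastfed="ever", mother_age_years=28, religion="christian",
            native_language="hausa", mother_education_years=6, urban=False,
            iwi=45.0, electricity=False, sanitation_access=True,
            region="southwest", location=GeoPoint(7.0, 9.0))
        defaults.update(kwargs)
        return ChildRecord(**defaults)

    return _make
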