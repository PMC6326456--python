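"""Conflict-intensity surfaces, partitioning, and window extrema."""

import itertools

import numpy as np
import pytest

from maternut import spatial_exposures as spx
from maternut.data_model_io import ConflictEvent, GeoPoint, SurveyCluster

SPEC = spx.GridSpec(lon_min=6.0, lat_min=8.0, lon_max=8.0, lat_max=10.0,
                    cell_deg=0.1)


def _event(lon, lat, month=24100, deaths=10):
    return ConflictEvent(GeoPoint(lon, lat), month, deaths)


class TestEstimateIntensity:
    def test_no_events_in_window_gives_zero_grid(self):
        grid = spx.estimate_intensity([_event(7.0, 9.0, month=24000)],
                                      ref_month=24101, spec=SPEC)
        assert np.all(grid.values == 0.0)

    def test_mass_conservation_single_event(self):
        grid = spx.estimate_intensity([_event(7.0, 9.0, deaths=40)],
                                      ref_month=24101, spec=SPEC)
        assert grid.values.sum() == pytest.approx(40.0, rel=0.01)

    def test_mass_conservation_random_event_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            events = [_event(float(rng.uniform(6.2, 7.8)),
                             float(rng.uniform(8.2, 9.8)),
                             month=int(24090 + rng.integers(12)),
                             deaths=int(rng.integers(1, 100)))
                      for _ in range(rng.integers(1, 15))]
            total = sum(e.deaths for e in events)
            grid = spx.estimate_intensity(events, ref_month=24102, spec=SPEC)
            assert abs(grid.values.sum() - total) / max(1, total) <= 0.01

    def test_mirror_symmetry(self):
        # two equal events mirror-symmetric about the vertical midline
        events = [_event(6.5, 9.0, deaths=10), _event(7.5, 9.0, deaths=10)]
        grid = spx.estimate_intensity(events, ref_month=24101, spec=SPEC)
        assert np.allclose(grid.values, grid.values[:, ::-1], atol=1e-9)

    def test_monotone_in_added_events(self):
        base = [_event(7.0, 9.0, deaths=10)]
        g1 = spx.estimate_intensity(base, ref_month=24101, spec=SPEC)
        g2 = spx.estimate_intensity(base + [_event(6.5, 8.5, deaths=5)],
                                    ref_month=24101, spec=SPEC)
        # adding an event cannot decrease any cell beyond numerical noise
        assert np.all(g2.values >= g1.values - 1e-9)

    def test_longitude_translation_equivariance(self):
        events = [_event(7.0, 9.0, deaths=25), _event(6.4, 9.6, deaths=5)]
        shift = 0.7
        spec2 = spx.GridSpec(SPEC.lon_min + shift, SPEC.lat_min,
                             SPEC.lon_max + shift, SPEC.lat_max,
                             SPEC.cell_deg)
        shifted = [_event(e.location.lon + shift, e.location.lat,
                          e.month, e.deaths) for e in events]
        g1 = spx.estimate_intensity(events, 24101, spec=SPEC)
        g2 = spx.estimate_intensity(shifted, 24101, spec=spec2)
        assert np.allclose(g1.values, g2.values, atol=1e-9)

    def test_empty_grid_spec_rejected(self):
        with pytest.raises(ValueError):
            spx.GridSpec(1.0, 1.0, 1.0, 2.0)


class TestLookupIntensity:
    def test_cell_center(self):
        grid = spx.estimate_intensity([_event(7.05, 9.05, deaths=40)],
                                      ref_month=24101, spec=SPEC)
        v = spx.lookup_intensity(grid, GeoPoint(7.05, 9.05))
        assert v == grid.values.max()

    def test_half_open_boundary_goes_east_north(self):
        grid = spx.estimate_intensity([_event(7.0, 9.0, deaths=40)],
                                      ref_month=24101, spec=SPEC)
        # a point exactly on an interior boundary belongs to the cell
        # on its east/north side
        v = spx.lookup_intensity(grid, GeoPoint(6.1, 8.1))
        ix = round((6.1 - SPEC.lon_min) / SPEC.cell_deg)
        iy = round((8.1 - SPEC.lat_min) / SPEC.cell_deg)
        assert v == grid.values[iy, ix]

    def test_outside_box_raises(self):
        grid = spx.estimate_intensity([], ref_month=24101, spec=SPEC)
        with pytest.raises(ValueError):
            spx.lookup_intensity(grid, GeoPoint(20.0, 9.0))


class TestAssignChildIntensity:
    def test_window_excludes_thirteenth_month(self, make_child):
        child = make_child()
        t = child.interview_month
        far = [_event(7.0, 9.0, month=t - 13, deaths=30)]
        near = [_event(7.0, 9.0, month=t - 1, deaths=30)]
        assert spx.assign_child_intensity(child, far, spec=SPEC) == 0.0
        assert spx.assign_child_intensity(child, near, spec=SPEC) > 0.0

    def test_degenerate_one_cell_grid_mass(self, make_child):
        child = make_child()
        one_cell = spx.GridSpec(6.95, 8.95, 7.05, 9.05, cell_deg=0.1)
        v = spx.assign_child_intensity(
            child, [_event(7.0, 9.0, month=child.interview_month - 1,
                           deaths=30)], spec=one_cell)
        assert v == pytest.approx(30.0, rel=0.01)

    def test_no_events_gives_zero(self, make_child):
        assert spx.assign_child_intensity(make_child(), [], spec=SPEC) == 0.0


class TestWindowExtremum:
    def test_single_value_both_modes(self):
        s = spx.MonthlySeries("c", [24100], [4.2])
        assert spx.window_extremum(s, 24101, mode="max") == 4.2
        assert spx.window_extremum(s, 24101, mode="min") == 4.2

    def test_max_and_min(self):
        s = spx.MonthlySeries("c", [24098, 24099, 24100], [1.0, 5.0, 3.0])
        assert spx.window_extremum(s, 24101, mode="max") == 5.0
        assert spx.window_extremum(s, 24101, mode="min") == 1.0

    def test_missing_months_skipped_and_empty_raises(self):
        s = spx.MonthlySeries("c", [24099, 24100], [np.nan, 2.0])
        assert spx.window_extremum(s, 24101, mode="min") == 2.0
        empty = spx.MonthlySeries("c", [24100], [np.nan])
        with pytest.raises(ValueError):
            spx.window_extremum(empty, 24101)

    def test_window_is_strictly_before_ref_month(self):
        s = spx.MonthlySeries("c", [24100, 24101], [1.0, 99.0])
        # the reference month itself is excluded
        assert spx.window_extremum(s, 24101, mode="max") == 1.0


def _cluster(cid, rnd, lon, lat):
    return SurveyCluster(cid, rnd, GeoPoint(lon, lat), urban=False)


def _brute_force_max_areas(clusters, adjacency):
    """Exhaustive search over contiguous feasible partitions (<= 8 seeds)."""
    n = len(clusters)
    best = 0

    def contiguous(group):
        group = list(group)
        seen = {group[0]}
        stack = [group[0]]
        while stack:
            i = stack.pop()
            for j in adjacency[i]:
                if j in group and j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == len(group)

    def feasible(group):
        return len({clusters[i].survey_round for i in group}) >= 2

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for sub in partitions(rest):
            for k in range(len(sub)):
                yield sub[:k] + [sub[k] + [first]] + sub[k + 1:]
            yield [[first]] + sub

    for part in partitions(list(range(n))):
        if all(contiguous(g) and feasible(g) for g in part):
            best = max(best, len(part))
    return best


class TestBuildPartition:
    def test_two_clusters_one_area(self):
        clusters = [_cluster("a", 2008, 7.0, 9.0),
                    _cluster("b", 2013, 7.5, 9.5)]
        part = spx.build_partition(clusters)
        assert len(part.areas) == 1
        assert sorted(part.areas[0].cluster_ids) == ["a", "b"]

    def test_two_separated_pairs_give_two_areas(self):
        clusters = [_cluster("a", 2008, 1.0, 1.0),
                    _cluster("b", 2013, 1.2, 1.2),
                    _cluster("c", 2008, 9.0, 9.0),
                    _cluster("d", 2013, 9.2, 9.2)]
        part = spx.build_partition(clusters)
        assert len(part.areas) == 2
        areas = {frozenset(a.cluster_ids) for a in part.areas}
        assert areas == {frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_single_round_infeasible(self):
        clusters = [_cluster(f"c{i}", 2008, 1.0 + i, 1.0) for i in range(5)]
        with pytest.raises(ValueError, match="infeasible"):
            spx.build_partition(clusters)

    def test_every_cluster_in_exactly_one_area(self, small_population):
        _, clusters, _, _, _ = small_population
        part = spx.build_partition(clusters)
        assignment = part.cluster_to_area()
        assert set(assignment) == {c.cluster_id for c in clusters}
        sizes = sum(len(a.cluster_ids) for a in part.areas)
        assert sizes == len(clusters)

    def test_feasibility_on_random_instances(self):
        rng = np.random.default_rng(11)
        for trial in range(200):
            n = int(rng.integers(2, 13))
            rounds = rng.choice([2008, 2013], size=n)
            if len(set(rounds.tolist())) < 2:
                continue
            clusters = [_cluster(f"c{i}", int(rounds[i]),
                                 float(rng.uniform(0, 10)),
                                 float(rng.uniform(0, 10)))
                        for i in range(n)]
            part = spx.build_partition(clusters)
            for area in part.areas:
                area_rounds = {c.survey_round for c in clusters
                               if c.cluster_id in area.cluster_ids}
                assert area_rounds == {2008, 2013}
            assert 1 <= len(part.areas) <= n

    def test_area_count_matches_exhaustive_search_small(self):
        rng = np.random.default_rng(23)
        checked = 0
        for trial in range(40):
            n = int(rng.integers(2, 9))
            rounds = rng.choice([2008, 2013], size=n)
            if len(set(rounds.tolist())) < 2:
                continue
            clusters = [_cluster(f"c{i}", int(rounds[i]),
                                 float(rng.uniform(0, 10)),
                                 float(rng.uniform(0, 10)))
                        for i in range(n)]
            points = np.array([[c.location.lon, c.location.lat]
                               for c in clusters])
            from shapely.geometry import box
            boundary = box(points[:, 0].min() - 0.5, points[:, 1].min() - 0.5,
                           points[:, 0].max() + 0.5, points[:, 1].max() + 0.5)
            _, adjacency = spx._voronoi_cells(points, boundary)
            optimum = _brute_force_max_areas(clusters, adjacency)
            part = spx.build_partition(clusters)
            assert len(part.areas) == optimum, \
                f"trial {trial}: greedy {len(part.areas)} vs opt {optimum}"
            checked += 1
        assert checked >= 20

    def test_geojson_export(self, tmp_path):
        clusters = [_cluster("a", 2008, 7.0, 9.0),
                    _cluster("b", 2013, 7.5, 9.5)]
        part = spx.build_partition(clusters)
        path = tmp_path / "partition.geojson"
        part.to_geojson(path)
        import json
        data = json.loads(path.read_text())
        assert data["type"] == "FeatureCollection"
        assert data["features"][0]["properties"]["cluster_ids"] == ["a", "b"]


def test_grid_long_csv_export(tmp_path):
    grid = spx.estimate_intensity([_event(7.0, 9.0, deaths=10)],
                                  ref_month=24101, spec=SPEC)
    path = tmp_path / "grid.csv"
    grid.to_long_csv(path)
    import pandas as pd
    df = pd.read_csv(path)
    assert len(df) == grid.values.size
    assert df["value"].sum() == pytest.approx(grid.values.sum())
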