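import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaxfootprint import (LastMileResult, SimulationParams, Tour, lastmile_emissions,
                          make_clusters, road_distance, simulate_month, tour_duration,
                          tsp_tour)
from vaxfootprint.errors import ConfigError, DomainError
from conftest import make_small_model


class TestRoadDistance:
    def test_coincident_points(self):
        assert road_distance((1.0, 2.0), (1.0, 2.0)) == 0.0

    def test_three_four_five(self):
        assert road_distance((0, 0), (3, 4), 1.3) == pytest.approx(6.5)

    def test_identity_factor_is_euclidean(self):
        assert road_distance((0, 0), (3, 4), 1.0) == pytest.approx(5.0)

    def test_factor_below_one_rejected(self):
        with pytest.raises(DomainError):
            road_distance((0, 0), (1, 1), 0.9)


class TestMakeClusters:
    def test_small_group_is_one_cluster(self, rng):
        pts = rng.uniform(0, 10, (20, 2))
        arcs = make_clusters((5, 5), pts)
        assert len(arcs) == 1 and len(arcs[0]) == 20

    def test_balanced_split_31(self, rng):
        pts = rng.uniform(0, 10, (31, 2))
        arcs = make_clusters((5, 5), pts, 15, 30)
        assert sorted(len(a) for a in arcs) == [15, 16]

    def test_empty_input(self):
        assert make_clusters((0, 0), np.empty((0, 2))) == []

    @pytest.mark.parametrize("n", [1, 14, 16, 29, 30, 31, 45, 59, 61, 100, 153])
    def test_partition_and_size_bounds(self, n, rng):
        pts = rng.uniform(0, 100, (n, 2))
        arcs = make_clusters((50, 50), pts, 15, 30)
        idx = np.sort(np.concatenate(arcs))
        np.testing.assert_array_equal(idx, np.arange(n))  # exact partition
        sizes = [len(a) for a in arcs]
        for s in sizes[:-1]:
            assert 15 <= s <= 30
        assert sizes[-1] <= 30 + 15 // 2  # remainder may merge into its neighbour

    def test_clusters_are_angularly_contiguous(self, rng):
        hub = np.array([50.0, 50.0])
        pts = rng.uniform(0, 100, (90, 2))
        arcs = make_clusters(hub, pts, 15, 30)
        ang = np.arctan2(*(pts - hub).T[::-1])
        spans = sorted((ang[a].min(), ang[a].max()) for a in arcs)
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            assert hi1 <= lo2 + 1e-9  # consecutive arcs do not interleave


class TestTspTour:
    def test_no_stops(self):
        tour = tsp_tour((0, 0), np.empty((0, 2)))
        assert tour.road_distance == 0.0 and tour.n_stops == 0

    @pytest.mark.parametrize("method", ["nearest_neighbour", "two_opt", "brute_force"])
    def test_unit_square_optimum(self, method):
        stops = np.array([[0, 1], [1, 1], [1, 0]])
        tour = tsp_tour((0, 0), stops, method=method, road_factor=1.0)
        assert tour.road_distance == pytest.approx(4.0)

    def test_brute_force_refuses_large_instances(self, rng):
        with pytest.raises(DomainError):
            tsp_tour((0, 0), rng.uniform(0, 1, (10, 2)), method="brute_force")

    def test_heuristics_bracket_the_optimum(self, rng):
        for _ in range(20):
            stops = rng.uniform(0, 100, (7, 2))
            opt = tsp_tour((0, 0), stops, "brute_force").road_distance
            nn = tsp_tour((0, 0), stops, "nearest_neighbour").road_distance
            two = tsp_tour((0, 0), stops, "two_opt").road_distance
            assert opt <= two + 1e-9 <= nn + 1e-9

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=1, max_size=12))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_tour_visits_every_stop_once_and_closes(self, coords):
        stops = np.array(coords)
        tour = tsp_tour((50, 50), stops)
        assert sorted(tour.order) == list(range(len(stops)))
        np.testing.assert_array_equal(tour.stops[0], tour.stops[-1])
        np.testing.assert_array_equal(tour.stops[0], [50, 50])


class TestTourDuration:
    def _tour(self, km, stops=0):
        pts = np.zeros((stops + 2, 2))
        return Tour(pts, np.arange(stops), km)

    def test_pure_driving(self):
        assert tour_duration(self._tour(224.0), 60.0, 0.0, 0.0) == pytest.approx(224.0)

    def test_stops_and_fixed_only(self):
        assert tour_duration(self._tour(0.0, stops=8), 40.0, 10.0, 30.0) == pytest.approx(110.0)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(DomainError):
            tour_duration(self._tour(10.0), 0.0, 10.0, 0.0)

    def test_reference_model_tour_is_425_km(self):
        network_leg = road_distance((0.0, 0.0), (75.0, 0.0)) * 2  # two-way 2 x 75 km
        assert network_leg == pytest.approx(195.0)
        assert network_leg + 224.0 + 6.0 == pytest.approx(425.0)


class TestSimulateMonth:
    def test_deterministic_per_seed(self):
        m1 = make_small_model()
        m2 = make_small_model()
        r1 = simulate_month(m1, seed=9)
        r2 = simulate_month(m2, seed=9)
        s1, s2 = r1.summary(), r2.summary()
        assert s1 == s2
        assert r1.tours.equals(r2.tours)

    def test_zero_deliveries_zero_distance(self, small_model):
        r = simulate_month(small_model, SimulationParams(deliveries_per_month=0))
        assert r.total_km == 0.0
        assert r.cluster_tours == 0 and r.gp_tours == 0

    def test_unlabelled_model_rejected(self):
        m = make_small_model(labelled=False)
        with pytest.raises(ConfigError):
            simulate_month(m)

    def test_coordinate_scaling_homogeneity(self, small_model):
        base = simulate_month(small_model, seed=0)
        doubled = small_model.scaled(2.0)
        doubled.wholesalers = small_model.wholesalers
        doubled.wholesaler_names = small_model.wholesaler_names
        doubled.gp_pharmacy = None
        scaled = simulate_month(doubled, seed=0)
        for attr in ("network_km", "cluster_km", "gp_km", "total_km"):
            assert getattr(scaled, attr) == pytest.approx(2 * getattr(base, attr), rel=1e-9)

    def test_clusters_partition_pharmacies(self, small_model):
        r = simulate_month(small_model, seed=0)
        cluster_rows = r.tours[r.tours["tier"] == "cluster"]
        assert cluster_rows["n_stops"].sum() == len(small_model.pharmacies)
        gp_rows = r.tours[r.tours["tier"] == "gp"]
        assert gp_rows["n_stops"].sum() == len(small_model.gp_practices)


class TestEmissions:
    #: Reference monthly metrics: tier distances of a dedicated-tour month,
    #: 42 t of payload carried ~849 km as additional load, 1.05 M vials.
    REFERENCE = LastMileResult(
        network_km=111_451.0, cluster_km=756_662.0, gp_km=366_600.0,
        deliveries_per_month=4, vials_per_month=1_050_000,
        loading_mass_kg=42_000.0, representative_km=849.0,
    )

    def test_most_likely_additional_load(self):
        total, per_vial = lastmile_emissions(self.REFERENCE, "most_likely")
        assert total == pytest.approx(3566, abs=1)
        assert per_vial == pytest.approx(0.0034, abs=1e-4)

    def test_worst_case_dedicated_tours(self):
        total, per_vial = lastmile_emissions(self.REFERENCE, "worst_case")
        assert total == pytest.approx(370_414, abs=1)
        assert per_vial == pytest.approx(0.353, abs=1e-3)

    def test_zero_distance_zero_emissions(self):
        empty = dataclasses.replace(self.REFERENCE, network_km=0.0, cluster_km=0.0,
                                    gp_km=0.0, representative_km=0.0)
        assert lastmile_emissions(empty, "most_likely")[0] == 0.0
        assert lastmile_emissions(empty, "worst_case")[0] == 0.0

    def test_zero_vials_rejected(self):
        bad = dataclasses.replace(self.REFERENCE, vials_per_month=0)
        with pytest.raises(DomainError):
            lastmile_emissions(bad, "most_likely")
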