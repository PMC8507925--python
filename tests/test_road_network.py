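"""Road graph construction, service snapping and travel-time fields."""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from careshed.io import CRSError
from careshed.road_network import (
    ServicePoint,
    load_network,
    nearest_node,
    point_travel_time,
    snap_service,
    travel_times_to_nearest_service,
)

from conftest import (
    path_network,
    random_geometric_network,
    snapped_services_at,
    write_lines_geojson,
)


class TestLoadNetwork:
    def test_single_line_travel_time(self, tmp_path):
        p = write_lines_geojson(tmp_path / "net.geojson",
                                [([(0, 0), (1000, 0)], {"speed": 60})])
        net = load_network(p)
        assert len(net.edges) == 1
        assert net.edges[0].travel_time == pytest.approx(1.0, rel=1e-9)

    def test_empty_file_is_an_error(self, tmp_path):
        p = write_lines_geojson(tmp_path / "net.geojson", [])
        with pytest.raises(ValueError, match="no edges"):
            load_network(p)

    def test_shared_endpoint_deduplicates_nodes(self, tmp_path):
        p = write_lines_geojson(
            tmp_path / "net.geojson",
            [([(0, 0), (1000, 0)], {"speed": 50}),
             ([(1000 + 5e-7, 0), (2000, 0)], {"speed": 50})],
        )
        net = load_network(p)
        assert len(net.nodes) == 3
        assert len(net.edges) == 2

    def test_geographic_crs_rejected(self, tmp_path):
        p = write_lines_geojson(tmp_path / "net.geojson",
                                [([(0, 0), (1, 1)], {"speed": 60})],
                                crs_tag="EPSG:4326")
        with pytest.raises(CRSError, match="geographic"):
            load_network(p)

    def test_degree_range_without_crs_rejected(self, tmp_path):
        import json
        doc = {"type": "FeatureCollection", "features": [
            {"type": "Feature",
             "geometry": {"type": "LineString", "coordinates": [[-8.5, 52.1], [-8.4, 52.2]]},
             "properties": {"speed": 60}}]}
        p = tmp_path / "net.geojson"
        p.write_text(json.dumps(doc))
        with pytest.raises(CRSError, match="degree"):
            load_network(p)

    def test_bad_speed_dropped_and_default_applied(self, tmp_path, caplog):
        p = write_lines_geojson(
            tmp_path / "net.geojson",
            [([(0, 0), (1000, 0)], {"speed": -5}),
             ([(0, 0), (0, 1000)], {}),
             ([(0, 0), (2000, 0)], {"speed": 80})],
        )
        with caplog.at_level("WARNING"):
            net = load_network(p, default_speed=50.0)
        assert len(net.edges) == 2
        assert {e.speed for e in net.edges} == {50.0, 80.0}
        assert any("default" in r.message for r in caplog.records)


class TestSnapService:
    def test_on_node_snaps_with_zero_distance(self):
        net = path_network()
        s = snap_service(net, ServicePoint("s", 0.0, 0.0))
        assert s.snapped_node == "a"
        assert s.snap_distance == 0.0

    def test_equidistant_tie_breaks_to_smallest_id(self):
        net = path_network()  # a at x=0, b at x=1000
        s = snap_service(net, ServicePoint("s", 500.0, 0.0))
        assert s.snapped_node == "a"

    def test_beyond_tolerance_is_an_error_naming_the_service(self):
        net = path_network()
        with pytest.raises(ValueError, match="hospice-1"):
            snap_service(net, ServicePoint("hospice-1", 10_000.0, 10_000.0),
                         tolerance=1000.0)


class TestTravelTimes:
    def test_chain_closed_form(self):
        net = path_network()  # 1 km edges at 60 km/h: 1 min each
        field = travel_times_to_nearest_service(net, snapped_services_at(net, ["a"]))
        assert field == pytest.approx({"a": 0.0, "b": 1.0, "c": 2.0})

    def test_services_everywhere_give_zero_field(self):
        net = path_network(5)
        field = travel_times_to_nearest_service(
            net, snapped_services_at(net, list(net.nodes)))
        assert all(t == 0.0 for t in field.values())

    def test_no_services_is_an_error(self):
        net = path_network()
        with pytest.raises(ValueError, match="snapped"):
            travel_times_to_nearest_service(net, [])

    def test_oneway_respects_direction_of_travel(self):
        # a -> b -> c one-way; patients drive toward the service at a.
        # From b or c there is no way back against the arrows.
        net = path_network(oneway=True)
        field = travel_times_to_nearest_service(net, snapped_services_at(net, ["a"]))
        assert field == {"a": 0.0}
        # service at c: everyone can flow downstream to it
        field_c = travel_times_to_nearest_service(net, snapped_services_at(net, ["c"]))
        assert field_c == pytest.approx({"c": 0.0, "b": 1.0, "a": 2.0})

    def test_matches_per_service_sparse_dijkstra_oracle(self):
        """Multi-source field equals the min over independent single-source runs."""
        net = random_geometric_network(n=50, seed=17)
        service_nodes = ["r03", "r21", "r42"]
        field = travel_times_to_nearest_service(
            net, snapped_services_at(net, service_nodes))
        ids = sorted(net.nodes)
        index = {nid: i for i, nid in enumerate(ids)}
        rows, cols, data = [], [], []
        for e in net.edges:
            rows += [index[e.u], index[e.v]]
            cols += [index[e.v], index[e.u]]
            data += [e.travel_time, e.travel_time]
        m = coo_matrix((data, (rows, cols)), shape=(len(ids),) * 2).tocsr()
        expected = np.min(
            [dijkstra(m, indices=index[s]) for s in service_nodes], axis=0)
        for nid, i in index.items():
            if np.isfinite(expected[i]):
                assert field[nid] == pytest.approx(expected[i], rel=1e-9)
            else:
                assert nid not in field

    def test_adding_services_never_increases_times(self):
        net = random_geometric_network(n=50, seed=17)
        f1 = travel_times_to_nearest_service(net, snapped_services_at(net, ["r03"]))
        f3 = travel_times_to_nearest_service(
            net, snapped_services_at(net, ["r03", "r21", "r42"]))
        for nid, t in f1.items():
            assert f3[nid] <= t + 1e-12

    def test_two_way_field_invariant_to_edge_orientation(self):
        from careshed.road_network import RoadEdge, RoadNetwork

        net = random_geometric_network(n=30, seed=5)
        flipped = RoadNetwork(
            dict(net.nodes),
            [RoadEdge(e.v, e.u, e.length, e.speed, False, e.geometry) for e in net.edges],
        )
        f = travel_times_to_nearest_service(net, snapped_services_at(net, ["r01"]))
        g = travel_times_to_nearest_service(flipped, snapped_services_at(flipped, ["r01"]))
        assert f.keys() == g.keys()
        for nid in f:
            assert f[nid] == pytest.approx(g[nid], rel=1e-12)

    def test_edge_consistency_and_zero_only_at_services(self):
        net = random_geometric_network(n=50, seed=17)
        services = ["r03", "r21", "r42"]
        field = travel_times_to_nearest_service(net, snapped_services_at(net, services))
        for e in net.edges:
            if e.u in field and e.v in field:
                assert abs(field[e.u] - field[e.v]) <= e.travel_time + 1e-9
        for nid, t in field.items():
            assert t >= 0
            assert (t == 0) == (nid in services)


class TestPointTravelTime:
    def test_point_on_service_node_is_zero(self):
        net = path_network()
        field = travel_times_to_nearest_service(net, snapped_services_at(net, ["a"]))
        assert point_travel_time(net, field, 0.0, 0.0) == 0.0

    def test_point_nearest_unreachable_node_is_none(self):
        from careshed.road_network import RoadNode, RoadNetwork, RoadEdge
        from shapely.geometry import LineString

        nodes = {
            "a": RoadNode("a", 0, 0), "b": RoadNode("b", 1000, 0),
            "z": RoadNode("z", 50_000, 0),  # isolated
        }
        edges = [RoadEdge("a", "b", 1000, 60, False, LineString([(0, 0), (1000, 0)]))]
        net = RoadNetwork(nodes, edges)
        field = travel_times_to_nearest_service(net, snapped_services_at(net, ["a"]))
        assert point_travel_time(net, field, 49_000.0, 0.0) is None

    def test_random_points_match_exhaustive_scan(self):
        net = random_geometric_network(n=50, seed=17)
        field = travel_times_to_nearest_service(
            net, snapped_services_at(net, ["r03", "r21", "r42"]))
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 10_000, size=(100, 2))
        for x, y in pts:
            # oracle: exhaustive nearest node with smallest-id tie-break
            best = min(
                net.nodes.values(),
                key=lambda n: (np.hypot(n.x - x, n.y - y), n.id),
            )
            assert point_travel_time(net, field, x, y) == field.get(best.id)
            assert nearest_node(net, x, y) == best.id
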