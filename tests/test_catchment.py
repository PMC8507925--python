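"""Isochrone polygonization, rings, reporting bands and surface coverage."""

import math

import numpy as np
import pytest
import shapely
from shapely.geometry import box

from careshed.catchment import (
    BandSet,
    CutoffScheme,
    build_rings,
    merge_bands,
    reachable_centreline,
    reachable_geometry,
    surface_coverage,
)
from careshed.road_network import travel_times_to_nearest_service

from conftest import path_network, random_geometric_network, snapped_services_at


@pytest.fixture(scope="module")
def geometric():
    net = random_geometric_network(n=50, seed=17)
    field = travel_times_to_nearest_service(
        net, snapped_services_at(net, ["r03", "r21", "r42"]))
    return net, field


class TestCutoffScheme:
    def test_default_is_valid_and_fine_intervals_partition(self):
        scheme = CutoffScheme()
        fine = scheme.fine_intervals()
        assert fine[0] == (0.0, 10.0)
        assert fine[-1] == (90.0, math.inf)
        assert all(a[1] == b[0] for a, b in zip(fine, fine[1:]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cutoffs": (10.0, 10.0)},
            {"cutoffs": (-5.0, 10.0)},
            {"band_edges": ((0.0, 45.0), (45.0, math.inf))},  # 45 not a cutoff
            {"band_edges": ((0.0, 30.0), (60.0, math.inf))},  # gap
            {"band_edges": ((0.0, 30.0), (30.0, 60.0))},  # no open tail
        ],
    )
    def test_invalid_schemes_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CutoffScheme(**kwargs)

    def test_interval_of_uses_half_open_convention(self):
        scheme = CutoffScheme()
        assert scheme.interval_of(30.0) == (20.0, 30.0)
        assert scheme.interval_of(30.0001) == (30.0, 40.0)
        assert scheme.interval_of(None) == (90.0, math.inf)


class TestReachableGeometry:
    def test_nothing_within_cutoff_gives_empty_polygon(self):
        net = path_network()
        field = {"a": 5.0, "b": 6.0, "c": 7.0}
        assert reachable_geometry(net, field, cutoff=1.0).is_empty

    def test_isolated_service_node_gives_disc(self):
        from careshed.road_network import RoadNetwork, RoadNode

        net = RoadNetwork({"a": RoadNode("a", 0, 0)}, [])
        geom = reachable_geometry(net, {"a": 0.0}, cutoff=10.0, buffer_width=200.0)
        assert geom.area == pytest.approx(math.pi * 200**2, rel=0.01)
        assert geom.contains(shapely.Point(0, 150))

    def test_partial_edge_cut_interpolates_linearly(self):
        # chain a-b-c, 1 min per km edge; cutoff 1.5 covers a-b and half of b-c
        net = path_network()
        field = {"a": 0.0, "b": 1.0, "c": 2.0}
        covered = sum(g.length for g in reachable_centreline(net, field, 1.5))
        assert covered == pytest.approx(1500.0, rel=1e-9)
        geom = reachable_geometry(net, field, 1.5, buffer_width=100.0)
        assert geom.contains(shapely.Point(1499, 0))
        assert not geom.contains(shapely.Point(1601, 0))

    def test_empty_field_is_an_error(self):
        net = path_network()
        with pytest.raises(ValueError, match="empty"):
            reachable_geometry(net, {}, cutoff=10.0)

    def test_nesting_in_cutoff(self, geometric):
        # nesting holds up to arc-approximation slivers: cap vertices of a
        # shorter covered subline may overhang the inscribed boundary of a
        # longer one by at most the sagitta of one buffer arc segment
        from careshed.catchment import PRECISION_GRID, QUAD_SEGS

        net, field = geometric
        sagitta = 200.0 * (1 - math.cos(math.pi / (4 * QUAD_SEGS)))
        prev = None
        for cutoff in (2.0, 5.0, 10.0, 20.0):
            geom = reachable_geometry(net, field, cutoff, buffer_width=200.0)
            if prev is not None:
                slack = prev.length * (sagitta + PRECISION_GRID)
                assert prev.difference(geom).area <= slack
            prev = geom

    def test_buffer_width_monotone_in_area(self, geometric):
        net, field = geometric
        areas = [reachable_geometry(net, field, 10.0, buffer_width=w).area
                 for w in (100.0, 200.0, 400.0)]
        assert areas[0] < areas[1] < areas[2]


class TestRings:
    def test_single_cutoff_ring_equals_reachable(self, geometric):
        net, field = geometric
        scheme = CutoffScheme(cutoffs=(30.0,), band_edges=((0.0, 30.0), (30.0, math.inf)))
        rings = build_rings(net, field, scheme, buffer_width=200.0)
        reach = reachable_geometry(net, field, 30.0, buffer_width=200.0)
        assert len(rings) == 1
        assert rings[0].geometry.symmetric_difference(reach).area <= 1e-6

    def test_rings_pairwise_disjoint(self, geometric):
        net, field = geometric
        rings = build_rings(net, field, CutoffScheme(), buffer_width=200.0)
        for i in range(len(rings)):
            for j in range(i + 1, len(rings)):
                inter = rings[i].geometry.intersection(rings[j].geometry)
                assert inter.area < 1e-6

    def test_ring_areas_sum_to_outer_reachable(self, geometric):
        net, field = geometric
        rings = build_rings(net, field, CutoffScheme(), buffer_width=200.0)
        outer = reachable_geometry(net, field, 90.0, buffer_width=200.0)
        total = sum(r.geometry.area for r in rings)
        assert total == pytest.approx(outer.area, rel=1e-6)


class TestMergeBands:
    def test_default_bands_union_consecutive_rings(self, geometric):
        net, field = geometric
        scheme = CutoffScheme()
        rings = build_rings(net, field, scheme, buffer_width=200.0)
        study = box(0, 0, 10_000, 10_000)
        bandset = merge_bands(rings, scheme, study)
        b030 = dict(bandset.bands)[(0.0, 30.0)]
        manual = shapely.unary_union([r.geometry for r in rings if r.hi <= 30]).intersection(study)
        assert b030.symmetric_difference(manual).area <= 1e-3

    def test_single_cutoff_scheme_gives_two_element_bandset(self, geometric):
        net, field = geometric
        scheme = CutoffScheme(cutoffs=(30.0,), band_edges=((0.0, 30.0), (30.0, math.inf)))
        rings = build_rings(net, field, scheme, buffer_width=200.0)
        bandset = merge_bands(rings, scheme, box(0, 0, 10_000, 10_000))
        assert len(bandset.bands) == 1
        assert bandset.residual_interval == (30.0, math.inf)

    def test_bands_plus_residual_partition_study_area(self, geometric):
        net, field = geometric
        scheme = CutoffScheme()
        rings = build_rings(net, field, scheme, buffer_width=200.0)
        study = box(0, 0, 10_000, 10_000)
        bandset = merge_bands(rings, scheme, study)
        total = sum(g.area for _, g in bandset.bands) + bandset.residual.area
        assert total == pytest.approx(study.area, rel=1e-6)

    def test_zero_area_study_area_is_an_error(self, geometric):
        net, field = geometric
        scheme = CutoffScheme()
        rings = build_rings(net, field, scheme, buffer_width=200.0)
        with pytest.raises(ValueError, match="study area"):
            merge_bands(rings, scheme, shapely.Polygon())


class TestSurfaceCoverage:
    def _bandset(self, bands, residual, study):
        scheme = CutoffScheme(cutoffs=(30.0,), band_edges=((0.0, 30.0), (30.0, math.inf)))
        return BandSet(scheme, bands, residual, study)

    def test_band_covering_everything_is_100_percent(self):
        study = box(0, 0, 10_000, 10_000)
        bs = self._bandset([((0.0, 30.0), study)], shapely.Polygon(), study)
        table = surface_coverage(bs)
        assert table.loc[table["band"] == "0-30", "percent"].item() == 100.00

    def test_fractional_band_share(self):
        study = box(0, 0, 10_000, 10_000)  # 100 km^2
        band = box(0, 0, 5400, 10_000)  # 54 km^2
        bs = self._bandset([((0.0, 30.0), band)], study.difference(band), study)
        table = surface_coverage(bs).set_index("band")
        assert table.loc["0-30", "percent"] == 54.00
        assert table.loc["over 30", "percent"] == 46.00
        assert table["percent"].sum() == pytest.approx(100.00, abs=0.01)

    def test_matches_rasterized_cell_count_oracle(self, small17):
        """Vector band shares agree with counting 50 m cells per band."""
        bs = small17.report_bandset
        grid = small17.grid
        nrows, ncols = grid.shape
        rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
        x, y = grid.cell_centroids(rr.ravel(), cc.ravel())
        pts = shapely.points(x, y)
        table = surface_coverage(bs).set_index("band")
        entries = list(bs.bands) + [(bs.residual_interval, bs.residual)]
        from careshed._util import interval_label

        for interval, geom in entries:
            n_cells = int(shapely.covers(geom, pts).sum())
            raster_pct = 100.0 * n_cells / len(pts)
            assert table.loc[interval_label(interval), "percent"] == pytest.approx(
                raster_pct, abs=0.5)
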