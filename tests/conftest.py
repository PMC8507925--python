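"""Shared fixtures: tiny hand-built networks and seeded synthetic countries."""

from __future__ import annotations

import json

import numpy as np
import pytest
from shapely.geometry import LineString

from careshed.pipeline import AnalysisResult, analyze_synthetic
from careshed.road_network import RoadEdge, RoadNetwork, RoadNode, ServicePoint
from careshed.synth import CountrySpec


def small_spec(seed: int = 17, **overrides) -> CountrySpec:
    """A fast synthetic country (~6 x 6 km, 50 m raster) for multi-seed loops."""
    params = dict(
        seed=seed, extent=(6000.0, 6000.0), grid_n=10, n_units=8, n_regions=3,
        n_services=2, settlement_centers=3, total_population=10_000,
        impervious_cell=50.0,
    )
    params.update(overrides)
    return CountrySpec(**params)


def path_network(n: int = 3, edge_km: float = 1.0, speed: float = 60.0,
                 oneway: bool = False) -> RoadNetwork:
    """A straight chain of nodes a, b, c, ... with equal edges (1 min each at defaults)."""
    names = [chr(ord("a") + i) for i in range(n)]
    step = edge_km * 1000.0
    nodes = {nm: RoadNode(nm, i * step, 0.0) for i, nm in enumerate(names)}
    edges = [
        RoadEdge(names[i], names[i + 1], step, speed, oneway,
                 LineString([(i * step, 0), ((i + 1) * step, 0)]))
        for i in range(n - 1)
    ]
    return RoadNetwork(nodes, edges)


def write_lines_geojson(path, lines, crs_tag="EPSG:2157"):
    """Write LineString features given as (coords, properties) pairs."""
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs_tag}},
        "features": [
            {"type": "Feature",
             "geometry": {"type": "LineString", "coordinates": coords},
             "properties": props}
            for coords, props in lines
        ],
    }
    path.write_text(json.dumps(doc))
    return path


@pytest.fixture(scope="session")
def seed17() -> AnalysisResult:
    """The full-size seed-17 study fixture, analyzed once per session."""
    return analyze_synthetic(CountrySpec(seed=17))


@pytest.fixture(scope="session")
def small17() -> AnalysisResult:
    """Fast small-country analysis for tests that don't need the full fixture."""
    return analyze_synthetic(small_spec(seed=17))


@pytest.fixture(scope="session")
def small_runs() -> list[AnalysisResult]:
    """Ten analyzed small countries, seeds 100..109 (conservation/partition sweeps)."""
    return [analyze_synthetic(small_spec(seed=100 + s)) for s in range(10)]


def random_geometric_network(n: int = 50, seed: int = 17) -> RoadNetwork:
    """Connected random geometric graph in a 10 km square with random speeds."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 10_000, size=(n, 2))
    ids = [f"r{i:02d}" for i in range(n)]
    nodes = {ids[i]: RoadNode(ids[i], *xy[i]) for i in range(n)}
    edges = []
    # connect each node to its 3 nearest neighbours; dedupe pairs
    from scipy.spatial import cKDTree

    tree = cKDTree(xy)
    seen = set()
    _, nbrs = tree.query(xy, k=4)
    for i in range(n):
        for j in nbrs[i][1:]:
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            length = float(np.hypot(*(xy[i] - xy[j])))
            speed = float(rng.uniform(30, 90))
            edges.append(RoadEdge(ids[i], ids[j], length, speed, False,
                                  LineString([xy[i], xy[j]])))
    return RoadNetwork(nodes, edges)


def snapped_services_at(network: RoadNetwork, node_ids: list[str]) -> list[ServicePoint]:
    return [
        ServicePoint(f"s{k}", network.nodes[nid].x, network.nodes[nid].y,
                     snapped_node=nid, snap_distance=0.0)
        for k, nid in enumerate(node_ids)
    ]
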