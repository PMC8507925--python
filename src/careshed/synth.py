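"""Seeded synthetic country: road grid, admin units, population, imperviousness, services.

Stands in for national datasets so every pipeline stage is testable offline
with known ground truth. The generator emulates the stylized facts that drive
accessibility patterns: population clustered around settlement centers,
built-up land decaying away from them, services concentrated in the most
populous units, and a road grid with a faster major-road subgrid and seeded
gaps (barrier analogue). Everything derives deterministically from the seed
via named RNG streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import LineString, Polygon, box

from careshed._util import Interval
from careshed.catchment import CutoffScheme
from careshed.dasymetric import AdminUnit, ImperviousGrid, PopulationCells
from careshed.road_network import RoadEdge, RoadNetwork, RoadNode, ServicePoint

# fixed stream ids so adding a stage never reshuffles earlier draws
_STREAM_NETWORK, _STREAM_SITES, _STREAM_CENTERS, _STREAM_POP, _STREAM_IMPERV = range(5)


@dataclass(frozen=True)
class CountrySpec:
    """Parameters of one synthetic country (all lengths in metres).

    Defaults give a 24 x 24 km country with a 30 x 30 road grid (828 m
    spacing; every 6th line a faster major road), 25 Voronoi admin units in
    5 regions, 5 settlement centers, 100k inhabitants and a 20 m
    imperviousness raster — small enough to run in seconds, large enough
    that catchment bands, units and settlements interact non-trivially.
    """

    seed: int = 17
    extent: tuple[float, float] = (24000.0, 24000.0)
    grid_n: int = 30
    speed_profile: dict = dataclass_field(
        default_factory=lambda: {"major": 30.0, "local": 15.0}
    )
    major_every: int = 6
    edge_deletion_rate: float = 0.05
    n_units: int = 25
    n_regions: int = 5
    n_services: int = 3
    settlement_centers: int = 5
    settlement_decay: float = 300.0  # imperviousness e-folding distance
    population_decay: float = 2000.0  # settlement pull on unit populations
    total_population: int = 100_000
    impervious_cell: float = 20.0
    noise_sd: float = 3.0
    speckle_rate: float = 0.003  # isolated rural built cells

    def __post_init__(self) -> None:
        if min(self.grid_n, self.n_units, self.n_regions, self.n_services,
               self.settlement_centers) < 1:
            raise ValueError("all counts must be >= 1")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("extent must be positive")
        if self.total_population < 0:
            raise ValueError("total_population must be >= 0")
        if self.n_services > self.n_units:
            raise ValueError("n_services cannot exceed n_units")

    def study_area(self) -> Polygon:
        return box(0.0, 0.0, self.extent[0], self.extent[1])

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _node_id(i: int, j: int) -> str:
    return f"n{i:03d}c{j:03d}"


def generate_network(spec: CountrySpec) -> RoadNetwork:
    """Regular two-way road grid with per-class speeds and seeded gaps.

    Every ``major_every``-th row/column line is a major road (faster class).
    A seeded fraction of edges is deleted, skipping any deletion that would
    disconnect the grid, so the network stays one connected component.
    """
    n = spec.grid_n
    dx = spec.extent[0] / max(n - 1, 1)
    dy = spec.extent[1] / max(n - 1, 1)
    speeds = spec.speed_profile
    nodes = {
        _node_id(i, j): RoadNode(_node_id(i, j), j * dx, i * dy)
        for i in range(n) for j in range(n)
    }

    def cls(line_index: int) -> str:
        return "major" if line_index % spec.major_every == 0 else "local"

    raw: list[tuple[str, str, float, float]] = []
    for i in range(n):
        for j in range(n):
            if j + 1 < n:  # horizontal edge along row line i
                raw.append((_node_id(i, j), _node_id(i, j + 1), dx, speeds[cls(i)]))
            if i + 1 < n:  # vertical edge along column line j
                raw.append((_node_id(i, j), _node_id(i + 1, j), dy, speeds[cls(j)]))

    g = nx.Graph((u, v) for u, v, _, _ in raw)
    rng = spec.rng(_STREAM_NETWORK)
    delete = rng.random(len(raw)) < spec.edge_deletion_rate
    kept: list[tuple[str, str, float, float]] = []
    for (u, v, length, speed), drop in zip(raw, delete):
        if drop and n > 1:
            g.remove_edge(u, v)
            if nx.is_connected(g):
                continue  # deletion accepted
            g.add_edge(u, v)  # would disconnect; keep the edge
        kept.append((u, v, length, speed))
    edges = [
        RoadEdge(u, v, length, speed, False,
                 LineString([(nodes[u].x, nodes[u].y), (nodes[v].x, nodes[v].y)]))
        for u, v, length, speed in kept
    ]
    return RoadNetwork(nodes, edges, crs_tag="synthetic-metre-grid")


def unit_sites(spec: CountrySpec) -> np.ndarray:
    """Voronoi seed points of the admin units (n_units x 2), seeded."""
    rng = spec.rng(_STREAM_SITES)
    return rng.uniform((0, 0), spec.extent, size=(spec.n_units, 2))


def settlement_centers(spec: CountrySpec) -> np.ndarray:
    """Settlement center coordinates (settlement_centers x 2), seeded."""
    rng = spec.rng(_STREAM_CENTERS)
    return rng.uniform((0, 0), spec.extent, size=(spec.settlement_centers, 2))


def _voronoi_polygons(sites: np.ndarray, extent: tuple[float, float]) -> list[Polygon]:
    """Voronoi cells of `sites` clipped to the extent box.

    Mirrors the sites across the four box edges so every original cell is
    finite, then clips; the cells tile the box exactly.
    """
    w, h = extent
    if len(sites) == 1:
        return [box(0, 0, w, h)]
    mirrors = [
        sites * (-1, 1),               # across x = 0
        sites * (1, -1),               # across y = 0
        np.column_stack([2 * w - sites[:, 0], sites[:, 1]]),
        np.column_stack([sites[:, 0], 2 * h - sites[:, 1]]),
    ]
    vor = Voronoi(np.vstack([sites] + mirrors))
    bbox = box(0, 0, w, h)
    polys = []
    for i in range(len(sites)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(bbox)
        polys.append(poly)
    return polys


def generate_units_and_population(spec: CountrySpec) -> list[AdminUnit]:
    """Voronoi admin units with settlement-weighted multinomial populations.

    Unit populations are one multinomial draw of ``total_population`` with
    weights decaying with the unit site's distance to the nearest settlement
    center (scale ``population_decay``) over a small uniform floor, so the
    total is conserved exactly and population clusters around settlements.
    Regions group units by proximity to ``n_regions`` seeded region sites.
    """
    sites = unit_sites(spec)
    centers = settlement_centers(spec)
    polys = _voronoi_polygons(sites, spec.extent)
    d_center = cKDTree(centers).query(sites)[0]
    weights = 0.05 + np.exp(-d_center / spec.population_decay)
    pops = spec.rng(_STREAM_POP).multinomial(spec.total_population, weights / weights.sum())
    region_seeds = sites[: spec.n_regions]
    region_of = cKDTree(region_seeds).query(sites)[1]
    return [
        AdminUnit(
            id=f"u{i:03d}",
            name=f"Unit {i:03d}",
            region_id=f"r{region_of[i]:02d}",
            country_id="SYN",
            geometry=polys[i],
            population=int(pops[i]),
        )
        for i in range(spec.n_units)
    ]


def generate_imperviousness(spec: CountrySpec, units: list[AdminUnit] | None = None) -> ImperviousGrid:
    """Imperviousness density raster decaying away from settlement centers.

    Base density is ``100 * exp(-d / settlement_decay)`` to the nearest
    center, floored to 0 below 1%; gaussian noise perturbs cells with
    non-zero base, and a seeded speckle of isolated built cells emulates
    scattered rural dwellings. Values are clipped to [0, 100].
    """
    cell = spec.impervious_cell
    ncols = int(round(spec.extent[0] / cell))
    nrows = int(round(spec.extent[1] / cell))
    xs = (np.arange(ncols) + 0.5) * cell
    ys = (np.arange(nrows) + 0.5) * cell
    gx, gy = np.meshgrid(xs, ys)  # row-major: gy varies along rows
    centers = settlement_centers(spec)
    d = cKDTree(centers).query(np.column_stack([gx.ravel(), gy.ravel()]))[0]
    base = 100.0 * np.exp(-d / spec.settlement_decay)
    base[base < 1.0] = 0.0
    rng = spec.rng(_STREAM_IMPERV)
    noise = rng.normal(0.0, spec.noise_sd, size=base.shape)
    values = np.where(base > 0, np.clip(base + noise, 0.0, 100.0), 0.0)
    speckle = (rng.random(base.shape) < spec.speckle_rate) & (values == 0)
    values[speckle] = rng.uniform(5.0, 40.0, size=int(speckle.sum()))
    return ImperviousGrid(values.reshape(nrows, ncols), 0.0, 0.0, cell)


def place_services(spec: CountrySpec, units: list[AdminUnit], k: int | None = None) -> list[ServicePoint]:
    """Service points at the Voronoi seeds of the k most populous units.

    Rank is by descending population with unit id as the deterministic
    tie-break, mirroring the tendency of providers to locate in populated
    areas. ``k`` defaults to ``spec.n_services``; because ranking is nested,
    the services for k=1 are a subset of those for k=3, and so on.
    """
    k = spec.n_services if k is None else k
    if k > len(units):
        raise ValueError("cannot place more services than there are units")
    sites = unit_sites(spec)
    order = sorted(range(len(units)), key=lambda i: (-units[i].population, units[i].id))
    return [
        ServicePoint(f"s{rank:02d}", float(sites[i][0]), float(sites[i][1]))
        for rank, i in enumerate(order[:k])
    ]


def ground_truth_bands(
    spec: CountrySpec,
    network: RoadNetwork,
    services: list[ServicePoint],
    cells: PopulationCells,
    scheme: CutoffScheme | None = None,
) -> list[Interval]:
    """Independent oracle: band of every population cell, from scratch.

    Reimplements the travel-time logic by a different route than the
    pipeline: sparse-matrix Dijkstra (scipy csgraph) per service with an
    explicit minimum across services, and exhaustive nearest-node lookup by
    brute-force distance scan. Shares no graph or KD-tree code with
    :mod:`careshed.road_network`.
    """
    if not services:
        raise ValueError("ground truth requires at least one service")
    scheme = scheme or CutoffScheme()
    ids = sorted(network.nodes)
    index = {nid: i for i, nid in enumerate(ids)}
    xy = np.array([(network.nodes[i].x, network.nodes[i].y) for i in ids])
    # reversed arcs: driving u->v toward the service = expanding v->u from it
    rows, cols, data = [], [], []
    for e in network.edges:
        tt = e.travel_time
        rows.append(index[e.v]); cols.append(index[e.u]); data.append(tt)
        if not e.oneway:
            rows.append(index[e.u]); cols.append(index[e.v]); data.append(tt)
    m = coo_matrix((data, (rows, cols)), shape=(len(ids), len(ids))).tocsr()
    per_service = []
    for s in services:
        if s.snapped_node is None:
            raise ValueError(f"service {s.id} is not snapped")
        per_service.append(dijkstra(m, directed=True, indices=index[s.snapped_node]))
    t_node = np.min(np.vstack(per_service), axis=0)

    px = cells.frame["x"].to_numpy()
    py = cells.frame["y"].to_numpy()
    out: list[Interval] = []
    fine = scheme.fine_intervals()
    chunk = 4096
    for start in range(0, len(px), chunk):
        dx = px[start:start + chunk, None] - xy[None, :, 0]
        dy = py[start:start + chunk, None] - xy[None, :, 1]
        dist = np.hypot(dx, dy)
        dmin = dist.min(axis=1)
        # first index within tie tolerance = smallest node id (ids sorted)
        nearest = (dist <= dmin[:, None] + 1e-9).argmax(axis=1)
        for t in t_node[nearest]:
            if not math.isfinite(t):
                out.append(fine[-1])
                continue
            for lo, hi in fine:
                if t <= hi:
                    out.append((lo, hi))
                    break
    return out


@dataclass
class SynthCountry:
    """Bundle of generated inputs for one synthetic country."""

    spec: CountrySpec
    network: RoadNetwork
    units: list[AdminUnit]
    grid: ImperviousGrid
    services: list[ServicePoint]

    def study_area(self) -> Polygon:
        return self.spec.study_area()


def generate_country(spec: CountrySpec) -> SynthCountry:
    """Generate all four inputs for one seed."""
    network = generate_network(spec)
    units = generate_units_and_population(spec)
    grid = generate_imperviousness(spec, units)
    services = place_services(spec, units)
    return SynthCountry(spec, network, units, grid, services)
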