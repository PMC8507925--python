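"""Travel-time-weighted road graph and driving time to the nearest service.

The road network is a directed graph whose edges carry driving times derived
from segment length and speed (``minutes = length_km / speed_kmh * 60``).
Patients drive *to* the provider, so times are shortest-path distances on the
reversed directed graph from every service node at once; taking the minimum
over services is what dissolves per-provider catchments into one field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dataclass_field
from typing import Mapping

import networkx as nx
import numpy as np
from shapely.geometry import LineString

from careshed.io import read_geojson

logger = logging.getLogger(__name__)

#: node id -> minutes to the nearest service; unreachable nodes are absent.
TravelTimeField = Mapping[str, float]

DEDUP_TOLERANCE = 1e-6  # metres; endpoint snap grid for node identity
DEFAULT_SNAP_TOLERANCE = 5000.0  # metres; max service-to-node snap distance


@dataclass(frozen=True)
class RoadNode:
    id: str
    x: float
    y: float


@dataclass(frozen=True)
class RoadEdge:
    """One road segment. ``oneway`` edges are traversable u -> v only."""

    u: str
    v: str
    length: float  # metres
    speed: float  # km/h
    oneway: bool = False
    geometry: LineString | None = None

    @property
    def travel_time(self) -> float:
        """Driving time in minutes."""
        return (self.length / 1000.0) / self.speed * 60.0


@dataclass
class RoadNetwork:
    nodes: dict[str, RoadNode]
    edges: list[RoadEdge]
    crs_tag: str = "unspecified-projected"
    _graph: nx.DiGraph | None = dataclass_field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("road network must have at least one node")
        for e in self.edges:
            if e.u not in self.nodes or e.v not in self.nodes:
                raise ValueError(f"edge {e.u}-{e.v} references a missing node")
            if e.travel_time <= 0:
                raise ValueError(f"edge {e.u}-{e.v} has non-positive travel time")

    def graph(self) -> nx.DiGraph:
        """Directed graph with ``travel_time`` edge weights (cached)."""
        if self._graph is None:
            g = nx.DiGraph()
            for nid, node in self.nodes.items():
                g.add_node(nid, x=node.x, y=node.y)
            for i, e in enumerate(self.edges):
                tt = e.travel_time
                self._add_directed(g, e.u, e.v, tt, i)
                if not e.oneway:
                    self._add_directed(g, e.v, e.u, tt, i)
            self._graph = g
        return self._graph

    @staticmethod
    def _add_directed(g: nx.DiGraph, u: str, v: str, tt: float, idx: int) -> None:
        # parallel edges: keep the fastest (shortest paths never use the slower)
        if g.has_edge(u, v) and g[u][v]["travel_time"] <= tt:
            return
        g.add_edge(u, v, travel_time=tt, edge_index=idx)

    def node_coordinates(self) -> tuple[list[str], np.ndarray]:
        ids = sorted(self.nodes)
        xy = np.array([(self.nodes[i].x, self.nodes[i].y) for i in ids])
        return ids, xy


@dataclass
class ServicePoint:
    """A geolocated specialized palliative care provider."""

    id: str
    x: float
    y: float
    snapped_node: str | None = None
    snap_distance: float | None = None


def _node_key(x: float, y: float) -> tuple[int, int]:
    r = DEDUP_TOLERANCE
    return (round(x / r), round(y / r))


def load_network(
    path,
    speed_field: str = "speed",
    default_speed: float | None = None,
) -> RoadNetwork:
    """Build a :class:`RoadNetwork` from a line-geometry GeoJSON file.

    Each LineString (or MultiLineString part) becomes one edge between its two
    endpoints; endpoints closer than 1e-6 m collapse into one node. Features
    may carry ``oneway`` (boolean) and a numeric speed property. A missing
    speed falls back to ``default_speed`` with a warning; zero or negative
    speeds drop the record.
    """
    feats, crs_tag = read_geojson(path)
    nodes: dict[tuple[int, int], str] = {}
    node_objs: dict[str, RoadNode] = {}
    edges: list[RoadEdge] = []

    def node_for(x: float, y: float) -> str:
        # grid hash plus neighbour-cell probe: points within the tolerance
        # merge even when they straddle a grid-cell boundary
        kx, ky = _node_key(x, y)
        for dx in (0, -1, 1):
            for dy in (0, -1, 1):
                nid = nodes.get((kx + dx, ky + dy))
                if nid is not None:
                    node = node_objs[nid]
                    if math.hypot(node.x - x, node.y - y) <= DEDUP_TOLERANCE:
                        return nid
        nid = f"n{len(node_objs):06d}"
        nodes[(kx, ky)] = nid
        node_objs[nid] = RoadNode(nid, x, y)
        return nid

    n_defaulted = n_rejected = 0
    for geom, props in feats:
        if geom.geom_type == "LineString":
            parts = [geom]
        elif geom.geom_type == "MultiLineString":
            parts = list(geom.geoms)
        else:
            continue
        speed = props.get(speed_field)
        if speed is None:
            if default_speed is None:
                n_rejected += 1
                logger.warning("feature without %r and no default speed; dropped", speed_field)
                continue
            speed = default_speed
            n_defaulted += 1
        speed = float(speed)
        if speed <= 0 or not math.isfinite(speed):
            n_rejected += 1
            logger.warning("feature with non-positive speed %s dropped", speed)
            continue
        oneway = bool(props.get("oneway", False))
        for part in parts:
            if part.length <= 0:
                continue
            (x0, y0), (x1, y1) = part.coords[0], part.coords[-1]
            edges.append(
                RoadEdge(node_for(x0, y0), node_for(x1, y1), part.length, speed, oneway, part)
            )
    if n_defaulted:
        logger.warning("%d features had no %r; default %s km/h applied", n_defaulted, speed_field, default_speed)
    if not edges:
        raise ValueError(f"{path}: no edges (no usable line features)")
    return RoadNetwork(node_objs, edges, crs_tag)


def snap_service(
    network: RoadNetwork,
    service: ServicePoint,
    tolerance: float = DEFAULT_SNAP_TOLERANCE,
) -> ServicePoint:
    """Attach a service to its nearest road node (Euclidean distance).

    Ties within 1e-9 m break toward the smallest node id so snapping is
    deterministic. A nearest node farther than ``tolerance`` is an error:
    a provider that far off the network is a data problem, not a snap.
    """
    ids, xy = network.node_coordinates()
    d = np.hypot(xy[:, 0] - service.x, xy[:, 1] - service.y)
    dmin = d.min()
    if dmin > tolerance:
        raise ValueError(
            f"service {service.id!r}: nearest road node is {dmin:.1f} m away "
            f"(tolerance {tolerance:.1f} m)"
        )
    tied = [ids[i] for i in np.flatnonzero(d <= dmin + 1e-9)]
    best = min(tied)
    return ServicePoint(service.id, service.x, service.y, snapped_node=best, snap_distance=float(dmin))


def travel_times_to_nearest_service(
    network: RoadNetwork, services: list[ServicePoint]
) -> dict[str, float]:
    """Minutes of driving from every road node to its nearest service.

    Multi-source Dijkstra on the reversed graph: an edge usable u->v when
    driving is usable v->u when expanding outward from the services, which
    yields, in one pass, the minimum over all providers (the dissolve).
    Unreachable nodes are simply absent from the result.
    """
    snapped = [s for s in services if s.snapped_node is not None]
    if not snapped:
        raise ValueError("no snapped services: snap_service must be applied first")
    sources = {s.snapped_node for s in snapped}
    missing = sources - set(network.nodes)
    if missing:
        raise ValueError(f"services snapped to unknown nodes: {sorted(missing)}")
    g_rev = network.graph().reverse(copy=False)
    field = nx.multi_source_dijkstra_path_length(g_rev, sources, weight="travel_time")
    return dict(field)


def nearest_node(network: RoadNetwork, x: float, y: float) -> str:
    """Nearest road node to a point; ties break to the smallest node id."""
    ids, xy = network.node_coordinates()
    d = np.hypot(xy[:, 0] - x, xy[:, 1] - y)
    dmin = d.min()
    tied = [ids[i] for i in np.flatnonzero(d <= dmin + 1e-9)]
    return min(tied)


def point_travel_time(
    network: RoadNetwork, field: TravelTimeField, x: float, y: float
) -> float | None:
    """Travel time at the road node nearest to (x, y); None if unreachable."""
    nid = nearest_node(network, x, y)
    return field.get(nid)
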