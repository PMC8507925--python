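"""Isochrone rings and reporting bands from a travel-time field.

Catchments are polygonized by buffering every road portion reachable within a
cut-off, including the partial prefix of a boundary edge (travel time varies
linearly along an edge). Because the field already holds the minimum time over
all providers, the polygons come out dissolved. Rings are set differences of
successive reachable polygons; reporting bands merge consecutive rings
(0-30, 30-60, 60-90, over 90 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point
from shapely.ops import substring, unary_union
from shapely.geometry.base import BaseGeometry

from careshed._util import Interval, interval_label, round_half_up
from careshed.road_network import RoadNetwork, TravelTimeField

DEFAULT_CUTOFFS = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 90.0]
DEFAULT_BAND_EDGES: list[Interval] = [(0.0, 30.0), (30.0, 60.0), (60.0, 90.0), (90.0, math.inf)]
DEFAULT_BUFFER_WIDTH = 200.0  # metres either side of the carriageway
PRECISION_GRID = 1e-3  # metres; output coordinates snap to this grid
QUAD_SEGS = 16  # buffer arc resolution; nesting of reachable polygons holds
# up to slivers bounded by the arc sagitta r*(1-cos(pi/(4*QUAD_SEGS)))


@dataclass(frozen=True)
class CutoffScheme:
    """Drive-time cut-offs (minutes) and the reporting bands built from them.

    Intervals are half-open ``(lo, hi]``: a location at exactly 30 minutes
    counts as within 30 minutes.
    """

    cutoffs: tuple[float, ...] = tuple(DEFAULT_CUTOFFS)
    band_edges: tuple[Interval, ...] = tuple(DEFAULT_BAND_EDGES)

    def __post_init__(self) -> None:
        cs = self.cutoffs
        if not cs or any(c <= 0 for c in cs) or any(b <= a for a, b in zip(cs, cs[1:])):
            raise ValueError("cutoffs must be positive and strictly increasing")
        edges = self.band_edges
        if not edges or edges[0][0] != 0 or not math.isinf(edges[-1][1]):
            raise ValueError("band edges must start at 0 and end at infinity")
        for (_, hi), (lo2, _) in zip(edges, edges[1:]):
            if hi != lo2:
                raise ValueError("band edges must form a partition of (0, inf)")
        finite = {e for lo, hi in edges for e in (lo, hi) if 0 < e < math.inf}
        missing = finite - set(cs)
        if missing:
            raise ValueError(f"band edges {sorted(missing)} are not cut-off times")

    def fine_intervals(self) -> list[Interval]:
        """One interval per cut-off plus the open tail, e.g. (0,10] ... (90,inf)."""
        los = (0.0,) + self.cutoffs
        his = self.cutoffs + (math.inf,)
        return list(zip(los, his))

    def interval_of(self, t: float | None) -> Interval:
        """Fine interval containing travel time ``t`` (None = unreachable -> tail)."""
        fine = self.fine_intervals()
        if t is None:
            return fine[-1]
        i = int(np.searchsorted(self.cutoffs, t, side="left"))
        return fine[i]


@dataclass(frozen=True)
class IsochroneRing:
    lo: float
    hi: float
    geometry: BaseGeometry


@dataclass
class BandSet:
    """Reporting bands clipped to the study area.

    ``bands`` holds the finite intervals; ``residual`` is the study area
    beyond the last cut-off (the open band, e.g. over 90 minutes).
    """

    scheme: CutoffScheme
    bands: list[tuple[Interval, BaseGeometry]]
    residual: BaseGeometry
    study_area: BaseGeometry = dataclass_field(default=None)

    @property
    def residual_interval(self) -> Interval:
        return self.scheme.band_edges[-1]


def _snap(geom: BaseGeometry) -> BaseGeometry:
    return shapely.set_precision(geom, PRECISION_GRID)


def reachable_centreline(
    network: RoadNetwork, field: TravelTimeField, cutoff: float
) -> list[LineString]:
    """Portions of road centreline reachable within ``cutoff`` minutes.

    On a two-way edge a point is reachable through either endpoint; on a
    one-way edge the patient can only drive forward, so reachability comes
    through the downstream node. The cut point interpolates linearly.
    """
    parts: list[LineString] = []
    for e in network.edges:
        geom = e.geometry if e.geometry is not None else LineString(
            [(network.nodes[e.u].x, network.nodes[e.u].y),
             (network.nodes[e.v].x, network.nodes[e.v].y)]
        )
        tt = e.travel_time
        t_u = field.get(e.u)
        t_v = field.get(e.v)
        # fraction of the edge (measured from u) reachable from each end
        pre = 0.0 if t_u is None or t_u > cutoff else min(1.0, (cutoff - t_u) / tt)
        suf = 1.0 if t_v is None or t_v > cutoff else max(0.0, 1.0 - (cutoff - t_v) / tt)
        if e.oneway:
            pre = 0.0  # cannot drive backwards toward u
        if pre >= suf:  # whole edge covered
            parts.append(geom)
            continue
        L = geom.length
        if pre > 0:
            parts.append(substring(geom, 0.0, pre * L))
        if suf < 1:
            parts.append(substring(geom, suf * L, L))
    return parts


def reachable_geometry(
    network: RoadNetwork,
    field: TravelTimeField,
    cutoff: float,
    buffer_width: float = DEFAULT_BUFFER_WIDTH,
) -> BaseGeometry:
    """Dissolved polygon of everything within ``cutoff`` minutes of a service.

    Union of the reachable centreline portions buffered by ``buffer_width``,
    plus a disc at every reachable node (covers isolated service nodes).
    Coordinates snap to a 1 mm grid to stabilize the set operations.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if buffer_width <= 0:
        raise ValueError("buffer_width must be positive")
    if not field:
        raise ValueError("empty travel-time field")
    pieces: list[BaseGeometry] = [
        g.buffer(buffer_width, quad_segs=QUAD_SEGS)
        for g in reachable_centreline(network, field, cutoff)
    ]
    pieces += [
        Point(network.nodes[nid].x, network.nodes[nid].y).buffer(
            buffer_width, quad_segs=QUAD_SEGS)
        for nid, t in field.items()
        if t <= cutoff
    ]
    if not pieces:
        return shapely.Polygon()
    return _snap(unary_union(pieces))


def build_rings(
    network: RoadNetwork,
    field: TravelTimeField,
    scheme: CutoffScheme,
    buffer_width: float = DEFAULT_BUFFER_WIDTH,
) -> list[IsochroneRing]:
    """Pairwise-disjoint rings: ring (lo, hi] = reachable(hi) minus reachable(lo)."""
    rings: list[IsochroneRing] = []
    prev: BaseGeometry | None = None
    for lo, hi in zip((0.0,) + scheme.cutoffs[:-1], scheme.cutoffs):
        reach = reachable_geometry(network, field, hi, buffer_width)
        ring = reach if prev is None else _snap(reach.difference(prev))
        rings.append(IsochroneRing(lo, hi, ring))
        prev = reach
    return rings


def merge_bands(
    rings: list[IsochroneRing],
    scheme: CutoffScheme,
    study_area: BaseGeometry,
) -> BandSet:
    """Merge consecutive rings into the scheme's reporting bands.

    Bands are clipped to the study area; the residual is the study area not
    covered by any finite band (beyond the last cut-off or off-network).
    """
    if study_area.is_empty or study_area.area <= 0:
        raise ValueError("study area must have positive area")
    for lo, hi in scheme.band_edges:
        if math.isinf(hi):
            continue
        if not any(r.lo >= lo and r.hi <= hi for r in rings):
            raise ValueError(f"band ({lo}, {hi}] matches no computed ring")
        for e in (lo, hi):
            if e > 0 and e not in set(scheme.cutoffs):
                raise ValueError(f"band edge {e} is not a cut-off time")
    bands: list[tuple[Interval, BaseGeometry]] = []
    for lo, hi in scheme.band_edges:
        if math.isinf(hi):
            continue
        members = [r.geometry for r in rings if r.lo >= lo and r.hi <= hi]
        geom = _snap(unary_union(members).intersection(study_area))
        bands.append(((lo, hi), geom))
    covered = unary_union([g for _, g in bands])
    residual = _snap(study_area.difference(covered))
    return BandSet(scheme, bands, residual, study_area)


def surface_coverage(bandset: BandSet) -> pd.DataFrame:
    """Area and share of the study area per band (the surface-coverage table).

    Percentages are computed from unrounded areas and printed half-up at two
    decimals; they sum to 100.00 within +/-0.01.
    """
    study_area = bandset.study_area
    if study_area is None or study_area.area <= 0:
        raise ValueError("band set has no study area")
    total = study_area.area
    rows = []
    entries = list(bandset.bands) + [(bandset.residual_interval, bandset.residual)]
    for interval, geom in entries:
        rows.append(
            {
                "band": interval_label(interval),
                "area_km2": round_half_up(geom.area / 1e6, 4),
                "percent": round_half_up(100.0 * geom.area / total, 2),
            }
        )
    return pd.DataFrame(rows)
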