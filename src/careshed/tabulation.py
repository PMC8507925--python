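"""Population-by-driving-time tables at national and regional level.

Cells are assigned to a driving-time band either geometrically (``polygon``
mode: innermost band polygon covering the cell centroid) or directly
(``direct`` mode: travel time at the nearest road node, the oracle for
polygon mode). Band populations are summed unrounded; printed tables round
counts half-up to whole persons and percentages half-up to two decimals,
with percentages always computed from the unrounded sums.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.ops import unary_union
from shapely.strtree import STRtree

from careshed._util import Interval, interval_label, round_half_up
from careshed.catchment import BandSet
from careshed.dasymetric import AdminUnit, PopulationCells
from careshed.road_network import RoadNetwork, TravelTimeField

logger = logging.getLogger(__name__)


def _nearest_node_times(
    network: RoadNetwork, field: TravelTimeField, x: np.ndarray, y: np.ndarray
) -> list[float | None]:
    """Travel time at each point's nearest road node (ties -> smallest node id)."""
    ids, xy = network.node_coordinates()
    tree = cKDTree(xy)
    k = min(4, len(ids))
    d, idx = tree.query(np.column_stack([x, y]), k=k)
    if k == 1:
        d, idx = d[:, None], idx[:, None]
    out: list[float | None] = []
    for i in range(len(x)):
        tied = idx[i][d[i] <= d[i, 0] + 1e-9]
        nid = min(ids[j] for j in tied)
        out.append(field.get(nid))
    return out


def _band_of_time(t: float | None, bandset: BandSet) -> Interval:
    if t is None:
        return bandset.residual_interval
    for (lo, hi), _ in bandset.bands:
        if (lo == 0 and t <= hi) or (lo < t <= hi):
            return (lo, hi)
    return bandset.residual_interval


def assign_bands(
    cells: PopulationCells,
    bandset: BandSet,
    mode: str = "polygon",
    network: RoadNetwork | None = None,
    field: TravelTimeField | None = None,
) -> list[Interval]:
    """One band interval per population cell.

    ``polygon``: the lowest (innermost) band whose geometry covers the cell
    centroid; a centroid on a shared boundary therefore falls in the faster
    band. Cells covered by no band (outside the study area or beyond every
    cut-off) go to the residual band, with a warning when outside the study
    area. ``direct``: band of the travel time at the nearest road node;
    unreachable cells go to the residual band.
    """
    if mode == "direct":
        if network is None or field is None:
            raise ValueError("direct mode requires the network and travel-time field")
        times = _nearest_node_times(
            network, field, cells.frame["x"].to_numpy(), cells.frame["y"].to_numpy()
        )
        return [_band_of_time(t, bandset) for t in times]
    if mode != "polygon":
        raise ValueError(f"unknown assignment mode {mode!r}")
    pts = cells.points()
    tree = STRtree(pts)
    n = len(pts)
    assigned = np.full(n, -1, dtype=int)
    order = sorted(range(len(bandset.bands)), key=lambda i: bandset.bands[i][0][0])
    for bi in order:
        geom = bandset.bands[bi][1]
        if geom.is_empty:
            continue
        idx = tree.query(geom, predicate="covers")
        fresh = idx[assigned[idx] < 0]
        assigned[fresh] = bi
    unassigned = assigned < 0
    if unassigned.any() and bandset.study_area is not None:
        outside = ~shapely.covers(bandset.study_area, pts[unassigned])
        if outside.any():
            logger.warning(
                "%d cells lie outside the study area; placed in the residual band",
                int(outside.sum()),
            )
    return [
        bandset.bands[a][0] if a >= 0 else bandset.residual_interval for a in assigned
    ]


def cells_far_from_band_boundaries(
    cells: PopulationCells, bandset: BandSet, margin: float
) -> np.ndarray:
    """Boolean mask of cells farther than ``margin`` metres from any band boundary.

    On this subset the geometric and direct assignments are expected to
    agree: disagreements concentrate where a cut-off frontier or a catchment
    buffer outline passes close to a cell centroid.
    """
    boundaries = [g.boundary for _, g in bandset.bands if not g.is_empty]
    if not bandset.residual.is_empty:
        boundaries.append(bandset.residual.boundary)
    if not boundaries:
        return np.ones(len(cells.frame), dtype=bool)
    near_zone = unary_union(boundaries)
    pts = cells.points()
    tree = STRtree(pts)
    near_idx = tree.query(near_zone, predicate="dwithin", distance=margin)
    mask = np.ones(len(pts), dtype=bool)
    mask[near_idx] = False
    return mask


def band_totals(
    counts: Mapping[Interval, float], band_edges: Sequence[Interval]
) -> dict[Interval, float]:
    """Aggregate fine-interval counts into reporting bands.

    Every fine interval must nest inside exactly one band; an interval that
    straddles a band edge is an error.
    """
    out: dict[Interval, float] = {b: 0.0 for b in band_edges}
    for (lo, hi), v in counts.items():
        homes = [b for b in band_edges if b[0] <= lo and hi <= b[1]]
        if not homes:
            raise ValueError(f"interval ({lo}, {hi}] straddles the band edges")
        out[homes[0]] += v
    return out


def tabulate(
    assignments: Sequence[Interval],
    cells: PopulationCells,
    units: Sequence[AdminUnit],
    level: str = "country",
    aggregate_bands: Sequence[Interval] | None = None,
    rounded: bool = True,
) -> pd.DataFrame:
    """Population per driving-time band for each country / region / unit.

    Returns one row per grouping key with, per band, a count column
    (label) and a percentage column (``pct <label>``), plus ``total``.
    With ``rounded`` (default) counts are half-up integers and percentages
    half-up two-decimals computed from the *unrounded* sums; pass
    ``rounded=False`` for the raw real-valued table.
    """
    if level not in ("country", "region", "unit"):
        raise ValueError(f"unknown level {level!r}")
    key_of = {
        u.id: {"country": u.country_id, "region": u.region_id, "unit": u.id}[level]
        for u in units
    }
    frame = cells.frame
    keys = frame["unit_id"].map(key_of)
    intervals = pd.Series(assignments, index=frame.index)
    if aggregate_bands is not None:
        mapping: dict[Interval, Interval] = {}
        for iv in set(assignments):
            mapping[iv] = next(b for b in aggregate_bands if b[0] <= iv[0] and iv[1] <= b[1])
        intervals = intervals.map(mapping)
        columns = sorted(set(aggregate_bands))
    else:
        columns = sorted(set(assignments))
    sums = (
        pd.DataFrame({"key": keys, "band": intervals, "population": frame["population"]})
        .groupby(["key", "band"], sort=True)["population"]
        .sum()
        .unstack(fill_value=0.0)
    )
    all_keys = sorted({key_of[u.id] for u in units})
    sums = sums.reindex(index=all_keys, columns=pd.Index(columns), fill_value=0.0)
    out = pd.DataFrame(index=sums.index)
    totals = sums.sum(axis=1)
    for band in columns:
        label = interval_label(band)
        n = sums[band]
        pct = np.where(totals > 0, 100.0 * n / totals.replace(0, np.nan), 0.0)
        if rounded:
            out[label] = [int(round_half_up(v)) for v in n]
            out[f"pct {label}"] = [round_half_up(v, 2) for v in pct]
        else:
            out[label] = n
            out[f"pct {label}"] = pct
    out["total"] = (
        [int(round_half_up(v)) for v in totals] if rounded else totals
    )
    out.index.name = level
    return out


def fine_interval_table(
    counts: Mapping[Interval, float], band_edges: Sequence[Interval]
) -> pd.DataFrame:
    """National fine-interval table with per-band subtotal rows and a total.

    ``counts`` maps fine intervals to (possibly real-valued) populations.
    Rows follow the reporting layout: each band's fine intervals, then a
    ``Subtotal`` row for the band, and a closing ``Total`` row. Counts are
    printed half-up as whole persons; percentages half-up at two decimals,
    always from the unrounded sums.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts sum to zero; nothing to tabulate")
    grouped = band_totals(counts, band_edges)
    rows = []
    for band in band_edges:
        members = sorted((iv for iv in counts if band[0] <= iv[0] and iv[1] <= band[1]))
        for iv in members:
            rows.append(
                {"row": interval_label(iv),
                 "n": int(round_half_up(counts[iv])),
                 "pct": round_half_up(100.0 * counts[iv] / total, 2)}
            )
        if len(members) > 1:
            rows.append(
                {"row": f"Subtotal {interval_label(band)}",
                 "n": int(round_half_up(grouped[band])),
                 "pct": round_half_up(100.0 * grouped[band] / total, 2)}
            )
    rows.append({"row": "Total", "n": int(round_half_up(total)), "pct": 100.00})
    return pd.DataFrame(rows)


def equity_summary(
    band_counts: Mapping[Interval, float], threshold: float
) -> tuple[float, float]:
    """(count, percent) of the population living beyond ``threshold`` minutes.

    ``threshold`` must coincide with a band edge; the summary is the sum of
    all bands at or beyond it (e.g. threshold 30 -> 30-60 plus every slower
    band). Percent is half-up two decimals of the grand total.
    """
    edges = sorted({lo for lo, _ in band_counts})
    if threshold not in edges:
        raise ValueError(f"threshold {threshold} is not a band edge (edges: {edges})")
    total = sum(band_counts.values())
    beyond = sum(v for (lo, _), v in band_counts.items() if lo >= threshold)
    pct = round_half_up(100.0 * beyond / total, 2) if total > 0 else 0.0
    return beyond, pct
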