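"""End-to-end orchestration: inputs -> catchments -> allocation -> tables.

:func:`analyze_country` runs the whole analysis in memory on loaded (or
generated) inputs; :func:`run` wraps it with file IO, validation, provenance
and the report bundle (band polygons, surface-coverage table, national
fine-interval table, regional tables, conservation report). A failed stage
removes any partial outputs so a run directory is either complete or absent.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field as dataclass_field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

import careshed
from careshed._util import Interval, interval_label, parse_interval_label
from careshed.catchment import (
    BandSet,
    CutoffScheme,
    DEFAULT_BAND_EDGES,
    DEFAULT_BUFFER_WIDTH,
    DEFAULT_CUTOFFS,
    build_rings,
    merge_bands,
    surface_coverage,
)
from careshed.dasymetric import (
    AdminUnit,
    ImperviousGrid,
    PopulationCells,
    allocate_population,
    builtup_mask,
    conservation_report,
)
from careshed.io import read_geojson, read_raster, write_geojson, write_raster
from careshed.road_network import (
    DEFAULT_SNAP_TOLERANCE,
    RoadNetwork,
    ServicePoint,
    load_network,
    snap_service,
    travel_times_to_nearest_service,
)
from careshed.synth import CountrySpec, SynthCountry, generate_country, ground_truth_bands
from careshed.tabulation import (
    assign_bands,
    band_totals,
    equity_summary,
    fine_interval_table,
    tabulate,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Either the four input paths are set, or ``synth_seed`` requests a
    generated country. Band edges must be drawn from the cut-off list; the
    final band is always open-ended.
    """

    network_path: str | None = None
    services_path: str | None = None
    units_path: str | None = None
    population_path: str | None = None
    raster_path: str | None = None
    synth_seed: int | None = None
    synth_options: dict = dataclass_field(default_factory=dict)
    out_dir: str = "careshed_out"
    cutoffs: Sequence[float] = tuple(DEFAULT_CUTOFFS)
    band_edges: Sequence[Interval] = tuple(DEFAULT_BAND_EDGES)
    buffer_width: float | None = None  # None: 200 m, or grid-aware for synth
    snap_tolerance: float = DEFAULT_SNAP_TOLERANCE
    builtup_threshold: float = 0.0
    assignment_mode: str = "polygon"
    speed_field: str = "speed"
    default_speed: float | None = None

    def scheme(self) -> CutoffScheme:
        return CutoffScheme(tuple(float(c) for c in self.cutoffs),
                            tuple((float(lo), float(hi)) for lo, hi in self.band_edges))

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        if "band_edges" in doc:
            doc["band_edges"] = [
                (float(lo), math.inf if hi in ("inf", "Infinity") else float(hi))
                for lo, hi in doc["band_edges"]
            ]
        return cls(**doc)


def suggested_buffer_width(spec: CountrySpec) -> float:
    """Catchment buffer that closes the gaps of the synthetic road grid.

    55% of the grid spacing: wide enough that buffered roads tile the blocks
    between them (no artificial unreachable holes), narrow enough to keep
    rings local. Real road data keeps the 200 m default.
    """
    spacing = max(spec.extent) / max(spec.grid_n - 1, 1)
    return max(DEFAULT_BUFFER_WIDTH, round(0.55 * spacing))


def validate_config(config: RunConfig) -> list[str]:
    """Issues preventing a run; empty list when runnable."""
    issues: list[str] = []
    if config.synth_seed is None:
        for name in ("network_path", "services_path", "units_path",
                     "population_path", "raster_path"):
            p = getattr(config, name)
            if p is None:
                issues.append(f"{name}: not set and no synth_seed requested")
            elif not os.path.exists(p):
                issues.append(f"{name}: {p} does not exist")
    try:
        config.scheme()
    except ValueError as exc:
        issues.append(f"cutoffs/band_edges: {exc}")
    if config.buffer_width is not None and config.buffer_width <= 0:
        issues.append("buffer_width: must be positive")
    if config.snap_tolerance <= 0:
        issues.append("snap_tolerance: must be positive")
    if not 0 <= config.builtup_threshold <= 100:
        issues.append("builtup_threshold: must lie in [0, 100]")
    if config.assignment_mode not in ("polygon", "direct"):
        issues.append(f"assignment_mode: unknown mode {config.assignment_mode!r}")
    return issues


@dataclass
class AnalysisResult:
    """Everything one analysis computes, before any file is written."""

    network: RoadNetwork
    services: list[ServicePoint]
    field: dict[str, float]
    scheme: CutoffScheme
    buffer_width: float
    fine_bandset: BandSet
    report_bandset: BandSet
    units: list[AdminUnit]
    grid: ImperviousGrid
    cells: PopulationCells
    assignments: list[Interval]
    conservation: pd.DataFrame

    def country_counts(self) -> dict[Interval, float]:
        """Unrounded national population per fine interval."""
        table = tabulate(self.assignments, self.cells, self.units,
                         level="country", rounded=False)
        out: dict[Interval, float] = {}
        for iv in self.scheme.fine_intervals():
            label = interval_label(iv)
            out[iv] = float(table[label].sum()) if label in table else 0.0
        return out

    def national_table(self) -> pd.DataFrame:
        return fine_interval_table(self.country_counts(), list(self.scheme.band_edges))

    def regional_table(self) -> pd.DataFrame:
        return tabulate(self.assignments, self.cells, self.units, level="region",
                        aggregate_bands=list(self.scheme.band_edges))

    def surface_table(self) -> pd.DataFrame:
        return surface_coverage(self.report_bandset)

    def beyond(self, threshold: float) -> tuple[float, float]:
        bands = band_totals(self.country_counts(), list(self.scheme.band_edges))
        return equity_summary(bands, threshold)


def analyze_country(
    network: RoadNetwork,
    services: list[ServicePoint],
    units: list[AdminUnit],
    grid: ImperviousGrid,
    study_area,
    scheme: CutoffScheme | None = None,
    buffer_width: float = DEFAULT_BUFFER_WIDTH,
    snap_tolerance: float = DEFAULT_SNAP_TOLERANCE,
    builtup_threshold: float = 0.0,
    mode: str = "polygon",
) -> AnalysisResult:
    """Run the full analysis in memory.

    Stages: snap services -> travel-time field -> isochrone rings at the
    fine cut-offs -> fine and reporting band sets -> built-up mask ->
    dasymetric allocation (conservation-checked) -> band assignment.
    Assignments are at fine-interval granularity; tables aggregate them.
    """
    scheme = scheme or CutoffScheme()
    snapped = [snap_service(network, s, snap_tolerance) for s in services]
    field = travel_times_to_nearest_service(network, snapped)
    logger.info("snapped %d services; %d/%d nodes reachable",
                len(snapped), len(field), len(network.nodes))
    rings = build_rings(network, field, scheme, buffer_width)
    fine_edges = tuple(scheme.fine_intervals())
    fine_scheme = CutoffScheme(scheme.cutoffs, fine_edges)
    fine_bandset = merge_bands(rings, fine_scheme, study_area)
    report_bandset = merge_bands(rings, scheme, study_area)
    mask = builtup_mask(grid, builtup_threshold)
    cells = allocate_population(units, grid, mask)
    conservation = conservation_report(cells, units, strict=True)
    logger.info("allocated %.0f people over %d cells", cells.total, len(cells.frame))
    assignments = assign_bands(cells, fine_bandset, mode=mode,
                               network=network, field=field)
    return AnalysisResult(network, snapped, dict(field), scheme, buffer_width,
                          fine_bandset, report_bandset, units, grid, cells,
                          assignments, conservation)


def analyze_synthetic(
    spec: CountrySpec,
    scheme: CutoffScheme | None = None,
    buffer_width: float | None = None,
    mode: str = "polygon",
    builtup_threshold: float = 0.0,
) -> AnalysisResult:
    """Generate a synthetic country and analyze it (grid-aware buffer default)."""
    country = generate_country(spec)
    return analyze_country(
        country.network, country.services, country.units, country.grid,
        country.study_area(), scheme=scheme,
        buffer_width=buffer_width if buffer_width is not None else suggested_buffer_width(spec),
        mode=mode, builtup_threshold=builtup_threshold,
    )


def _load_units(units_path: str, population_path: str) -> list[AdminUnit]:
    feats, _ = read_geojson(units_path)
    pop = pd.read_csv(population_path, dtype={"unit_id": str})
    required = {"unit_id", "population", "region_id"}
    missing = required - set(pop.columns)
    if missing:
        raise ValueError(f"{population_path}: missing columns {sorted(missing)}")
    by_id = pop.set_index("unit_id")
    units = []
    for geom, props in feats:
        uid = str(props.get("unit_id", props.get("id")))
        if uid not in by_id.index:
            raise ValueError(f"unit {uid!r} has no population row")
        row = by_id.loc[uid]
        units.append(AdminUnit(
            id=uid,
            name=str(row.get("region_name", props.get("name", uid))),
            region_id=str(row["region_id"]),
            country_id=str(row.get("country_id", "ALL")),
            geometry=geom,
            population=int(row["population"]),
        ))
    return units


def _load_services(path: str) -> list[ServicePoint]:
    if path.endswith(".csv"):
        df = pd.read_csv(path)
        return [ServicePoint(str(r.id), float(r.x), float(r.y)) for r in df.itertuples()]
    feats, _ = read_geojson(path)
    return [
        ServicePoint(str(props.get("id", i)), geom.x, geom.y)
        for i, (geom, props) in enumerate(feats)
    ]


def run(config: RunConfig) -> dict[str, str]:
    """Execute a configured run and write the report bundle.

    Returns a mapping of artifact name to path. Any stage failure removes
    partial outputs and re-raises with the stage name.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    os.makedirs(config.out_dir, exist_ok=True)
    written: list[str] = []
    stage = "setup"

    def path_of(name: str) -> str:
        p = os.path.join(config.out_dir, name)
        written.append(p)
        return p

    try:
        stage = "load inputs"
        scheme = config.scheme()
        if config.synth_seed is not None:
            opts = dict(config.synth_options)
            if "extent" in opts:
                opts["extent"] = tuple(opts["extent"])
            spec = CountrySpec(seed=config.synth_seed, **opts)
            country = generate_country(spec)
            network, services = country.network, country.services
            units, grid = country.units, country.grid
            study_area = country.study_area()
            buffer_width = (config.buffer_width if config.buffer_width is not None
                            else suggested_buffer_width(spec))
        else:
            network = load_network(config.network_path, config.speed_field,
                                   config.default_speed)
            services = _load_services(config.services_path)
            units = _load_units(config.units_path, config.population_path)
            values, ox, oy, cell, _ = read_raster(config.raster_path)
            grid = ImperviousGrid(values, ox, oy, cell)
            from shapely.ops import unary_union

            study_area = unary_union([u.geometry for u in units])
            buffer_width = (config.buffer_width if config.buffer_width is not None
                            else DEFAULT_BUFFER_WIDTH)

        stage = "analysis"
        result = analyze_country(
            network, services, units, grid, study_area, scheme=scheme,
            buffer_width=buffer_width, snap_tolerance=config.snap_tolerance,
            builtup_threshold=config.builtup_threshold, mode=config.assignment_mode,
        )

        stage = "write outputs"
        bands_features = [
            (geom, {"lo": lo, "hi": None if math.isinf(hi) else hi})
            for (lo, hi), geom in result.report_bandset.bands
        ]
        lo_res, _ = result.report_bandset.residual_interval
        bands_features.append((result.report_bandset.residual, {"lo": lo_res, "hi": None}))
        write_geojson(path_of("bands.geojson"), bands_features, network.crs_tag)
        result.surface_table().to_csv(path_of("surface_coverage.csv"), index=False)
        result.national_table().to_csv(path_of("table_country.csv"), index=False)
        result.regional_table().to_csv(path_of("table_regions.csv"))
        result.conservation.to_csv(path_of("conservation.csv"), index=False)
        provenance = {
            "config": {k: (str(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
            "versions": _versions(),
            "n_services_snapped": len(result.services),
            "n_cells": int(len(result.cells.frame)),
            "total_population": result.cells.total,
        }
        with open(path_of("provenance.json"), "w") as fh:
            json.dump(provenance, fh, indent=2, default=str)
            fh.write("\n")
    except Exception:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        logger.error("pipeline failed at stage %r; partial outputs removed", stage)
        raise
    return {os.path.basename(p): p for p in written}


def _versions() -> dict[str, str]:
    import networkx
    import numpy
    import pandas
    import scipy
    import shapely

    return {
        "careshed": careshed.__version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "shapely": shapely.__version__,
        "networkx": networkx.__version__,
    }


def write_synth_inputs(spec: CountrySpec, out_dir: str) -> dict[str, str]:
    """Materialize a synthetic country as the pipeline's file formats.

    Writes network.geojson, units.geojson, population.csv, impervious.tif
    (with .tfw sidecar), services.geojson and truth.csv (the independent
    oracle band of every built-up cell).
    """
    os.makedirs(out_dir, exist_ok=True)
    country = generate_country(spec)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    feats = [(e.geometry, {"speed": e.speed, "oneway": e.oneway})
             for e in country.network.edges]
    write_geojson(p("network.geojson"), feats, country.network.crs_tag)
    write_geojson(
        p("units.geojson"),
        [(u.geometry, {"unit_id": u.id, "name": u.name}) for u in country.units],
        country.network.crs_tag,
    )
    pd.DataFrame(
        [{"unit_id": u.id, "population": u.population, "region_id": u.region_id,
          "region_name": u.region_id, "country_id": u.country_id}
         for u in country.units]
    ).to_csv(p("population.csv"), index=False)
    write_raster(p("impervious.tif"), country.grid.values, country.grid.origin_x,
                 country.grid.origin_y, country.grid.cell_size)
    paths["impervious.tfw"] = os.path.join(out_dir, "impervious.tfw")
    from shapely.geometry import Point

    write_geojson(
        p("services.geojson"),
        [(Point(s.x, s.y), {"id": s.id}) for s in country.services],
        country.network.crs_tag,
    )
    snapped = [snap_service(country.network, s) for s in country.services]
    mask = builtup_mask(country.grid)
    cells = allocate_population(country.units, country.grid, mask)
    truth = ground_truth_bands(spec, country.network, snapped, cells)
    frame = cells.frame[["x", "y", "unit_id", "population"]].copy()
    frame["band"] = [interval_label(iv) for iv in truth]
    frame.to_csv(p("truth.csv"), index=False)
    return paths
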