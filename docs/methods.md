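# Methods

`careshed` estimates a population's *potential* geographic accessibility to
specialized palliative care: for every inhabited place, the driving time to
the nearest provider over a road network, summarized as the population and
surface share of driving-time bands (0–30, 30–60, 60–90, over 90 minutes)
nationally and per region.

## Travel-time model

The road network is a directed graph. Each edge carries a travel time
derived from its length and a free-flow speed,

    t_edge = (length_m / 1000) / speed_kmh * 60   [minutes],

with no turn penalties, signals, traffic profiles or time-of-day effects.
Patients drive *to* the provider, so the travel-time field
`t(n) = min_s shortestpath(n -> s)` is computed as one multi-source Dijkstra
pass over the reversed graph from all service nodes simultaneously; the
minimum over providers is what dissolves per-provider catchments into a
single field. On two-way edges the direction convention is unobservable; it
matters only for one-way streets. Unreachable nodes are *absent* from the
field rather than carrying an infinity, so no arithmetic can silently use
them.

Services join the network by snapping to the nearest node (default
tolerance 5000 m; a provider farther than that from any road is treated as
a data error). Snapping is node-based, not edge-splitting: it is exactly
reproducible and errs by at most half an edge length, which is well below
one band width at the edge lengths used here.

## Catchment polygons, rings and bands

Drive-time cut-offs default to 10, 20, 30, 40, 50, 60 and 90 minutes. The
reachable region for a cut-off is polygonized by buffering every road
portion reachable within it — including the *partial* prefix of a boundary
edge, cut by linear interpolation of travel time along the edge — plus a
disc at every reachable node. Rings are set differences of successive
reachable polygons; reporting bands union consecutive rings and are clipped
to the study area, whose uncovered remainder is the residual (over-90 /
off-network) band. Intervals are half-open `(lo, hi]`: a location at
exactly 30 minutes counts as within 30.

Numerical choices:

* buffer width defaults to 200 m per side; for the synthetic road grid the
  pipeline widens it to 55% of the grid spacing so that buffered roads tile
  the blocks between them instead of leaving artificial unreachable holes;
* output coordinates snap to a 1 mm grid (`set_precision`) to stabilize the
  set operations;
* buffer arcs use 16 segments per quadrant. Consequently *nesting* of
  reachable polygons across cut-offs holds up to slivers bounded by the arc
  sagitta `r·(1 − cos(π/64))` times the perimeter (≈10⁻⁸ of the area at the
  scales used); rings and bands, built by explicit set difference, are
  disjoint and partition the study area to 10⁻⁶ relative regardless.

Known limitation: along a dead-end stub shorter than the buffer width whose
travel time crosses a cut-off, the faster band's round buffer cap swallows
the slower stub, so a small number of cells (≈0.02% in synthetic sweeps)
classify one band faster geometrically than by node lookup. This is the
usual overestimation of buffer-extrapolated service areas; the `direct`
assignment mode (below) is the reference against it.

## Dasymetric population allocation

Each administrative unit's census population is spread **evenly** over the
built-up raster cells whose centroids fall inside the unit. Built-up means
imperviousness density strictly above a threshold (default 0 on a 0–100
scale, i.e. any sealed surface); imperviousness marks where people can
live, not how many per sealed square metre, hence the uniform split. A
density-weighted split exists behind a flag. Cell membership is by centroid
(deterministic at 20 m resolution; boundary cells are not area-split), with
contested centroids going to the smallest-area unit.

Fallbacks keep conservation exact: a unit with no built-up cell spreads its
population over *all* its cells; a unit containing no cell centroid at all
puts it on the single cell nearest its geometric centroid (both logged).
Allocations stay real-valued until reporting. A conservation report
recomputes per-unit sums independently and aborts the pipeline beyond 10⁻⁹
relative error.

## Tabulation and rounding

Cells are assigned to bands either geometrically (`polygon`: innermost band
polygon covering the centroid, lower band winning on shared boundaries) or
directly (`direct`: band of the travel time at the nearest road node;
unreachable → residual). Direct mode is the oracle for polygon mode; the
two agree on cells whose centroids keep clear of band boundaries (tested at
a margin of twice the buffer width).

Band populations are summed unrounded; printed tables round counts half-up
to whole persons and percentages half-up to two decimals, always computed
from the unrounded sums. Because each printed row is rounded independently,
a printed subtotal can differ by up to half a person per member row from
the sum of printed rows, and a percentage pair recomputed from rounded
counts can differ by ±0.01 from the printed one; table-arithmetic tests use
exactly these slacks. The published national tables for Ireland, Spain and
Switzerland ship with the package and are re-derived through the same
operations as a worked check of the arithmetic (two quirks of the source —
one-person subtotal offsets and a Spain total that differs between its
national and regional tables — are kept as printed).

## Synthetic countries

The generator produces all four inputs with known ground truth from a
single seed (independent named RNG streams, so adding a stage never
reshuffles earlier draws):

* **Road network**: an n×n grid (default 30×30 over 24×24 km, 828 m
  spacing) with every 6th line a faster class (30 vs 15 km/h — deliberately
  slow so that the default cut-offs produce several occupied bands inside a
  small extent); 5% of edges are deleted where removal keeps the grid
  connected, as a barrier/relief analogue.
* **Admin units**: Voronoi cells of 25 seeded sites (so unit/cell
  intersections are irregular), grouped into 5 regions by proximity;
  populations are one multinomial draw of the 100 000 total with weights
  decaying with distance from settlement centers (2 km scale), conserving
  the total exactly.
* **Imperviousness**: 20 m raster, density `100·exp(−d/300 m)` to the
  nearest of 5 settlement centers, floored below 1%, with seeded Gaussian
  noise on settled cells plus a 0.3% speckle of isolated rural cells.
* **Services**: placed at the sites of the most populous units
  (rank-nested, so k=1 services are a subset of k=3), mirroring providers
  concentrating in populated areas.

An independent oracle recomputes each cell's band by a disjoint route
(scipy sparse-graph Dijkstra per service with an explicit minimum, plus
brute-force nearest-node scan) and must agree with the pipeline's direct
mode cell for cell.

What the generator does **not** emulate: real road hierarchies and travel
speeds, coastline/relief geometry, heterogeneous unit sizes of real
censuses, multi-floor density, or geocoding error. Passing tests therefore
demonstrate the correctness of the *computation* (shortest paths,
geometry, conservation, arithmetic) and the qualitative
population-vs-surface pattern, not calibration to any real country.

Problem sizes: the study fixture (seed 17, defaults above) yields ~900
nodes, ~1700 edges and ~60 000 built-up cells and runs in a few seconds;
multi-seed sweeps (conservation, partition) use a reduced country (6×6 km,
10×10 grid, 8 units, 50 m cells, 10 000 people) so ten seeds stay within
seconds. Both sizes are the package's own choice of test scale; every
stated property is scale-free.

## Reproducibility

Every random draw derives from the user seed. Reruns with an identical
configuration produce byte-identical tables; the report bundle includes a
provenance record (configuration, library versions, seed) and no
timestamps.
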