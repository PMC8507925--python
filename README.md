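# careshed

**Drive-time accessibility of populations to specialized palliative care.**

`careshed` answers a health-planning question: *what share of a country's
population lives within a reasonable drive of a specialized palliative care
provider, and where do the gaps concentrate?* It is written for health
geographers, palliative-care planners and epidemiologists who have (1) a
road network with speeds, (2) geolocated providers, (3) small-area census
populations and (4) an imperviousness (built-up density) raster — and who
want reproducible national and regional tables of population per
driving-time band rather than a one-off desktop-GIS exercise.

## Method

For a set of providers *S* on a travel-time-weighted road graph, every node
*n* gets the driving time to its nearest provider,

&nbsp;&nbsp;&nbsp;&nbsp;*t(n) = min<sub>s∈S</sub> d(n, s)*,&nbsp;&nbsp;
*d* = shortest-path minutes with edge time = length/speed,

computed in one multi-source Dijkstra pass on the reversed graph (the
minimum over providers dissolves per-provider catchments). Reachable road
portions — including partial edges, cut by linear interpolation — are
buffered and differenced into isochrone **rings** at cut-offs 10, 20, 30,
40, 50, 60, 90 min, then merged into reporting **bands** 0–30, 30–60,
60–90, >90 (half-open: exactly 30 min counts as within 30).

Population is placed by **dasymetric mapping**: each census unit's count is
split evenly over the built-up raster cells (imperviousness > 0) inside it,
so people sit where the built environment is rather than uniformly over
administrative polygons. Allocation conserves every unit's census count to
10⁻⁹ relative and the pipeline aborts otherwise. Cells are intersected with
the bands (geometrically, or via the travel time at the nearest node, which
serves as the oracle for the geometric route) and tabulated per band ×
region: counts half-up to whole persons, percentages half-up to two
decimals from the unrounded sums.

A seeded synthetic-country generator (road grid with a fast sub-grid and
barrier gaps, Voronoi census units, settlement-clustered populations and
imperviousness, services in the most populous units) provides full inputs
with known ground truth, so the entire pipeline is testable offline. See
`docs/methods.md` for model details, parameter defaults and limitations.

## Worked example

```python
from careshed.pipeline import analyze_synthetic
from careshed.synth import CountrySpec

result = analyze_synthetic(CountrySpec(seed=17))   # 24x24 km, 100k people
print(result.national_table().to_string(index=False))
```

```
           row      n    pct
          0-10  56965  56.96
         10-20  26495  26.49
         20-30  13076  13.08
 Subtotal 0-30  96536  96.54
         30-40   2773   2.77
         40-50    660   0.66
         50-60     31   0.03
Subtotal 30-60   3464   3.46
         60-90      0   0.00
       over 90      0   0.00
         Total 100000 100.00
```

96.5% of the synthetic population lives within 30 minutes of one of its
three services, but only 80.2% of the *surface* does
(`result.surface_table()`) — the signature pattern of services located in
populated places. `result.beyond(30.0)` returns the equity headline: 3 464
people (3.46%) beyond a 30-minute drive. `result.regional_table()` breaks
the same counts down by region; region `r00` has 73.8% of its people beyond
30 minutes, the kind of sub-national gap the national figure hides.

The same analysis runs from files through the CLI:

```bash
careshed synth --seed 17 --out country/        # write the inputs as files
careshed run --config run.toml                 # catchments -> tables bundle
careshed tabulate --synth-seed 17 --level region --bands 30,60
careshed validate --config run.toml
```

`careshed run` writes band polygons (GeoJSON), a surface-coverage table, the
national fine-interval table, regional tables, a conservation report and a
provenance record; reruns are byte-identical.

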