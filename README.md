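# driftshift

Tools for measuring how wintering waterfowl distributions shift around
extreme winter weather using citizen-science checklist data, with GPS
telemetry as the validation yardstick.

Late winter pits two pressures against each other: photoperiod cues *pull*
ducks and geese northward toward spring staging, while severe cold snaps —
polar-vortex outbreaks that freeze wetlands and bury food under snow — can
*push* them back south. Continuous citizen-science data streams (eBird-style
checklists) make it possible to watch continental distributions respond to a
single event at weekly resolution, something planned surveys cannot do.
`driftshift` packages that analysis end to end for seven wintering waterfowl
species (Mallard, Green-winged Teal, Gadwall, Northern Pintail, Northern
Shoveler, Greater White-fronted Goose, Snow Goose), grouped into three
foraging guilds: generalists, grubbing/browsing geese, and wetland obligates.

## What it computes

1. **Effort filtering.** Checklists are semi-structured; effort metadata is
   filtered to control detection bias: complete checklists only; stationary
   protocols or traveling < 5 km; one record per unique (latitude,
   longitude, date); ≤ 10 observers; no group-duplicated checklists; ≤ 5 h
   duration — with a per-rule attrition audit.
2. **Shift statistic.** For each species × year × scope (continent, flyway,
   or a latitude band), the abundance-weighted mean position ("center of
   mass") of positive counts is computed for an early window (Jan 1–Feb 6)
   and a late window (Feb 7–28). The response is the great-circle distance
   between the two centroids (sphere radius 6371.0088 km), signed by the
   north–south direction of the move:

   Δᵢⱼ = ± hav(c_early, c_late)  (km, + north)

3. **Severe-February classification.** A February is severe when temperature
   anomalies ≤ −4 °C cover strictly more than 15 % of the conterminous US
   (cell-count or area-weighted on a masked grid).
4. **Hierarchical shift model.** Shifts are modeled as

   Δᵢⱼ = β₀ + α_year(i) + β_strategy + β_ECE + β_strategy×ECE + εᵢⱼ,
   α_year ~ N(0, σ²_year), ε ~ N(0, σ²_ε)

   with dummy coding (reference: generalist in a non-event year), vague
   normal(0, 2.5) priors on the standardized-response scale, and half-normal
   priors on the scales. The posterior is sampled by a blocked Gibbs sampler
   (3 chains; convergence accepted at split-R̂ ≤ 1.10) and summarised as
   estimated marginal medians with 66 % / 95 % credible intervals per
   strategy × event cell.
5. **Validation.** The same centroid machinery applies to GPS fix streams,
   so eBird-derived shifts can be compared against independently tracked
   birds (|Δ_eBird − Δ_GPS|).

Synthetic-data generators (checklists with injected rule violations, GPS
streams with realistic deployment imbalance, flyway polygons, anomaly grids
with exact cold-cell counts, and shift records drawn from the model itself)
provide known ground truth for every stage.

## Worked example

Simulate shift records from known effects (generalist non-event mean 143 km,
event main effect −85 km, 100 records per cell across 2009–2021 with three
severe years), fit the model, and summarise:

```python
from driftshift import (SimConfig, gen_shift_dataset, fit_shift_model,
                        ModelSpec, marginal_medians)
from driftshift.model import check_convergence

cfg = SimConfig(seed=8, years=tuple(range(2009, 2022)))
design, truth = gen_shift_dataset(cfg, n_per_cell=100)
draws = fit_shift_model(design, ModelSpec(seed=8))
conv = check_convergence(draws)
print(f"max split-R-hat: {conv.max_rhat:.3f} (converged: {conv.passed})")
print(marginal_medians(draws).round(1).to_string(index=False))
```

Output:

```
max split-R-hat: 1.034 (converged: True)
        strategy   ece  median_km  lo66  hi66  lo95  hi95
      generalist False      144.0 133.8 154.2 120.7 165.3
      generalist  True       94.1  77.0 111.7  55.3 132.2
        grubbing False      182.6 172.7 192.7 159.9 204.3
        grubbing  True        9.3  -7.6  27.0 -29.0  46.8
wetland_obligate False       62.2  52.0  71.9  39.0  83.9
wetland_obligate  True       10.4  -7.0  28.3 -28.5  48.0
```

The generalist non-event cell recovers the true 144 ≈ 143 km; every guild's
northward shift collapses in event years (e.g. grubbing geese: 182.6 km
north in ordinary years vs. ~9 km — statistically indistinguishable from
staying put — under a severe February), mirroring the push–pull reading:
severe weather stalls, rather than reverses, the pre-migratory drift north.

The same workflow runs from the shell against files:

```bash
driftshift run --config run.yaml --out results/
# or stage by stage:
driftshift filter --in ebd.tsv --out filtered.tsv --report report.json
driftshift centroids --in filtered.tsv --flyways flyways.geojson --out shifts.csv
driftshift classify --grid 2021 anomaly_2021.nc --out labels.json
driftshift fit --shifts shifts.csv --labels labels.json --analysis severe_feb --out posterior.json
driftshift report --posterior posterior.json --out cells.csv
```

`run` writes a `manifest.json` recording every stage's input/output content
hashes and the seed, so a run is fully reproducible.

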