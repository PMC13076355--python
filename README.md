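# lfmove

Analysis of animal telemetry around linear landscape features (roads, foot
trails, roadside buffers, powerline clear cuts): trajectory-randomization
null models with a percentile crossing statistic, step selection functions
with relative selection strength, and hurdle / context-dependent movement
models — plus a ground-truth simulator so the whole pipeline is testable
without field data.

## What it does

- **geometry** — planar primitives in projected meters: transversal
  crossing counts, boundary-inclusive polygon occupancy, minimum convex
  polygons, unions, buffers, rigid path transforms, GeoJSON layer I/O.
- **trajectory** — the relocation-averaging field protocol (sub-meter
  movements collapse onto the previous location; paired GPS readings within
  3 m are averaged) and per-animal-year trajectories with step sequences.
- **nullpaths** — 1000 randomized copies of each annual path (rotation
  about the start, or random start + rotation inside the study area),
  sex-pooled feature tallies, the mid-rank percentile statistic `P`, and
  leave-one-individual-out cross-validation.
- **ssf** — choice sets of one realized step plus 10 random available steps
  (gamma lengths, uniform turns), binary feature covariates, the exact
  conditional-logistic maximizer, an independent Poisson-reformulation
  route with per-stratum intercepts, Laplace-approximate individual random
  slopes, and RSS = exp(beta).
- **movement_models** — sex-specific gamma hurdle model (move probability
  and step length with animal random intercepts) and binomial
  context-dependent movement models, with the odds / probability transforms
  used for reporting.
- **synthetic_data** — landscapes and telemetry with known parameters;
  the simulator's choice rule is exactly the likelihood the SSF fitter
  maximizes, so parameter-recovery tests close the loop.
- **cli** — file-based pipeline: `simulate`, `preprocess`, `nullpaths`,
  `ssf`, `models`, `report`, `all`.

## Command line

```bash
# full pipeline on a simulated dataset
lfmove all --out runs/demo --seed 1

# or stage by stage on your own data
lfmove preprocess --fixes fixes.csv --out runs/mine
lfmove nullpaths --trajectories runs/mine/trajectories.csv \
    --landscape landscape.geojson --n-paths 1000 --seed 1 --out runs/mine
lfmove ssf --trajectories runs/mine/trajectories.csv \
    --landscape landscape.geojson --out runs/mine
lfmove models --trajectories runs/mine/trajectories.csv \
    --landscape landscape.geojson --out runs/mine
```

Relocation input is delimited text with header
`animal_id,sex,timestamp,x,y[,reading_index]` (ISO-8601 timestamps,
projected planar coordinates in meters). Landscape layers are a GeoJSON
FeatureCollection whose features carry a `layer` property with one of the
roles `roads | trails | powerline | road_polygon | road_buffer | boundary`.

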