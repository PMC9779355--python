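# habicon

Habitat suitability modelling and ecological-corridor extraction on raster
landscapes. The package chains a presence-background maximum-entropy
species distribution model with a minimum-cumulative-resistance corridor
analysis, plus land-cover projection and landscape-pattern metrics:

1. **occurrences** — load, de-duplicate, and spatially thin occurrence
   points (greedy seeded thinning, default 100 m).
2. **grids** — raster data model (ESRI ASCII + GeoTIFF I/O, alignment,
   Horn slope/aspect, distance-to-class rasters).
3. **maxent** — variable screening (Pearson |r| threshold with
   contribution-based tie-breaking), L1-regularized maximum-entropy
   fitting by coordinate descent (linear/quadratic/product/hinge/
   categorical features), logistic prediction, replicate AUC evaluation,
   percent contribution, jackknife, response curves.
4. **suitability** — four-class classification (cuts 0.2/0.5/0.7),
   class-area tables, scenario deltas, suitability-weighted habitat
   centroids and centroid shifts.
5. **camarkov** — land-class transition matrices, Markov area projection,
   scenario adjustment, cellular-automata spatial allocation, refreshed
   distance-to-water/grassland layers.
6. **corridors** — five-level resistance schemes (from a fitted model's
   response curves or a packaged table), contribution-weighted resistance
   surfaces, Dijkstra cost distance, least-cost corridors between
   most-suitable source patches.
7. **metrics** — NP, PD, LSI, CONTAG, DIVISION, SHEI landscape metrics.
8. **synthetic** — seeded synthetic landscapes and presence samples with
   known response structure for end-to-end testing.

## CLI

`habicon` exposes the pipeline as composable subcommands:

```bash
# write a ready-to-run synthetic workspace (rasters, points, config)
habicon synth --seed 1 --shape 60,60 -o workspace/

# run the full pipeline from its YAML config
habicon run workspace/config.yaml
```

The run directory contains every intermediate as a standard-format file
(ASCII grids, CSV, GeoJSON, model JSON) and a `manifest.json` with stage
timings, seeds, and output hashes. Individual stages are also available:
`thin`, `screen`, `fit`, `predict`, `classify`, `areas`, `centroid`,
`lucc-project`, `resistance`, `corridors`, `metrics`.

Layer arguments use `NAME=PATH[:kind]`, e.g.
`habicon fit Bio1=bio1.asc LUCC=lucc.asc:categorical --points pts.csv -o model.json`.

## Conventions

- Rasters are square-celled, projected (metres); row 0 is the
  northernmost row; cell centre of `(r, c)` is
  `(x_min + (c+0.5)·cs, y_max − (r+0.5)·cs)`.
- Aspect is the downhill compass direction (degrees clockwise from
  north); flat cells carry the sentinel −1.
- Distance rasters are centre-to-centre Euclidean.
- Suitability classes bin half-open upward: [0,0.2) / [0.2,0.5) /
  [0.5,0.7) / [0.7,1].
- Cost distance uses 8-connectivity with average-resistance step costs
  `d·(R_a+R_b)/2`.
- In scheme files and configs, `DW` is distance to water, `DH` distance
  to high-coverage grassland, `DR` distance to roads (some legacy tables
  reuse "DW" for roads; the loader normalizes names).

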