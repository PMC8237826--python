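# gapmeter

Quantify sampling coverage, bias and gaps in gridded species-occurrence
data.  The package chains:

1. **records** — occurrence-record cleaning (duplicates → coordinate
   precision → study-extent → populated-place centroids → taxonomy) and
   assignment to an equal-area analysis grid (1 km² default).  Coordinate
   precision is judged on the *raw coordinate strings*, so `-46.700` and
   `-46.7` are different inputs to the three-decimal rule.
2. **landscape** — six per-cell metrics from binary habitat/road/urban
   rasters: habitat proportion (moving window), fragment size (log10 ha,
   8-connectivity), functional connectivity (patches ≤ 180 m apart merged,
   log10 ha × 100), vegetation-index homogeneity, and Euclidean distances to
   roads and urban areas.
3. **envspace** — standardized PCA with varimax rotation (2 components),
   binned PC1×PC2 frequency surfaces with shared bin edges, and per-cell
   rarity scores (1 − own-bin frequency / modal frequency).
4. **completeness** — sample-based species accumulation curves (mean over
   random record orderings), Clench-model fits S(t) = a·t/(1+b·t),
   completeness = S_obs/(a/b), and the two-route well-sampled rule
   (> 50 records AND completeness > 0.7, or a trusted local inventory).
5. **coverage** — Schoener's D between the well-sampled and all-cells
   frequency surfaces, a resampling null (uniform redraws of the same number
   of cells, one-sided lower-tail, add-one p), and the coverage-surface
   fraction (occupied bins reached).
6. **spatial** — Average-Nearest-Neighbor analysis with a
   randomize-inside-the-polygon null envelope and a per-site
   aggregated/overdispersed classification.
7. **bias** — tie-corrected Kruskal-Wallis tests of well-sampled cells vs
   all cells on PC axes and rarity, optionally per stratum.
8. **synthetic** — a fully seeded scenario generator (fragmented habitat
   from thresholded Gaussian random fields, autocorrelated climate layers,
   roads/urban masks, logistic climate-driven communities, and surveys whose
   site choice can be biased toward large fragments and accessibility) with
   ground truth for recovery and calibration experiments.

All spatial data live in one planar metric CRS.  Rasters are exchanged as
ESRI ASCII grids, tables as CSV, results as JSON.

## CLI

Every stage runs standalone; `gapmeter all` chains them from one YAML
config:

```sh
gapmeter simulate --config scenario.yaml --out scenario/
gapmeter clean --records records.csv --polygon study.geojson --out cleaned/
gapmeter landscape --habitat habitat.asc --roads roads.asc --urban urban.asc --veg veg.asc --out metrics/
gapmeter envspace --vars metrics/ --out envspace/
gapmeter completeness --records cleaned/cleaned_records.csv --out completeness/
gapmeter coverage --scores envspace/scores.csv --wellsampled ws.csv --out coverage/
gapmeter ann --sites sites.csv --polygon study.geojson --out ann/
gapmeter bias --scores envspace/scores.csv --wellsampled ws.csv --out bias/
gapmeter all --config run.yaml --out run/
```

A minimal `run.yaml` driving a synthetic end-to-end run:

```yaml
seed: 7
scenario: {seed: 7, width: 60, height: 60, n_sites: 40, effort_per_site: 80}
n_bins: 50
null_iters: 1000
ann_iters: 1000
```

Reruns with the same config produce byte-identical `report.json`.

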