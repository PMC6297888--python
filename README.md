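# wildcons

A desk-scale pipeline for computing a "comprehensiveness of conservation of
useful wild plants" indicator: from species/use/country tables and occurrence
records, through presence/background species distribution modeling, to
per-species ex situ / in situ conservation scores and country, regional and
global indicator values. A synthetic-world generator emulates every input
(climate grids, land mask, countries, ecoregions, protected areas, species
with planted niches and deliberately dirty occurrence records) with recorded
ground truth, so the whole pipeline runs and is tested without any downloads.

## Modules

| Module | Role |
| --- | --- |
| `wildcons.core_grid` | lon/lat raster grid, polygons, haversine, point-in-polygon, plain-text raster + GeoJSON I/O |
| `wildcons.taxa` | species/use/country tables; selection of useful wild species; table-driven name standardization |
| `wildcons.occurrences` | G/H record classification, scrubbing (water / non-native / pre-1950), count summaries |
| `wildcons.predictors` | 26-layer eco-geographic stack; Horn-method slope and (cos, sin) aspect components from altitude |
| `wildcons.sdm` | penalized-logistic presence/background model (linear+quadratic features, L1), k-fold AUC validation, max(sens+spec) thresholding, CA50 50-km buffer fallback |
| `wildcons.rasterize` | cell-center and maximum-area polygon-to-raster rules; protected-area status filter; binary PA raster |
| `wildcons.conservation` | SRS/GRS/ERS/FCS scores ex situ and in situ, combined score, priority categories |
| `wildcons.indicator` | native-range scope membership, M49-style scopes, per-scope score aggregation |
| `wildcons.synthgen` | seeded synthetic world + ground truth |
| `wildcons.pipeline` | end-to-end driver |

## CLI

```sh
# generate a synthetic world (all file contracts)
wildcons synthgen make --seed 3 --out world/

# select useful wild species
wildcons taxa select --names world/names.csv --uses world/uses.csv \
    --dist world/distributions.csv --out selected.csv

# scrub occurrences against the land mask and native ranges
wildcons occ scrub --species-dir world/occurrences --mask world/mask.asc \
    --dist world/distributions.csv --out scrubbed/

# assemble the 26-layer predictor stack (derives slope/aspect)
wildcons predictors build --bioclim-dir world/predictors \
    --altitude world/predictors/wc2.0_bio_2.5m_23.asc \
    --solar world/predictors/wc2.0_bio_2.5m_20.asc \
    --wind world/predictors/wc2.0_bio_2.5m_21.asc \
    --vapor world/predictors/wc2.0_bio_2.5m_22.asc --out stack/

# rasterize protected areas (status filter + maximum-area rule, 0/1 output)
wildcons rasterize --rule max-area --polygons world/protected_areas.geojson \
    --like world/mask.asc --wdpa-filter --binary --out pa.asc

# full pipeline on a synthetic world -> scores.csv + indicator.csv
wildcons run --seed 4 --out results/
```

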