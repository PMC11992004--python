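# dendritemp

Temporal β-diversity analysis of bacterial communities in dendritic stream
networks.

## The problem

Rivers are branching (dendritic) networks in which the abiotic environment
changes predictably from headwaters to the mainstem, and where bacterial
dispersal is largely passive and unidirectional. Headwater streams receive
pulsed inputs of soil bacteria from the riparian zone — especially during
rainfall — while downstream reaches integrate immigrants from many upstream
branches. This package implements the statistics needed to ask how a site's
**position in the network** (dendritic distance from the upstream source)
shapes the **temporal** variability of three community types sampled
repeatedly at the same sites: suspended bacteria (bacterioplankton), benthic
biofilm, and riparian soil. It is aimed at microbial ecologists working with
ASV (amplicon sequence variant) count tables from repeated spatial surveys.

## Statistics implemented

For each site *s* and habitat, with samples at occasions *t* = 1…T and
Bray–Curtis dissimilarity d on relative abundances of the rarefied table:

* **Temporal β-diversity (turnover)** — mean dissimilarity across
  consecutive occasions, `β_s = mean_t d(x_t, x_{t+1})`.
* **Temporal distance decay** — the OLS slope of all T(T−1)/2 pairwise
  dissimilarities against elapsed time |Δt| (days by default).
* **Environmental temporal variability** — mean Euclidean distance between
  consecutive occasions on z-scored variable sets (water chemistry:
  pH, TotP, NO₂+NO₃, SUVA; physical: temperature, water level; soil: pH,
  conductivity, TotC, TotN).
* **Network-position regressions** — each site-level statistic regressed on
  dendritic distance; **partial regressions** (residual-on-residual) test
  environmental drivers while controlling for network position.
* **PERMANOVA** (one-way, free label permutation, default 999 permutations)
  and **NMDS** (SMACOF majorization of Kruskal stress-1 with isotonic fits)
  with group-centroid distances in ordination space.
* **Soil–stream linkage** — time-matched Bray–Curtis similarity between
  soil and each aquatic habitat (mean, sd), and **shared-ASV counts** per
  aquatic sample against the soil community's site-level occurrence union,
  with their trend along the network.

A seeded synthetic generator (`dendritemp.synthetic`) produces data sets
with the same design (13 sites over three stream orders, 7 occasions,
3 habitats, multinomial read depths) and known, mechanism-based gradients,
so every stage of the pipeline is validated by parameter recovery.

## Worked example

```sh
dendritemp simulate --seed 1 --out sim/
dendritemp run --asv sim/asv_table.tsv --meta sim/metadata.tsv \
    --env sim/environment.tsv --seed 1 --out results/
```

`results/report.json` from this run contains (abridged):

| quantity | value | reading |
|---|---|---|
| temporal β vs distance, bacterioplankton | slope −0.0202, p = 1.9e−6 | water-column turnover is highest in headwaters and declines downstream |
| temporal β vs distance, biofilm | slope +0.0223, p = 1.2e−11 | biofilm turnover rises downstream |
| temporal β vs distance, soil | slope −0.0057, p = 0.70 | soil turnover has no network signal |
| soil β vs soil-environment variability | R² = 0.92, p < 0.001 | soil communities track their local environment |
| PERMANOVA biofilm vs soil | F = 191.8, p = 0.001 | habitats host distinct communities |
| shared ASVs (soil–plankton) vs distance | slope −11.7 per km | soil taxa wash into headwaters and are gradually lost |
| NMDS stress (273 samples, k = 2) | 0.090 | good 2-D representation |

Mean temporal β for this data set is 0.410 (bacterioplankton), 0.375
(biofilm) and 0.380 (soil). Figures analogous to the standard report views
(solid fit lines for p < 0.05, dashed otherwise) are written to
`results/figures/`.

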