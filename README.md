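# resurvey

Tools for comparing historical and recent species occurrence surveys along
elevation gradients, and for attributing community change to climate
warming.

The package covers the full analysis chain:

- **records** — normalize species names (synonyms, unresolvable species
  complexes), filter occurrence records by explicit quality rules
  (elevation-span limit, required dates, elevation window, period-scoped
  exclusions, a single-nest-excavation heuristic), pool them into
  `year#site#meanElevMSL` sampling units with coarse historical elevation
  bins replicated for the resurvey, and build a binary incidence matrix
  with per-cell provenance.
- **community** — Sørensen dissimilarities, Ward minimum-variance
  clustering (both the direct and squared-dissimilarity variants), tree
  cutting at a fixed height, and crossing of elevation clusters with
  sampling period.
- **ordination** — principal coordinates analysis, distance-based
  constrained ordination (CAP) with permutation ANOVA (whole-model and
  sequential terms), bidirectional stepwise constraint selection,
  Ezekiel-adjusted R², fitted environmental vectors and species scores.
- **stats** — PERMANOVA with sequential sums of squares (plus an exact
  enumeration mode for small n), multivariate homogeneity of group
  dispersions, tie-corrected Kruskal–Wallis tests, and Holm / Bonferroni /
  Benjamini–Hochberg multiplicity adjustment.
- **diversity** — incidence-based Hill numbers (q = 0, 1, 2) with
  rarefaction/extrapolation to twice the sample size, Chao2-type
  undetected richness, sample coverage, bootstrap confidence bands, and
  point estimates at a common size (twice the smallest group).
- **traits** — trait tables with twelve canonical columns, complex-species
  trait averaging, z-scaling, community-weighted means, and between-period
  Kruskal–Wallis comparisons per elevation cluster.
- **climate** — fusion of a coarse long-term monthly temperature grid with
  a fine-resolution grid (patch-style biquadratic regridding, per-cell
  per-month linear bias correction, splice year), four temperature indices
  (annual, summer/winter half-years, spring = March–June), lapse-rate
  downscaling onto a DEM, equivalent-elevation shifts and glacier-change
  summaries.
- **synth** — synthetic occurrence records, trait tables and
  two-resolution climate rasters with known ground truth (Gaussian thermal
  niches, a configurable parasite decline, a known warming offset and
  affine inter-grid bias) for parameter-recovery testing.

## Command-line pipeline

Every stage reads and writes a shared output directory and a flat YAML
config (defaults: 999 permutations, 95% CIs, Ward cut height 1.5,
spring = March–June, gradient −6.68 K/km, elevation window 1100–2899 m):

```bash
resurvey all --config config.yaml --outdir out --seed 1
```

Stages can also be run individually and are re-entrant:
`simulate`, `harmonize`, `cluster`, `ordinate`, `tests`, `diversity`,
`traits`, `climate`. Each stage writes tidy CSV/JSON artifacts plus a
manifest with the config, seeds and input checksums.

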