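# ecogc

Comparative analysis of teleost fish traits across environmental salinity
and migratory lifestyle: routine metabolic rate (MR), specific gill area
(Gill) and genomic GC content (GC%), compared between freshwater/seawater
and migratory/non-migratory groups with rank tests, a bootstrap two-way
factorial ANOVA, a cross-variable convergence test, and a CDS-level
expression-by-GC-bin analysis.

## What it does

- **species_io** — reads delimited species-trait tables, validates them, and
  classifies species into FW/SW (freshwater, freshwater-brackish and
  catadromous vs marine, marine-brackish and anadromous; the diadromous
  migration classes override the habitat descriptor) and M/NM (catadromous,
  potamodromous, amphidromous, oceanodromous, anadromous vs everything else,
  with "no information" meaning non-migratory). Replicate measurements per
  species collapse to the median; a built-in exclusion list drops the nine
  species with conflicting ecology descriptors.
- **metabolic_norm** — Boltzmann temperature correction
  `MR = MR0 * exp(E/(k*T))` with E = 0.65 eV, k = 8.62e-5 eV/K,
  T in kelvin (Celsius + 273.15), followed by ln-normalization.
- **group_stats** — Mann-Whitney tests (exact for small tie-free samples,
  normal approximation with tie/continuity corrections otherwise),
  Bonferroni adjustment, Shapiro-Wilk screening, and an order-level
  pairwise screen for phylogenetic signal.
- **bootstrap_anova** — two-way (salinity x migration) ANOVA via nested
  least squares (Type I/II/III, Type II default for unbalanced data) with a
  pooled-response bootstrap null; `p = #(resampled F > observed F) / B`.
- **convergence** — does one group (e.g. SWM) attain the top median in all
  variables? Closed forms `(1/g)^k` and `g*(1/g)^k` plus a seeded
  label-permutation test.
- **cds_expression** — CDS filtering (>=100 bp, unambiguous, ATG start,
  stop codon, in-frame), GC%, isochore binning at user-supplied cutpoints,
  Kruskal-Wallis across bins and Mann-Whitney between the two main bins.
- **synthetic** — seeded generators for trait tables (four-group structure,
  right-skewed noise, unbalanced cells) and CDS/expression sets with tagged
  rule-violating sequences, for end-to-end testing without any downloads.
- **pipeline** — orchestration with YAML config, per-stage record-count
  audit logging, and JSON/Markdown/TSV reports.

## Input format

Trait tables are UTF-8 TSV (comma accepted) with a header:

| column        | content                                                        |
| ------------- | -------------------------------------------------------------- |
| `species`     | binomial (unique after case/whitespace normalization)          |
| `family`      | family name                                                    |
| `order`       | order name                                                     |
| `salinity`    | `freshwater`, `freshwater-brackish`, `marine`, `marine-brackish` |
| `migration`   | `catadromous`, `potamodromous`, `amphidromous`, `oceanodromous`, `anadromous`, `non-migratory`, or empty |
| `value`       | trait value (mg O2/kg/h for raw MR, cm^2/g for Gill, percent for GC) |
| `temperature` | assay temperature in Celsius (MR tables only)                  |

Column names can be remapped via `column_map` in the run config or the
`columns=` argument of `read_trait_table`. Habitat descriptors outside the
vocabulary above (e.g. bare `brackish`) raise an error by default; extend
the vocabulary explicitly if you want them classified.

## CLI

```sh
ecogc classify --variable gc --in gc.tsv --out gc_classified.tsv
ecogc normalize-mr --in mr.tsv --out mr_norm.tsv
ecogc compare --variable gc --in gc.tsv --split salinity
ecogc compare --variable mr --in mr.tsv --split migration --one-tailed
ecogc phylo-signal --variable gc --in gc.tsv
ecogc anova --variable gc --in gc.tsv --resamples 1000 --seed 42 --ss-type II
ecogc convergence --mr mr.tsv --gill gill.tsv --gc gc.tsv --focal SWM \
    --permutations 10000 --seed 7
ecogc expression --fasta cds.fasta --expr expression.tsv --cutpoints 42,47,52
ecogc simulate traits|cds|suite --seed 1 --out simdir
ecogc run --config config.yaml
```

The isochore GC cutpoints are **required** for the expression analysis:
no numeric limits ship with the package, because the four-class limits
used historically are published only graphically. `42,47,52` in the
examples is a placeholder, not a recommendation.

## Reproducibility notes

- Every stochastic step (bootstrap, permutation test, generators) takes an
  explicit seed; identical config + seed gives identical output.
- The bootstrap resampling scheme (pooled-response, labels fixed) and the
  Type II sums of squares are documented defaults, selectable via
  `--ss-type` / `scheme="residual"`; the strict `>` in the bootstrap
  p-value follows the published formula, with an optional `(r+1)/(B+1)`
  correction.
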