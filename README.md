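# traitstab

Species- versus functional-trait community-stability analysis for
multitrophic survey data.

Given long-format fish survey records (pond, year, month, station, species,
count, fork lengths), per-individual measurements of 13 functional traits
(5 energy-acquisition, 5 locomotion, 3 nutrient-recycling), and a
species → feeding-mode lookup, the pipeline:

1. **imputes traits** for every surveyed individual with per-trait additive
   models (`value ~ taxon + s(fork_length)`, penalized thin-plate spline,
   REML-selected penalty; species-level taxa for morphometric traits,
   family-level for nutrient-recycling traits);
2. builds the **species abundance matrix** (counts averaged over stations
   within months, then over months) and the **community-weighted trait
   matrix**, one row per pond × year;
3. computes **Bray–Curtis** dissimilarities, **PCoA** and **nMDS**
   ordinations (all implemented from scratch, including the
   negative-eigenvalue handling and isotonic-regression stress
   minimization);
4. quantifies stability as **year-to-centroid** distance (betadisper-style,
   in PCoA space, or raw distance to the time-mean composition) and
   **year-to-year** distance, max-normalized per composition type, compared
   with a crossed two-way **ANOVA** (pond × composition type);
5. runs **PERMANOVA** (`pond + year(numeric) + pond:year`, free row
   permutation), restricted **SIMPER** decompositions (each year vs its
   pond's time-mean; consecutive-year pairs), and **vector fitting** of
   species / feeding-mode abundances onto the trait ordination;
6. controls for dimensional reduction by resampling **mock communities** of
   equal species and trait dimensionality and re-running the stability
   comparison.

A synthetic-survey generator (`traitstab.synth`) produces inputs with the
statistical structure the analysis assumes — configurable within-mode
trait redundancy, persistent pond-level filters, and compensatory
interannual dynamics — so the whole pipeline is testable without any data
download.

## CLI

```bash
# generate a synthetic fixture shaped like the study design
traitstab fixture paper_shape --out-dir fixture --seed 1

# run everything: imputation, matrices, ordinations, stability + ANOVA,
# PERMANOVA, SIMPER, envfit, mock-community control, manifest
traitstab all --survey-csv fixture/survey.csv \
              --traits-csv fixture/trait_measurements.csv \
              --lookup-csv fixture/feeding_modes.csv \
              --out-dir results/bundle --seed 1
```

Per-stage subcommands (`impute`, `matrices`, `stability`, `anova`,
`permanova`, `simper`, `envfit`, `mocksim`) operate on the intermediate
CSVs; `traitstab all --config pipeline.yaml` reads a YAML config with the
same keys as `PipelineConfig`, with command-line flags taking precedence.
Every run writes a `manifest.json` recording all flags and the seed;
re-running from the same config reproduces every output byte-for-byte.

### File formats

- survey CSV: `pond,year,month,station,species,count,fork_length_mm`; one
  row per measured individual (`count == 1`) plus a count-only row per haul
  carrying the unmeasured remainder (empty length).
- trait measurements CSV: `species,family,fork_length_mm,trait,value` with
  trait names `Osf,Osh,Ops,Pro,ES,EP,Bsf,Bsh,Pfp,Cpt,NH4,PO4,N_P`.
- lookup CSV: `species,feeding_mode[,family]` with modes `detritivore`,
  `planktivore`, `hunting_meiofauna`, `hunting_macrofauna`.

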