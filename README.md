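# hetscreen

Analysis toolkit for quantitative, multi-domain heterochromatin silencing
reporter screens in fission yeast, covering the full path from long-format
colony-size tables to calibrated hit calls, phenotypic-profile clustering,
protein-complex coherence testing, and single-cell reporter-state
quantification — plus a synthetic-data generator with known ground truth so
every stage is testable offline.

## What it does

- **screen_io** — read/validate/write tidy colony-size tables
  (screen × medium × plate × well × replicate), apply strain-annotation
  corrections (exclusions, `gene*` renames with confirmed-copy
  deduplication), read gold-standard gene lists, complex-membership tables,
  per-cell fluorescence CSVs, and supplementary-style XLSX score tables.
- **scoring** — relative growth (selective / non-selective colony size),
  384-plate median normalization, log2, technical-replicate averaging,
  per-(screen, readout) scaling (SD → 1) and median-centering, and the
  combined FOA/URA score (`scaled(URA) − scaled(FOA)`).
- **hit_calling** — one-sample t-tests against 0, per-screen effect-size
  thresholds (median combined score > 2.5 for MAT/SUBTEL/TEL, > 3 for CEN;
  reciprocal −2/−3 for anti-silencing), domain-overlap summaries,
  gold-standard recall, transcript fold-change precision (strict > 1.5),
  group normalization, and Fisher's exact cluster-enrichment tests.
- **profile_clustering** — consensus k-means (label alignment across runs,
  majority vote, support fractions) on the 8-column median log2
  relative-growth matrix with half-weighted SUBTEL/TEL columns, plus
  within-cluster hierarchical leaf ordering (Euclidean, complete linkage by
  default).
- **complex_coherence** — pairwise Pearson correlation of per-gene domain
  profiles, within/between-complex fractions at a correlation threshold,
  and a one-sided label-permutation test (exhaustive enumeration on tiny
  inputs, vectorized Monte Carlo otherwise, add-one p estimator).
- **flow_reporter** — per-cell normalization to the euchromatic red
  channel, color-positive gating from a red-only control, max-scaling to a
  no-heterochromatin control, OFF/intermediate/ON fractions, density curves
  and 2D-histogram ("hexbin") tables.
- **synthetic_data** — deterministic generators for screens (lognormal
  colonies, multiplicative plate effects on selective plates, planted
  per-gene effects split across the two readouts), coherent complex-profile
  sets, and bimodal cell populations; each returns a ground-truth object.
- **cli** — `hetscreen` command with `simulate`, `score`, `call-hits`,
  `cluster`, `coherence`, `flow` and `run-all` subcommands; every run
  writes a `manifest.json` with config hash and output checksums.

## CLI quick start

```sh
# simulate a screen, score it, and call hits
hetscreen simulate --seed 1 --outdir out/sim
hetscreen score --colonies out/sim/colonies.tsv --outdir out/scores
hetscreen call-hits --combined out/scores/combined.tsv --outdir out/hits

# or the whole chain at once
hetscreen run-all --seed 1 --k 7 --outdir out/run
```

Input colony tables are long/tidy TSV or CSV with columns
`screen, medium, plate_id, row, col, strain_id, gene_name, bio_rep,
tech_rep, size` (screen ∈ {CEN, MAT, SUBTEL, TEL}; medium ∈ {NS, URA,
FOA}; empty `size` = missing colony).

## Notes on conventions

- Missing colonies stay missing through every stage (no pseudocounts); a
  zero size on either medium also yields a missing ratio.
- Scaling uses the sample SD (n−1) and is applied per (screen, readout)
  dataset pooled over biological replicates.
- Hit calling uses raw P values (no multiple-testing correction), matching
  the original analysis; a Benjamini–Hochberg column is emitted for
  information only.
- Corrected strain names carry a literal `*` suffix in all outputs.
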