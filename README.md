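# clonotrack

Longitudinal B-cell receptor (BCR) heavy-chain repertoire analysis for
transplant-style cohorts: from annotated rearrangement tables to clonal
structure, lineage trees, tissue-mixing, diversity and clone-size dynamics.

## What it does

- **airr_io** — reads/writes AIRR-C rearrangement TSVs (plus an ImmuneDB-style
  column mapping) and sample metadata; validates records, normalizes V/J calls
  to gene level, filters to quiescent (rejection-free) samples.
- **clonal** — groups sequences into clones (same V gene, J gene and CDR3
  length, single-linkage at ≥85% CDR3 amino-acid identity) and applies the
  published filters: detectability (productive member with copy number ≥2),
  clone size as unique instances per time bracket, mutated-clone classification
  (average V mutation frequency >2%), trunk clones (≥5 mutations shared by
  ≥85% of unique sequences), and the ≥3-unique-sequences/both-tissues filter.
- **lineage** — germline-rooted mutation-containment trees with inferred
  ancestors at set intersections; Newick + per-node TSV output.
- **clumpiness** — 0–1 tissue-mixing metric on lineage trees (0 = labels on
  disjoint root clades, 1 = every populated node carries both labels), with
  per-individual medians filtered at >5 clones.
- **metrics** — Hill-number diversity (order 0 = richness), evenness
  (order-1 diversity / richness), cosine similarity of clone-size vectors.
- **stats** — POD time brackets (0 / 1–90 / 91–365 / >365), exact sign test on
  clone-size changes, two-sided Mann-Whitney U, trapezoidal chimerism AUC
  normalized by days of measurement, ≥40-cell parent-gate filter, MFI-based
  DSA positivity calls (2,000 serum / 500 supernatant increments).
- **simulate** — deterministic synthetic generator (branching-process
  lineages, power-law clone sizes, tunable tissue mixing π and growth bias)
  so the whole pipeline is testable without external data.
- **pipeline / cli** — end-to-end report generation with a threshold manifest.

## CLI

```sh
# synthetic dataset (rearrangements.tsv + metadata.tsv)
clonotrack simulate --seed 1 --out data/ --config n_patients=3 --config n_clones=100

# full analysis: clones, mutated fractions, evenness, sign tests,
# clumpiness (+ medians), cosine similarities, chimerism AUC, manifest
clonotrack report --rearrangements data/rearrangements.tsv \
                  --metadata data/metadata.tsv --out report/

# individual stages
clonotrack clones|lineages|clumpiness|metrics|stats --help
```

All outputs are plain TSV/JSON and byte-reproducible for identical inputs.
Thresholds (identity 0.85, copy ≥2, mutated >2%, trunk 5/0.85, >5 clones,
≥3 unique sequences, gate ≥40) default to the published values and are
recorded in `report/manifest.json`.

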