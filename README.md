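# nichediverge

A tested, reusable pipeline for climatic niche-divergence analysis:

- **occurrences** — CSV reading/validation, great-circle (haversine) spatial
  thinning with a max-degree-removal heuristic, minimum-sample filtering.
- **envsel** — raster value extraction, great-circle background buffers,
  variance inflation factors with a stepwise forward variable screen, PCA of
  normalised variables.
- **maxent** — a from-scratch maximum-entropy presence-background model:
  L/Q/H/P/T feature classes, per-class L1 regularization, FISTA optimizer,
  AICc model selection, replicate AUC evaluation, permutation variable
  importance, clamped raster projection, logistic output.
- **overlap** — Schoener's D, Latin-hypercube model overlap with Spearman
  rho, identity (equivalency), background (similarity) and linear/blob
  range-breaking permutation tests, plus ordination-based (kernel occupancy
  surface) equivalency/similarity counterparts.
- **refugia** — suitability binarization at a midpoint and multi-period
  stability stacking with refugium area reports.
- **physig** — Blomberg's K from the Brownian-motion variance-covariance
  matrix, with occurrence-level resampling (mean ± SE).
- **synthgen** — synthetic climate landscapes (Gaussian random fields with
  controlled cross-correlation), virtual species with known suitability,
  occurrence samples, paleo layer series, Brownian-motion traits — so every
  stage is testable without external downloads.
- **cli** — end-to-end orchestration with seed fan-out and a manifest.

Rasters are read and written as plain-text ESRI ASCII grids (one `.asc` per
layer plus `stack.json` for a multilayer stack); occurrences are CSV
(taxon,lon,lat), trees are Newick, models serialize to JSON.

## Command line

```bash
# all-synthetic demonstration run (generates inputs, runs the full pipeline)
nichediverge demo --out demo_dir --seed 7

# individual stages
nichediverge thin --input occ.csv --output thinned.csv --min-km 10 --reps 100 --seed 1
nichediverge select-vars --occurrences occ.csv --stack stack_dir \
    --seed-vars BIO10,BIO11,BIO12 --threshold 10 --buffer-km 200 --n-background 1000
nichediverge fit-enm --occurrences occ.csv --stack stack_dir --taxon "My species" \
    --classes L,LQ,LQH --rms 0.5,1,2,3,4 --model-out model.json
nichediverge refugia --periods p1.asc,p2.asc,p3.asc,p4.asc,p5.asc \
    --midpoint 0.5 --out stability.asc
nichediverge physig --tree tree.nwk --traits env.csv --resamples 10000 --out k.csv

# full pipeline from a YAML config (see PipelineConfig for keys)
nichediverge run --config config.yml
```

A pipeline run writes `tables/` (thinned occurrences, model selection,
pairwise test results, PCA scores, Blomberg's K), `rasters/` (per-period
suitability and stability layers), `models/` (JSON) and `manifest.json`
(every parameter and seed used).

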