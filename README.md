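# creatlas

Consensus atlas construction and downstream analyses for brain-active
candidate cis-regulatory elements (cCREs) from chromatin-accessibility
data, exercisable end to end on synthetic inputs with planted structure.

The package implements:

- **tracks** — BED/bedGraph readers and writers, run-length signal
  tracks, base-weighted mean signal over elements, track summation and
  interval overlap primitives (0-based half-open coordinates throughout).
- **atlas** — per-experiment activity calling from log-transformed
  z-scores (active at z > 1.64), two-phase consensus definition of
  brain-active elements (support in ≥ 5 experiments, with a z > 2.32
  rescue path for sparsely supported fetal elements) and life-stage
  classification (adult-specific / fetal-specific / shared / non-brain).
- **celltype** — neuron/glia aggregate-track classification, top-50k
  pseudo-bulk coverage metrics (datasets calling < 10k elements are
  dropped) and pairwise overlap-coefficient matrices.
- **conservation** — aggregate conservation profiles with rolling-mean
  smoothing, alignment-fraction triangle coordinates (N1 = genomes
  aligning ≥ 90%, N2 = genomes aligning ≤ 10%), G1/G2/G3 conservation
  groups, 16-slice density-balanced triangle partitioning, evolutionary
  origin labels, and GC/CpG-exactly-matched random control regions.
- **enrichment** — fractional weighting of validation (transgenic
  enhancer assay) regions across element classes, tissue-class
  assignment, length-preserving shuffle-null interval enrichment,
  TSS-window targets, priority assignment against external catalogs and
  greedy selection of genetically independent traits (rg² ≤ 0.1).
- **ctfbs** — candidate TF-binding-site calling from base-resolution
  importance scores: dataset-level z-normalization, ±1.96 discretization
  into {−1, 0, +1}, a 3-state Baum–Welch HMM, Viterbi segmentation with
  excision of ≥ 4-zero runs, padded PWM similarity scoring (0.25 for
  unaligned positions), best-motif assignment and Yates-corrected
  chi-square motif-set comparison (≥ 25 instances per set).
- **motif_rf** — PWM max log-odds features, exact dinucleotide shuffling
  (Euler-path construction), a 10-model random-forest importance
  ensemble and combination with enrichment scores and differential
  expression.
- **synth** — generators for every input (genome, elements,
  accessibility tracks, alignment fractions, importance tracks, motif
  catalogs, validation regions, genetic-correlation matrices) with
  planted, recoverable structure and a serializable truth record.

## Command-line pipeline

```sh
creatlas run-all --outdir runs/demo --seed 1
```

generates a synthetic input bundle and runs every stage
(`simulate → atlas → celltype → conserve → enrich → ctfbs → motifs`),
writing a `manifest.json` with the full config echo and SHA-256
checksums of all outputs (identical config + seed ⇒ identical
checksums). Each stage is also an independent subcommand, e.g.

```sh
creatlas simulate --outdir runs/demo/inputs --seed 1
creatlas atlas --indir runs/demo/inputs --outdir runs/demo/atlas
```

Thresholds live in a YAML config (`--config`); unknown keys are
rejected. Defaults: `active_z: 1.64`, `rescue_z: 2.32`,
`min_support: 5`, `importance_z: 1.96`, `min_zero_run: 4`,
`min_instances: 25`, `n_shuffles: 100`, `n_models: 10`,
`window: 100000`, `top_k: 50000`, `min_active: 10000`.

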