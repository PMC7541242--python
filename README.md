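# het5c

A tested pipeline for targeted chromosome-conformation (5C) analysis of
pericentromeric heterochromatin:

- **`het5c.synthetic`** — generates every pipeline input with planted ground
  truth: tiled forward/reverse primer sets (T7/T3 universal tails),
  block-structured contact counts over a power-law distance decay with
  Poisson replicate noise, paired FASTQ with tail + primer + EcoRI-junction
  read structure (configurable decoys and quality floors), feature tracks
  with tunable border enrichment, and per-gene FPKM tables tied to TAD
  activity.
- **`het5c.quant`** — raw read pairs to contact matrices: 5'/3' trimming,
  Phred-25/80% quality filtering, exact-match assignment to forward x
  reverse primer combinations (multi-matching reads discarded), total-count
  normalization, median binning with smoothing, and a distance-stratified
  expected model with log2 observed/expected validity calls.
- **`het5c.tads`** — Directionality Index (100 kb window,
  `DI = sign(B-A) * ((A-E)^2/E + (B-E)^2/E)` with `E = (A+B)/2`), 3-state
  discrete-emission HMM segmentation, TAD/border extraction per replicate,
  and cross-replicate consensus boundaries (single-linkage at 50 kb,
  majority support).
- **`het5c.overlap`** — permutation overlap tests (length- and
  chromosome-preserving randomization within a declared universe, add-one
  p, Z score), scaled border (30 kb / 10 kb bins) and intra-TAD
  (150 kb / 30 kb bins) meta-profiles, and exact feature-subset combination
  counts for interaction anchors.
- **`het5c.compare`** — inter- vs intra-TAD interaction classification,
  replicate pooling by mean, notched-boxplot summaries with a notch
  non-overlap flag, FPKM categorization (no < 1, low 1-10, moderate 10-50,
  high > 50), TAD-expression concordance, and DE gene-list set algebra.

## CLI

```bash
het5c simulate --out-dir data --seed 1                 # synthetic dataset
het5c quant --fastq1 data/rep1_R1.fastq --fastq2 data/rep1_R2.fastq \
    --primers data/primers.tsv --bin-step 10000 --norm-factor 8.65 \
    --out-prefix out/rep1
het5c tads --matrix out/rep1.matrix.tsv --matrix out/rep2.matrix.tsv \
    --seed 1 --out-prefix out/tads
het5c enrich --borders out/tads.consensus.borders.bed --features tracks/ \
    --universe-length 1000000 --n-perm 1000 --seed 1 --out out/enrich.tsv
het5c compare --wt out/wt.pairs.tsv --kd out/kd.pairs.tsv \
    --tads out/tads.consensus.tads.bed --out-prefix out/cmp
het5c expression --fpkm data/expression.tsv \
    --tads out/tads.consensus.tads.bed --out-prefix out/expr
```

All randomness is seed-controlled; identical seeds give byte-identical
outputs.

## Notes

- Primer-pair assignment uses exact substring matching against the
  forward x reverse junction catalog instead of an external aligner;
  `quant.assign_premapped` accepts pre-mapped pair lists for real data.
- Normalization factors are per-dataset calibration constants supplied via
  `--norm-factor`; they are not re-derived.
- The expected model is the per-distance-stratum median with stratum width
  equal to the bin size; the smoother is a +-10 kb median over present
  cells.
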