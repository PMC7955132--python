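# fusenet

Candidate cancer gene biomarker discovery from **fused dual-metric gene
co-expression networks**.

For each condition (normal / cancer) the pipeline builds two co-expression
networks over the same gene universe — one from the Euclidean distance
between expression profiles (thresholded at the 99th weight percentile) and
one from Pearson correlation (pruned by a 10-shuffle permutation null and
balanced to the Euclidean edge count by p-value) — and merges them into a
single condition network. The two condition networks are fused by
similarity-network cross-diffusion through K-nearest-neighbor kernels, the
fused network is reduced to its statistically significant backbone with the
disparity filter, and Louvain modularity communities of the backbone yield
the **Integrated Community (IC) genes**. IC genes are validated by
LASSO-reduced Random-Forest normal/cancer classification (5-fold stratified
CV repeated 100×, Wilcoxon signed-rank comparisons against DE / random /
single-measure baselines), univariate + multivariate Cox
proportional-hazards screening, and Fisher-exact knowledge enrichment.

A first-class synthetic-data generator produces paired normal/cancer
FPKM-scale matrices with planted co-expression modules (optionally rewired
or condition-specific), fold-change genes, a zFPKM noise floor, survival
times from an exponential proportional-hazards model, and boolean
knowledge annotations — so the whole pipeline is testable offline.

## CLI

All stages are driven by a YAML config (see `fusenet.pipeline.RunConfig`
for every knob). A minimal synthetic end-to-end run:

```yaml
# config.yaml
output_dir: run
seed: 7
n_repetitions: 100
simulation:
  n_rna: 250
  n_mirna: 50
  n_samples_normal: 60
  n_samples_cancer: 60
  n_de_genes: 20
  de_log2fc: 1.0
  noise_floor_fraction: 0.1
  seed: 7
  modules:
    - member_genes: [RNA00000, RNA00001, RNA00002, RNA00003, RNA00004]
      within_correlation: 0.9
      active_in: both
      rewired_in_cancer: false
```

```bash
fusenet run-all --config config.yaml
```

writes expression/annotation/survival TSVs, per-condition network edge
lists (+ JSON sidecars), the fused backbone, community partition, gene
sets, classification metric distributions, Cox screens, enrichment tables
and a `manifest.json` with per-stage counts and seeds into `run/`.

Individual stages are available as
`fusenet simulate | preprocess | networks | fuse | validate | survival | enrich`;
each reads/writes the plain-text artifacts of its stage (see `--help`).

To run on real data instead of a simulation, replace the `simulation:`
block with file paths:

```yaml
expression_normal: normal.tsv    # genes x samples, FPKM
expression_cancer: cancer.tsv
annotation: annotation.tsv       # gene_id <tab> biotype
survival: survival.tsv           # sample_id, event, time   (optional)
knowledge_flags: flags.tsv       # gene_id, 0/1             (optional)
```

## Package layout

| module | contents |
| --- | --- |
| `fusenet.matrix` | `ExpressionMatrix` container + TSV I/O |
| `fusenet.simulate` | synthetic expression / survival / annotation generators |
| `fusenet.preprocess` | biotype filter, zFPKM transform, active-gene filter |
| `fusenet.coexpression` | Euclidean + Pearson networks, thresholding, combination |
| `fusenet.fusion` | KNN kernels, SNF cross-diffusion, disparity filter, communities |
| `fusenet.validation` | LASSO selection, DE baseline, RF classification, comparisons |
| `fusenet.survival_enrichment` | Cox screening, concordance, Fisher enrichment |
| `fusenet.pipeline` | orchestration, manifests, topology metrics |
| `fusenet.cli` | click-based CLI (`fusenet` entry point) |

## Notes on method choices

- The per-sample zFPKM fit locates the log2-density mode by Gaussian KDE
  (Silverman bandwidth, 512-point grid) and estimates the spread from the
  right half of the distribution; zero FPKMs map to a −30 sentinel.
- Euclidean log-normalization uses log1p before max-normalization so that
  distances ≤ 1 keep positive weights.
- The raw alternating cross-diffusion recursion is generically
  non-convergent; `snf_fuse` therefore mixes a configurable fraction of
  the identity into each step (`identity_mixing`, default 0.3), making the
  update an affine contraction with a unique fixed point. Setting it to 0
  recovers the literal recursion.
- The disparity backbone keeps the most significant ~1% of fused edges
  (α below the 1st percentile of the per-edge α distribution); direction
  and percentile are configurable.
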