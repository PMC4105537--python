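# tissuenet

A multi-tissue transcriptome and co-expression network pipeline. Given a
genes × libraries RPKM matrix with a sample sheet (tissue, animal,
physiological state PRE/POST), a transcription-factor list and a GWAS
association table, it runs:

1. **Expressed-gene filtering** — keep genes with mean RPKM ≥ 0.2 in at
   least one (tissue, state) cell.
2. **Mixed-model normalization** — EM-REML fit of
   `Y = µ + L + G + GT + GA + GP + e` on log2 RPKM (library fixed; gene,
   gene×tissue, gene×animal, gene×state random); normalized expression is
   the sum of random-effect solutions, validated by hierarchical clustering
   of library profiles.
3. **Differential expression** — per-tissue POST−PRE contrasts of
   normalized expression, called through a two-component normal mixture
   with an empirical null (small-variance component) at an estimated FDR
   threshold.
4. **Tissue specificity** — Shannon entropy of per-tissue expression
   proportions with a permutation-derived calling threshold, plus the
   categorical score `Q = H − log2 p`.
5. **Regulator impact** — differential-wiring scores contrasting each TF's
   target co-expression between states, z-standardized across regulators.
6. **PCIT networks** — per-state co-expression networks filtered by the
   partial-correlation-and-information-theory algorithm; hub detection at
   mean + 2 SD connectivity.
7. **Network comparison** — persistent / disappeared / emerged edges,
   per-tissue connection percentages, exhaustive best-TF-trio expansion,
   nine-criteria TF ranking, and tissue-restricted sub-network extraction.
8. **GWAS integration** — SNPs (p < 1%, within 10 kb) joined to expressed
   genes with DE or TS evidence.

A first-class synthetic-data module generates datasets with planted DE
genes, tissue-specific genes, rewired regulators and SNP tables, plus a
truth table used throughout the test suite for recovery checks.

## CLI

Simulate a dataset:

```sh
tissuenet simulate --outdir sim --seed 7 --n-genes 500
```

Run the full pipeline from a config file:

```sh
tissuenet run --config config.yaml [--seed N] [--outdir DIR] [--stages de,ts]
```

Example `config.yaml`:

```yaml
version: 1
seed: 7
outdir: out
simulation:            # or use `inputs:` with expression/samples/snps/tf_list paths
  n_genes: 500
  n_de: 50
  n_ts: 30
  n_regulators: 20
  n_rewired_regulators: 2
  n_snps: 60
  seed: 7
thresholds:
  fdr: 0.01
  ts_permutations: 1000
```

Outputs land in `outdir` as tab-delimited tables, SIF edge lists and a
`manifest.json` with per-stage counts and sha256 hashes of every file
(re-running with the same config reproduces identical hashes).

File-based inputs use plain tab-delimited text: the expression matrix has
library ids as header and gene ids in the first column; the sample sheet has
columns `library`, `tissue`, `animal`, `state`; the SNP table has columns
`snp`, `chrom`, `pos`, `trait`, `pvalue`, `gene`, `distance_bp`, `side`.

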