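# dosewise

Statistical toolkit for multi-genotype (gene-dose) single-nucleus RNA-seq:
pseudobulk negative-binomial differential expression with an ordinal-dose
likelihood-ratio test, DEG-burden downsampling, trajectory timing statistics,
resampling gene-set enrichment, and regulon activity/specificity scoring —
plus a synthetic-data generator that plants the dose-response and
maturation-delay structure the analysis is designed to detect.

## What's inside

| Module | Purpose |
|---|---|
| `dosewise.simulate` | Synthetic allelic-series snRNA-seq datasets (dose 0 = KO, 1 = Het, 2 = WT) with known per-gene truth: dose-sensitive repressed genes, threshold-like activated genes, pseudotime-dynamic programs, cell-cycle and mito genes, maturation lag, NB noise |
| `dosewise.io` | Matrix Market (10x orientation) / TSV / GMT readers and writers |
| `dosewise.preprocess` | QC filters (UMI/gene/mito/log-ratio rules), log2 CP10K normalization, LISI mixing score, cell-cycle scoring, Wilcoxon marker detection |
| `dosewise.pseudobulk` | (cluster, sample) aggregation, median-of-ratios size factors, Cox-Reid dispersion estimation, NB GLM with Wald and nested LRT tests, DEG calling and dose-response classification, DEG-burden downsampling |
| `dosewise.composition` | Per-sample proportion tables and empirical-Bayes moderated t / F tests (arcsin-sqrt transform) |
| `dosewise.trajectory` | kNN-geodesic root-anchored pseudotime, Moran's I dynamic-gene test, per-cluster KS shift tests, density-difference curves, KL-divergence timing permutation test |
| `dosewise.enrichment` | Hypergeometric ORA, expression-matched resampling enrichment, Yates chi-square, Fisher's exact |
| `dosewise.regulons` | AUCell-style recovery-curve activity, regulon specificity scores (1 − JSD), differential regulon activity |
| `dosewise.pipeline` / `dosewise.cli` | End-to-end runner and `dosewise` CLI |

## CLI

```bash
dosewise simulate --outdir ds --seed 1            # synthetic dataset + truth
dosewise simulate --outdir nds --null             # genotype-null twin
dosewise run-all --outdir out --seed 1            # qc -> ... -> regulons
dosewise run-all --config run.yaml                # parameters from YAML
```

`run-all` writes one TSV per stage (`qc.tsv`, `markers.tsv`, `de.tsv`,
`composition.tsv`, `trajectory.tsv`, `timing.tsv`, `enrichment.tsv`,
`regulons.tsv`, `rss.tsv`) and a `run_log.json` with versions, seeds and
parameters. Any stage failure aborts with the stage name and a nonzero
exit status.

Library usage mirrors the CLI; for example:

```python
from dosewise.simulate import SimConfig, simulate_dataset
from dosewise.pseudobulk import aggregate_pseudobulk, run_dose_lrt

counts, cells, truth = simulate_dataset(SimConfig(seed=1))
pb = aggregate_pseudobulk(counts, cells)
cols = pb.columns_for_cluster("T1")
res = run_dose_lrt(pb.counts[cols], pb.coldata.loc[cols])
res[res["called"]].head()
```

## Conventions

- Counts are cells × genes in memory; on disk MTX uses genes-as-rows.
- All fold changes and thresholds are log2; GLM coefficients are reported
  on the log2 scale.
- Every p-value family is adjusted with Benjamini-Hochberg within the
  family stated by the operation that produced it.
- Every stochastic step takes an explicit seed and is reproducible
  bit-for-bit.
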