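# tmtde

Quantitative analysis of multi-batch isobaric-labelling (TMT) case–control
proteomics, built for the common neurodegeneration study design: several
11-plex batches covering three subject groups (e.g. PSP, PD and healthy
controls), with a master-pool (MP) reference channel and a pooled QC
aliquot in every batch.

The package provides, as a tested library plus a thin CLI:

- **Normalization** — MP-reference division, per-protein median scaling,
  log2 + z-score, strict missing-value filtering, and a parametric
  empirical-Bayes (ComBat) batch correction written here and verified
  against Bioconductor `sva`.
- **QC metrics** — CV of the QC aliquots, subject-to-QC signal-to-noise
  ratios, and a PCA batch-effect summary (η² of the batch factor on
  PC1–2).
- **Dual differential expression** — a SAM-style moderated t statistic
  d = Δmean/(se + s₀) with permutation-based FDR q-values, and a
  bootstrap-ROC procedure (Mann–Whitney AUC, stratified resampling,
  permuted-label count-ratio q-values), intersected into a consensus call.
- **Overrepresentation** — one-sided Fisher exact test of the consensus
  genes against GMT gene sets (DAVID-style EASE variant optional).
- **Power analysis** — exact noncentral-t sample-size solving for the
  two-sample t-test.
- **Synthetic data** — a ground-truthed generator of the 5-batch 11-plex
  design (planted log2 fold changes, batch effects, batch-level dropout)
  so the whole pipeline is testable without any raw data.

See `docs/methods.md` for the statistical models and the reasoning behind
the defaults.

## Worked example

```python
from tmtde import (SimulationConfig, simulate_dataset, normalize_pipeline,
                   SamConfig, sam_qvalues, BrocConfig, broc_qvalues,
                   consensus_select)

cfg = SimulationConfig(n_proteins=2000, frac_de=0.2, seed=11)
matrix, truth = simulate_dataset(cfg)
corrected = normalize_pipeline(matrix)["batch_corrected"]

sam_res = sam_qvalues(corrected, ("PSP", "HC"), SamConfig(n_permutations=250, seed=1))
broc_res = broc_qvalues(corrected, ("PSP", "HC"), BrocConfig(n_bootstrap=500, seed=2))
merged, venn = consensus_select(sam_res, broc_res, q_threshold=0.05)
```

Running this (it is `examples/04_differential_expression.py`) prints:

```
SAM calls (q<0.05)        : 345
bootstrap-ROC calls       : 325
Venn: SAM-only 20 | both 325 | bROC-only 0
planted effects recovered : 312/312 (100.0%), false calls 13
```

2000 simulated proteins carry a planted |log2FC| = 0.585 on 20% of
proteins; after normalization and batch correction, the SAM test calls
345 proteins and the bootstrap-ROC test 325 at q < 0.05, overlapping in
325. All 312 planted effects that survived the missing-value filter are
recovered by the consensus, with 13 false calls (0.8% of the null
proteins) — consistent with the design's power regime, where a 1.5-fold
change against a residual SD of 0.208 with 15 subjects per group is a
very large standardized effect (d ≈ 2.8).

The power side of that statement:

```bash
$ python examples/01_power_analysis.py
Cohen's d           : 2.8123
n per group         : 9.40  (round up to 10)
power at solution   : 0.800000
```

i.e. at significance 1e-4 and power 0.8, ~9.4 subjects per group suffice
to detect a 1.5-fold change, so a 15-per-group design has ample headroom.

The other scripts in `examples/` cover simulation + normalization, the QC
metrics, and overrepresentation, each printing a few annotated numbers.

A shell interface mirrors the library
(`tmtde simulate|normalize|qc|de-sam|de-broc|consensus|enrich|power|run`);
`tmtde run --seed 7 --out runs/demo` executes the full chain on synthetic
data and writes every intermediate table plus a deterministic
`summary.json`.

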