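# ctbulk

Cell-type-resolved comparison of two patient groups from sparse
single-nucleus RNA-seq.

Single-nucleus studies of matched tumor cohorts — e.g. brain versus
extracranial melanoma metastases — ask which *cell types* carry the
expression differences between the groups. Answering that from snRNA data
is statistically delicate: integration methods impute the ~88% of entries
that were never measured, per-cell counts are too noisy for patient-level
inference, and with a dozen patients per group every multivariate step is
one unlucky draw away from overfitting. `ctbulk` packages the analysis
pattern built for that setting, for computational biologists who want the
whole chain reproducible and testable:

- **imputation masking** — every entry whose raw count is zero is marked
  missing, so no statistic ever consumes an imputed value;
- **masked pseudobulk** — mean expression per (patient, cell type) over
  observed cells, kept only with ≥ 10 supporting cells;
- **moderated-t differential expression** per cell type: per-gene OLS over
  each gene's observed patients (eligibility: ≥ 4 patients per group),
  empirical-Bayes variance shrinkage
  s̃²_g = (d0·s0² + d_g·s²_g)/(d0 + d_g) with (d0, s0²) estimated by
  digamma/trigamma moment matching, t̃ = β/√(s̃²·v) on d0 + d_g df, BH FDR
  within cell type;
- **homogeneity analysis** — pairwise-complete Pearson correlations
  between patients' profiles at pseudobulk and single-cell resolution,
  compared across A-A / B-B / A-B pair classes by Welch tests and by the
  random-intercept model r ~ pair_class + (1 | patient_pair) (profiled
  REML);
- **signature clustering** — complete linkage on an overlap-scaled
  Euclidean distance over the top-50-by-p genes per cell type, with
  two-group separation assessment and multiscale-bootstrap AU/BP support;
- **NIPALS PCA** that skips missing entries;
- **ordered-query enrichment** — minimum hypergeometric tail over ranking
  prefixes against a custom background, with permutation (max-T)
  family-wise calibration;
- a **synthetic cohort generator** with hierarchical patient effects,
  planted group effects restricted to designated cell types and a
  group-differential homogeneity parameter, so every claim above is tested
  against known ground truth.

## Worked example

```python
from ctbulk import (default_study_template, simulate_dataset, lognormalize,
                    mask_imputed, aggregate, run_de, DesignSpec)

cfg = default_study_template(seed=1)          # 6v6 patients, 5 cell types
matrix, cells, truth = simulate_dataset(cfg)  # sparse counts + ground truth
print(f"{matrix.n_genes} genes x {matrix.n_cells} cells, "
      f"{1 - matrix.values.nnz / (matrix.n_genes * matrix.n_cells):.1%} zeros")

masked = mask_imputed(lognormalize(matrix), matrix)
pb = aggregate(masked, cells, min_cells=10)
de = run_de(pb, DesignSpec(groups=pb.groups))
print(de.summary[de.summary.fdr_cutoff == 0.05].to_string(index=False))
print("planted in stromal:", len(truth.planted("stromal")),
      "| recovered:", (de.for_cell_type("stromal").fdr < 0.05).sum())
```

Output:

```
2000 genes x 3588 cells, 88.0% zeros
cell_type  fdr_cutoff  n_tested  n_up  n_down  n_significant
    tumor        0.05       518     0       0              0
  stromal        0.05       553    19      29             48
    Tcell        0.05       403    23      28             51
  myeloid        0.05       439     0       0              0
    Bcell        0.05       453     0       0              0
planted in stromal: 200 | recovered: 48
```

The generator planted effects only in the microenvironment types
("stromal", "Tcell") — the tumor type reports zero significant genes while
the effect-bearing types report ~50 each, predominantly down-regulated, as
planted. About a quarter of planted genes are recovered here because at
88% sparsity many planted genes never reach the 10-cell / 4-patient
support rules; among *tested* planted genes sensitivity is ≈ 0.6.

## Command line

Each stage is also a subcommand operating on a shared workspace:

```sh
ctbulk simulate --out ws --seed 7
ctbulk qc        --config ws/raw/config.yaml --out ws
ctbulk normalize --config ws/raw/config.yaml --out ws
ctbulk mask      --config ws/raw/config.yaml --out ws
ctbulk pseudobulk --config ws/raw/config.yaml --out ws
ctbulk de        --config ws/raw/config.yaml --out ws
ctbulk correlate --config ws/raw/config.yaml --out ws
ctbulk cluster   --config ws/raw/config.yaml --out ws
ctbulk pca       --config ws/raw/config.yaml --out ws
ctbulk enrich    --config ws/raw/config.yaml --out ws --gmt sets.gmt
```

Outputs are plain TSV/MTX/Newick files; every threshold lives in the YAML
run config and is overridable by a flag of the same name. `simulate`
writes a desk-scale config matched to the synthetic cohort.

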