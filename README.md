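# aimsel

Selection of minimal panels of ancestry-informative SNP and/or
gene-expression (GE) markers by forward stepwise flexible discriminant
analysis (FDA) with cross-validation, plus the accompanying marker
quality-control chain and a synthetic-data generator for
population-structured SNP/GE cohorts.

## What it does

Given genotype calls (VCF or a tabular AA/AB/BB matrix), an optional
expression matrix (probes × samples, series-matrix style), a sample →
population label file, and marker annotation:

1. **QC** — SNPs are removed when the genotype call rate is below 0.9, the
   minor allele frequency is 0, a permutation-based Hardy–Weinberg test
   (FDR-adjusted) rejects at 0.05, or the marker lies on a sex chromosome.
   Expression probes are removed when non-RefSeq, on a sex chromosome, or
   lacking a gene symbol. All removal reasons are recorded per marker.
2. **Cross-validated forward selection** — samples are stratified into k
   folds (default 10). Within each training set, markers are added
   greedily: the candidate with the maximum increment of training accuracy
   of an optimal-scoring FDA fit wins; ties go to the candidate with the
   smaller univariate SSW/SSB (within- over between-population sum of
   squares), then to the lexicographically smaller marker ID. Selection
   stops at training accuracy 1.0, when the increment drops below 0.001
   (configurable), or at a marker cap.
3. **Model choice** — each fold's panel is scored on its held-out fold; the
   best model maximizes testing accuracy, with ties broken by fewer
   markers, then higher cross-validation consistency, then fold index.
4. **Reports** — accuracy-vs-panel-size curves per fold, parallel
   coordinates, classical MDS coordinates of samples on the best panel,
   per-population genotype/expression distributions of selected markers,
   per-sample misclassification proportions, marker selection times, and a
   run manifest that reproduces every table byte-identically. Plots are
   optional renderings of the tables (`--plots`, requires matplotlib).

## CLI

```sh
# synthetic data with known ground truth (4 populations, 60/60/45/45)
aimsel simulate --preset hapmap-like --seed 1 --out data/

# QC only
aimsel qc --genotypes data/genotypes.tsv --expression data/expression.tsv \
    --labels data/labels.tsv --annotation data/probe_annotation.tsv \
    --snp-annotation data/snp_annotation.tsv --seed 1 --out qc_out/

# full run: QC + CV forward selection + reports
aimsel select --genotypes data/genotypes.tsv --expression data/expression.tsv \
    --labels data/labels.tsv --annotation data/probe_annotation.tsv \
    --snp-annotation data/snp_annotation.tsv \
    --mode snp+ge --folds 10 --seed 1 --out run_out/

# or from a YAML config / a previously written run manifest
aimsel run --config run_out/run_manifest.yaml
```

Key outputs in the run directory: `selection_trace.tsv`,
`candidate_models.tsv`, `best_model.txt`, `selection_times.tsv`,
`overlay.tsv`, `parallel_coordinates.tsv`, `mds.tsv`,
`marker_distribution.tsv`, `misclassification.tsv`, `marker_impact.tsv`,
`qc_report_snp.tsv`, `qc_report_probes.tsv`, `run_manifest.yaml`.

Analysis modes: `ge` (expression only), `snp` (genotypes only), `snp+ge`
(integrated candidate pool).

## Library

```python
from aimsel import (
    SimulationConfig, simulate_dataset, SNPQCConfig, filter_snps,
    make_cv_partition, SelectionConfig, run_cross_validation,
)

g, e, labels, *_ = simulate_dataset(SimulationConfig(seed=1))
g, qc_report = filter_snps(g, labels, SNPQCConfig(seed=1))
cv = make_cv_partition(labels, k=10, seed=1)
models = run_cross_validation(g, e, labels, cv, SelectionConfig())
print(models.traces[models.best_fold].selected_markers)
```

`fda.fit_fda` / `fda.predict` expose the optimal-scoring discriminant
directly (with a linear regression basis it is decision-equivalent to
LDA); `fda.save_model` / `fda.load_model` serialize fitted panels as plain
text.

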