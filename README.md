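# mmpt — myeloma pharmacotyping toolkit

A tested, reusable implementation of an image-based ex vivo drug-response
analysis pipeline for multiple myeloma bone-marrow samples. Starting from
per-cell phenotype tables and 384-well plate layouts, it computes:

- **Drug-response scores** — relative cell fractions (RCF) per treated well
  against matched DMSO/isotype controls, zero-centered PCY scores
  (`1 − mean RCF` over technical replicates), replicate QC, cross-validated
  LASSO imputation of missing responses, and elastic-net ranking of protein
  predictors (`mmpt.drug_response`).
- **PhenoGroups** — bone-marrow composition modes from latent cell features:
  PCA-based selection of the top-100 features, spectral clustering (k = 15)
  of a balanced training subsample, k-NN label propagation, control-well
  composition matrices, correlation similarity and a 3-group dendrogram cut
  (`mmpt.phenogroups`).
- **Proteome integration** — double z-score normalization, Spearman
  associations of protein abundance with myeloma content (exact permutation
  p-values at small n, Storey q-values), paired big/small validation fold
  changes, the quadrant signature with Fisher concordance, hypergeometric
  gene-set enrichment, covariate residualization and drug–protein
  correlation networks (|ρ| > 0.585, p < 0.05, plus per-drug top/bottom-2)
  (`mmpt.proteomics`).
- **scRNA-seq & cytokines** — UMI QC filtering (≥ 300 non-Ig UMIs, ≤ 50%
  mitochondrial, lineage-marker exclusion), big-like signature-ratio scoring
  per cell and patient, and detection-limit-aware two-stage cytokine
  z-scoring (`mmpt.expression`).
- **Clinical outcomes** — ANOVA/t-test feature–drug association networks
  with cross-validated stability, integrated PCY (iPCY) scores by matching
  tested treatments to clinical regimens, mean-threshold sensitivity
  stratification and Kaplan–Meier / log-rank / hazard-ratio survival
  analysis of time to next treatment (`mmpt.outcomes`).
- **Phenotyping** — confidence filtering, marker-gate class assignment
  (stand-in for the trained CNN classifiers), big/small plasma-cell size
  split, KDE-valley marker-positivity thresholds and spatial cell–cell
  interaction scores (`mmpt.phenotyping`).

A synthetic-cohort generator (`mmpt.synthetic`) produces every input the
pipeline consumes — cells, plate layouts, proteomes, cytokines, scRNA
counts and clinical tables — from a single seed, with ground truth for all
planted structure, so the full pipeline is testable without patient data.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the simulation-based acceptance criteria
(control normalization, PCY recovery, PhenoGroup recovery, signature
selection, statistical-oracle equivalence, survival calibration, LASSO /
elastic-net recovery, scRNA scoring, cytokine invariants); the rest of the
suite covers each module against closed-form and brute-force oracles.

## CLI

```sh
mmpt simulate  --out sim --seed 1 --samples 12        # synthetic cohort
mmpt phenotype --cells sim/cells.tsv --layout sim/plate_layout.csv --out pheno
mmpt score     --cells sim/cells.tsv --layout sim/plate_layout.csv --out score
mmpt phenogroup --cells sim/cells.tsv --layout sim/plate_layout.csv \
               --out pg --k 15 --groups 3 --seed 7
mmpt proteome-integrate --proteome sim/proteome.tsv \
               --fraction-big pheno/fraction_big.csv \
               --validation-big sim/validation_big.tsv \
               --validation-small sim/validation_small.tsv --out prot
mmpt cytokines --panel sim/cytokines.csv --status sim/cytokine_status.csv --out ck
mmpt outcome   --drug-matrix score/drug_response.tsv --clinical sim/clinical.csv \
               --out surv
mmpt run-all   --out run --seed 1                     # everything, in order
```

Stage parameters (confidence cutoff 0.6, k = 15, 3 PhenoGroups, p < 0.05
and |log2FC| > 0.3 signature cutoffs, |ρ| > 0.585 network threshold,
elastic-net α = 0.5, 100-point λ scans in 10-fold CV, 300-UMI / 50%-mito
scRNA filters, p < 0.01 ANOVA filter) default to the published analysis
values and are configurable through a YAML file passed with `--config`.

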