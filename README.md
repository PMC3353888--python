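# pathscan

Pathway-focused SNP association analysis for hypertension-style cohorts:
quality control, additive per-SNP models, LD-aware set-based permutation
tests at pathway and gene level, and an unfavorable-allele-ratio genetic
risk score — plus a seeded synthetic-cohort generator so the whole pipeline
is testable end to end without any external data.

## What it does

- **Cohort model & I/O** (`pathscan.cohort`): dense minor-allele dosage
  matrices (0/1/2, NaN missing; male X hemizygous 0/1), PLINK text
  (.ped/.map) and PLINK 1 binary (.bed/.bim/.fam) codecs, plain-text VCF,
  TSV phenotype/gene/pathway tables. Dosages are always re-oriented to the
  observed minor allele. SNPs are assigned to genes with a ±20 kb flank
  (inclusive bounds); pathways are de-duplicated unions of gene SNP sets.
- **Synthetic cohorts** (`pathscan.simulate`): threshold latent-Gaussian
  genotypes with block LD (calibrated to a target r²), covariates matched
  to the study cohort's marginals, logistic-liability hypertension with
  per-SNP odds ratios concentrated in a causal pathway, SBP/DBP consistent
  with the case label, and medication effects on stored raw BP. One root
  seed, named substreams, bit-reproducible.
- **QC** (`pathscan.qc`): SNP missingness (>0.05), MAF (<1%), exact
  Hardy–Weinberg test (probability-ordered, P<1e-6; females only on X),
  then a sample filter on the homozygosity-based inbreeding coefficient
  (outside 4 SD), plus duplicate-concordance checking.
- **Association** (`pathscan.association`): additive logistic (hypertension)
  and linear (medication-adjusted SBP/DBP, +15/+10 mmHg) models adjusted
  for sex, age, age², BMI; 1-df Wald chi-square statistics; X dosages coded
  0/1 for males.
- **Set-based test** (`pathscan.settest`): greedy selection of the most
  significant SNPs at a P cutoff with r² pruning, set statistic = mean
  chi-square of the selection, phenotype-label permutation with empirical
  p = (1+r)/(n+1), Bonferroni helpers, and a Default/Strict/Loose
  sensitivity grid run against identical permutations. Two engines:
  `wald_refit` (full GLM refits, reference) and `score_fast` (vectorized
  residualized statistics). An exhaustive mode enumerates all distinct
  permutations for exact small-sample tests.
- **Risk score** (`pathscan.riskscore`): per-sample r/n ratio of unfavorable
  alleles (minor allele of risk SNPs, major allele of protective SNPs),
  quintile categorization, adjusted quintile regression vs the lowest
  quintile.
- **Pipeline** (`pathscan.pipeline`): one config + seed → QC report,
  association TSVs, pathway/gene tables (sorted, starred at the Bonferroni
  cutoff), sensitivity table, risk-score quintile models, JSON manifest.

## CLI

```sh
# generate a synthetic cohort (PLINK text + genes/pathways TSV + truth manifest)
pathscan simulate --spec spec.yaml --out data/ --seed 7

# stage by stage
pathscan qc --in data/cohort --pheno data/cohort.pheno.tsv --out clean/
pathscan assoc --in clean/cohort --pheno clean/cohort.pheno.tsv --outcome htn --out assoc.tsv
pathscan settest --in clean/cohort --pheno clean/cohort.pheno.tsv \
    --genes data/genes.tsv --sets data/pathways.tsv \
    --r2 0.5 --p-cutoff 0.05 --n-perm 10000 --seed 7 --out settest.tsv
pathscan riskscore --in clean/cohort --pheno clean/cohort.pheno.tsv \
    --model model.tsv --outcome htn --out scores.tsv

# or everything from one YAML config
pathscan run --config cfg.yaml
```

Minimal `cfg.yaml` for a simulated run:

```yaml
out_dir: out
seed: 7
simulate:
  n_samples: 1614
  pathways: [[ADRA1, 3, 10], [NULL1, 3, 10], [NULL2, 3, 10]]
  causal_pathway: ADRA1
  effect_or_range: [1.2, 1.3]
set_test:
  n_perm: 10000
  stat_mode: score_fast
```

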