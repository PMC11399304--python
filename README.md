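# sexstrat

Sex-stratified genetic architecture analysis of quantitative traits,
exercised end-to-end on synthetic genotype/phenotype data with known ground
truth.

The pipeline covers:

* **synthetic_data** — HWE genotype simulation (autosomes + X for XY/XX
  individuals), per-sex polygenic phenotypes with target heritabilities
  `h2_male`/`h2_female` and between-sex effect correlation `rg`, injected
  sex-differentiated SNP effects, and spherical multi-region phenotype
  panels with network labels.
* **qc** — variant filters (biallelic, MAF, Hardy–Weinberg chi-square,
  missingness; X evaluated per sex) and sample filters (Euler number,
  per-sex ICV outliers, genotype missingness, per-sex phenotype SD window).
* **grm** — GCTA-style genetic relationship matrices for autosomes and the
  X chromosome under three dosage-compensation codings (FDC/NDC/EV),
  likelihood-based coding selection, and greedy relatedness pruning.
* **reml** — average-information REML with EM warm-up: univariate
  multi-GRM fits with delta-method heritability SEs, boundary-aware
  likelihood-ratio tests, and the bivariate between-sex fit reporting the
  genetic correlation `r_g = C_G / sqrt(V_Gm V_Gf)` with an LRT against
  `r_g = 1`.
* **gwas** — phenotype residualization (per sex, with global-measure
  correction) and sex-stratified per-variant linear association with
  PLINK2-style output.
* **sexdiff** — the difference-of-estimates z statistic
  `z = (est_m - est_f)/sqrt(se_m^2 + se_f^2)` applied to heritability and
  SNP-effect pairs, Bonferroni threshold arithmetic, paired t/Wilcoxon
  region tests, the phenotypic sex-difference linear model, and the nested
  V_G-on-V_P model comparison.
* **spatial** — spin-permutation (random rotation) enrichment of binary
  region maps against network partitions via Fisher odds ratios.

File formats: PLINK1 `.bed/.bim/.fam`, dosage TSV, GCTA binary GRM
triplets (`.grm.bin/.grm.N.bin/.grm.id`), phenotype/covariate TSVs, and
JSON sidecars for simulation truth and QC reports.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite (threshold
arithmetic, REML parameter recovery, z-test calibration, injected-SNP
rank recovery, oracle equivalence, spin-test calibration, GRM round
trips); the simulation-heavy tests take several minutes on one CPU.

## CLI

```sh
sexstrat simulate --n-male 500 --n-female 500 --m-auto 2000 --h2 0.4 --seed 1 --out sim
sexstrat qc sim --out sim_qc
sexstrat grm sim_qc --out sim_grm --prune 0.05
sexstrat reml --grm sim_grm --pheno sim.pheno.tsv --out sim.hsq
sexstrat reml-bivar --grm sim_grm --pheno sim.pheno.tsv --out sim.rg.tsv
sexstrat gwas sim_qc --pheno sim.pheno.tsv --sex male --out gwas_m.tsv
sexstrat sexdiff --male gwas_m.tsv --female gwas_f.tsv --strict-n 361 --out diff.tsv
sexstrat spin --map map.tsv --annotations annot.tsv --n-perm 10000 --seed 42 --out spin.tsv
```

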