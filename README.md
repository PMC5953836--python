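# tmbkit

Post-variant-calling analysis of tumor mutation burden (TMB) as an
immunotherapy biomarker in non-small-cell lung cancer cohorts. Given
per-patient somatic variant tables (with read support), clinical outcomes,
tumor purity / local copy number, HLA class-I alleles, and precomputed
peptide–MHC binding affinities, the package computes:

- **TMB** — the absolute count of nonsynonymous SNVs and indels per tumor
  exome (after excluding variants with allele fraction < 0.05 and samples
  with mean coverage < 60X tumor / < 30X normal), optionally restricted to
  the genes of a targeted sequencing panel, plus percentile ranks against a
  mixed-histology reference cohort (80% adenocarcinoma / 20% squamous).
- **Mutation clonality** — for each SNV, a posterior over the cancer cell
  fraction (CCF) on a 100-point grid, from the binomial likelihood of the
  observed alt reads `a` of depth `N` at the expected allele fraction
  `E[VAF | CCF] = p·CCF·m / (CPN_norm·(1−p) + p·CPN_mut)` (purity `p`,
  multiplicity `m = 1`); a mutation is clonal when `P(CCF > 0.95) > 0.5`.
- **Neoantigen candidate burden** — counts of mutant 8–11mer peptides
  binding a patient allele at IC50 ≤ 500 nM (strong ≤ 50 nM), with window
  enumeration and clonal-only burdens.
- **Biomarker statistics** — Fisher exact odds ratios, Mann-Whitney tests,
  ROC AUC (with the `AUC = U/(n₁n₀)` identity), Kaplan-Meier / log-rank
  comparisons with Mantel-Haenszel `(O₁/E₁)/(O₂/E₂)` hazard ratios,
  Spearman correlations, Cochran-Armitage trend tests for composite
  TMB × PD-L1 groups, per-gene Fisher scans with Benjamini-Hochberg
  correction, and multivariable logistic / Cox models.
- **Synthetic cohorts** — a seeded generator producing complete study
  datasets (clinical, variants, CCF inputs, HLA, affinities, panels,
  reference cohort, latent truth) with the statistical structure the
  analysis assumes, so every stage is testable without external data.

The intended users are cancer-genomics analysts who have already run a
somatic calling pipeline (alignment, MuTect/Indelocator-style calling,
ABSOLUTE purity/copy-number, HLA typing, MHC binding prediction are all
upstream and out of scope) and want the downstream biomarker analysis to be
reproducible and testable.

## Worked example

Run the whole pipeline on a 75-patient synthetic cohort:

```bash
cat > config.yaml <<EOF
synthetic:
  n_patients: 75
  seed: 7
EOF
tmbkit run-all --config config.yaml --out demo_run
```

which prints:

```
CohortStudy results (tmbkit 0.1.0)
  patients: 75 (TMB-high 37 / TMB-low 38, median TMB 142)
  ORR high vs low TMB: 54% vs 16% (OR 6.27, p 0.00065)
  DCB high vs low TMB: 70% vs 37% (OR 4.05, p 0.0054)
  TMB responder vs non-responder: median 224.5 vs 107 (Mann-Whitney p 0.0024); ROC AUC 0.71
  PFS high vs low TMB: HR 0.53 [0.33, 0.85], log-rank p 0.0041
  composite TMB x PD-L1 trend: chi2 3.43, p 0.064
  neoantigen burden vs TMB: Spearman rho 1.00 (p 1.2e-116)
```

Reading the output: the cohort is split at the median TMB (142 mutations;
ties go low, so 37 high / 38 low). Objective response (confirmed CR/PR) is
much more frequent in the TMB-high arm (54% vs 16%; Fisher exact odds ratio
6.27), durable clinical benefit likewise, progression-free survival is
longer in the TMB-high arm (Mantel-Haenszel hazard ratio 0.53, high-TMB
group in the numerator), and the per-patient neoantigen candidate burden
tracks TMB almost perfectly. `demo_run/report.json` holds every block
(including the per-gene scan and the multivariable models) with a
provenance section recording the config hash and seed; re-running the same
config reproduces the report byte-for-byte.

The same analyses are available as a library:

```python
import tmbkit as tk

post = tk.ccf_posterior(alt_count=48, depth=120, purity=0.8)
print(post.ccf_mode, post.prob_ccf_gt, post.clonal)   # 1.0 0.3449... False

rep = tk.contingency_report([[19, 18], [5, 33]], [[24, 13], [13, 25]])
print(rep["orr"]["fisher"].effect)                    # 6.966...
```

Individual stages are exposed as subcommands (`tmbkit simulate`,
`tmbkit tmb`, `tmbkit clonality`, `tmbkit neoantigens`, `tmbkit table-mode`);
`tmbkit table-mode` computes the Fisher statistics directly from printed
2×2 contingency counts without patient-level data.

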