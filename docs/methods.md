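# Methods

## Scope and data model

The package starts where a somatic-calling pipeline ends. Its inputs are
per-patient variant tables (MAF-like TSV with gene, coordinates, alleles,
consequence, tumor alt-read count and depth), a clinical table (best
response, durable clinical benefit, progression-free survival time and
event, PD-L1 percent, histology, smoking, ECOG, mean coverages), gene-panel
lists, per-variant purity / local copy number, patient HLA class-I alleles,
and precomputed peptide–MHC IC50 tables. Alignment, variant calling,
purity/ploidy estimation, HLA typing, and binding prediction are upstream
tools whose outputs are consumed, never reimplemented.

Two record-level filters are applied before any counting: variants with
tumor allele fraction strictly below 0.05 are excluded (the boundary value
is retained), and samples with mean target coverage strictly below 60X in
tumor or 30X in normal fail QC. Missing PD-L1 is a first-class missing
value: such patients are excluded from PD-L1 analyses, never imputed.
Site-artifact (panel-of-normals) filtering is represented only as an
optional boolean exclusion column, since no normal panel ships with the
package.

## TMB

TMB is the absolute number of nonsynonymous variants (SNVs and indels
alike) per tumor exome — an absolute count, not a per-megabase rate; no
capture-size normalization is applied. A second scheme counts all variants,
silent ones included, for sensitivity analyses. Consequence terms are
normalized into {nonsynonymous, synonymous, other} through an editable YAML
vocabulary (`src/tmbkit/data/effect_classes.yaml`); unrecognized terms fall
into `other` so they cannot silently inflate TMB.

Panel-restricted TMB counts only variants in genes covered by a named panel
(e.g. 468- or 315-gene clinical panels) and is by construction bounded by
exome TMB.

Percentile ranks are computed against a reference cohort assembled as all
adenocarcinoma samples plus a seeded uniform subsample of squamous samples
(defaults 569 + 141 of 491, i.e. a 710-sample 80/20 mix). The rank
convention is midrank — `100·(#below + 0.5·#ties)/N` — chosen for stability
under ties (integer TMB values tie often) and monotonicity; it is
configurable in the sense that the strict-below and at-or-below counts are
recoverable from the entries.

Stratification rules: median split labels "high" strictly above the median
(ties go low, so a 75-patient cohort with one value at the median splits
37/38); tertiles/quartiles use inclusive-lower half-open bins at empirical
quantile cut points with the top bin closed; an explicit threshold rule is
also available. All cut points are reported alongside the labels.

## Cancer cell fraction and clonality

For an SNV with `a` alt reads at depth `N`, sample purity `p`, local copy
numbers `CPN_norm` (normal) and `CPN_mut` (tumor), the expected allele
fraction at cancer cell fraction `c` is

    E[VAF | c] = p·c·m / (CPN_norm·(1−p) + p·CPN_mut)

with multiplicity `m` fixed to 1 (exposed as a parameter for sensitivity
analysis). The denominator is the mean number of locus copies per sampled
cell; the numerator the mean number of mutant copies. The likelihood of `c`
is `Binom(a | N, E[VAF | c])`, evaluated in log space (stable to depth 10^5
and beyond) on a uniform grid of 100 CCF values 0.01 … 1.00 and normalized
— with the implicit uniform grid prior, the normalized likelihood is the
posterior. A mutation is called **clonal** when the posterior mass strictly
above 0.95 exceeds 0.5 (both inequalities strict); the rule is deliberately
conservative so clonal mutations are not over-called.

Clonality estimation is restricted to SNVs; indels, rows with missing
purity/copy number, and degenerate likelihoods are flagged `unresolved`,
logged, and excluded from clonal counts.

Numerical notes: the mass "above 0.95" is the sum over grid points
{0.96, …, 1.00}, computed with a small epsilon so float representation of
0.95 cannot flip the boundary; posteriors are renormalized after
exponentiation so weights sum to 1 within 1e-9.

Precision limits worth knowing: at depth 1000 on diploid copy-neutral loci
in a fully pure sample, binomial VAF noise maps to CCF error with Jacobian
2, so the posterior mode recovers a true CCF within ±0.05 for ~95.4% of
mutations in expectation (a single 500-SNV simulation fluctuates by about
±1 percentage point around that). Because the grid is capped at 1.0 and the
clonal rule is conservative, truly clonal mutations in impure samples are
systematically under-called: label accuracy against simulated truth is
~0.92 at purity 1 but degrades to ~0.79 when purity is uniform on
(0.3, 0.9). This is a property of the classification rule, not an
implementation artifact.

## Neoantigen candidates

For a single-residue change in a protein of length `L`, every 8–11mer
window fully inside the protein containing the mutated position is a mutant
peptide (38 windows for an interior mutation, 4 at a terminus, 1 for an
8-residue protein). For multi-residue variants (e.g. frameshifts) windows
containing the variant start or lying downstream are enumerated, since all
downstream sequence is altered.

A candidate neoantigen is a peptide whose minimum IC50 across the patient's
class-I alleles is ≤ 500 nM (inclusive); strong binders use ≤ 50 nM. The
burden unit is the distinct (mutation, peptide) pair — a peptide binding
several alleles counts once; counting peptide–allele pairs instead is a
documented option, since deduplication conventions vary across pipelines.
Clonal neoantigen burden restricts the count to mutations classified
clonal; unresolved mutations are excluded with a logged tally.

## Association statistics

All p-values are two-sided. Conventions:

- **Fisher 2×2**: point estimate is the cross-product odds ratio
  `(a·d)/(b·c)`; the exact p sums hypergeometric probabilities no larger
  than the observed table's (the common software convention). Zero-cell
  odds ratios are reported as 0 / ∞ sentinels with a Haldane-Anscombe
  corrected value in the notes. The CI is Woolf (logit ± 1.96 SE), defined
  only for all-positive tables; published CIs computed by other conventions
  will differ even when the OR and p match exactly.
- **Mann-Whitney**: exact enumeration for pooled n ≤ 12 without ties,
  otherwise normal approximation with tie correction.
- **ROC AUC**: trapezoidal over the empirical curve (ties count half), so
  AUC ≡ U/(n₁·n₀); the p-value is the Mann-Whitney p between classes. This
  identity is property-tested.
- **Survival**: Kaplan-Meier per group; log-rank p; hazard ratio by the
  Mantel-Haenszel observed/expected method `HR = (O₁/E₁)/(O₂/E₂)` with the
  first-listed group in the numerator (orientation echoed in every result)
  and CI `exp(log HR ± 1.96·√(1/E₁+1/E₂))`. The O/E estimator is mildly
  attenuated toward 1 for strong effects (a true exponential HR of 0.41 at
  500 events/arm is estimated around 0.43–0.49, where Cox regression — used
  as a cross-check in the tests — centers on 0.41); this is a known
  property of the estimator, shared with common clinical software.
- **Composite TMB × PD-L1**: PD-L1-positive is inclusive (≥ 1%), TMB-high
  strict (> median); patients are labelled both / one / neither and the
  response trend across the ordered groups uses the Cochran-Armitage
  chi-square for trend (validated against R's `prop.trend.test` to 1e-8).
- **Gene scans**: per-gene Fisher tests of mutation × response with
  unadjusted p plus Benjamini-Hochberg q (both reported, since small
  cohorts are typically read unadjusted); never-mutated or absent genes are
  skipped with an explicit note.
- **Multivariable models**: logistic (response) and Cox (PFS) on complete
  cases, with the dropped-case count logged. Constant covariates are
  dropped with a warning; perfect separation refuses the fit rather than
  returning unstable estimates. Time-horizon AUCs (6 and 12 months)
  classify progression-by-horizon using the Cox linear predictor, excluding
  patients censored before the horizon.

Standard machinery (exact hypergeometric/Mann-Whitney/Spearman p-values,
KM curves, log-rank, BH correction, logistic and Cox fitting) is delegated
to scipy, statsmodels and lifelines; the O/E hazard ratio, the trend test,
and the CCF posterior are implemented here.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with defaults that reproduce the target study conditions:

- 75 patients, objective response rate 0.32.
- TMB | response class ~ log-normal with medians 273 (responders) and 114
  (non-responders) and common log-sd 0.9. The dispersion is a calibration
  choice: with equal log-sd σ in both classes the asymptotic
  TMB-response AUC is Φ(ln(273/114)/(σ√2)), and σ = 0.9 puts it at ≈ 0.75.
- PD-L1 independent of TMB by construction: mass 0.33 at 0%, else uniform
  1–100%; 5/75 missing.
- Durable-benefit rates conditioned on TMB group (0.65 high / 0.34 low),
  sampled directly rather than derived from PFS so contingency structure is
  controlled exactly.
- PFS exponential within TMB group with administrative censoring at 30
  months (typical follow-up at database lock). The printed group medians
  (17.1 / 3.7 months) and hazard ratio (0.41) cannot both hold under
  exponential survival (the median ratio implies HR ≈ 0.22), so `pfs_mode`
  selects which to match; the default `match_hr` anchors the low-TMB median
  at 3.7 months and sets the high-TMB hazard to 0.41× — the hazard ratio
  being the headline statistic.
- Reads follow the clonality forward model: 80% of variants clonal
  (CCF 1), the rest CCF ~ U(0.1, 0.6); purity ~ U(0.2, 0.9) per patient;
  depth ~ Poisson(148) (the study's mean tumor coverage); alt reads
  binomial at the expected VAF. Variants landing below VAF 0.05 are dropped
  from the emitted table and tallied in the truth record, mirroring the
  real filter.
- 25% of variants are silent; 10% of nonsynonymous variants are frameshift
  indels; genes are uniform over a ~19,000-symbol universe; panels are
  seeded random 468- and 315-gene subsets (true panel contents are not
  public inputs here).
- Affinities: per nonsynonymous variant, all windows containing the mutated
  residue (capped at the 38 interior windows for frameshifts) receive an
  IC50 drawn log-uniformly over 10^0–10^4.7 nM against a random patient
  allele. Candidate burden is then a binomial thinning of windows per
  mutation, which ties burden tightly to TMB.
- The reference cohort draws log-normal TMB per histology (medians 160
  adeno / 210 squamous, log-sd 1.0 — plausible for NSCLC exomes) and mixes
  569 + 141-of-491 samples.

Everything derives from one seeded generator, so a config reproduces its
dataset byte-for-byte. The truth record (true TMB, CCF, clonality,
uncensored PFS, drop counts) is written separately and never read by
analysis stages.

**What the generator does not model** — and hence what passing tests do not
show about real data: sequencing error and caller artifacts, mutational
signatures and gene-level hotspots (gene assignment is uniform, so the gene
scan exercises machinery, not biology), allele-specific binding (IC50s are
exchangeable across peptides, making the burden–TMB correlation ~1.0,
tighter than the ~0.92 seen in real cohorts), non-exponential hazards, and
informative censoring. Patient-level results of the original cohort are not
reproducible from printed data; only its contingency-table statistics are
checked exactly, everything else through calibration of this generator.

## Problem sizes used in the checks

The shipped checks run at sizes chosen to make Monte Carlo noise small
relative to the tolerances: calibration cohorts of 2,000–5,000 patients
(clinical-level only), survival recovery at ~500 patients/arm, CCF oracle
agreement on 100 random inputs, recovery simulations of 500 SNVs per
replicate (averaged over ten fixed replicates where a single draw would be
noise-dominated), and full end-to-end runs at the study's own size of 75
patients with affinity tables included.
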