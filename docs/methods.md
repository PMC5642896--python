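# Methods

## The analysis

The package models a retrospective case-control pharmacogenomic study of
isoniazid-induced liver injury (INH-DILI). The exposure of interest is the
NAT2 *slow acetylator* (SA) phenotype, a diplotype property: a person is SA
when both NAT2 haplotypes carry an acetylation-slowing coding variant.
The pipeline stages are genotype QC, rule-based phenotype inference,
candidate-SNP association under genetic models with correlated-test
adjustment, a clinical-validity calculus, and ROC comparison of risk
models. Each stage is usable as a library function; the `pgxvalidity` CLI
chains them.

## Acetylator inference

Phenotype is inferred from a 4-SNP panel (rs1801280, rs1799930, rs1799931,
rs1801279), dosages oriented as counts of the acetylation-slowing allele:
RA if all dosages are 0, IA if exactly one SNP is heterozygous, SA if two
or more SNPs are heterozygous or any SNP is homozygous variant. The rule
set is total and monotone in variant burden (property-tested). rs1801279
is essentially monomorphic in East/Southeast and South Asian populations,
so a missing call there is imputed as homozygous reference and flagged;
a missing call at any other panel SNP refuses the call under the default
policy rather than silently imputing an informative genotype. The panel is
configuration, not hard-coded: any SNP set with declared allele
orientation can be supplied.

The tag SNP rs1495741 (14.5 kb 3' of NAT2) proxies the phenotype through
its genotype class: AA predicts SA, AG/GG predict non-SA. Concordance is
reported as the fraction of samples where the two agree, with a 2×2
cross-table.

## Synthetic cohort generator

Because individual-level data from such studies are typically not
deposited, every stage is exercised against a seeded generator whose
defaults *are* the study conditions the analysis assumes:

- **Scale and strata.** 24 cases / 79 controls across four self-reported
  ethnic strata (Chinese 12/57, Malay 5/10, Indian 1/7, Others 6/5).
- **Haplotypes, not SNPs, are the generative unit**, because SA status is
  a diplotype property. Seven coding SNPs define the haplotype table;
  packaged frequencies are synthetic stand-ins calibrated so control-group
  marginal minor-allele frequencies land near the observed values
  (rs1041983 ≈ 0.367, rs1799930 ≈ 0.222, rs1799931 ≈ 0.139, rs1801280 ≈
  0.095, rs1799929 ≈ 0.076); the Indian stratum shifts mass toward the
  NAT2\*5B haplotype as seen in South Asian populations. Population-level
  SA frequency under these defaults is ≈ 0.21, and the case-enriched
  cohort averages ≈ 0.31 inferred SA.
- **Disease model.** `logit p = β₀ + β_SA·[SA] + β_F·[female]` with
  defaults β₀ = −4.6 (≈1% baseline risk), β_SA = ln 10 (the adjusted SA
  odds ratio the analysis is designed to recover), β_F = 1.59 (the female
  excess among cases, OR ≈ 4.9 from the cohort's sex margins).
- **Fixed margins.** Statuses are Bernoulli draws over a candidate pool;
  exactly the configured cases and controls per stratum are then
  subsampled uniformly *within* status, which preserves the
  status-conditional genotype distribution — the defining property of
  retrospective sampling. The pool doubles automatically if a quota is
  not reached; an unreachable quota raises.
- **Tag SNP as a class-flip.** The tag is set to the class-concordant
  genotype with probability 0.98 (AG/GG split 0.62/0.38, the
  Hardy–Weinberg split at a G frequency of 0.55), because the emulated
  design reports only a concordance percentage, not phase with rs1495741.
- **Background SNPs** (default 300) have base frequencies Uniform(0.05,
  0.5) perturbed per stratum on the logit scale by N(0, δ²) — an
  F_ST-like divergence (defaults 0.25–0.9, largest for the Indian stratum
  so PC1 separates it, as in the emulated study's structure).
- **Grades.** Cases draw CTCAE grades from (10/24, 13/24, 1/24) over
  grades 2/3/4, independent of genotype by default; a trend switch tilts
  the grade distribution of SA cases upward to emulate a dose–response of
  severity.
- **Missingness** is independent per call (default 0.005 in the pipeline
  demo; 0 in consistency tests). One global seed drives every draw.

What the generator does **not** emulate: linkage disequilibrium beyond the
NAT2 haplotype block and the tag's class-flip, genotyping-intensity
artefacts, relatedness, age or dose effects on risk, and
genotype-dependent missingness. Passing tests therefore demonstrate the
*statistical machinery* — calibration, recovery, invariances — not
robustness to those real-data features.

## Statistical conventions

- **HWE exact test**: conditional on sample size and minor-allele count;
  the two-sided p sums the probabilities of heterozygote counts whose
  probability does not exceed the observed one. Verified exhaustively
  against rational-arithmetic enumeration for all configurations with
  n ≤ 50. Testing is restricted to one reference stratum (default
  "Chinese", the largest) so admixture is not mistaken for genotyping
  error.
- **Fisher's exact test**: two-sided by the point-probability convention;
  the reported odds ratio is the sample cross-product (a·d)/(b·c), with
  zero cells flagged (conditional-MLE ORs are out of scope). Verified
  exhaustively against hypergeometric enumeration for totals ≤ 40.
- **Covariate comparisons**: continuous-normal variables use the
  two-sample t test, skewed ones Mann–Whitney U; binary variables use the
  continuity-corrected chi-square on the 2×2 and multi-level categorical
  variables use per-level Fisher tests (each level vs the rest) plus an
  overall chi-square. This mixed convention reproduces the printed
  comparisons of the emulated study's cohort table.
- **Logistic association**: maximum likelihood with Wald CIs and p-values;
  complete-case per test. A coded genotype constant overall or within
  either outcome group is inestimable (reported as such, mirroring "NA"
  rows in small candidate studies); separation (|log-OR| > 15 or exploding
  SE) is flagged inestimable rather than penalized — Firth correction is a
  deliberate non-goal.
- **Correlated-test adjustment**: the m×m correlation of test statistics
  is approximated by the correlation of covariate-residualized coded
  predictor vectors (a score-test approximation); non-PSD estimates are
  repaired by eigenvalue clipping (flagged). For each test,
  `p_adj = 1 − Pr(|Z_j| ≤ z_i ∀ j)` under N(0, R), evaluated by a Genz
  separation-of-variables quasi-Monte-Carlo integrator (scrambled Sobol
  points, seeded; point count doubles until the scramble-to-scramble SE
  falls below 10⁻⁴, capped at 2¹⁴ points × 8 scrambles). The integrator
  is validated at the independence limit (Šidák) and the
  perfect-correlation limit (no adjustment) to 2×10⁻³. Adjusted values
  are clipped to [raw, 1]; the family is whatever is estimable at run
  time, and its size is reported.
- **Clinical validity**: sensitivity and specificity are kept as exact
  fractions of the table counts; rounding happens only in the report
  formatter (decimal half-up, matching printed clinical tables). PPV/NPV
  come from Bayes' theorem at an assumed prevalence (default 10%, sweep
  5–20%). Two PAF estimators are co-reported: the incidence formula
  (IP_t − IP_o)/IP_t and the case-based p_c·(OR−1)/OR; they coincide when
  the OR is replaced by the risk ratio at the same prevalence (identity
  property-tested). The absolute risk reduction backing the NNT is
  implemented as risk_exposed − risk_unexposed = PPV − (1 − NPV): a
  literal "incidence in total minus incidence in exposed" reading does
  not reproduce the standard NNT and is documented here as a discrepancy
  in the usual presentation of these formulas. NNT is undefined (flagged)
  when the risk difference is ≤ 0.
- **ROC analysis**: risk models are in-sample logistic fits (apparent
  AUC); ethnicity enters as indicators with the largest stratum as
  reference. AUC is the exact pairwise statistic with half-credit for
  ties; DeLong's test uses placement-value covariances. On separation the
  risk-model coefficients are capped at ±15 and the model is still
  scored, flagged. Youden's optimum scans all distinct score thresholds,
  ties broken toward higher specificity.

## Calibration caveat for nested ROC comparisons

DeLong's test is calibrated for *fixed* paired scores (the suite verifies
a nominal rejection rate in that regime). Comparing a clinical model with
the same model plus an uninformative feature, both refit in-sample on the
same data, is deeply *conservative*: the added noise feature perturbs both
nested models' scores almost identically, so the paired variance shrinks
faster than the AUC difference. The suite asserts that this comparison is
never anticonservative rather than that it is exactly nominal.

## Problem sizes used by the suite

Replicate-based properties use 200 study-scale cohorts (24/79) with a
reduced background-SNP count (the properties tested do not involve the
background variants); the power computation uses 2,000–4,000 Monte-Carlo
replicates; exhaustive oracle checks cover all 2×2 tables with total ≤ 40
(reduced by their margin symmetries, which are asserted separately) and
all HWE configurations with total ≤ 50; the DeLong permutation oracle uses
10,000 within-pair swaps on an n = 30 fixture. The packaged pipeline demo
finishes in well under a minute on one CPU.

## Known limitations

- No star-allele (NAT2\*) haplotype naming or phasing; inference is
  panel-rule based only.
- Sex checks from array intensities are out of scope; a mismatch list can
  be injected into QC.
- No confidence intervals for PPV/NPV/PAF/NNT (the validity calculus is a
  point transform of the 2×2 and the assumed prevalence).
- In-sample (apparent) AUCs; no cross-validation, penalization, or
  reclassification indices.
- The generator's ethnic haplotype tables are calibrated stand-ins, not
  measured population frequencies.
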