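# Methods

This note documents the models, defaults and numerical choices behind
`gestmr`, and what the synthetic studies do and do not demonstrate.

## Synthetic cohort model

Each stratum is simulated independently. Genotypes are drawn in
Hardy-Weinberg proportions from per-stratum allele-frequency ranges, SNPs
assigned round-robin to chromosomes (no within-chromosome LD beyond family
structure). Relatedness is generated as sib pairs from explicit parental
genotypes: the second sib re-uses the first sib's parental allele slot with
probability 2·kinship, which at kinship = 0.25 is exactly Mendelian
transmission (shared-allele count 0/1/2 with probabilities 1/4, 1/2, 1/4)
and extends continuously to any kinship in [0, 0.5] with expected genotype
correlation 2·kinship.

Metabolites (mmol/L) follow
`met_k = baseline + Σ_j effect_jk·dosage_j + λ_k·U + ε_k`, with the residual
split between a class-shared latent factor (correlation `class_correlation`)
and an independent part. U is a single shared confounder; multiple
confounders would be a configuration extension. Glucose is generated
multiplicatively — `log(glucose) = log μ + Σ_k β_k (met_k − E[met_k]) +
λ_y·U + pleiotropy + ε` — so the natural-log transform of the outcome is
exactly correct. Medians default to 4.5 (fasting) and 6.0 mmol/L (2-hour)
with log-scale residual SD 0.12, placing the dysglycemia rates (fasting
> 6.1 or 2-hour > 7.8 mmol/L, strict) at a few percent. Horizontal
pleiotropy is an optional direct per-allele effect of a named SNP on a log
outcome. All coefficients, confounder draws, means and realised
heritabilities are returned as ground truth; everything is exactly
reproducible from (config, seed).

What the generator does **not** emulate: within-chromosome LD (instrument
thinning therefore mostly exercises engineered duplicates and family-induced
correlation), imputation uncertainty, missing metabolite values,
consanguinity beyond sib pairs, X chromosome, and non-Gaussian metabolite
error. Passing tests show the estimators behave correctly under their own
assumptions, not that those assumptions hold in any real cohort.

## Phenotype preparation

Outliers are masked per metabolite and per stratum, single pass, before any
transform. Two fence conventions exist: Tukey quartile fences
[Q1 − k·IQR, Q3 + k·IQR] (default, k = 1.5) and median-anchored fences
median ± k·IQR (default for the stringent composite stage, k = 3). Quartiles
use linear interpolation (type 7); the interval is closed, so a constant
series masks nothing. The `auto` transform picks log or sqrt by smallest
|sample skewness|; the rank-based normal-score transform (Blom,
Φ⁻¹((r−3/8)/(n+1/4)) with average ranks) has zero skewness by construction
and is therefore the fallback when the best analytic transform leaves
|skewness| > 0.2, not a competitor in the skewness comparison. The chosen
transform is logged per metabolite. Statistics are never pooled across
strata.

## Mixed-model association scan

REML for y = Cγ + u + e, u ~ N(0, A σ²_g) profiles the total variance and
optimises the ratio h = σ²_g/(σ²_g+σ²_e) in 1-D (bounded scalar
minimisation, explicit boundary check at h = 0) after a one-time
eigendecomposition of each GRM. A near-identity GRM (eigenvalue range
< 1e-8) is flagged non-identifiable rather than fitted. Variance components
are estimated once per (phenotype, left-out chromosome) under the no-SNP
null model and re-used for every SNP on that chromosome; per-SNP effects and
SEs come from GLS under V̂ with a Wald normal p. `loco_chromosome` is the
default policy; `loo_snp` (rank-one GRM downdate, dense solve per SNP) is
provided for toy scale; `global` exhibits the expected proximal
contamination; `none` is the naive OLS comparator.

MAF filtering at 0.05 is applied before scanning. λ is computed as
median(χ²)/χ²₀.₅(1) overall and within fixed MAF bins
{<0.001, [0.001,0.005), [0.005,0.01), [0.01,0.05), [0.05,0.1), ≥0.1}; bins
with under 20 SNPs are flagged unreliable, λ ≥ 1.1 flags inflation (with a
1e-12 float tolerance so the boundary rule is exact). Suggestive is
p ≤ 1e-5 (inclusive); genome-wide significance is p < 5e-8 (strict).

A design point worth stating: the GRM should come from a dense panel even
when only a subset of SNPs is scanned. With a sparse GRM panel (a few
thousand SNPs at n ≈ 1000) the GRM's eigen-noise attenuates the REML
heritability estimate (roughly by 1/(1 + 4n/m)), leaving residual
family-structure inflation in the mixed-model scan. The inflation study
therefore genotypes 50k SNPs, builds the GRM/LOCO from all of them, scans
5000, and places the polygenic background (h² = 0.5) on the non-scanned
loci so every scanned SNP is exactly null. Because a single scan's λ has
shared-dependence noise (SD ≈ 0.04 — all SNPs share one phenotype draw), λ
is pooled over 10 replicate phenotypes on the same cohort.

## Instruments and TSLS

Suggestive SNPs are pooled per metabolite class and greedily thinned by
in-sample LD: visit by ascending p (ties: chromosome, position), keep iff
r² < 0.2 against every kept SNP; undefined r² (monomorphic) counts as 0.
Each metabolite's instrument is its kept suggestive SNPs weighted by its own
GWAS betas; the GRS is unstandardised so the first stage has interpretable
units. In-sample LD replaces any external reference panel — the synthetic
cohort has none.

TSLS is implemented through the explicit two-stage algebra on
covariate-residualised data, with the single-instrument ratio identity
asserted against it in tests. SEs are conventional homoskedastic 2SLS with
residuals from the observed exposure; CI = β ± 1.96·SE; significance means
the 95% CI excludes zero. No covariates enter the MR stages by default
(stratification is implicit); a `covariates` argument adjusts both stages
symmetrically. The Wu-Hausman test uses the control-function form (t-test on
the first-stage-residual coefficient), which is exact under normal errors
and degenerates gracefully (statistic 0, p 1) when the GRS equals the
exposure. Leave-one-out rebuilds the reduced GRS with original weights;
single-SNP instruments return an empty table with the reason recorded.

## Meta-analysis

Records are allele-harmonised before pooling (sign flip for swapped effect
alleles, strand complements renamed, A/T and C/G SNPs flagged ambiguous,
incompatible pairs excluded with a reason). Fixed-effect IVW with
w = 1/se²; Q, I² floored at 0; two-sided normal p; direction string in the
"+−" convention. Random-effects pooling is out of scope.

## Composites

Per class: stringent outlier masking (median ± 3·IQR by default),
complete-case rows, standardisation, PCA by SVD. Eligibility requires PC1
to explain ≥ 70% of class variance and at least `min_members` members —
default 2 (the smallest PCA-meaningful class; the study pipeline itself uses
3, matching the "more than two metabolites" convention). PC1 is oriented so
the loading sum is positive, making scores deterministic across linear
algebra backends; composite MR results are flagged direction-not-
interpretable. The composite pipeline hands PC1 scores to the identical
GWAS → instrument → TSLS code path used for single metabolites.

## MR power

Power of the two-sided TSLS Wald test from NCP = n·R²_xz·β²·σ²_x/σ²_res
with σ²_res = var_y − β_obs²·var_x (the continuous-outcome bookkeeping of
the standard MR power calculators; inconsistent inputs raise). β defaults to
the MR estimate for the post-hoc second pass; adequate means power ≥ 0.80 at
α = 0.05, which triggers the α = 0.01 evaluation. Because published variants
of this formula family differ in their residual-variance bookkeeping, the
implementation is anchored to a Monte-Carlo oracle (simulate, run the
package's TSLS, count rejections). The validation grid spans n in 500–5000,
R² in 0.01–0.1 and β in 0.1–0.5 with every cell at expected first-stage
F = n·R² ≥ 50: the formula is asymptotic in instrument strength, and below
F ≈ 30 the single-instrument TSLS Wald statistic is structurally
conservative (bounded by the first-stage t), so the formula is validated in
the regime where instruments are strong enough to be used at all. The grid
cohorts use residual outcome variance 2.0 so the exposure's causal share of
outcome variance stays modest.

## Study-scale choices

The end-to-end study uses two strata of n = 1000, 2000 SNPs on 10
chromosomes, 250 sib-pair families per stratum, and 10 metabolites in 3
classes (four causal SNPs of 0.3 mmol/L per allele each; the fatty-acid
class shares one SNP set and has class correlation 0.7, making it the one
class whose PC1 passes the 70% rule). These sizes put per-SNP suggestive
power near 0.8 and first-stage F in the tens-to-hundreds, the regime the
design targets, while a full run stays in the low minutes on one CPU. The
causal effect (M05 → 2-hour glucose, 0.08 log-units per mmol/L, SA only)
gives near-certain detection in SA; the null stratum's test still carries
its nominal ≈5% type-I probability, so the replicated study reports
detection counts over three independent cohorts rather than one draw.

## Known limitations

Wu-Hausman calibration is reported for oracle-weighted instruments;
in-sample weight estimation (the one-sample MR reality) makes the test
mildly conservative (size ≈ 0.044 at these settings) — a property of the
design, not the test. The `loo_snp` policy re-uses globally estimated
variance components. The meta-analysis stage reproduces
selection-before-pooling (SNPs suggestive in exactly one stratum), which
carries winner's curse; it is reported, not corrected. In-sample LD thinning
and the absence of background LD mean instrument redundancy is milder here
than in real data. CI coverage with in-sample GRS weights sits slightly
below nominal (≈93% at the recovery-study settings) because the plug-in
2SLS variance treats the weights as fixed; oracle-weighted instruments
restore nominal coverage.
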