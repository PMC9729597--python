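# Methods

`pedseg` implements a two-arm analysis of rare coding variation in
multiplex families ascertained for serious mental illness (SMI), together
with a synthetic-cohort generator that makes every stage testable without
access to patient data.

## Variant model and RPD classification

Input variants are normalized biallelic records (multi-allelic VCF sites
are split; a variant annotated to several genes becomes one record per
gene). Phase is never used: every analysis works on carrier status or
allele dosage. Coordinates are 1-based VCF convention throughout.

A variant is **rare predicted-deleterious (RPD)** when

* its alternate-allele frequency is ≤ 1e-3 in *both* reference panels
  (South-Asian and global); a frequency missing from a panel is treated
  as 0 — absence from a large panel is evidence of rarity, and this
  matches how filter-based annotation pipelines behave; and
* it is protein-truncating (stop-gain, stop-loss, start-loss, canonical
  ±2 splice site, or frameshift indel — in-frame indels do not qualify),
  or missense with deleterious calls from ≥ 4 of the 5 predictors
  (SIFT, LRT, MutationTaster, MutationAssessor, MetaSVM).

Under the default *strict* consensus rule a missing predictor call is a
non-vote, so more than one missing call makes the 4-of-5 threshold
unreachable; a *lenient* rule (votes ≥ ⌈4/5 · available⌉) is available
behind a flag for annotation sets with patchy coverage. Minor-allele
frequencies are taken as alternate-allele frequencies, the standard
reading for rare gnomAD variants.

A second rarity tier at ≤ 1e-4 in both panels feeds the stringent
segregation class below. Tightening either threshold can only shrink the
selected set (tested property).

## Within-pedigree segregation tiers

Only families with ≥ 3 sequenced affected members ("multi-sample"
families) enter the screen; any SMI diagnosis counts toward sharing, since
the families are trans-diagnostic.

* **shared-broad (sb-RPD)**: an RPD variant carried by ≥ 3 affected
  members of one family and by zero unrelated population controls.
  "Absent in controls" means zero called carriers; missing genotypes
  count as non-carriers. Families without a sequenced unaffected member
  remain eligible.
* **shared-stringent (ss-RPD)**: an sb-RPD variant that additionally
  passes the 1e-4 rarity tier and is carried by at most one unaffected
  family control — one carrier is tolerated to allow for incomplete
  penetrance. The carrier limit is applied across all sequenced family
  controls cohort-wide (the per-family variant is a config option).

Carrier status ignores zygosity; hemizygous alternate calls count as
carriers. A variant segregating in two families produces two result rows.
Results are ordered by (family, chrom, pos, alt) so output is
reproducible. The cross-family overlap report queries the segregating
genes and exact variants against RPDs carried by cases of the remaining
(< 3-case) families, excluding anything seen in unrelated controls.

## Gene-set overrepresentation

The segregating gene list is tested against curated gene sets by
Fisher's exact test on the 2×2 table `a` = prioritized ∩ set, `b` =
prioritized \ set, `c` = set \ prioritized, `d` = remaining universe,
with the universe defaulting to 20,203 protein-coding genes. The
reported odds ratio is the unconditional sample OR (a·d)/(b·c); the
conditional-MLE OR that exact-test software prints is available behind a
flag. The two-sided p sums hypergeometric probabilities of all tables at
least as extreme under the minimum-likelihood rule (scipy's
`fisher_exact`; an exhaustive integer-arithmetic enumeration backs it in
the test suite). The 95% CI is Wald on log OR; exact conditional CIs are
deliberately not an output surface because their construction varies
across software.

The specificity scan runs the same test against many organ-system gene
sets and Bonferroni-corrects by the number of sets (p·m, capped at 1).
Two odds ratios are compared on the log scale with standard errors
recovered from Wald CIs as (log CI_hi − log CI_lo)/(2·1.96), giving a
one-tailed normal z — usable both on fresh tables and on printed
summaries. Gene-level score comparisons (conservation, constraint,
expression) use Welch's t with Satterthwaite degrees of freedom.

## Kinship-adjusted SKAT

The cross-pedigree arm contrasts cases against unrelated controls only
(family controls are excluded from the phenotype vector). Because cases
are clustered in families, the null model is a linear mixed model on the
binary phenotype (the EMMAX-style approximation):

    y = Xβ + u + ε,  u ~ N(0, σg² K),  ε ~ N(0, σe² I)

* **K** is the standardized genomic relationship matrix Z Zᵀ/m from
  common variants (within-sample MAF ≥ 0.05, mean-imputed missing
  dosages). GRM sampling noise matters: with n ≈ 200 samples a panel of
  a few hundred SNPs leaves the adjusted test visibly inflated, while
  ≥ ~5×10³ SNPs (typical for exome common variants) gives nominal
  calibration. The calibration cohorts therefore use 6,000 SNPs.
* **X** holds an intercept, the top 3 principal components of the
  standardized genotype matrix, and ancestry-cluster indicators from
  k-means (k = 3, seeded) on the PC scores, encoded as k−1 dummies;
  collinear columns are dropped.
* REML fitting uses one eigendecomposition of K and a bounded Brent
  search over log(σg²/σe²) on [−10, 10] after a 41-point grid bracket.
  Phenotype and covariates are rotated into the eigenbasis and scaled by
  1/√(σe²(λ·s+1)), reducing the model to OLS; the resulting decorrelated
  residuals are orthogonal to the transformed covariates and
  approximately exchangeable.

For a unit (gene, or a gene set pooled into one variant set) with dosage
matrix G and weights w (Beta(1, 25) density at the within-sample MAF, the
rare-variant convention; flat weights by flag) the statistic is

    Q = r̃ᵀ G̃ W² G̃ᵀ r̃

where G̃ is G taken through the same whitening transform *and projected
off the covariates*. The projection leaves the observed score unchanged
(the residuals are already orthogonal to X) but is essential for the
permutation null: permuted residuals lose that orthogonality, and
without the projection the resampled statistics are systematically
larger than the asymptotic mixture.

Null distribution: Q ~ Σ λᵢ χ²₁ with λᵢ the eigenvalues of G̃ᵀG̃
(eigenvalues below 1e-10 of the maximum are dropped). Tail probabilities
come from characteristic-function inversion (Imhof's integral) with the
spectrum rescaled to λ_max = 1, split integration over [0, 200] ∪
[200, ∞), and an absolute tolerance of 1e-5; a single eigenvalue is an
exact χ²₁. When the quadrature error exceeds the tolerance, or the
estimate sinks below ten times the integration error (deep tail), the
Liu–Tang–Zhang moment-matching approximation is used and the fallback is
recorded. The resampling p permutes the decorrelated residuals with an
adaptive early stop (at 200 exceedances) under a permutation ceiling B;
the reported p follows the switching rule: resampling p when the
asymptotic p > 1e-5, asymptotic (Davies) p below that. Gene-level
significance uses 0.05/20,203 ≈ 2.4e-6; gene-set analyses report
Bonferroni-scaled p over the sets tested.

Known limitation: with a binary phenotype handled on the linear scale the
decorrelated residuals are not Gaussian, so the permutation and
asymptotic nulls differ by a small systematic amount (≈0.007 in p at
p ≈ 0.3 in our null experiments). At the adaptive-resampling defaults the
two routes agree within three resampling standard errors in the large
majority of replicates; a logistic mixed model would remove the
discrepancy at considerable cost and is out of scope.

## Synthetic cohorts

The generator reproduces the structure the analysis assumes, with
defaults chosen once to match the familial study design:

* 75 multi-generation families (founder couple, 3–5 children, ~half of
  whom marry in a spouse and have 0–3 children), 16 of them guaranteed
  multi-sample; 60 unrelated controls; sequenced cases per family range
  1–6 with median 2. Sequenced family controls appear in ~75% of
  multi-sample families.
* Genotypes are produced by Mendelian gene-dropping of founder alleles.
  Founders of the common panel (3,000 SNPs, ancestral frequencies
  U(0.05, 0.5)) are drawn from three sub-populations under
  Balding–Nichols drift (Fst = 0.05), one per family, creating the three
  broad ancestry clusters the covariate model expects. The rare exome
  panel is 1,000 genes × 20 variants with log-uniform population
  frequencies on (2e-5, 8e-3), giving ~50–80 rare-variant carriers per
  sample.
* Phenotypes follow a liability-threshold model: family random effect
  (variance 0.5) plus unit noise against a threshold set by a 1%
  population prevalence. Families are ascertained by redrawing
  liabilities until the recruitment minimum of affected members is met
  (2 for ~70% of families, 1 otherwise), emulating proband-driven
  sampling. Planted variants are seeded as a heterozygous founder allele
  and re-dropped until ≥ 3 family members carry them; a carrier is
  affected with probability equal to the planted penetrance (so
  penetrance-1 carriers are always affected, which is what realizes the
  multi-sample guarantee). By default one fully penetrant variant is
  planted per multi-sample family, 75% of them in the 120-gene synthetic
  "CNS" set — this is the effect configuration behind the end-to-end
  enrichment checks.
* Annotations mimic the real fields: panel frequencies are binomial
  resamples of the true frequency at the panel size (15,308 / 70,000
  diploid individuals), so ultra-rare alleles are often panel-absent
  (exact zero or missing); consequence classes follow fixed exome
  proportions; predictor calls are drawn per class with 5% missingness.
  Planted variants satisfy the RPD definition by construction.

What the generator does **not** model: linkage disequilibrium, sequencing
error, genotype-calling batch effects, X-chromosome inheritance, de novo
mutation, and polygenic background beyond the single family random
effect. Passing tests therefore demonstrate the statistical machinery is
correct under the assumed model, not that real-data artifacts are
handled.

A second, lighter generator (`simulate_null_family_cohort`) produces
50 nuclear families of 4 with gene-dropped genotypes and a
family-clustered phenotype but *no* genotype–phenotype association; it is
the null world for type-I-error calibration, sized n = 200 with a 20-
variant test unit and a 6,000-SNP kinship panel.

## Problem sizes used in the shipped checks

Chosen to keep the default suite fast while leaving Monte-Carlo error
well below the decision margins: 1,000 replicates for SKAT calibration
(binomial 95% band [0.037, 0.064] at α = 0.05); 50 eigenvalue spectra ×
10⁶ draws for the Davies check; 100 planted-variant cohorts (500 planted
variants) for segregation recovery; 50 replicates at n = 500 for REML
recovery; 100 default-scale cohorts for end-to-end enrichment power. The
acceptance script reports the same quantities at moderately reduced
replicate counts.
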