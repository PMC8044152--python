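# Methods

`bestgene` implements a drug-target prioritization and validation workflow
built around *bidirectional effect* genes — genes in which some variants push
a quantitative phenotype up and others push it down. The pipeline has three
scientific layers, each exercised end-to-end on synthetic data generated
under the study conditions the analyses are designed to detect.

## 1. The bidirectional screen

A mutation catalog of (gene, disease label) records is reduced to unique
pairs; genes with fewer than two unique disease associations are excluded
before any direction logic. Each surviving label is classified against a
*direction lexicon*: per phenotype axis, lists of antonym phrases ("high LDL
cholesterol" / "low LDL cholesterol", "tall stature" / "short stature",
"long QT syndrome" / "short QT syndrome"). Matching is whole-phrase
containment after lowercasing and punctuation stripping — auditable and
deterministic where the original selection was a manual curation. Labels on
an exclusion list of molecular/benign phenotypes (enzyme activity, cell
permeability, pigmentation, ...) are never classified; labels matching more
than one (axis, direction) are treated as ambiguous. A gene is a BEST
(Bidirectional Effect Selected Target) candidate on an axis iff it has at
least one up- and one down-call on that same axis; genes bidirectional on two
axes yield one record per axis. Labels the lexicon cannot classify on genes
that survive the minimum-two-diseases filter are exported to a review queue,
preserving the human-curation step as an explicit artifact rather than an
invisible judgment.

## 2. Clinical-phase transition enrichment

Every target–indication pair carries its highest phase reached
(PhaseI < PhaseII < PhaseIII < Approved). For a transition X→Y a pair is at
risk iff it reached ≥X and a success iff it reached ≥Y. A pair is *supported*
by evidence class C (BEST, unidirectional-OMIM, GWAS; precedence in that
order, configurable) iff its target gene has class-C evidence for a trait
whose semantic similarity to the indication exceeds a threshold. The
enrichment statistic is the risk ratio

    RR = [a/(a+b)] / [c/(c+d)]

with supported pairs in the numerator and unsupported (no evidence class)
pairs in the denominator, and the Katz log-method 95% CI
`exp(ln RR ± 1.96·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)))`. A zero numerator
cell triggers the 0.5 continuity correction on all four cells, flagged. The
odds ratio from the same 2×2 is reported alongside; RR is the headline. The
similarity threshold is swept over 0–1 in steps of 0.01 and the threshold
maximizing the PhaseI→Approval RR is reported, ties to the smallest.
Sensitivity modes: *exclude* drops the evidence annotations of named
phenotype categories and recomputes; *stratify* estimates per category,
skipping categories with ≤5 BEST genes.

## 3. Exome cohort analysis

**QC cascade (conjunctive, order-free in the final kept set).** Samples are
excluded for failed ancestry assignment; sex-chromosome aneuploidy;
PCA-corrected heterozygosity outside [0.17, 0.21]; >80,000 non-reference
variants; >200 singletons; het/hom ratio outside [1.3, 1.85]; call rate
<0.985; chip heterozygote concordance <0.98 when available. An attrition
table reports removals per criterion in application order. A Ti/Tv rule
(">2.5") is available behind a flag but off by default: typical exomes sit
near 3.0, so the rule as printed would exclude essentially everyone.
Relatedness (degree ≤2) is pruned greedily: repeatedly drop the sample with
the most remaining close-kin links (ties by id), which removes exactly one
member of an isolated pair and two of a triangle. Variants require call rate
≥0.99 and an exact Hardy–Weinberg p ≥ 1e-10 (conditional-on-allele-counts
test, computed by the standard recurrence over heterozygote counts). Variants
with an external reference frequency are additionally checked by a two-sided
binomial test of the cohort allele count against that frequency (drop at
p < 1e-7, with a 1/(2·panel) frequency floor for absent-but-covered sites);
variants with no reference frequency are kept as unfilterable.

**Masks.** protein_altering = {VEP impact high or moderate} at within-cohort
MAF < 1e-4; ptv = {stop_gained, frameshift, splice_acceptor, splice_donor} at
the same cutoff, hence ptv ⊆ protein_altering per gene. Genes with cumulative
protein-altering allele count <20 are excluded from gene-level testing.

**Phenotype.** Standing height is split by sex, residualized on age and five
principal components by least squares, and scaled to unit SD within stratum;
ISS (idiopathic short stature) is the strict z < −2 tail (2.28% under a
Gaussian tail).

**Tests.** The burden score is the per-sample sum of alternate-allele dosages
over a unit's mask variants (carrier-indicator mode behind a flag; male X
dosages count 0/1). Linear burden regresses z-height on the score; logistic
burden regresses ISS on the score plus sex and age and reports the odds ratio
with a Wald CI, falling back to a Jeffreys-penalized (Firth) fit under
separation. SKAT computes Q = rᵀGW²Gᵀr with intercept-only null residuals r
(covariates are already absorbed into z) and per-variant Beta(1, 25)-density
MAF weights (flat weights behind a flag); the null distribution of Q is the
weighted chi-square mixture given by the eigenvalues of the projected
weighted kernel times the residual variance. Gene-level significance is
Bonferroni over the five-gene battery; set-level over the number of non-empty
annotation-intersection cells tested. All 2⁵ = 32 exclusive intersection
cells of the five evidence annotations (GWAS, HGMD_SHORT, HGMD_TALL,
OMIM_SHORT, OMIM_OVERGROWTH) are enumerated; named sets are Set1 (all five),
Set2 (the four HGMD/OMIM flags without GWAS), Bidirectional (all four
HGMD/OMIM flags), Tall (tall-side without short-side evidence), Short (both
short-side flags without tall-side evidence).

**Mixture-of-chi-square p-values.** The tail probability
P(Σλᵢχ²₁ ≥ q) is computed by numerical inversion of the characteristic
function in Imhof's real-integral form. After rescaling by max λ (the
p-value is scale-invariant), the integrand is integrated with 24-point
Gauss–Legendre panels whose width adapts to the local phase speed
|θ′(u)| (each panel under a quarter oscillation), truncated at a point U
where the first-order integration-by-parts tail correction
f(U)cosθ(U)/θ′(U) has a certified-small remainder; the correction itself is
added. Accuracy against χ² closed forms is ~1e-12; a 10⁷-draw Monte-Carlo
oracle agrees within sampling error. When truncation cannot be certified the
Liu–Tang–Zhang moment-matched noncentral-χ² approximation is used and the
result is labelled accordingly.

**Polygenic score.** GWAS summary statistics are shrunk per LD block with the
closed-form infinitesimal model `(M/(N·h²)·I + D)⁻¹·β̂` (the ridge term makes
the solve well-posed for any h² > 0); the full point-normal MCMC model is out
of scope — the stratification analyses only need a well-calibrated score.
Scoring is the weighted allele-dosage sum with sign flips for effect-allele
mismatches and mean imputation (2·AF) for missing dosages. Samples are split
into five rank-based, equally sized score groups (remainders to the lower
groups, ties by stable order). Within each quintile the carrier/non-carrier
height contrast is estimated per carrier class (lof > missense precedence for
dual carriers) and combined by fixed-effect inverse-variance meta-analysis;
heterogeneity is Cochran's Q, I² = max(0, (Q−df)/Q) and its χ² p-value. ISS
odds ratios per (quintile × carrier status) group come from one logistic
regression with the middle-quintile non-carriers as reference, fitted by
IRLS so that empty-case cells drift to divergent coefficients with enormous
standard errors, which the SE > 100 removal rule then excludes — the same
mechanism as the original analysis.

**Functional integration.** Per-variant cGMP activity relative to wild type
is binned low (<0.2) / intermediate / supranormal (>1), boundaries exclusive.
Carrier standardized heights are regressed on activity (slope in SD per 100%
of wild-type activity; each carrier one observation, per-variant collapse
behind a flag) and, in parallel, on an in-silico deleteriousness score; the
predictor with higher R² is flagged. The published smooth-surface fit of
height on (PS, log activity) is deliberately replaced by the linear model:
the scientific claim under test is additivity, which a linear fit tests
directly.

## The synthetic-data generator

All inputs are generated from one root seed through named substreams
(catalog / trials / cohort / functional / qc), so identical configurations
give byte-identical outputs and each stage is independently reproducible.

Defaults encode the study conditions (units in parentheses):

| parameter | default | meaning |
|---|---|---|
| n_samples | 34,000 | cohort size after the published post-QC scale |
| n_genes / n_best_genes | 40 / 5 | gene universe; planted bidirectional set |
| carrier_freq | 0.01 | per-gene carrier probability (set ≈ 5%) |
| rare_effect_sd | −0.20 | mean height effect per rare alt allele (SD) |
| ptv_fraction / ptv_effect_sd | 0.10 / −0.85 | PTV share and effect (SD) |
| set_iss_or | 2.75 | target ISS odds ratio per rare allele in the set |
| prs_h2 | 0.20 | height variance explained by the common-variant score |
| iss_threshold | −2 | ISS definition (z-score) |
| mean_variants_per_gene | 204 | Poisson mean of observed rare variants |
| n_common_snps / n_gwas | 2,000 / 700,000 | score SNPs; GWAS sample behind the summary statistics |
| trial_rr / omim_rr / gwas_rr | 4 / 2 / 1.1 | planted PhaseI→Approval risk ratios |
| phase_attrition | 0.56 / 0.36 / 0.55 | baseline per-transition success |
| n_pairs | 26,884 | target–indication pairs |
| sim_threshold | 0.83 | similarity above which planted support applies |
| functional_slope | 0.9 | SD height per 100% cGMP in the focal gene |

**Catalog.** Planted BEST genes receive one up- and one down-label (drawn
from the lexicon itself) on a shared axis; the remaining genes cycle through
negative controls — unidirectional pairs, benign-only labels, single-disease
genes, same- and opposite-direction labels on different axes — plus
duplicated records. Screen recall and precision on this catalog are exactly
1 by construction; passing says the grouping, filtering and direction logic
are correct, not that the lexicon would reproduce a manually curated list
from free-text clinical vocabulary.

**Trials.** Pairs draw targets from BEST/OMIM/GWAS evidence genes and an
unsupported pool, and indications biased toward each evidence gene's
semantically matched set (matched similarities ~Beta(40, 3), background
~Beta(2, 6)). A pair whose drawn similarity exceeds `sim_threshold` has each
of its three transition probabilities multiplied by rr^(1/3) (capped at 1
with a warning), so the planted PhaseI→Approval *risk ratio* equals the
configured rr exactly. Because planted support is a step function of
similarity, the swept RR is flat in expectation for thresholds above the
planted one; the argmax is therefore only guaranteed to land in [0.83, 1).

**Cohort.** Covariates: sex ~ Bernoulli(½), age ~ U(45, 75), five standard
normal PCs. Common SNPs are independent (AF ~ U(0.05, 0.5)); standardized
true effects are drawn so the true score has variance prs_h2, and summary
statistics add N(0, 1/(N·2f(1−f))) estimation noise — realistic LD structure
beyond block-diagonal is a non-goal. Rare variants: per-gene Poisson variant
counts with a Binomial(n, carrier_freq) total allele count multinomially
allocated (zero-count variants unobserved), giving the singleton-heavy AF
spectrum the masks expect; ~10% PTVs, ~76% missense, the rest low-impact.
Height is `sex mean + age slope + PC effects + sex SD · (true score + rare
effects + Gaussian noise)`, so the normalization step recovers the latent
standard-normal scale.

*Joint effect calibration.* A homogeneous −0.20 SD shift cannot produce an
ISS odds ratio of 2.75 at the z < −2 threshold (it gives ≈1.6): observing
both requires effect heterogeneity. PTVs carry −0.85 SD. The focal
(receptor-like) gene's effects follow the activity model
`effect = 0.9·(activity − 1)` with a GoF-heavy activity mixture (10% below
0.2, 36% intermediate, 54% above 1 — the tall-direction allelic series a
bidirectional gene implies), making the activity–height slope a genuine
planted truth. The remaining missense background gets a mild +0.12 SD
gain-of-function effect, and a subset of those alleles — chosen after the
genotypes are drawn — receives one shared large negative effect whose allele
count and size are solved jointly from the *realized* allele counts so that,
in every generated dataset, the maskable set matches both the mean
per-allele effect (−0.20) and the target per-allele carrier odds ratio
(2.75) exactly. The mildest solution (largest spike allele count) is chosen;
an unattainable draw falls back to the closest achievable planting with a
warning.

QC metrics are generated passing for most samples/variants with small
planted failure groups for every criterion (restricted to genes without
planted effects, so QC removal never biases effect recovery), including
excess-homozygosity variants for the HWE test, frequency-inflated variants
for the external-AF test, second-degree kinship pairs, one triangle, and one
third-degree pair that must survive.

**What passing does and does not show.** Recovery of the planted quantities
shows the estimators are consistent and approximately unbiased under the
generator's assumptions: independent common SNPs, independent carrier
assignment, Gaussian residual height, a step-function support rule, and
effect sizes constant within their class. It does not validate lexicon
coverage on real clinical vocabulary, LD-aware score construction,
population stratification control, or the VEP annotation step (annotations
are consumed as input, never computed).

## Numerical and scale choices

- Degenerate inputs: monomorphic variants get HWE p = 1; zero-carrier units
  are flagged untestable, all-zero genotype columns are dropped before SKAT;
  all-equal scores are split by stable order with a warning; q = 0 gives
  p = 1.
- Boundary semantics follow the printed rules: heterozygosity window
  inclusive; singleton/non-reference rules strict ">"; variant call rate
  ≥0.99 kept; activity 0.2 and 1.0 are intermediate; ISS is strict z < −2;
  MAF cutoff strict "<".
- Burden SEs are classical OLS. Under the spike mixture, carrier residuals
  are mildly heteroskedastic, so CI coverage of the planted mean runs
  slightly below nominal; robust (sandwich) SEs would widen CIs at the cost
  of departing from the field's standard burden output.
- Problem sizes: the recovery analyses run at the full default scale
  (34,000 samples; 26,884 pairs). Null calibration uses 500 replicates of
  1,500-sample cohorts with six genes — the test statistics' calibration
  does not depend on cohort scale. The SKAT permutation oracle uses 2×10⁵
  permutations with its Monte-Carlo error bound computed for that count; the
  mixture-tail Monte-Carlo oracle uses 10⁷ draws.
- The ISS prevalence of the generator is the Gaussian tail (2.28% at z < −2)
  rather than the published 1.67%, whose denominator is internally
  inconsistent in the source material; the prevalence is an emergent
  property here, not a dial.

## Known limitations

- The lexicon is exact-phrase; real catalogs need curated axis vocabularies,
  and borderline labels are deliberately deferred to the review queue.
- Only the infinitesimal-model score is implemented; scores for traits with
  sparse architecture would need the point-normal model.
- SKAT-O, variance-component meta-analysis, and exome-wide scans beyond the
  configured gene lists are out of scope.
- The evidence-class precedence rule (BEST > OMIM > GWAS) is an assumption
  where a pair has several supported classes; it is configurable.
- X-chromosome allele-number accounting (males hemizygous) is honored in
  mask AN counts but the generator plants autosomal variants only.
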