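# Methods

`famvar` implements variance-component genetics for extended pedigrees: the
family of models used to dissect quantitative hemostasis phenotypes (such as
the thrombin-generation parameters lag time, thrombin peak and endogenous
thrombin potential) and binary disease outcomes (venous thromboembolism,
VTE) in family studies ascertained through thrombophilic probands.  This
note records the models, their assumptions, the defaults, and the design
choices made where several implementations were defensible.

## The variance-component model

For a quantitative trait measured on the members of a family, the vector of
trait values is modelled as multivariate normal,

    y ~ N( X β ,  σ²g · 2Φ + σ²c · H + σ²e · I ),

where 2Φ is the additive (numerator) relationship matrix — twice the kinship
coefficient, computed from the pedigree by the classic recursion
Φ(i,i) = ½ + ½Φ(f,m), Φ(i,j) = ½[Φ(f,j) + Φ(m,j)] with founders non-inbred
and mutually unrelated — and H is the indicator of shared household.
Families are independent, so the likelihood is a product over family
blocks.  Results are reported as fractions of the phenotypic variance
σ²p = σ²g + σ²c + σ²e: the narrow-sense heritability h² = σ²g/σ²p and the
household (common-environment) effect c² = σ²c/σ²p.  Residual variance
absorbs dominance, epistasis and gene–environment interaction, so h² is a
lower bound on the total genetic contribution.

Assumptions worth keeping in mind: multivariate normality of the trait on
the analysis scale (positive skewed traits are log-transformed first, via
`transform_trait`); autosomal additive inheritance (no X-linked or
imprinted component); households contribute exchangeably (one common
variance for all co-resident pairs); no inbreeding among founders.

### Numerics

The fixed effects β are profiled out by generalized least squares and the
total variance by its closed-form ML expression, so the optimisation runs
over only (h², c²) on the simplex {h², c² ≥ 0, h² + c² ≤ 1}.  The simplex
is parameterised as (s, f) → (h², c²) = (s·f, s·(1−f)) with box bounds, so
the h²=0 and c²=0 boundaries are exactly reachable — essential for null
fits.  L-BFGS-B runs from four fixed starting points; a final snap-to-edge
step accepts a boundary point whenever it does not lower the likelihood.
The residual variance is kept ≥ 10⁻⁴·σ²p so family covariance blocks stay
positive definite.

Standard errors come from the numerically differenced observed information
over (h², c², log σ²p, β); at a boundary optimum Wald theory degrades, and
the result carries a `boundary` flag.  Likelihood-ratio tests of h²=0 or
c²=0 test a variance on its boundary, so the null distribution is the ½:½
mixture of χ²₀ and χ²₁; the implementation follows the convention
p = ½·P(χ²₁ > T), which returns 0.5 at T = 0.  Interior hypotheses (e.g.
correlation = 0) use the plain χ².

Candidate covariates (age, age², sex, oral-contraceptive use, smoking,
physical activity) are screened in a single pass: fit the full model, keep
terms with Wald p < 0.05, refit.  Age enters centred at the sample mean,
age² as the square of centred age.  A residual excess-kurtosis diagnostic
is reported and flagged above 0.8 — a flag, not a hard failure, since ML
point estimates are robust to mild non-normality while their SEs are not.
Missing phenotypes drop an individual from the likelihood but not from the
pedigree, so kinship paths through unphenotyped connectors are preserved.

## Liability-threshold model for binary disease

Disease status is mapped to a latent liability with unit marginal variance:
liability ~ N(Xβ, 2Φ·h² + I·(1−h²)) per family, affected ⇔ liability > t.
The family likelihood is the rectangle probability that every member's
liability lies on the observed side of t, computed with scipy's Genz
quasi-Monte-Carlo integrator.  The integrator is seeded with a fixed
internal constant on every call, so the likelihood surface is deterministic
and can be optimised by Nelder-Mead (with h² box-bounded in [0, 0.999]).
Defaults: `maxpts=20000` (≈10⁻³ relative accuracy), family-size cap 60 —
larger families are supported by raising the cap, at steeply growing cost.
When h²=0 the likelihood factorizes into independent probit terms; this
fast path is also used for the null fit of the LRT, and with `fix_h2=0` on
unrelated individuals the fit reduces exactly to probit regression
(verified to 10⁻⁶ against a Newton-solved oracle).

There is no household term in the binary model by default (it can be
enabled through the simulation/bivariate machinery); the reference disease
model is pure additive liability at prevalence K = 0.10 with h² = 0.67.

Coefficients are reported so that positive β increases liability;
`flip_signs=True` reproduces the reversed convention some packages print,
where a negative coefficient means increased risk.

### Ascertainment correction

Families ascertained through a proband are not a random sample: affected
probands drag their relatives' liabilities upward, and naive ML overstates
prevalence and misestimates h².  The classic single-proband correction
divides each family's likelihood by the marginal probability of the
proband's observed status.  In the package's ascertainment experiments
(proband rule: affected with onset before 45, or with an affected
first-degree relative; one proband per family, earliest onset), the
corrected fit recovers the generative h² while the uncorrected fit is
biased downward by roughly 0.2 and overstates prevalence.  A known
limitation: the rule conditions on more than affection status (onset age,
affected relatives), so the corrected *threshold* remains somewhat biased
even though h² is recovered; multiplex/sequential ascertainment schemes are
out of scope.

## Bivariate models

For two quantitative traits the joint family covariance carries cross-trait
blocks 2Φ·ρg·σg1σg2 + H·ρc·σc1σc2 + I·ρe·σe1σe2.  Each component's 2×2
matrix is PSD whenever |ρ| ≤ 1, so the joint covariance is valid on the
whole box; correlations are optimised directly with bounds ±0.999 and
flagged when they pin at the edge (as they should when trait2 is a copy of
trait1).  The fixed effects of both traits are profiled by GLS; marginal
variance fractions use the same simplex parameterisation as the univariate
model, initialised at the univariate fits, with the initial correlations
set to the empirical residual correlation.

ρg = 0 and ρe = 0 are interior hypotheses: their LRT p-values use χ²₁.
The household cross-correlation ρc is estimated only when both traits carry
household variance (decided from the univariate fits, override available)
and fixed to 0 otherwise.

The derived phenotypic correlation is

    ρp = √(h²₁·h²₂)·ρg + √(1−h²₁)·√(1−h²₂)·ρe ,

which deliberately omits the household term; with household variance
present the derived value is an approximation to the full model-implied
correlation.  Its p-value is a delta-method approximation on the fitted
parameters and is flagged as such — it is reported for table compatibility,
not as a calibrated test.

A binary trait may enter as trait 1: the joint likelihood multiplies the
continuous trait's normal density by the conditional rectangle probability
of the liability given the observed continuous values (conditional-normal
decomposition, cross-covariance 2Φ·ρg·√(h²L·h²₂)·σ2 + I·ρe·√((1−h²L)·e²₂)·σ2).
Design choice: this fit is two-stage — the marginal parameters are held at
their univariate ML estimates and only (ρg, ρe) are maximised.  Full joint
ML would re-integrate every family rectangle inside a much larger
parameter search for a modest efficiency gain; the two-stage SEs for the
correlations are curvature-based and approximate.

## Measured-genotype association

A SNP's additive allele count (or imputed dosage) enters the fixed effects
of the variance-component model.  Default scan mode profiles the variance
components once under the null model, whitens trait, covariates and all
genotype columns by the per-family Cholesky factors, and tests each SNP by
GLS in the whitened model; the LRT statistic is the drop in whitened
residual sum of squares (χ²₁).  This makes a genome scan a single pass of
linear algebra while `refit=True` provides the exact per-SNP re-estimation
for follow-up regions.  Conditional analysis (e.g. on a known functional
variant) adds the conditioning SNP as a fixed covariate.

QC follows array conventions: call rate ≥ 0.98, founder MAF ≥ 0.01,
founder-only Hardy–Weinberg exact test at p ≥ 10⁻⁶ (testing relatives
violates the independence the test assumes), and info ≥ 0.3 when an
imputation-quality column exists.  The HWE test enumerates heterozygote
counts conditional on allele counts and sums the probabilities of
configurations no likelier than the observed one.  MAF is computed on
founders by default to avoid pedigree inflation (a full-sample option
exists).  Missing genotypes are mean-imputed for testing.  Significance
classes use 5×10⁻⁸ (genome-wide) and 10⁻⁵ (suggestive).  Genomic inflation
is λ = median(χ²)/0.4549; on 5,000 null gene-dropped SNPs against a
polygenic h²=0.5 trait the scan yields λ ≈ 1 and χ²₁-distributed
statistics (Kolmogorov–Smirnov checked), mirroring the calibration a
family-based mixed model is supposed to deliver.

## Synthetic data: what it emulates, and what it does not

`generate_pedigree` grows families founder-couple-down: each couple has
Poisson(2.6)+ children, each non-terminal child marries with probability
0.75, and 40% of families receive a fourth generation; families with fewer
than 10 members (or fewer than 3 generations) are redrawn.  These defaults
were set once so that 35 families average ≈930 individuals with a realistic
share of deep pedigrees, matching the design of an idiopathic-thrombophilia
family study.  Households follow nuclear units: a couple and its unmarried
children share a household; each marriage founds a new one.  Ages decrease
by generation (means 75, 49, 23, … with SD 8, truncated to [2, 101]
years), giving the age covariate pedigree-realistic structure; smoking,
physical activity and oral-contraceptive use (women 18–50) are Bernoulli
covariates.

Traits are drawn directly from the model's multivariate normal (per-family
Cholesky of 2Φ⊗G + H⊗C + I⊗E) rather than by allelic gene dropping: the
generator then matches the inference model exactly, which is what
parameter-recovery tests require.  Consequently, passing recovery tests
demonstrates correctness of the estimators under the model's own
assumptions — they say nothing about robustness to non-normal residuals,
assortative mating, dominance, or shared environments that do not follow
household boundaries, none of which the generator produces.  SNP genotypes
*are* gene-dropped (founder alleles Bernoulli(MAF), Mendelian transmission),
so association tests face genuine pedigree-structured genotype correlation.
Binary disease uses the liability threshold at prevalence K; age at onset
for affected individuals is uniform on (18, age), since only the before-45
criterion of the proband rule consumes it.  The household cross-trait
correlation defaults to ρe when unspecified.

## Reference study sizes

The recovery studies in `famvar.studies` use 20 replicates of the full
35-family design for the continuous and bivariate models, 16 replicates of
25 three-generation families for the liability model, and a single
35-family study with 5,000 null SNPs for GWAS calibration.  The liability
replicate count reflects the estimator's intrinsic noise: a single ~400
person, 10%-prevalence study estimates liability h² with a sampling SD of
roughly 0.25 (boundary estimates of 0 or 1 occur and are legitimate ML
solutions), so 16 replicates hold the Monte-Carlo error of the reported
mean near 0.06.  Liability studies use three-generation families because
the rectangle-integration cost grows steeply with family size; the model
itself handles larger families via `size_cap`.

## Known limitations

- Founders are assumed non-inbred and unrelated; inbred pedigrees are out
  of scope (the kinship recursion would need condensed identity
  coefficients).
- Sex-linked inheritance is not modelled.
- The liability integrator's QMC error (~10⁻³ relative at defaults) feeds
  into liability SEs, which are therefore computed with wide finite-
  difference steps and should be read as approximate.
- `derived_rho_p` ignores the household term by construction; for trait
  pairs with large c² the derived and model-implied phenotypic correlations
  differ.
- The GWAS fast path holds variance components at their null estimates;
  for SNPs of very large effect the exact `refit` mode is preferable.
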