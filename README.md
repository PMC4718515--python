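# famvar

Variance-component genetics on extended pedigrees: heritability and
household effects for quantitative traits, a liability-threshold model for
binary disease with proband-ascertainment correction, bivariate
genetic/environmental correlations, and measured-genotype association
testing — plus a synthetic family-study generator that makes every stage
verifiable at desk scale.

## Who this is for

Family studies of complex disease — the setting here is idiopathic
thrombophilia, with thrombin-generation parameters (lag time, thrombin
peak, endogenous thrombin potential) as intermediate phenotypes for venous
thromboembolism — recruit extended pedigrees through affected probands and
ask three questions: how much trait variance is genetic (h²) versus shared
household environment (c²); whether a disease and an intermediate phenotype
share genes (genetic correlation ρg, i.e. pleiotropy); and which measured
variants shift trait means once family structure is accounted for.
`famvar` answers all three with maximum-likelihood variance-component
models on the pedigree's kinship structure.

## The model

For a quantitative trait on one family,

    y ~ N( Xβ ,  σ²g·2Φ + σ²c·H + σ²e·I )

with 2Φ twice the kinship matrix (recursive founder-to-descendant
computation) and H the household indicator; h² = σ²g/σ²p, c² = σ²c/σ²p.
Binary disease is modelled as a latent liability exceeding a threshold
(probit link), with each ascertained family's likelihood conditioned on its
proband.  Bivariate models partition cross-trait covariance into genetic,
household and residual parts; the phenotypic correlation derives as
ρp = √(h²₁h²₂)ρg + √(1−h²₁)√(1−h²₂)ρe.  SNPs are tested by adding the
allele count to the fixed effects of the variance-component model, with
call-rate/MAF/Hardy-Weinberg/info QC and the genomic inflation factor
λ = median(χ²)/0.4549.  Details and numerics: `docs/methods.md`.

## Worked example

```python
import famvar as fv
from famvar.simulate import thrombin_generation_spec, simulate_covariates

ped = fv.generate_pedigree(n_families=35, seed=7)       # ~900 members, 3-4 generations
cov = simulate_covariates(ped, seed=7)
traits = fv.simulate_traits(ped, thrombin_generation_spec(), covariates=cov, seed=7)

res = fv.fit_univariate(ped, traits["ETP"], cov,
                        ["age", "age2", "female", "oc", "smoking", "phys_act"])
print(f"h2 = {res.h2:.2f} (SE {res.se_h2:.2f}, LRT p = {res.p_h2:.2e})")
print(f"c2 = {res.c2:.2f} (SE {res.se_c2:.2f}, LRT p = {res.p_c2:.2e})")

biv = fv.fit_bivariate(ped, traits["ETP"], traits["TP"], cov,
                       ["age", "age2", "oc"], ["age", "age2", "female", "oc"])
print(f"rho_g = {biv.rho_g:.2f} (SE {biv.se_rho_g:.2f}), rho_p = {biv.rho_p:.2f}")
```

prints

```
h2 = 0.54 (SE 0.07, LRT p = 4.41e-17)
c2 = 0.25 (SE 0.05, LRT p = 2.30e-11)
rho_g = 0.84 (SE 0.03), rho_p = 0.82
```

The study was generated with h² = 0.52, c² = 0.23 and ρg = 0.87: one
~900-person study estimates the heritability to about ±0.07 and the
genetic correlation to a few hundredths, and the covariate screen retains
the age and oral-contraceptive terms that actually carry effects.

The same pipeline is scriptable from a shell:

```sh
famvar simulate --families 35 --seed 1 --snps 1000 --out-dir study/
famvar fit study/pedigree.tsv study/phenotypes.csv --trait ETP \
    --covariates age,age2,female,oc,smoking,phys_act --out-dir study/fit/
famvar fit-binary study/pedigree.tsv study/phenotypes.csv --trait affected \
    --out-dir study/vte/
famvar corr study/pedigree.tsv study/phenotypes.csv --trait1 ETP --trait2 TP \
    --out-dir study/corr/
famvar gwas study/pedigree.tsv study/phenotypes.csv study/genotypes.tsv \
    --trait ETP --out-dir study/gwas/
```

Each subcommand writes fixed-order TSV tables plus a JSON manifest with the
seed, configuration hash and package versions.

File formats: LINKAGE-style pedigree files (`FID IID FATHER MOTHER SEX
[HOUSEHOLD PROBAND]`, 0/NA = missing), CSV/TSV phenotype tables with an
`id` column, and genotype TSVs with SNPs as rows and individuals as columns
(0/1/2 or dosages, optional `info` column).

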