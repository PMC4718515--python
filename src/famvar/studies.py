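"""Reference simulation studies: parameter recovery and test calibration.

Each function simulates family studies at the package's default study
design — 35 extended families of at least 10 members over at least 3
generations, roughly 900 individuals — with generative parameters at the
magnitudes reported for thrombin-generation phenotypes and venous
thromboembolism (VTE), runs the corresponding inference module, and returns
summary recovery statistics.  They back both the test suite and the
reproducibility script, so the numbers they produce are always recomputed
from scratch.

Problem sizes are chosen so every study runs in minutes on a single core
while keeping the Monte-Carlo error of each reported mean well inside the
sampling noise of a single study: 20 replicates for the continuous and
bivariate recovery studies, and 16 replicates of three-generation families
for the liability study, whose per-replicate estimates are intrinsically
noisy and whose joint-probability integration dominates the cost.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from famvar.association import run_gwas
from famvar.bivariate import fit_bivariate
from famvar.liability import fit_liability
from famvar.pedigree import kinship_matrix
from famvar.simulate import (
    TraitModelSpec,
    ascertain_families,
    generate_pedigree,
    simulate_binary_trait,
    simulate_genotypes,
    simulate_traits,
)
from famvar.varcomp import fit_univariate

__all__ = [
    "etp_recovery_study",
    "liability_recovery_study",
    "ascertainment_study",
    "bivariate_recovery_study",
    "gwas_null_study",
]

#: generative values for the endogenous-thrombin-potential-like trait
ETP_H2, ETP_C2 = 0.52, 0.23
#: thrombin-peak-like trait and its correlations with ETP
TP_H2, TP_C2, RHO_G, RHO_E = 0.54, 0.27, 0.87, 0.82
#: VTE-like disease liability
VTE_H2, VTE_PREVALENCE = 0.67, 0.10


def etp_recovery_study(
    n_reps: int = 20,
    n_families: int = 35,
    h2: float = ETP_H2,
    c2: float = ETP_C2,
    seed: int = 0,
) -> dict:
    """Univariate recovery: simulate at (h2, c2), fit, average estimates."""
    spec = TraitModelSpec(
        traits=("ETP",), h2=(h2,), c2=(c2,), mean=(48.53,), total_var=(3.3,)
    )
    h2s, c2s, ns = [], [], []
    for rep in range(n_reps):
        ped = generate_pedigree(n_families, seed=seed + 11 * rep)
        kin = kinship_matrix(ped)
        traits = simulate_traits(ped, spec, seed=seed + 11 * rep + 1, kin=kin)
        fit = fit_univariate(ped, traits["ETP"], kin=kin, compute_se=False)
        h2s.append(fit.h2)
        c2s.append(fit.c2)
        ns.append(fit.n)
    return {
        "mean_h2": float(np.mean(h2s)),
        "mean_c2": float(np.mean(c2s)),
        "h2": h2s,
        "c2": c2s,
        "mean_n": float(np.mean(ns)),
        "true_h2": h2,
        "true_c2": c2,
    }


def _liability_pedigree(n_families, seed):
    # three-generation families keep the joint-probability integration cheap
    return generate_pedigree(
        n_families, extra_generation_prob=0.0, seed=seed
    )


def liability_recovery_study(
    n_reps: int = 16,
    n_families: int = 25,
    h2: float = VTE_H2,
    prevalence: float = VTE_PREVALENCE,
    seed: int = 0,
    maxpts: int = 2500,
) -> dict:
    """Unascertained liability recovery at the VTE generative values.

    Binary-trait heritability estimates are intrinsically noisy (per-replicate
    sampling SD around 0.25 at ~400 individuals and 10% prevalence), so the
    study averages enough replicates to pin the Monte-Carlo error of the mean
    near 0.06.
    """
    h2s, ns = [], []
    for rep in range(n_reps):
        ped = _liability_pedigree(n_families, seed + 13 * rep)
        kin = kinship_matrix(ped)
        phen = simulate_binary_trait(
            ped, h2=h2, prevalence=prevalence, seed=seed + 13 * rep + 1, kin=kin
        )
        fit = fit_liability(
            ped, phen["affected"], kin=kin, compute_se=False, maxpts=maxpts,
            xatol=5e-3, fatol=5e-3,
        )
        h2s.append(fit.h2)
        ns.append(fit.n)
    return {
        "mean_h2": float(np.mean(h2s)),
        "h2": h2s,
        "total_n": int(np.sum(ns)),
        "true_h2": h2,
    }


def ascertainment_study(
    n_reps: int = 4,
    n_candidate_families: int = 60,
    n_keep: int = 25,
    h2: float = VTE_H2,
    prevalence: float = VTE_PREVALENCE,
    seed: int = 0,
    maxpts: int = 2500,
) -> dict:
    """Proband-ascertained families fitted with and without correction.

    Families are retained only when they contain a qualifying proband
    (early onset or an affected first-degree relative), mimicking selection
    through thrombophilic probands; the corrected fit conditions each
    family's likelihood on its proband.
    """
    corrected, uncorrected, prev_corr, prev_unc = [], [], [], []
    for rep in range(n_reps):
        ped = _liability_pedigree(n_candidate_families, seed + 17 * rep)
        kin = kinship_matrix(ped)
        phen = simulate_binary_trait(
            ped, h2=h2, prevalence=prevalence, seed=seed + 17 * rep + 1, kin=kin
        )
        asc, probands = ascertain_families(ped, phen)
        keep = sorted(asc.families)[:n_keep]
        asc = asc.subset_families(keep)
        sub_kin = kinship_matrix(asc)
        aff = phen["affected"].loc[asc.ids]
        fit_c = fit_liability(
            asc, aff, correct_ascertainment=True, kin=sub_kin,
            compute_se=False, maxpts=maxpts, xatol=5e-3, fatol=5e-3,
        )
        fit_u = fit_liability(
            asc, aff, correct_ascertainment=False, kin=sub_kin,
            compute_se=False, maxpts=maxpts, xatol=5e-3, fatol=5e-3,
        )
        corrected.append(fit_c.h2)
        uncorrected.append(fit_u.h2)
        prev_corr.append(fit_c.prevalence)
        prev_unc.append(fit_u.prevalence)
    return {
        "mean_h2_corrected": float(np.mean(corrected)),
        "mean_h2_uncorrected": float(np.mean(uncorrected)),
        "mean_prevalence_corrected": float(np.mean(prev_corr)),
        "mean_prevalence_uncorrected": float(np.mean(prev_unc)),
        "true_h2": h2,
        "true_prevalence": prevalence,
    }


def bivariate_recovery_study(
    n_reps: int = 20,
    n_families: int = 35,
    seed: int = 0,
) -> dict:
    """Bivariate recovery at the ETP / thrombin-peak generative values."""
    spec = TraitModelSpec(
        traits=("ETP", "TP"),
        h2=(ETP_H2, TP_H2),
        c2=(ETP_C2, TP_C2),
        mean=(48.53, 32.09),
        total_var=(3.3, 3.3),
        rho_g=RHO_G,
        rho_e=RHO_E,
    )
    rgs, res_, rps = [], [], []
    for rep in range(n_reps):
        ped = generate_pedigree(n_families, seed=seed + 19 * rep)
        kin = kinship_matrix(ped)
        traits = simulate_traits(ped, spec, seed=seed + 19 * rep + 1, kin=kin)
        fit = fit_bivariate(
            ped, traits["ETP"], traits["TP"], kin=kin,
            compute_se=False, compute_lrt=False,
        )
        rgs.append(fit.rho_g)
        res_.append(fit.rho_e)
        rps.append(fit.rho_p)
    return {
        "mean_rho_g": float(np.mean(rgs)),
        "mean_rho_e": float(np.mean(res_)),
        "mean_rho_p": float(np.mean(rps)),
        "rho_g": rgs,
        "true_rho_g": RHO_G,
        "true_rho_e": RHO_E,
    }


def gwas_null_study(
    n_snps: int = 5000,
    n_families: int = 35,
    trait_h2: float = 0.5,
    n_studies: int = 4,
    seed: int = 0,
) -> dict:
    """Null association scans: gene-dropped SNPs against a polygenic trait.

    No SNP affects the trait, so the LRT statistics should follow
    chi-square(1).  Within one scan all SNPs share the same realized trait,
    which correlates their statistics and makes a single study's inflation
    factor fluctuate by several hundredths even for a perfectly calibrated
    test; the study therefore averages the inflation factor over
    ``n_studies`` independent scans (of ``n_snps`` SNPs each) and runs the
    Kolmogorov-Smirnov check on the pooled statistics.
    """
    spec = TraitModelSpec(
        traits=("y",), h2=(trait_h2,), c2=(0.0,), mean=(0.0,), total_var=(1.0,)
    )
    lambdas, pooled, n_tot = [], [], 0
    for rep in range(n_studies):
        s = seed + 23 * rep
        ped = generate_pedigree(n_families, seed=s)
        kin = kinship_matrix(ped)
        trait = simulate_traits(ped, spec, seed=s + 1, kin=kin)["y"]
        rng = np.random.default_rng([s, 3])
        mafs = rng.uniform(0.05, 0.5, n_snps)
        geno = simulate_genotypes(ped, maf=mafs, n_snps=n_snps, seed=s + 2)
        res, summary = run_gwas(ped, trait, geno, qc=False, kin=kin)
        lambdas.append(float(summary["lambda"]))
        pooled.append(res["chi2"].dropna().to_numpy())
        n_tot += len(ped)
    chi2 = np.concatenate(pooled)
    ks = stats.kstest(chi2, stats.chi2(1).cdf)
    return {
        "lambda": float(np.mean(lambdas)),
        "lambdas": lambdas,
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "n_snps": int(n_snps),
        "n": n_tot,
    }
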