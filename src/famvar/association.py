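"""Measured-genotype association testing on pedigrees.

A SNP's additive allele count (or imputed dosage) enters the fixed effects
of the pedigree variance-component model, so genotype-specific differences
in trait means are tested while the kinship-structured covariance absorbs
the non-independence among family members.  Variance components are profiled
once under the null model and held fixed across SNPs (a score-test-like
speedup that makes genome scans linear algebra); an exact per-SNP re-fit is
available through ``refit=True``.

Quality control follows standard array conventions: call rate, founder MAF,
founder Hardy-Weinberg exact test, and the imputation info score when one is
provided.  Genome-wide and suggestive significance default to 5e-8 and 1e-5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.special import gammaln

from famvar.pedigree import (
    HouseholdMatrix,
    KinshipMatrix,
    Pedigree,
    household_matrix,
    kinship_matrix,
)
from famvar.varcomp import FitResult, fit_univariate

__all__ = [
    "AssociationResult",
    "hwe_exact_test",
    "qc_filter",
    "measured_genotype_test",
    "genomic_lambda",
    "run_gwas",
]

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5

#: theoretical median of the chi-square(1) distribution
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class AssociationResult:
    """Per-SNP measured-genotype test result."""

    snp: str
    maf: float
    info: Optional[float]
    beta: float
    se: float
    p: float
    n: int
    flags: dict = field(default_factory=dict)
    significance: str = "none"  # {"genome-wide", "suggestive", "none"}


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one.  Counts should come from founders only (relatives are
    not independent draws from the population).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotype observations")
    n_a = 2 * n_aa + n_Aa  # minor-allele count (label irrelevant by symmetry)
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0
    # heterozygote count has the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = (n - hets - homr) - 0  # common homozygotes
    logp = (
        hets * math.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
    )
    logp -= np.max(logp)
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _founder_maf(geno: pd.DataFrame, founder_ids: Sequence[str]) -> pd.Series:
    g = geno.loc[[i for i in founder_ids if i in geno.index]]
    freq = g.mean(axis=0, skipna=True) / 2.0
    return np.minimum(freq, 1 - freq)


def qc_filter(
    genotypes: pd.DataFrame,
    ped: Pedigree,
    info: Optional[pd.Series] = None,
    maf_min: float = 0.01,
    callrate_min: float = 0.98,
    hwe_p_min: float = 1e-6,
    info_min: float = 0.3,
    maf_on_founders: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply call-rate, MAF, Hardy-Weinberg and info-score filters.

    ``genotypes`` is individuals x SNPs with values 0/1/2 (or dosages; NaN =
    missing).  MAF and HWE are computed on founders; the HWE test runs only
    on hard-called (integer) genotypes, and the info filter only when an
    ``info`` series is given.  A filter is disabled by passing ``None`` for
    its threshold.  Flags are a pure function of the genotypes, never of any
    trait.

    Returns (passing genotype columns, flag table).
    """
    founders = ped.founders if maf_on_founders else list(genotypes.index)
    maf = _founder_maf(genotypes, founders)
    callrate = genotypes.notna().mean(axis=0)
    fg = genotypes.loc[[i for i in founders if i in genotypes.index]]
    hwe_p = pd.Series(np.nan, index=genotypes.columns)
    for snp in genotypes.columns:
        col = fg[snp].dropna()
        if len(col) and np.allclose(col, np.round(col)):
            c = np.round(col).astype(int)
            hwe_p[snp] = hwe_exact_test(
                int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum())
            )
    flags = pd.DataFrame(
        {
            "maf": maf,
            "callrate": callrate,
            "hwe_p": hwe_p,
            "info": info.reindex(genotypes.columns) if info is not None else np.nan,
        }
    )
    flags["maf_fail"] = (maf < maf_min) if maf_min is not None else False
    flags["callrate_fail"] = (
        (callrate < callrate_min) if callrate_min is not None else False
    )
    flags["hwe_fail"] = (
        hwe_p.notna() & (hwe_p < hwe_p_min) if hwe_p_min is not None else False
    )
    if info is not None and info_min is not None:
        flags["info_fail"] = flags["info"] < info_min
    else:
        flags["info_fail"] = False
    flags["pass"] = ~(
        flags[["maf_fail", "callrate_fail", "hwe_fail", "info_fail"]].any(axis=1)
    )
    return genotypes.loc[:, flags["pass"]], flags


class _NullModelWhitener:
    """Cholesky whitening by the null-model covariance, per family block."""

    def __init__(self, ids, kin: KinshipMatrix, fit: FitResult):
        self.ids = list(ids)
        kin_s = kin.submatrix(self.ids)
        self.blocks = list(kin_s.family_blocks().items())
        self.kin_s = kin_s
        self.fit = fit

    def whiten(self, M: np.ndarray, hh: HouseholdMatrix) -> np.ndarray:
        fit = self.fit
        hh_s = hh.submatrix(self.ids)
        out = np.empty_like(M, dtype=float)
        e2 = max(1 - fit.h2 - fit.c2, 1e-8)
        for fam, idx in self.blocks:
            S = fit.total_var * (
                fit.h2 * self.kin_s.values[np.ix_(idx, idx)]
                + fit.c2 * hh_s.values[np.ix_(idx, idx)]
                + e2 * np.eye(len(idx))
            )
            L = np.linalg.cholesky(S)
            out[idx] = solve_triangular(L, M[idx], lower=True, check_finite=False)
        return out


def _classify(p: float, genome_wide: float, suggestive: float) -> str:
    if p < genome_wide:
        return "genome-wide"
    if p < suggestive:
        return "suggestive"
    return "none"


def measured_genotype_test(
    ped: Pedigree,
    trait: pd.Series,
    genotype: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    covariate_names: Optional[Sequence[str]] = None,
    condition_on: Optional[pd.Series] = None,
    null_fit: Optional[FitResult] = None,
    refit: bool = False,
    kin: Optional[KinshipMatrix] = None,
    hh: Optional[HouseholdMatrix] = None,
    info: Optional[float] = None,
    genome_wide: float = GENOME_WIDE_P,
    suggestive: float = SUGGESTIVE_P,
) -> AssociationResult:
    """Test one SNP's additive effect on a pedigree trait.

    Default: variance components fixed at the null fit, SNP tested by
    generalized least squares in the whitened model (LRT is then the drop in
    whitened residual sum of squares, chi-square 1 df).  ``refit=True``
    re-estimates variance components with the SNP in the model and uses the
    full likelihood ratio.  ``condition_on`` enters a second SNP as a fixed
    covariate (conditional analysis).
    """
    kin = kin if kin is not None else kinship_matrix(ped)
    hh = hh if hh is not None else household_matrix(ped)
    snp_name = str(genotype.name or "snp")

    ids = [i for i in ped.ids if i in trait.dropna().index and i in genotype.index]
    g = genotype.loc[ids].astype(float)
    if g.isna().any():  # mean-impute missing genotypes
        g = g.fillna(g.mean())
    if float(g.max() - g.min()) == 0.0:
        return AssociationResult(
            snp=snp_name, maf=float(_founder_maf(g.to_frame(), ped.founders).iloc[0]),
            info=info, beta=np.nan, se=np.nan, p=np.nan, n=len(ids),
            flags={"monomorphic": True}, significance="none",
        )
    maf = float(_founder_maf(g.to_frame(), ped.founders).iloc[0])

    cov = covariates.copy() if covariates is not None else pd.DataFrame(index=ids)
    names = list(covariate_names) if covariate_names else []
    if condition_on is not None:
        cov = cov.reindex(ids)
        cov["_cond_snp"] = condition_on.loc[ids].astype(float)
        names = names + ["_cond_snp"]

    if refit:
        cov2 = cov.reindex(ids)
        cov2["_snp"] = g
        alt = fit_univariate(ped, trait, cov2, names + ["_snp"], screen=False,
                             kin=kin, hh=hh, compute_se=True)
        null = fit_univariate(ped, trait, cov2 if names else None,
                              names or None, screen=False, kin=kin, hh=hh,
                              compute_se=False)
        T = max(0.0, 2 * (alt.loglik - null.loglik))
        p = float(stats.chi2.sf(T, 1))
        beta = float(alt.beta.loc["_snp", "beta"])
        se = float(alt.beta.loc["_snp", "se"])
    else:
        if null_fit is None:
            null_fit = fit_univariate(ped, trait, cov if names else None,
                                      names or None, screen=False, kin=kin,
                                      hh=hh, compute_se=False)
        from famvar.simulate import design_matrix

        if names:
            X, _ = design_matrix(cov.reindex(ids), names)
        else:
            X = np.ones((len(ids), 1))
        wh = _NullModelWhitener(ids, kin, null_fit)
        yw = wh.whiten(trait.loc[ids].to_numpy(float)[:, None], hh)[:, 0]
        Xw = wh.whiten(X, hh)
        gw = wh.whiten(g.to_numpy()[:, None], hh)[:, 0]
        Q, _ = np.linalg.qr(Xw)
        ry = yw - Q @ (Q.T @ yw)
        rg = gw - Q @ (Q.T @ gw)
        gg = float(rg @ rg)
        beta = float(rg @ ry) / gg
        se = 1.0 / np.sqrt(gg)
        T = (float(rg @ ry) ** 2) / gg  # drop in whitened RSS
        p = float(stats.chi2.sf(T, 1))

    return AssociationResult(
        snp=snp_name, maf=maf, info=info, beta=beta, se=se, p=p, n=len(ids),
        flags={"monomorphic": False},
        significance=_classify(p, genome_wide, suggestive),
    )


def genomic_lambda(
    p_values: Optional[Sequence[float]] = None,
    chi2_stats: Optional[Sequence[float]] = None,
) -> float:
    """Median-based genomic inflation factor.

    ``lambda = median(chi2) / 0.4549``, the chi-square(1) theoretical median;
    p-values are converted through the inverse upper tail.  Values near 1
    indicate a calibrated test.
    """
    if chi2_stats is None:
        if p_values is None or len(p_values) == 0:
            raise ValueError("provide p-values or chi-square statistics")
        chi2_stats = stats.chi2.isf(np.asarray(p_values, float), 1)
    chi2_stats = np.asarray(chi2_stats, float)
    if chi2_stats.size == 0:
        raise ValueError("empty statistics")
    return float(np.median(chi2_stats) / _CHI2_1_MEDIAN)


def run_gwas(
    ped: Pedigree,
    trait: pd.Series,
    genotypes: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    covariate_names: Optional[Sequence[str]] = None,
    info: Optional[pd.Series] = None,
    positions: Optional[pd.DataFrame] = None,
    condition_on: Optional[str] = None,
    qc: bool = True,
    genome_wide: float = GENOME_WIDE_P,
    suggestive: float = SUGGESTIVE_P,
    kin: Optional[KinshipMatrix] = None,
    hh: Optional[HouseholdMatrix] = None,
) -> tuple[pd.DataFrame, dict]:
    """QC + per-SNP measured-genotype tests + genomic inflation summary.

    The null variance-component model is fitted once and its covariance is
    used to whiten trait, covariates and all genotype columns, so the scan
    is a single pass of linear algebra.  Results are ordered by chromosome/
    position when ``positions`` (columns ``chrom``, ``pos``) is given, else
    by SNP id.  Returns (result table, summary with ``lambda`` and counts
    per significance class).
    """
    kin = kin if kin is not None else kinship_matrix(ped)
    hh = hh if hh is not None else household_matrix(ped)
    if genotypes.shape[1] == 0:
        return (
            pd.DataFrame(
                columns=["snp", "maf", "info", "beta", "se", "p", "n", "significance"]
            ),
            {"lambda": np.nan, "lambda_defined": False, "n_snps": 0,
             "n_genome_wide": 0, "n_suggestive": 0},
        )
    flags = None
    if qc:
        genotypes, flags = qc_filter(genotypes, ped, info=info)
    ids = [i for i in ped.ids if i in trait.dropna().index and i in genotypes.index]
    G = genotypes.loc[ids].astype(float)
    G = G.fillna(G.mean())

    cov = covariates.copy() if covariates is not None else pd.DataFrame(index=ids)
    names = list(covariate_names) if covariate_names else []
    if condition_on is not None:
        cov = cov.reindex(ids)
        cov["_cond_snp"] = G[condition_on]
        names = names + ["_cond_snp"]

    null_fit = fit_univariate(ped, trait, cov if names else None, names or None,
                              screen=False, kin=kin, hh=hh, compute_se=False)
    from famvar.simulate import design_matrix

    if names:
        X, _ = design_matrix(cov.reindex(ids), names)
    else:
        X = np.ones((len(ids), 1))
    wh = _NullModelWhitener(ids, kin, null_fit)
    yw = wh.whiten(trait.loc[ids].to_numpy(float)[:, None], hh)[:, 0]
    Xw = wh.whiten(X, hh)
    Gw = wh.whiten(G.to_numpy(), hh)
    Q, _ = np.linalg.qr(Xw)
    ry = yw - Q @ (Q.T @ yw)
    Rg = Gw - Q @ (Q.T @ Gw)
    gg = np.einsum("ij,ij->j", Rg, Rg)
    gy = ry @ Rg
    ok = gg > 1e-12
    beta = np.where(ok, gy / np.where(ok, gg, 1.0), np.nan)
    se = np.where(ok, 1.0 / np.sqrt(np.where(ok, gg, 1.0)), np.nan)
    T = np.where(ok, gy**2 / np.where(ok, gg, 1.0), np.nan)
    p = stats.chi2.sf(T, 1)

    maf = _founder_maf(genotypes, ped.founders)
    res = pd.DataFrame(
        {
            "snp": genotypes.columns,
            "maf": maf.values,
            "info": (info.reindex(genotypes.columns).values
                     if info is not None else np.nan),
            "beta": beta,
            "se": se,
            "chi2": T,
            "p": p,
            "n": len(ids),
        }
    )
    res["significance"] = [
        _classify(pv, genome_wide, suggestive) if np.isfinite(pv) else "none"
        for pv in res["p"]
    ]
    if positions is not None:
        res = res.merge(positions, left_on="snp", right_index=True, how="left")
        res = res.sort_values(["chrom", "pos", "snp"]).reset_index(drop=True)
    else:
        res = res.sort_values("snp").reset_index(drop=True)

    valid = res["chi2"].dropna()
    summary = {
        "lambda": genomic_lambda(chi2_stats=valid.to_numpy()) if len(valid) >= 1 else np.nan,
        "lambda_defined": bool(len(valid)),
        "n_snps": int(len(res)),
        "n_genome_wide": int((res["significance"] == "genome-wide").sum()),
        "n_suggestive": int((res["significance"] == "suggestive").sum()),
        "null_h2": null_fit.h2,
        "null_c2": null_fit.c2,
    }
    if flags is not None:
        summary["n_qc_fail"] = int((~flags["pass"]).sum())
    return res, summary
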