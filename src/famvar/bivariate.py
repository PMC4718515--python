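"""Bivariate variance-component models: genetic and environmental correlations.

For two quantitative traits the per-family joint covariance of the stacked
vector ``[y1; y2]`` has blocks

    cov(y_t, y_u) = 2Phi * rho_g * sg_t sg_u  +  H * rho_c * sc_t sc_u
                    +  I * rho_e * se_t se_u

(with ``rho = 1`` on the diagonal blocks), so the cross-trait covariance is
partitioned into additive-genetic, shared-household and residual parts.
``rho_g`` quantifies pleiotropy; the phenotypic correlation derives from the
component correlations and the heritabilities as

    rho_p = sqrt(h2_1 h2_2) rho_g + sqrt(1 - h2_1) sqrt(1 - h2_2) rho_e

(the household term is deliberately omitted from this derivation, matching
the standard reporting convention; with household variance present the
derived value is approximate).

A binary disease trait may enter as the first trait: its marginal model is
the liability threshold fit, and the joint likelihood multiplies the
continuous trait's normal density by the conditional rectangle probability
of the liability given the observed continuous values (conditional-normal
decomposition).  The marginal parameters are held at their univariate ML
estimates and the correlations are maximised — a two-stage fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import multivariate_normal as _mvn

from famvar.pedigree import (
    HouseholdMatrix,
    KinshipMatrix,
    Pedigree,
    household_matrix,
    kinship_matrix,
)
from famvar.liability import _QMC_SEED, fit_liability
from famvar.simulate import design_matrix
from famvar.varcomp import fit_univariate, lrt_boundary

__all__ = ["BivariateFitResult", "derived_rho_p", "fit_bivariate"]

_MAX_S = 0.9999
_MAX_RHO = 0.999


def derived_rho_p(h2_1: float, h2_2: float, rho_g: float, rho_e: float) -> float:
    """Phenotypic correlation implied by the component correlations.

    ``sqrt(h2_1*h2_2)*rho_g + sqrt(1-h2_1)*sqrt(1-h2_2)*rho_e``.
    """
    for name, v, lo, hi in (
        ("h2_1", h2_1, 0, 1), ("h2_2", h2_2, 0, 1),
        ("rho_g", rho_g, -1, 1), ("rho_e", rho_e, -1, 1),
    ):
        if not (lo <= v <= hi):
            raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
    return float(
        np.sqrt(h2_1 * h2_2) * rho_g
        + np.sqrt(1 - h2_1) * np.sqrt(1 - h2_2) * rho_e
    )


@dataclass
class BivariateFitResult:
    """Bivariate variance-component fit."""

    h2_1: float
    c2_1: float
    h2_2: float
    c2_2: float
    total_var_1: float
    total_var_2: float
    rho_g: float
    se_rho_g: float
    p_rho_g: float
    rho_e: float
    se_rho_e: float
    p_rho_e: float
    rho_c: float
    rho_c_estimated: bool
    rho_p: float
    se_rho_p: float
    p_rho_p: float  # delta-method approximation
    loglik: float
    loglik_rho_g0: float
    loglik_rho_e0: float
    converged: bool
    n: int
    boundary: bool
    binary_trait1: bool = False


class _BivBlocks:
    """Per-family (y1, y2, X, 2Phi, H) blocks; beta profiled by GLS."""

    def __init__(self, y1, y2, X1, X2, kin: KinshipMatrix, hh: HouseholdMatrix):
        self.n_obs = 2 * len(y1)
        self.p1, self.p2 = X1.shape[1], X2.shape[1]
        self.blocks = []
        for fam, idx in kin.family_blocks().items():
            self.blocks.append(
                (
                    y1[idx], y2[idx], X1[idx], X2[idx],
                    kin.values[np.ix_(idx, idx)], hh.values[np.ix_(idx, idx)],
                )
            )

    def profile(self, phi):
        """Log-likelihood at GLS-profiled fixed effects.

        ``phi = (h21, c21, h22, c22, logv1, logv2, rg, re, rc)``.
        """
        from scipy.linalg import cho_factor, cho_solve

        h21, c21, h22, c22, lv1, lv2, rg, re, rc = phi
        v1, v2 = np.exp(lv1), np.exp(lv2)
        e21, e22 = 1 - h21 - c21, 1 - h22 - c22
        sg = np.sqrt(v1 * h21 * v2 * h22)
        sc = np.sqrt(v1 * c21 * v2 * c22)
        se = np.sqrt(v1 * e21 * v2 * e22)
        p = self.p1 + self.p2
        XtSX = np.zeros((p, p))
        XtSy = np.zeros(p)
        ySy = 0.0
        logdet = 0.0
        for y1, y2, X1, X2, K, H in self.blocks:
            m = len(y1)
            I = np.eye(m)
            S11 = v1 * (h21 * K + c21 * H + e21 * I)
            S22 = v2 * (h22 * K + c22 * H + e22 * I)
            S12 = rg * sg * K + rc * sc * H + re * se * I
            S = np.block([[S11, S12], [S12.T, S22]])
            y = np.concatenate([y1, y2])
            X = np.zeros((2 * m, p))
            X[:m, : self.p1] = X1
            X[m:, self.p1:] = X2
            try:
                c, low = cho_factor(S, lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                return -1e12, None
            logdet += 2 * np.log(np.diag(c)).sum()
            Sy = cho_solve((c, low), y, check_finite=False)
            SX = cho_solve((c, low), X, check_finite=False)
            XtSX += X.T @ SX
            XtSy += X.T @ Sy
            ySy += y @ Sy
        beta = np.linalg.solve(XtSX, XtSy)
        quad = ySy - beta @ XtSy
        ll = -0.5 * (self.n_obs * np.log(2 * np.pi) + logdet + quad)
        return float(ll), beta


def _pack(x, fix):
    """Map optimiser coordinates to phi, honouring fixed entries."""
    phi = np.empty(9)
    s1, f1, s2, f2 = x[0], x[1], x[2], x[3]
    phi[0], phi[1] = s1 * f1, s1 * (1 - f1)
    phi[2], phi[3] = s2 * f2, s2 * (1 - f2)
    phi[4], phi[5] = x[4], x[5]
    phi[6] = fix.get("rg", x[6])
    phi[7] = fix.get("re", x[7])
    phi[8] = fix.get("rc", x[8])
    return phi


def _fit_continuous(
    ped, trait1, trait2, covariates, covariate_names_1, covariate_names_2,
    kin, hh, estimate_rho_c, compute_se, compute_lrt=True,
    fix_rho_g=None, fix_rho_e=None,
):
    both = trait1.dropna().index.intersection(trait2.dropna().index)
    ids = [i for i in ped.ids if i in both]
    if len(ids) < 4:
        raise ValueError("traits overlap on too few individuals")
    y1 = trait1.loc[ids].to_numpy(float)
    y2 = trait2.loc[ids].to_numpy(float)
    kin_s, hh_s = kin.submatrix(ids), hh.submatrix(ids)

    def dm(names):
        if covariates is not None and names:
            X, _ = design_matrix(covariates.loc[ids], names)
        else:
            X = np.ones((len(ids), 1))
        return X

    X1, X2 = dm(covariate_names_1), dm(covariate_names_2)

    # univariate fits initialise the marginals and decide whether rho_c is free
    uni1 = fit_univariate(ped, trait1, covariates, covariate_names_1,
                          screen=False, kin=kin, hh=hh, compute_se=False)
    uni2 = fit_univariate(ped, trait2, covariates, covariate_names_2,
                          screen=False, kin=kin, hh=hh, compute_se=False)
    if estimate_rho_c is None:
        estimate_rho_c = uni1.c2 > 0.01 and uni2.c2 > 0.01

    r = np.corrcoef(y1 - X1 @ np.linalg.lstsq(X1, y1, rcond=None)[0],
                    y2 - X2 @ np.linalg.lstsq(X2, y2, rcond=None)[0])[0, 1]
    r0 = float(np.clip(r, -0.9, 0.9))

    data = _BivBlocks(y1, y2, X1, X2, kin_s, hh_s)

    def solve(fix):
        def neg(x):
            ll, _ = data.profile(_pack(x, fix))
            return -ll

        x0 = np.array([
            min(uni1.h2 + uni1.c2, 0.98), uni1.h2 / max(uni1.h2 + uni1.c2, 1e-6),
            min(uni2.h2 + uni2.c2, 0.98), uni2.h2 / max(uni2.h2 + uni2.c2, 1e-6),
            np.log(uni1.total_var), np.log(uni2.total_var),
            r0, r0, r0,
        ])
        bounds = [(0, _MAX_S), (0, 1), (0, _MAX_S), (0, 1),
                  (None, None), (None, None),
                  (-_MAX_RHO, _MAX_RHO), (-_MAX_RHO, _MAX_RHO),
                  (-_MAX_RHO, _MAX_RHO)]
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-11, "maxiter": 500})
        phi = _pack(res.x, fix)
        ll, beta = data.profile(phi)
        return phi, ll, res.success

    fix_base = {} if estimate_rho_c else {"rc": 0.0}
    if fix_rho_g is not None:
        fix_base["rg"] = fix_rho_g
    if fix_rho_e is not None:
        fix_base["re"] = fix_rho_e
    phi, ll, ok = solve(fix_base)
    if compute_lrt:
        _, ll_g0, _ = solve({**fix_base, "rg": 0.0})
        _, ll_e0, _ = solve({**fix_base, "re": 0.0})
        p_rg = lrt_boundary(min(ll_g0, ll), ll, 0, df_interior=1)
        p_re = lrt_boundary(min(ll_e0, ll), ll, 0, df_interior=1)
    else:
        ll_g0 = ll_e0 = np.nan
        p_rg = p_re = np.nan

    h21, c21, h22, c22 = phi[0], phi[1], phi[2], phi[3]
    rg, re, rc = phi[6], phi[7], phi[8]
    rho_p = derived_rho_p(h21, h22, rg, re)

    se_rg = se_re = se_rp = np.nan
    p_rp = np.nan
    if compute_se:
        free = [0, 1, 2, 3, 4, 5, 6, 7] + ([8] if estimate_rho_c else [])
        cov = _profile_hessian_cov(data, phi, free)
        se_rg = np.sqrt(max(cov[free.index(6), free.index(6)], 0))
        se_re = np.sqrt(max(cov[free.index(7), free.index(7)], 0))
        se_rp, p_rp = _rho_p_delta(phi, cov, free)

    boundary = (
        min(h21, c21, h22, c22) < 1e-4
        or max(abs(rg), abs(re)) > _MAX_RHO - 1e-4
    )
    return BivariateFitResult(
        h2_1=float(h21), c2_1=float(c21), h2_2=float(h22), c2_2=float(c22),
        total_var_1=float(np.exp(phi[4])), total_var_2=float(np.exp(phi[5])),
        rho_g=float(rg), se_rho_g=float(se_rg), p_rho_g=float(p_rg),
        rho_e=float(re), se_rho_e=float(se_re), p_rho_e=float(p_re),
        rho_c=float(rc), rho_c_estimated=bool(estimate_rho_c),
        rho_p=float(rho_p), se_rho_p=float(se_rp), p_rho_p=float(p_rp),
        loglik=float(ll), loglik_rho_g0=float(ll_g0), loglik_rho_e0=float(ll_e0),
        converged=bool(ok), n=len(ids), boundary=boundary,
    )


def _profile_hessian_cov(data, phi, free):
    """Covariance of the free natural parameters from the profile Hessian."""
    k = len(free)
    steps = np.full(k, 1e-3)

    def ll(z):
        q = phi.copy()
        q[free] = z
        q[0] = min(max(q[0], 0), 1); q[1] = min(max(q[1], 0), 1)
        q[2] = min(max(q[2], 0), 1); q[3] = min(max(q[3], 0), 1)
        out, _ = data.profile(q)
        return out

    z0 = phi[free].copy()
    # pull points off the boundary for differencing
    for i, g in enumerate(free):
        if g in (0, 1, 2, 3):
            z0[i] = min(max(z0[i], steps[i]), 1 - steps[i])
        if g in (6, 7, 8):
            z0[i] = min(max(z0[i], -_MAX_RHO + steps[i]), _MAX_RHO - steps[i])
    H = np.zeros((k, k))
    f0 = ll(z0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                H[i, i] = (ll(z0 + ei) - 2 * f0 + ll(z0 - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    ll(z0 + ei + ej) - ll(z0 + ei - ej)
                    - ll(z0 - ei + ej) + ll(z0 - ei - ej)
                ) / (4 * steps[i] * steps[j])
    return np.linalg.pinv(-H)


def _rho_p_delta(phi, cov, free):
    """Delta-method SE and (approximate) p-value for the derived rho_p."""
    h21, h22, rg, re = phi[0], phi[2], phi[6], phi[7]
    rho_p = derived_rho_p(h21, h22, rg, re)
    grad = np.zeros(len(free))
    pos = {g: i for i, g in enumerate(free)}
    sq_g = np.sqrt(max(h21 * h22, 1e-12))
    sq_e = np.sqrt(max((1 - h21) * (1 - h22), 1e-12))
    if 0 in pos:
        grad[pos[0]] = 0.5 * rg * h22 / sq_g - 0.5 * re * (1 - h22) / sq_e
    if 2 in pos:
        grad[pos[2]] = 0.5 * rg * h21 / sq_g - 0.5 * re * (1 - h21) / sq_e
    if 6 in pos:
        grad[pos[6]] = sq_g
    if 7 in pos:
        grad[pos[7]] = sq_e
    var = float(grad @ cov @ grad)
    se = np.sqrt(max(var, 0.0))
    p = 2 * stats.norm.sf(abs(rho_p) / se) if se > 0 else np.nan
    return se, p


def _fit_binary_continuous(
    ped, affection, trait2, covariates, covariate_names_1, covariate_names_2,
    kin, hh, probands, correct_ascertainment, maxpts, compute_se,
):
    """Two-stage liability-by-continuous fit: marginals fixed, correlations ML."""
    lia = fit_liability(
        ped, affection, covariates, covariate_names_1, probands=probands,
        correct_ascertainment=correct_ascertainment, kin=kin,
        maxpts=maxpts, compute_se=False,
    )
    uni = fit_univariate(ped, trait2, covariates, covariate_names_2,
                         screen=False, kin=kin, hh=hh, compute_se=False)
    both = affection.dropna().index.intersection(trait2.dropna().index)
    ids = [i for i in ped.ids if i in both]
    aff = affection.loc[ids].to_numpy().astype(bool)
    y2 = trait2.loc[ids].to_numpy(float)
    kin_s, hh_s = kin.submatrix(ids), hh.submatrix(ids)
    if covariates is not None and covariate_names_2:
        X2, _ = design_matrix(covariates.loc[ids], covariate_names_2)
    else:
        X2 = np.ones((len(ids), 1))
    if covariates is not None and covariate_names_1:
        X1, _ = design_matrix(covariates.loc[ids], covariate_names_1,
                              add_intercept=False)
        mu1 = X1 @ lia.beta["beta"].to_numpy() * (-1 if lia.sign_flipped else 1)
    else:
        mu1 = np.zeros(len(ids))
    beta2 = np.linalg.lstsq(X2, y2, rcond=None)[0]  # refined below by GLS residual
    h2L, t = lia.h2, lia.threshold
    h22, c22, e22, v2 = uni.h2, uni.c2, 1 - uni.h2 - uni.c2, uni.total_var

    blocks = []
    for fam, idx in kin_s.family_blocks().items():
        blocks.append((aff[idx], y2[idx], X2[idx], mu1[idx],
                       kin_s.values[np.ix_(idx, idx)], hh_s.values[np.ix_(idx, idx)]))

    from scipy.linalg import cho_factor, cho_solve

    def loglik(rg, re):
        ll = 0.0
        for a, y, X, m1, K, H in blocks:
            m = len(a)
            I = np.eye(m)
            S22 = v2 * (h22 * K + c22 * H + e22 * I)
            S12 = np.sqrt(v2) * (
                rg * np.sqrt(h2L * h22) * K + re * np.sqrt((1 - h2L) * e22) * I
            )
            c, low = cho_factor(S22, lower=True, check_finite=False)
            r2 = y - X @ beta2
            w = cho_solve((c, low), r2, check_finite=False)
            ll += -0.5 * (m * np.log(2 * np.pi) + 2 * np.log(np.diag(c)).sum() + r2 @ w)
            mu_c = m1 + S12 @ w
            S11 = h2L * K + (1 - h2L) * I
            Sc = S11 - S12 @ cho_solve((c, low), S12.T, check_finite=False)
            Sc = 0.5 * (Sc + Sc.T) + 1e-9 * I
            z = t - mu_c
            if m == 1:
                p = stats.norm.sf(z[0]) if a[0] else stats.norm.cdf(z[0])
            else:
                lower = np.where(a, z, -np.inf)
                upper = np.where(a, np.inf, z)
                p = _mvn.cdf(upper, mean=np.zeros(m), cov=Sc, lower_limit=lower,
                             maxpts=maxpts, rng=np.random.default_rng(_QMC_SEED))
            ll += float(np.log(max(float(p), 1e-300)))
        return ll

    def solve(fix_rg=None, fix_re=None):
        def neg(x):
            rg = fix_rg if fix_rg is not None else x[0]
            re = fix_re if fix_re is not None else x[-1]
            return -loglik(rg, re)

        n_free = (fix_rg is None) + (fix_re is None)
        x0 = np.zeros(n_free)
        res = optimize.minimize(
            neg, x0, method="Nelder-Mead",
            bounds=[(-_MAX_RHO, _MAX_RHO)] * n_free,
            options={"xatol": 1e-4, "fatol": 1e-6},
        )
        rg = fix_rg if fix_rg is not None else float(res.x[0])
        re = fix_re if fix_re is not None else float(res.x[-1])
        return rg, re, -float(res.fun), res.success

    rg, re, ll, ok = solve()
    _, _, ll_g0, _ = solve(fix_rg=0.0)
    _, _, ll_e0, _ = solve(fix_re=0.0)
    p_rg = lrt_boundary(min(ll_g0, ll), ll, 0, df_interior=1)
    p_re = lrt_boundary(min(ll_e0, ll), ll, 0, df_interior=1)
    rho_p = derived_rho_p(h2L, h22, rg, re)

    se_rg = se_re = np.nan
    if compute_se:
        step = 0.05
        f0 = loglik(rg, re)
        rgc = float(np.clip(rg, -_MAX_RHO + step, _MAX_RHO - step))
        rec = float(np.clip(re, -_MAX_RHO + step, _MAX_RHO - step))
        d2g = (loglik(rgc + step, rec) - 2 * loglik(rgc, rec) + loglik(rgc - step, rec)) / step**2
        d2e = (loglik(rgc, rec + step) - 2 * loglik(rgc, rec) + loglik(rgc, rec - step)) / step**2
        se_rg = float(np.sqrt(max(-1 / d2g, 0))) if d2g < 0 else np.nan
        se_re = float(np.sqrt(max(-1 / d2e, 0))) if d2e < 0 else np.nan

    return BivariateFitResult(
        h2_1=float(h2L), c2_1=0.0, h2_2=float(h22), c2_2=float(c22),
        total_var_1=1.0, total_var_2=float(v2),
        rho_g=float(rg), se_rho_g=se_rg, p_rho_g=float(p_rg),
        rho_e=float(re), se_rho_e=se_re, p_rho_e=float(p_re),
        rho_c=0.0, rho_c_estimated=False,
        rho_p=float(rho_p), se_rho_p=np.nan, p_rho_p=np.nan,
        loglik=float(ll), loglik_rho_g0=float(ll_g0), loglik_rho_e0=float(ll_e0),
        converged=bool(ok), n=len(ids),
        boundary=max(abs(rg), abs(re)) > _MAX_RHO - 1e-4,
        binary_trait1=True,
    )


def fit_bivariate(
    ped: Pedigree,
    trait1: pd.Series,
    trait2: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    covariate_names_1: Optional[Sequence[str]] = None,
    covariate_names_2: Optional[Sequence[str]] = None,
    estimate_rho_c: Optional[bool] = None,
    kin: Optional[KinshipMatrix] = None,
    hh: Optional[HouseholdMatrix] = None,
    probands=None,
    correct_ascertainment: bool = False,
    maxpts: int = 20000,
    compute_se: bool = True,
    compute_lrt: bool = True,
    fix_rho_g: float | None = None,
    fix_rho_e: float | None = None,
) -> BivariateFitResult:
    """ML bivariate variance-component fit for a pair of traits.

    ``trait1`` may be a 0/1 disease trait; it is then modelled on the
    liability scale (see module docstring).  ``rho_c`` (the household
    cross-correlation) is estimated only when both traits carry household
    variance; by default this is decided from the univariate fits.  p-values
    for ``rho_g`` and ``rho_e`` are likelihood-ratio tests against the
    constrained model (interior parameter, chi-square with 1 df).
    """
    kin = kin if kin is not None else kinship_matrix(ped)
    hh = hh if hh is not None else household_matrix(ped)
    vals = set(pd.unique(trait1.dropna()))
    if vals <= {0, 1, 0.0, 1.0, True, False}:
        return _fit_binary_continuous(
            ped, trait1, trait2, covariates, covariate_names_1,
            covariate_names_2, kin, hh, probands, correct_ascertainment,
            maxpts, compute_se,
        )
    return _fit_continuous(
        ped, trait1, trait2, covariates, covariate_names_1, covariate_names_2,
        kin, hh, estimate_rho_c, compute_se, compute_lrt,
        fix_rho_g, fix_rho_e,
    )
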