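"""Univariate variance-component estimation on pedigrees.

The model for a quantitative trait ``y`` on ``n`` phenotyped pedigree
members is

    y ~ N(X beta,  sigma2_g * 2Phi + sigma2_c * H + sigma2_e * I)

where ``2Phi`` is the additive relationship matrix and ``H`` the household
indicator.  Families are independent, so the likelihood factors into family
blocks.  Estimates are reported as variance fractions ``h2 = sigma2_g /
sigma2_p`` (heritability) and ``c2 = sigma2_c / sigma2_p`` (household
effect).

Fixed effects and the total variance are profiled out analytically (GLS and
closed-form scale), leaving a two-dimensional maximisation over the variance
fractions on the simplex ``h2, c2 >= 0, h2 + c2 <= 1`` — the boundary is
reachable, so null fits (h2 = 0) are exact.  Standard errors come from the
numerically evaluated observed information; likelihood-ratio tests for
variance fractions use the half-chi-square boundary mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from famvar.pedigree import (
    HouseholdMatrix,
    KinshipMatrix,
    Pedigree,
    household_matrix,
    kinship_matrix,
)
from famvar.simulate import design_matrix

__all__ = [
    "FitResult",
    "transform_trait",
    "mvn_loglik",
    "fit_univariate",
    "lrt_boundary",
]

#: default candidate covariates screened in trait models
CANDIDATE_COVARIATES = ("age", "age2", "female", "oc", "smoking", "phys_act")

_BOUND_EPS = 1e-4  # fraction closer than this to 0 or the simplex edge is "boundary"
_MAX_S = 0.9999  # keep a sliver of residual variance so family blocks stay PD


def transform_trait(values) -> np.ndarray | pd.Series:
    """Natural-log transform of a strictly positive trait.

    Raises a domain error identifying the first offending record when any
    value is non-positive.
    """
    arr = np.asarray(values, float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        if isinstance(values, pd.Series):
            label = values.index[bad[0]]
        else:
            label = int(bad[0])
        raise ValueError(
            f"trait values must be strictly positive for log transform; "
            f"record {label!r} has value {arr[bad[0]]!r}"
        )
    if isinstance(values, pd.Series):
        return np.log(values)
    return np.log(arr)


def lrt_boundary(
    loglik_null: float,
    loglik_alt: float,
    n_boundary_params: int = 1,
    df_interior: int = 0,
    tol: float = 1e-6,
) -> float:
    """Likelihood-ratio p-value with boundary-corrected null distribution.

    For one variance parameter tested at its boundary the LRT statistic is
    asymptotically a 50:50 mixture of a point mass at zero and chi-square(1);
    for two, a 1/4 : 1/2 : 1/4 mixture of chi-square(0, 1, 2).  Interior
    parameters (``n_boundary_params=0``) use the plain chi-square with
    ``df_interior`` degrees of freedom.
    """
    T = 2.0 * (loglik_alt - loglik_null)
    if T < -tol * max(1.0, abs(loglik_null)):
        raise ValueError(
            f"alternative log-likelihood {loglik_alt} below null {loglik_null}"
        )
    T = max(T, 0.0)
    if n_boundary_params == 0:
        if df_interior < 1:
            raise ValueError("df_interior required for an interior test")
        return float(stats.chi2.sf(T, df_interior))
    if n_boundary_params == 1:
        return float(0.5 * stats.chi2.sf(T, 1))
    if n_boundary_params == 2:
        return float(0.25 * stats.chi2.sf(T, 2) + 0.5 * stats.chi2.sf(T, 1))
    raise ValueError("n_boundary_params must be 0, 1 or 2")


def mvn_loglik(
    trait: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    sigma2_g: float,
    sigma2_c: float,
    sigma2_e: float,
    kin: KinshipMatrix,
    hh: HouseholdMatrix,
) -> float:
    """Gaussian log-likelihood of the variance-component model.

    Sum over family blocks of the multivariate-normal log-density with mean
    ``X @ beta`` and covariance ``sigma2_g * 2Phi + sigma2_c * H +
    sigma2_e * I``; the block-diagonal structure (independent families) is
    exploited.
    """
    if min(sigma2_g, sigma2_c, sigma2_e) < 0 or sigma2_g + sigma2_c + sigma2_e <= 0:
        raise ValueError("variance components must be nonnegative, not all zero")
    y = np.asarray(trait, float)
    r = y - np.asarray(X, float) @ np.asarray(beta, float)
    ll = 0.0
    for fam, idx in kin.family_blocks().items():
        S = (
            sigma2_g * kin.values[np.ix_(idx, idx)]
            + sigma2_c * hh.values[np.ix_(idx, idx)]
            + sigma2_e * np.eye(len(idx))
        )
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular covariance for family {fam!r}"
            ) from None
        u = _chol_solve(L, r[idx])
        ll += -0.5 * (
            len(idx) * np.log(2 * np.pi)
            + 2 * np.log(np.diag(L)).sum()
            + r[idx] @ u
        )
    return float(ll)


def _chol_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    return solve_triangular(
        L.T, solve_triangular(L, b, lower=True, check_finite=False),
        lower=False, check_finite=False,
    )


@dataclass
class FitResult:
    """Univariate variance-component fit."""

    h2: float
    c2: float
    se_h2: float
    se_c2: float
    total_var: float
    beta: pd.DataFrame  # columns: beta, se, p
    loglik: float
    p_h2: float
    p_c2: float
    covariate_var_fraction: float
    residual_kurtosis: float
    kurtosis_flag: bool
    converged: bool
    n: int
    boundary: bool = False
    retained_covariates: tuple[str, ...] = ()

    @property
    def sigma2_g(self) -> float:
        return self.h2 * self.total_var

    @property
    def sigma2_c(self) -> float:
        return self.c2 * self.total_var

    @property
    def sigma2_e(self) -> float:
        return (1 - self.h2 - self.c2) * self.total_var


class _BlockData:
    """Per-family blocks of (y, X, 2Phi, H) for fast profile likelihoods."""

    def __init__(self, y, X, kin: KinshipMatrix, hh: HouseholdMatrix):
        self.n = len(y)
        self.p = X.shape[1]
        self.blocks = []
        for fam, idx in kin.family_blocks().items():
            self.blocks.append(
                (
                    np.ascontiguousarray(y[idx]),
                    np.ascontiguousarray(X[idx]),
                    np.ascontiguousarray(kin.values[np.ix_(idx, idx)]),
                    np.ascontiguousarray(hh.values[np.ix_(idx, idx)]),
                )
            )

    def profile(self, h2: float, c2: float):
        """Profile out beta (GLS) and the total variance (closed form).

        Returns (loglik, beta_hat, sigma2_p_hat, XtRiX) at the maximising
        beta and scale for the given variance fractions.
        """
        from scipy.linalg import cho_factor, cho_solve

        e2 = 1.0 - h2 - c2
        XtRX = np.zeros((self.p, self.p))
        XtRy = np.zeros(self.p)
        yRy = 0.0
        logdet = 0.0
        for y, X, K, H in self.blocks:
            m = len(y)
            R = h2 * K + c2 * H + e2 * np.eye(m)
            c, low = cho_factor(R, lower=True, check_finite=False)
            logdet += 2 * np.log(np.diag(c)).sum()
            Ry = cho_solve((c, low), y, check_finite=False)
            RX = cho_solve((c, low), X, check_finite=False)
            XtRX += X.T @ RX
            XtRy += X.T @ Ry
            yRy += y @ Ry
        beta = np.linalg.solve(XtRX, XtRy)
        rss = yRy - beta @ XtRy
        rss = max(rss, 1e-12)
        s2 = rss / self.n
        ll = -0.5 * (self.n * np.log(2 * np.pi * s2) + logdet + self.n)
        return float(ll), beta, float(s2), XtRX

    def full_loglik(self, beta, h2, c2, log_s2p):
        s2p = np.exp(log_s2p)
        ll = 0.0
        from scipy.linalg import cho_factor, cho_solve

        e2 = 1.0 - h2 - c2
        for y, X, K, H in self.blocks:
            m = len(y)
            S = s2p * (h2 * K + c2 * H + e2 * np.eye(m))
            c, low = cho_factor(S, lower=True, check_finite=False)
            r = y - X @ beta
            ll += -0.5 * (
                m * np.log(2 * np.pi)
                + 2 * np.log(np.diag(c)).sum()
                + r @ cho_solve((c, low), r, check_finite=False)
            )
        return float(ll)


def _maximize_profile(data: _BlockData, fix_h2_zero=False, fix_c2_zero=False):
    """Maximise the profile likelihood over the (h2, c2) simplex."""
    if fix_h2_zero and fix_c2_zero:
        ll, beta, s2, _ = data.profile(0.0, 0.0)
        return 0.0, 0.0, ll, beta, s2, True

    if fix_h2_zero or fix_c2_zero:
        def neg(s):
            h2 = 0.0 if fix_h2_zero else s
            c2 = s if fix_h2_zero else 0.0
            return -data.profile(h2, c2)[0]

        res = optimize.minimize_scalar(neg, bounds=(0.0, _MAX_S), method="bounded",
                                       options={"xatol": 1e-8})
        s = float(res.x)
        # check the exact boundary (bounded method cannot land on it)
        if neg(0.0) <= res.fun:
            s = 0.0
        h2 = 0.0 if fix_h2_zero else s
        c2 = s if fix_h2_zero else 0.0
        ll, beta, s2, _ = data.profile(h2, c2)
        return h2, c2, ll, beta, s2, True

    def neg(x):
        s, f = x
        return -data.profile(s * f, s * (1 - f))[0]

    best = None
    for start in ((0.6, 0.7), (0.3, 0.5), (0.85, 0.9), (0.1, 0.5)):
        res = optimize.minimize(
            neg, np.array(start), method="L-BFGS-B",
            bounds=[(0.0, _MAX_S), (0.0, 1.0)],
            options={"ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    s, f = best.x
    h2, c2 = float(s * f), float(s * (1 - f))
    # snap numerically-zero fractions to the exact boundary if it helps
    for cand in ((0.0, c2), (h2, 0.0), (0.0, 0.0)):
        if -data.profile(*cand)[0] <= best.fun + 1e-10:
            h2, c2 = cand
            break
    ll, beta, s2, _ = data.profile(h2, c2)
    return h2, c2, ll, beta, s2, bool(best.success)


def _observed_information_se(data: _BlockData, beta, h2, c2, s2p):
    """SEs of (h2, c2, betas) from the numerical observed information."""
    p = len(beta)
    theta0 = np.concatenate([[h2, c2, np.log(s2p)], beta])

    def ll(theta):
        return data.full_loglik(theta[3:], theta[0], theta[1], theta[2])

    k = len(theta0)
    steps = np.full(k, 1e-4)
    steps[2] = 1e-4
    steps[3:] = 1e-4 * np.maximum(1.0, np.abs(beta))
    # keep finite-difference points inside the parameter space
    lo_ok = np.array([h2, c2]) >= steps[:2]
    Hmat = np.zeros((k, k))
    f0 = ll(theta0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                Hmat[i, i] = (ll(theta0 + ei) - 2 * f0 + ll(theta0 - ei)) / steps[i] ** 2
            else:
                Hmat[i, j] = Hmat[j, i] = (
                    ll(theta0 + ei + ej) - ll(theta0 + ei - ej)
                    - ll(theta0 - ei + ej) + ll(theta0 - ei - ej)
                ) / (4 * steps[i] * steps[j])
    info = -Hmat
    try:
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return se[0], se[1], se[3:]


def fit_univariate(
    ped: Pedigree,
    trait: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    covariate_names: Optional[Sequence[str]] = None,
    screen: bool = True,
    alpha: float = 0.05,
    kin: Optional[KinshipMatrix] = None,
    hh: Optional[HouseholdMatrix] = None,
    compute_se: bool = True,
    kurtosis_threshold: float = 0.8,
) -> FitResult:
    """Maximum-likelihood heritability and household effect for one trait.

    Individuals with a missing trait or covariate value are dropped from the
    likelihood but kept in the pedigree, so kinship paths through them are
    preserved (the relationship matrix is computed on the full pedigree and
    then subset).  Candidate covariates are screened by a single-pass Wald
    test at ``alpha`` on the full model, then the model is refit with the
    significant terms.

    LRT p-values for ``h2`` and ``c2`` use the half-chi-square boundary
    mixture.  SEs come from the observed information; at a boundary optimum
    Wald theory degrades and the result is flagged.
    """
    trait = trait.dropna()
    ids = [i for i in ped.ids if i in trait.index]
    if covariates is not None and covariate_names:
        cov_sub = covariates.loc[[i for i in ids if i in covariates.index]]
        need = {"age" if c == "age2" else c for c in covariate_names}
        cov_sub = cov_sub.dropna(subset=[c for c in need if c in cov_sub.columns])
        ids = [i for i in ids if i in cov_sub.index]
    if len(ids) < 3:
        raise ValueError("too few phenotyped individuals")
    fams = {ped[i].family_id for i in ids}
    if len(fams) < 2:
        raise ValueError("need phenotyped members in at least 2 families")
    y = trait.loc[ids].to_numpy(float)
    if np.allclose(y, y[0]):
        raise ValueError("trait is constant; variance components undefined")

    kin = kin if kin is not None else kinship_matrix(ped)
    hh = hh if hh is not None else household_matrix(ped)
    kin_s = kin.submatrix(ids)
    hh_s = hh.submatrix(ids)

    names = list(covariate_names) if covariate_names else []
    if covariates is not None and names:
        X, labels = design_matrix(covariates.loc[ids], names)
    else:
        X, labels = np.ones((len(ids), 1)), ["intercept"]

    def run(X, labels):
        data = _BlockData(y, X, kin_s, hh_s)
        h2, c2, ll, beta, s2, ok = _maximize_profile(data)
        return data, h2, c2, ll, beta, s2, ok

    data, h2, c2, ll, beta, s2, ok = run(X, labels)

    if screen and len(labels) > 1:
        se_h2_, se_c2_, se_b = _observed_information_se(data, beta, h2, c2, s2)
        pvals = 2 * stats.norm.sf(np.abs(beta) / np.where(se_b > 0, se_b, np.inf))
        keep = [labels[0]] + [
            lab for lab, pv in zip(labels[1:], pvals[1:]) if pv < alpha
        ]
        if keep != labels:
            keep_idx = [labels.index(k) for k in keep]
            X, labels = X[:, keep_idx], keep
            data, h2, c2, ll, beta, s2, ok = run(X, labels)

    if compute_se:
        se_h2, se_c2, se_b = _observed_information_se(data, beta, h2, c2, s2)
    else:
        se_h2 = se_c2 = np.nan
        se_b = np.full(len(beta), np.nan)
    pvals_b = 2 * stats.norm.sf(np.abs(beta) / np.where(se_b > 0, se_b, np.inf))

    # boundary LRTs for the variance fractions
    _, _, ll0g, _, _, _ = _maximize_profile(data, fix_h2_zero=True)
    _, _, ll0c, _, _, _ = _maximize_profile(data, fix_c2_zero=True)
    p_h2 = lrt_boundary(ll0g, ll, 1)
    p_c2 = lrt_boundary(ll0c, ll, 1)

    resid = y - X @ beta
    cov_frac = float(max(0.0, 1.0 - resid.var() / y.var())) if X.shape[1] > 1 else 0.0
    kurt = float(stats.kurtosis(resid))  # excess kurtosis
    boundary = (
        min(h2, c2) < _BOUND_EPS or h2 + c2 > 1 - _BOUND_EPS
    )
    beta_df = pd.DataFrame(
        {"beta": beta, "se": se_b, "p": pvals_b}, index=labels
    )
    return FitResult(
        h2=float(h2),
        c2=float(c2),
        se_h2=float(se_h2),
        se_c2=float(se_c2),
        total_var=float(s2),
        beta=beta_df,
        loglik=float(ll),
        p_h2=float(p_h2),
        p_c2=float(p_c2),
        covariate_var_fraction=cov_frac,
        residual_kurtosis=kurt,
        kurtosis_flag=kurt > kurtosis_threshold,
        converged=bool(ok),
        n=len(ids),
        boundary=boundary,
        retained_covariates=tuple(l for l in labels if l != "intercept"),
    )
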