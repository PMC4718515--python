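"""Liability-threshold (probit) variance-component model for binary disease.

Disease status is modelled through an unobserved continuous liability: for
family ``f`` the members' liabilities are jointly normal with mean ``X beta``
and covariance ``2Phi * h2 + I * (1 - h2)`` (unit marginal variance on the
liability scale), and an individual is affected iff their liability exceeds
a threshold ``t``.  The family log-likelihood is the log of the joint
rectangle probability that every member's liability falls on the observed
side of the threshold, evaluated by randomized quasi-Monte-Carlo integration
with a fixed internal seed (so the likelihood surface is deterministic).

When families are ascertained through a proband, each family's likelihood is
divided by the marginal probability of the proband's observed status
(conditioning on the proband) so that estimates generalise to the unselected
population.

Sign convention: covariate coefficients are reported so that positive values
*increase* liability.  ``flip_signs=True`` reproduces the reversed reporting
convention used by some packages, where a negative printed coefficient means
an increased disease risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import multivariate_normal as _mvn

from famvar.pedigree import KinshipMatrix, Pedigree, kinship_matrix
from famvar.simulate import design_matrix
from famvar.varcomp import lrt_boundary

__all__ = ["LiabilityFit", "family_binary_loglik", "fit_liability"]

_QMC_SEED = 20160119  # fixed internal seed: deterministic likelihood surface
_LOG_FLOOR = 1e-300


@dataclass
class LiabilityFit:
    """Liability-scale variance-component fit for a binary trait.

    ``beta`` rows are on the liability scale with positive = higher risk
    (unless the fit was run with ``flip_signs``).
    """

    h2: float
    se_h2: float
    threshold: float
    beta: pd.DataFrame
    loglik: float
    p_h2: float
    converged: bool
    ascertainment_corrected: bool
    n: int
    prevalence: float  # implied population prevalence at covariate means
    sign_flipped: bool = False


def family_binary_loglik(
    affected: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    h2: float,
    kin_block: np.ndarray,
    threshold: float,
    maxpts: int = 20000,
    size_cap: int = 60,
) -> float:
    """Log rectangle probability of one family's affection pattern.

    ``kin_block`` is the family's ``2Phi`` block.  Liability covariance is
    ``2Phi*h2 + I*(1-h2)``; member ``i`` contributes the orthant
    ``liability > threshold`` when affected, its complement otherwise.
    """
    aff = np.asarray(affected, bool)
    m = len(aff)
    if not (0 <= h2 <= 1):
        raise ValueError("h2 must be in [0, 1]")
    mu = np.asarray(X, float) @ np.asarray(beta, float) if np.size(beta) else np.zeros(m)
    z = threshold - mu  # affected: liability - mu > z
    if h2 == 0.0 or m == 1:  # factorizes; no integration, no size cap
        logp = np.where(aff, stats.norm.logsf(z), stats.norm.logcdf(z))
        return float(logp.sum())
    if m > size_cap:
        raise ValueError(
            f"family of {m} exceeds the integration size cap {size_cap}; "
            "raise size_cap (and maxpts) to integrate larger families"
        )
    cov = h2 * np.asarray(kin_block, float) + (1 - h2) * np.eye(m)
    lower = np.where(aff, z, -np.inf)
    upper = np.where(aff, np.inf, z)
    p = _mvn.cdf(
        upper,
        mean=np.zeros(m),
        cov=cov,
        lower_limit=lower,
        maxpts=maxpts,
        rng=np.random.default_rng(_QMC_SEED),
    )
    return float(np.log(max(float(p), _LOG_FLOOR)))


class _BinaryData:
    def __init__(self, aff, X, kin: KinshipMatrix, proband_pos, maxpts, size_cap):
        self.blocks = []
        self.maxpts = maxpts
        self.size_cap = size_cap
        for fam, idx in kin.family_blocks().items():
            pb = proband_pos.get(fam) if proband_pos is not None else None
            local_pb = None
            if pb is not None:
                local = np.flatnonzero(idx == pb)
                local_pb = int(local[0]) if local.size else None
            self.blocks.append(
                (aff[idx], X[idx], kin.values[np.ix_(idx, idx)], local_pb)
            )

    def loglik(self, threshold, h2, beta, correct):
        ll = 0.0
        for aff, X, K, pb in self.blocks:
            ll += family_binary_loglik(
                aff, X, beta, h2, K, threshold,
                maxpts=self.maxpts, size_cap=self.size_cap,
            )
            if correct:
                if pb is None:
                    raise ValueError("ascertainment correction needs a proband per family")
                mu_p = float(X[pb] @ beta) if np.size(beta) else 0.0
                z = threshold - mu_p
                lp = stats.norm.logsf(z) if aff[pb] else stats.norm.logcdf(z)
                ll -= float(lp)
        return ll


def fit_liability(
    ped: Pedigree,
    affection: pd.Series,
    covariates: Optional[pd.DataFrame] = None,
    covariate_names: Optional[Sequence[str]] = None,
    probands: Optional[Mapping[str, str]] = None,
    correct_ascertainment: bool = False,
    kin: Optional[KinshipMatrix] = None,
    maxpts: int = 20000,
    size_cap: int = 60,
    compute_se: bool = True,
    flip_signs: bool = False,
    fix_h2: float | None = None,
    xatol: float = 1e-4,
    fatol: float = 1e-5,
) -> LiabilityFit:
    """ML liability-scale heritability for a 0/1 disease trait.

    With ``correct_ascertainment`` each family's likelihood is conditioned on
    its proband's observed status; probands are taken from ``probands``
    (family id -> individual id) or from the pedigree's proband flags.
    The LRT p-value for ``h2`` uses the half-chi-square boundary mixture.
    ``fix_h2`` pins the heritability (e.g. 0 for a plain probit regression)
    instead of estimating it.
    """
    aff_s = affection.dropna()
    ids = [i for i in ped.ids if i in aff_s.index]
    if len(ids) < 3:
        raise ValueError("too few individuals with affection status")
    aff = aff_s.loc[ids].to_numpy()
    if not set(np.unique(aff)) <= {0, 1}:
        raise ValueError("affection must be coded 0/1")
    if aff.min() == aff.max():
        raise ValueError("no variation in affection status")
    aff = aff.astype(bool)

    kin = kin if kin is not None else kinship_matrix(ped)
    kin_s = kin.submatrix(ids)

    if covariates is not None and covariate_names:
        X, labels = design_matrix(covariates.loc[ids], covariate_names,
                                  add_intercept=False)
    else:
        X, labels = np.empty((len(ids), 0)), []

    proband_pos = None
    if correct_ascertainment:
        if probands is None:
            probands = {
                ind.family_id: ind.id for ind in ped.individuals if ind.proband
            }
        if not probands:
            raise ValueError(
                "ascertainment correction requested but no probands flagged"
            )
        idx_of = {iid: k for k, iid in enumerate(ids)}
        proband_pos = {}
        for fam in {ped[i].family_id for i in ids}:
            pid = probands.get(fam)
            if pid is None or pid not in idx_of:
                raise ValueError(f"family {fam!r} lacks a phenotyped proband")
            proband_pos[fam] = idx_of[pid]

    data = _BinaryData(aff, X, kin_s, proband_pos, maxpts, size_cap)
    p_obs = float(aff.mean())
    t0 = stats.norm.ppf(1 - min(max(p_obs, 0.01), 0.99))
    p = X.shape[1]

    if fix_h2 is not None:
        def negf(theta):
            return -data.loglik(theta[0], fix_h2, theta[1:], correct_ascertainment)

        # at h2 = 0 the likelihood factorizes and is smooth: a quasi-Newton
        # polish brings the probit limit to full precision
        method = "BFGS" if fix_h2 == 0.0 else "Nelder-Mead"
        opts = ({"gtol": 1e-10, "maxiter": 500} if fix_h2 == 0.0 else
                {"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000, "maxfev": 8000})
        res = optimize.minimize(
            negf, np.concatenate([[t0], np.zeros(p)]), method=method,
            options=opts,
        )
        t_hat, h2_hat = float(res.x[0]), float(fix_h2)
        beta_hat = res.x[1:]
        ll = -float(res.fun)
    else:
        def neg(theta):
            t, h2 = theta[0], theta[1]
            if not (0 <= h2 <= 0.999):
                return 1e10
            return -data.loglik(t, h2, theta[2:], correct_ascertainment)

        x0 = np.concatenate([[t0, 0.5], np.zeros(p)])
        bounds = [(None, None), (0.0, 0.999)] + [(None, None)] * p
        res = optimize.minimize(
            neg, x0, method="Nelder-Mead", bounds=bounds,
            options={"xatol": xatol, "fatol": fatol, "maxiter": 2000,
                     "maxfev": 4000},
        )
        t_hat, h2_hat = float(res.x[0]), float(res.x[1])
        beta_hat = res.x[2:]
        ll = -float(res.fun)

    # null fit (h2 = 0): the likelihood factorizes into probit terms
    def neg0(theta):
        return -data.loglik(theta[0], 0.0, theta[1:], correct_ascertainment)

    res0 = optimize.minimize(
        neg0, np.concatenate([[t0], np.zeros(p)]), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    ll0 = -float(res0.fun)
    if fix_h2 is None and ll0 > ll:  # h2=0 is the global optimum; adopt it
        t_hat, h2_hat, beta_hat, ll = float(res0.x[0]), 0.0, res0.x[1:], ll0
    p_h2 = lrt_boundary(min(ll0, ll), ll, 1) if fix_h2 is None else np.nan

    se_h2 = np.nan
    se_b = np.full(p, np.nan)
    if compute_se:
        se_h2, se_b = _liability_se(data, t_hat, h2_hat, beta_hat,
                                    correct_ascertainment)

    sign = -1.0 if flip_signs else 1.0
    beta_df = pd.DataFrame(
        {
            "beta": sign * beta_hat,
            "se": se_b,
            "p": 2 * stats.norm.sf(np.abs(beta_hat) / np.where(se_b > 0, se_b, np.inf)),
        },
        index=labels,
    )
    return LiabilityFit(
        h2=h2_hat,
        se_h2=float(se_h2),
        threshold=t_hat,
        beta=beta_df,
        loglik=ll,
        p_h2=float(p_h2),
        converged=bool(res.success),
        ascertainment_corrected=bool(correct_ascertainment),
        n=len(ids),
        prevalence=float(stats.norm.sf(t_hat)),
        sign_flipped=flip_signs,
    )


def _liability_se(data, t, h2, beta, correct):
    """Observed-information SEs; steps sized for the QMC likelihood noise."""
    theta0 = np.concatenate([[t, h2], beta])
    k = len(theta0)
    steps = np.full(k, 0.02)
    steps[1] = min(0.04, max(0.01, min(h2, 0.999 - h2))) if 0 < h2 < 0.999 else 0.04

    def ll(theta):
        h = min(max(theta[1], 0.0), 0.999)
        return data.loglik(theta[0], h, theta[2:], correct)

    H = np.zeros((k, k))
    f0 = ll(theta0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                H[i, i] = (ll(theta0 + ei) - 2 * f0 + ll(theta0 - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    ll(theta0 + ei + ej) - ll(theta0 + ei - ej)
                    - ll(theta0 - ei + ej) + ll(theta0 - ei - ej)
                ) / (4 * steps[i] * steps[j])
    cov = np.linalg.pinv(-H)
    d = np.sqrt(np.clip(np.diag(cov), 0, None))
    return d[1], d[2:]
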