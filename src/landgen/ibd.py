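"""Isolation-by-distance analyses on pairwise distance matrices.

Provides geographic distance matrices, Mantel tests, and the GLS model with a
maximum-likelihood-population-effects (MLPE) correlation structure for
regressions of genetic distance on a predictor distance:

    Y_ij = alpha + beta (X_ij - xbar) + H_i [+ H_i (X_ij - xbar)] + tau_ij + e_ij

where pairs sharing a population are correlated through a population-level
random effect tau (incidence structure Z Z'), and H is an optional ecotope
stratum term. The variance ratio gamma = sigma_u^2 / sigma_e^2 is profiled by
a golden-section search on the log scale; fixed effects are solved by GLS at
each candidate; all fits are plain maximum likelihood (not REML) so that
log-likelihoods are comparable across fixed-effect structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, norm

from .datatypes import AnalysisError, ConfigurationError, DistanceMatrix
from .rng import substream

__all__ = [
    "geographic_distances",
    "mantel_test",
    "pair_table",
    "fit_mlpe",
    "slope_contrast",
    "MLPEFit",
]


def geographic_distances(sites: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances (km) between site coordinates given in metres.

    `sites` must have columns site_id, x, y (projected metres).
    """
    if sites[["x", "y"]].isna().any().any():
        raise ConfigurationError("missing site coordinates")
    labels = [str(s) for s in sites["site_id"]]
    xy = sites[["x", "y"]].to_numpy(dtype=float)
    km = squareform(pdist(xy)) / 1000.0
    return DistanceMatrix(labels, km, kind="geographic_km")


def mantel_test(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> dict:
    """Mantel test: Pearson r over lower triangles, permutation p.

    The null permutes rows and columns of `dm_b` jointly;
    p = (b + 1)/(n_perm + 1), one-sided ("greater") by default.
    """
    if dm_a.n < 4:
        raise AnalysisError("Mantel test needs at least 4 labels")
    dm_b = dm_a.align(dm_b)
    x, y = dm_a.condensed(), dm_b.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r_m": float("nan"), "p": float("nan"),
                "note": "constant matrix: correlation undefined"}
    r = float(np.corrcoef(x, y)[0, 1])
    rng = substream(seed, "mantel")
    n = dm_a.n
    tril = np.tril_indices(n, -1)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = np.corrcoef(x, dm_b.values[np.ix_(perm, perm)][tril])[0, 1]
        if alternative == "greater":
            hit = rp >= r - 1e-15
        elif alternative == "less":
            hit = rp <= r + 1e-15
        else:
            hit = abs(rp) >= abs(r) - 1e-15
        b += int(hit)
    return {"r_m": r, "p": (b + 1) / (n_perm + 1), "n_perm": n_perm}


def pair_table(
    genetic: DistanceMatrix,
    predictor: DistanceMatrix,
    strata: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Unordered-pair table for MLPE fitting.

    Columns: group_i, group_j, y (genetic), x (predictor), stratum. When
    `strata` maps group -> ecotope, only pairs whose two groups share a
    stratum are retained (cross-stratum pairs have no H label in the model).
    """
    predictor = genetic.align(predictor)
    rows = []
    for i in range(1, genetic.n):
        for j in range(i):
            a, b = genetic.labels[i], genetic.labels[j]
            st = ""
            if strata is not None:
                sa, sb = strata[a], strata[b]
                if sa != sb:
                    continue
                st = sa
            rows.append(
                {
                    "group_i": a,
                    "group_j": b,
                    "y": genetic.values[i, j],
                    "x": predictor.values[i, j],
                    "stratum": st,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MLPEFit:
    """Fitted MLPE regression.

    coef/se are indexed by term name; `rho` is the correlation between two
    pairs sharing one population, rho = gamma / (2 gamma + 1) in (0, 0.5);
    `k` counts fixed-effect coefficients (incl. intercept).
    """

    coef: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    rho: float
    gamma: float
    sigma2_e: float
    sigma2_u: float
    loglik: float
    k: int
    n_pairs: int
    n_groups: int
    terms: list[str] = field(default_factory=list)
    xbar: float = 0.0

    def summary(self) -> dict:
        return {
            "coef": self.coef.to_dict(),
            "se": self.se.to_dict(),
            "rho": self.rho,
            "sigma2_e": self.sigma2_e,
            "sigma2_u": self.sigma2_u,
            "logLik": self.loglik,
            "k": self.k,
            "n_pairs": self.n_pairs,
            "n_groups": self.n_groups,
            "xbar": self.xbar,
        }


def _design(pairs: pd.DataFrame, stratum_effect: bool, interaction: bool):
    x = pairs["x"].to_numpy(dtype=float)
    xbar = float(x.mean())
    xc = x - xbar
    cols = {"intercept": np.ones(len(pairs)), "x_centred": xc}
    if stratum_effect or interaction:
        strata = sorted(set(pairs["stratum"]))
        if len(strata) < 2:
            raise AnalysisError("stratum term requested but only one stratum present")
        ref = strata[0]
        for s in strata[1:]:
            ind = (pairs["stratum"] == s).to_numpy(dtype=float)
            cols[f"stratum[{s}]"] = ind
            if interaction:
                cols[f"x_centred:stratum[{s}]"] = ind * xc
    W = np.column_stack(list(cols.values()))
    return W, list(cols.keys()), xbar


def _incidence(pairs: pd.DataFrame) -> tuple[np.ndarray, int]:
    labels = pd.unique(pd.concat([pairs["group_i"], pairs["group_j"]]))
    index = {lab: i for i, lab in enumerate(labels)}
    Z = np.zeros((len(pairs), len(labels)))
    for r, (a, b) in enumerate(zip(pairs["group_i"], pairs["group_j"])):
        Z[r, index[a]] = 1.0
        Z[r, index[b]] = 1.0
    return Z, len(labels)


def _profile_loglik(gamma: float, y, W, ZZt, m):
    """ML log-likelihood with sigma_e^2 profiled out, at variance ratio gamma."""
    sigma = np.eye(m) + gamma * ZZt
    c, low = cho_factor(sigma, lower=True)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    si_y = cho_solve((c, low), y)
    si_W = cho_solve((c, low), W)
    wtw = W.T @ si_W
    theta = np.linalg.solve(wtw, W.T @ si_y)
    resid = y - W @ theta
    rss = float(resid @ cho_solve((c, low), resid))
    s2 = rss / m
    ll = -0.5 * (m * np.log(2.0 * np.pi * s2) + logdet + m)
    return ll, theta, s2, wtw, (c, low)


def fit_mlpe(
    pairs: pd.DataFrame,
    stratum_effect: bool = False,
    interaction: bool = False,
    gamma_bounds: tuple[float, float] = (1e-8, 1e3),
    tol: float = 1e-8,
) -> MLPEFit:
    """Maximum-likelihood MLPE fit of y on centred x over population pairs.

    The covariance is Sigma = sigma_e^2 I + sigma_u^2 Z Z' with Z the
    pair-population incidence matrix. gamma = sigma_u^2/sigma_e^2 is profiled
    by golden-section search on log(gamma) within `gamma_bounds` (gamma = 0 is
    also evaluated, so the fit reduces exactly to OLS when the data carry no
    population effect).
    """
    if len(pairs) < 3:
        raise AnalysisError("need at least 3 pairs")
    y = pairs["y"].to_numpy(dtype=float)
    W, terms, xbar = _design(pairs, stratum_effect, interaction)
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise AnalysisError("singular design matrix (check strata and x values)")
    Z, n_groups = _incidence(pairs)
    if n_groups < 4:
        raise AnalysisError("need pairs over at least 4 groups")
    ZZt = Z @ Z.T
    m = len(y)

    def obj(loggamma: float) -> float:
        return -_profile_loglik(np.exp(loggamma), y, W, ZZt, m)[0]

    lo, hi = np.log(gamma_bounds[0]), np.log(gamma_bounds[1])
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c1 = b - invphi * (b - a)
    c2 = a + invphi * (b - a)
    f1, f2 = obj(c1), obj(c2)
    while b - a > tol:
        if f1 < f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - invphi * (b - a)
            f1 = obj(c1)
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + invphi * (b - a)
            f2 = obj(c2)
    gamma = float(np.exp(0.5 * (a + b)))
    ll, theta, s2, wtw, _ = _profile_loglik(gamma, y, W, ZZt, m)
    ll0, theta0, s20, wtw0, _ = _profile_loglik(0.0, y, W, ZZt, m)
    if ll0 >= ll:
        gamma, ll, theta, s2, wtw = 0.0, ll0, theta0, s20, wtw0
    cov = s2 * np.linalg.inv(wtw)
    se = np.sqrt(np.diag(cov))
    rho = gamma / (2.0 * gamma + 1.0)
    return MLPEFit(
        coef=pd.Series(theta, index=terms),
        se=pd.Series(se, index=terms),
        cov=pd.DataFrame(cov, index=terms, columns=terms),
        rho=float(rho),
        gamma=gamma,
        sigma2_e=float(s2),
        sigma2_u=float(gamma * s2),
        loglik=float(ll),
        k=len(terms),
        n_pairs=m,
        n_groups=n_groups,
        terms=terms,
        xbar=xbar,
    )


def slope_contrast(fit: MLPEFit, reduced: MLPEFit | None = None) -> dict:
    """Test of the stratum difference in distance slopes.

    Wald test on the x:stratum interaction coefficient; when a no-interaction
    `reduced` fit is supplied, a likelihood-ratio test (1 df) is added.
    """
    inter = [t for t in fit.terms if t.startswith("x_centred:stratum")]
    if not inter:
        raise AnalysisError("fit has no x:stratum interaction term")
    term = inter[0]
    est = float(fit.coef[term])
    se = float(fit.se[term])
    z = est / se
    out = {
        "delta_beta": est,
        "se": se,
        "z": z,
        "p_wald": float(2.0 * norm.sf(abs(z))),
    }
    if reduced is not None:
        lrt = 2.0 * (fit.loglik - reduced.loglik)
        out["lrt"] = float(lrt)
        out["p_lrt"] = float(chi2.sf(max(lrt, 0.0), df=len(inter)))
    return out
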