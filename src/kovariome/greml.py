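"""GREML: genetic relationship matrix, REML variance components, and the
analytic power formula.

The mixed model is ``y = X beta + g + e`` with ``g ~ N(0, A sigma_g^2)``
for the genetic relationship matrix (GRM) ``A`` and
``e ~ N(0, I sigma_e^2)``; narrow-sense heritability is
``h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)``.  The bivariate extension
adds a genetic covariance ``sigma_g12`` (and residual covariance
``sigma_e12``) and defines the genetic correlation
``rG = sigma_g12 / sqrt(sigma_g1^2 sigma_g2^2)``.

REML is maximized on the eigenbasis of the GRM: after rotating trait and
design by the eigenvectors, the covariance is diagonal (univariate) or
2x2-block-diagonal (bivariate), so each likelihood evaluation is O(n).
The eigendecomposition is computed once per GRM and cached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import MISSING, GenotypeMatrix

_VAR_FLOOR = 1e-8


@dataclass
class GRM:
    """Genetic relationship matrix with cached eigendecomposition.

    ``A[j, k] = (1/M) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``
    over the M retained variants with alternate AF ``p_i``; with missing
    calls the per-pair divisor is the number of variants observed in both
    samples.
    """

    A: np.ndarray
    M: int
    af: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    _eig: tuple[np.ndarray, np.ndarray] | None = None

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.A)
            self._eig = (np.maximum(vals, 0.0), vecs)
        return self._eig


def build_grm(genotypes: GenotypeMatrix, maf_min: float = 0.01) -> GRM:
    """Standardized-genotype GRM over variants with MAF >= ``maf_min``.

    Monomorphic variants (AF 0 or 1) are excluded.  Missing dosages are
    skipped with the per-pair variant count adjusted accordingly.
    """
    af = genotypes.alt_allele_frequency()
    maf = np.minimum(af, 1 - af)
    use = np.isfinite(af) & (af > 0) & (af < 1) & (maf >= maf_min)
    if use.sum() == 0:
        raise ValueError("no variants usable for the GRM")
    d = genotypes.dosages[:, use].astype(np.float64)
    p = af[use]
    called = d != MISSING
    w = (d - 2 * p[None, :]) / np.sqrt(2 * p * (1 - p))[None, :]
    w[~called] = 0.0
    counts = called.astype(np.float64) @ called.T.astype(np.float64)
    a = (w @ w.T) / np.maximum(counts, 1.0)
    return GRM(A=a, M=int(use.sum()), af=p, sample_ids=list(genotypes.sample_ids))


# ---------------------------------------------------------------------------
# univariate REML
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    h2: float
    sigma_g2: float
    sigma_e2: float
    se: float
    ci95: tuple[float, float]
    significant: bool
    loglik: float
    converged: bool
    at_boundary: bool


def _reml_loglik_uni(
    theta: np.ndarray, lam: np.ndarray, yt: np.ndarray, xt: np.ndarray
) -> float:
    sg, se_ = theta
    v = lam * sg + se_
    if np.any(v <= 0):
        return -np.inf
    vinv = 1.0 / v
    xtvx = xt.T @ (xt * vinv[:, None])
    sign, logdet_xvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf
    xtvy = xt.T @ (yt * vinv)
    ypy = float(yt @ (yt * vinv) - xtvy @ np.linalg.solve(xtvx, xtvy))
    return -0.5 * (float(np.sum(np.log(v))) + logdet_xvx + ypy)


def _uni_expected_information(
    sg: float, se_: float, lam: np.ndarray, xt: np.ndarray
) -> np.ndarray:
    """Expected (Fisher) information of (sigma_g2, sigma_e2) under REML.

    Uses the projection matrix ``P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1``
    on the GRM eigenbasis, where all traces reduce to weighted sums and
    small p x p products::

        I = 0.5 * [[tr(PAPA), tr(PAP)], [tr(PAP), tr(PP)]]
    """
    v = lam * sg + se_
    u = 1.0 / v
    a = lam

    def m(s: np.ndarray) -> np.ndarray:
        return xt.T @ (xt * s[:, None])

    b = np.linalg.inv(m(u))
    m_u2a = m(u**2 * a)
    m_u2 = m(u**2)
    tr_papa = (
        float(np.sum(u**2 * a**2))
        - 2 * float(np.trace(b @ m(u**3 * a**2)))
        + float(np.trace(b @ m_u2a @ b @ m_u2a))
    )
    tr_pap = (
        float(np.sum(u**2 * a))
        - 2 * float(np.trace(b @ m(u**3 * a)))
        + float(np.trace(b @ m_u2a @ b @ m_u2))
    )
    tr_pp = (
        float(np.sum(u**2))
        - 2 * float(np.trace(b @ m(u**3)))
        + float(np.trace(b @ m_u2 @ b @ m_u2))
    )
    return 0.5 * np.array([[tr_papa, tr_pap], [tr_pap, tr_pp]])


def reml_h2(
    grm: GRM,
    trait: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> HeritabilityEstimate:
    """REML fit of the single-trait GRM model; h2 with SE and 95% CI.

    Variance components are constrained nonnegative by bounded
    optimization; when the genetic component lands on the zero boundary
    the SE comes from the unconstrained information matrix and the
    estimate is flagged ``at_boundary``.  The CI is the Wald interval
    ``h2 +/- 1.96 SE`` truncated to [0, 1]; ``significant`` means its
    lower bound is positive.
    """
    y = np.asarray(trait, dtype=float)
    n = len(y)
    if n != grm.A.shape[0]:
        raise ValueError("trait length does not match GRM")
    x = np.ones((n, 1))
    if covariates is not None:
        c = np.asarray(pd.DataFrame(covariates), dtype=float)
        x = np.column_stack([x, c])
    ok = ~np.isnan(y)
    if x.shape[1] > 1:
        ok &= ~np.isnan(x).any(axis=1)
    if ok.sum() < x.shape[1] + 10:
        raise ValueError("too few complete observations for REML")
    if not ok.all():
        # restrict GRM to complete cases; eigen cache does not apply
        a = grm.A[np.ix_(ok, ok)]
        lam, u = np.linalg.eigh(a)
        lam = np.maximum(lam, 0.0)
        y, x = y[ok], x[ok]
    else:
        lam, u = grm.eigen()
    yt = u.T @ y
    xt = u.T @ x

    vy = float(np.var(y, ddof=1))
    obj = lambda t: -_reml_loglik_uni(t, lam, yt, xt)
    best = None
    for frac in (0.5, 0.1, 0.9):
        res = optimize.minimize(
            obj,
            x0=np.array([vy * frac, vy * (1 - frac)]),
            method="L-BFGS-B",
            bounds=[(_VAR_FLOOR * vy, None), (_VAR_FLOOR * vy, None)],
        )
        if best is None or res.fun < best.fun:
            best = res
    sg, se_ = best.x
    ll = -best.fun
    h2 = sg / (sg + se_)
    at_boundary = sg <= 2 * _VAR_FLOOR * vy

    # SE from the analytic expected information (evaluated at the optimum,
    # which is the unconstrained point unless a component hit the boundary)
    info = _uni_expected_information(sg, se_, lam, xt)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    grad = np.array([se_, -sg]) / (sg + se_) ** 2
    h2_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    lo = max(0.0, h2 - 1.96 * h2_se)
    hi = min(1.0, h2 + 1.96 * h2_se)
    return HeritabilityEstimate(
        h2=float(np.clip(h2, 0.0, 1.0)),
        sigma_g2=float(sg),
        sigma_e2=float(se_),
        se=h2_se,
        ci95=(lo, hi),
        significant=lo > 0,
        loglik=float(ll),
        converged=bool(best.success),
        at_boundary=bool(at_boundary),
    )


def _numeric_cov(obj, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Inverse numerical Hessian of ``obj`` (the negative log-likelihood)."""
    k = len(x0)
    h = np.maximum(np.abs(x0) * rel_step, 1e-10)
    hess = np.empty((k, k))
    f0 = obj(x0)
    for i in range(k):
        for j in range(i, k):
            xpp = x0.copy(); xpp[i] += h[i]; xpp[j] += h[j]
            xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
            xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
            xmm = x0.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
            if i == j:
                hess[i, i] = (obj(x0 + np.eye(k)[i] * h[i]) - 2 * f0 +
                              obj(x0 - np.eye(k)[i] * h[i])) / h[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    obj(xpp) - obj(xpm) - obj(xmp) + obj(xmm)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return cov


# ---------------------------------------------------------------------------
# bivariate REML / genetic correlation
# ---------------------------------------------------------------------------

@dataclass
class GeneticCorrelationEstimate:
    rg: float
    se: float
    p_lrt: float
    sigma: dict
    loglik: float
    converged: bool
    excluded: bool = False
    reason: str = ""


def _reml_loglik_biv(
    theta: np.ndarray,
    lam: np.ndarray,
    y1: np.ndarray,
    y2: np.ndarray,
    xt: np.ndarray,
) -> float:
    g11, g22, g12, e11, e22, e12 = theta
    c11 = lam * g11 + e11
    c22 = lam * g22 + e22
    c12 = lam * g12 + e12
    det = c11 * c22 - c12**2
    if np.any(det <= 0) or np.any(c11 <= 0):
        return -np.inf
    i11 = c22 / det
    i22 = c11 / det
    i12 = -c12 / det
    p = xt.shape[1]
    a11 = xt.T @ (xt * i11[:, None])
    a22 = xt.T @ (xt * i22[:, None])
    a12 = xt.T @ (xt * i12[:, None])
    a = np.block([[a11, a12], [a12, a22]])
    b = np.concatenate([xt.T @ (i11 * y1 + i12 * y2), xt.T @ (i12 * y1 + i22 * y2)])
    sign, logdet_a = np.linalg.slogdet(a)
    if sign <= 0:
        return -np.inf
    yvy = float(np.sum(i11 * y1**2 + 2 * i12 * y1 * y2 + i22 * y2**2))
    ypy = yvy - float(b @ np.linalg.solve(a, b))
    return -0.5 * (float(np.sum(np.log(det))) + logdet_a + ypy)


def bivariate_rg(
    grm: GRM,
    trait1: np.ndarray | pd.Series,
    trait2: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> GeneticCorrelationEstimate:
    """Bivariate REML genetic correlation with a likelihood-ratio test.

    Fits the six-component model (two genetic variances, genetic
    covariance, two residual variances, residual covariance) by
    Nelder-Mead on the GRM eigenbasis, then refits with the genetic
    covariance pinned to zero; ``p_lrt`` is the chi-square(1) upper tail
    of twice the log-likelihood difference.  Non-convergence yields an
    excluded-with-reason record rather than a silent NA.
    """
    y1 = np.asarray(trait1, dtype=float)
    y2 = np.asarray(trait2, dtype=float)
    n = grm.A.shape[0]
    if len(y1) != n or len(y2) != n:
        raise ValueError("trait length does not match GRM")
    x = np.ones((n, 1))
    if covariates is not None:
        x = np.column_stack([x, np.asarray(pd.DataFrame(covariates), dtype=float)])
    ok = ~np.isnan(y1) & ~np.isnan(y2) & ~np.isnan(x).any(axis=1)
    if not ok.all():
        a = grm.A[np.ix_(ok, ok)]
        lam, u = np.linalg.eigh(a)
        lam = np.maximum(lam, 0.0)
        y1, y2, x = y1[ok], y2[ok], x[ok]
    else:
        lam, u = grm.eigen()
    y1t, y2t, xt = u.T @ y1, u.T @ y2, u.T @ x

    v1, v2 = np.var(y1, ddof=1), np.var(y2, ddof=1)
    c12 = float(np.cov(y1, y2)[0, 1])

    def obj(t):
        ll = _reml_loglik_biv(t, lam, y1t, y2t, xt)
        return 1e12 if not np.isfinite(ll) else -ll

    x0 = np.array([0.5 * v1, 0.5 * v2, 0.5 * c12, 0.5 * v1, 0.5 * v2, 0.5 * c12])
    res = optimize.minimize(
        obj, x0, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8, "adaptive": True},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        return GeneticCorrelationEstimate(
            rg=np.nan, se=np.nan, p_lrt=np.nan, sigma={}, loglik=np.nan,
            converged=False, excluded=True, reason="log-likelihood did not converge",
        )
    g11, g22, g12, e11, e22, e12 = res.x
    g11, g22 = max(g11, _VAR_FLOOR * v1), max(g22, _VAR_FLOOR * v2)
    rg = float(np.clip(g12 / np.sqrt(g11 * g22), -1.0, 1.0))
    ll_full = -res.fun

    def obj0(t5):
        t = np.array([t5[0], t5[1], 0.0, t5[2], t5[3], t5[4]])
        return obj(t)

    res0 = optimize.minimize(
        obj0, np.array([0.5 * v1, 0.5 * v2, 0.5 * v1, 0.5 * v2, 0.5 * c12]),
        method="Nelder-Mead",
        options={"maxiter": 3000, "xatol": 1e-8, "fatol": 1e-8, "adaptive": True},
    )
    ll_null = -res0.fun if np.isfinite(res0.fun) and res0.fun < 1e11 else -np.inf
    lrt = max(0.0, 2 * (ll_full - ll_null))
    p_lrt = float(stats.chi2.sf(lrt, df=1))

    cov = _numeric_cov(obj, res.x)
    # delta method for rg = g12 / sqrt(g11 g22)
    grad = np.zeros(6)
    s = np.sqrt(g11 * g22)
    grad[0] = -0.5 * g12 / (s * g11)
    grad[1] = -0.5 * g12 / (s * g22)
    grad[2] = 1.0 / s
    rg_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    return GeneticCorrelationEstimate(
        rg=rg,
        se=rg_se,
        p_lrt=p_lrt,
        sigma={"g11": g11, "g22": g22, "g12": g12,
               "e11": e11, "e22": e22, "e12": e12},
        loglik=float(ll_full),
        converged=bool(res.success or res.fun < 1e11),
    )


# ---------------------------------------------------------------------------
# analytic power
# ---------------------------------------------------------------------------

def greml_power(
    n: int, h2: float, var_a: float = 2e-5, alpha: float = 0.05
) -> float:
    """Analytic GREML detection power.

    ``SE(h2) = sqrt(2 / (n^2 var_a))`` with ``var_a`` the variance of the
    GRM off-diagonal elements (default 2e-5, typical for conventionally
    unrelated samples), and ``power = Phi(h2 / SE - z_{1 - alpha/2})``
    for a two-sided test at level ``alpha``.
    """
    if n <= 0 or var_a <= 0:
        raise ValueError("n and var_a must be positive")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    se = np.sqrt(2.0 / (n**2 * var_a))
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(h2 / se - z_crit))
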