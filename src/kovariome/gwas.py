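"""Covariate-adjusted whole-genome-wide association (WGWAS).

Per-variant additive-model regression of a trait on alternate-allele
dosage with fixed covariates (sex, age, age^2, BMI, top principal
components), genomic-inflation diagnostics (lambda_median), greedy LD
clumping of summary statistics, and Benjamini-Hochberg FDR control.

Linear models are solved by least squares; the fast path residualizes
trait and dosages against the covariates once (Frisch-Waugh-Lovell) and
is exact for variants with no missing dosage in the analyzed subsample.
Variants with missing calls fall back to per-variant complete-case OLS.
Binary traits use logistic regression fitted by IRLS with a 25-iteration
cap and separation detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import MISSING, GenotypeMatrix, standardized_dosages
from .qc import hwe_exact_many

CHI2_1_NULL_MEDIAN = 0.4549364231195724  # median of chi-square with 1 df

SIGNIFICANT_P = 5e-8
SUGGESTIVE_P = 1e-5


@dataclass
class CovariateSpec:
    """Covariate columns for the association model.

    ``age_squared`` is derived from ``age`` when requested.  ``exclusions``
    maps trait name -> covariate columns to drop for that trait (e.g. BMI
    is never a covariate in the association scan of BMI itself or of
    BMI-derived traits).
    """

    columns: list[str] = field(
        default_factory=lambda: ["sex", "age", "age2", "bmi"]
    )
    n_pcs: int = 0
    exclusions: dict[str, list[str]] = field(default_factory=dict)

    def columns_for(self, trait: str) -> list[str]:
        drop = set(self.exclusions.get(trait, []))
        cols = [c for c in self.columns if c not in drop]
        cols += [f"pc{i + 1}" for i in range(self.n_pcs)]
        return cols


def build_covariates(
    traits: pd.DataFrame,
    spec: CovariateSpec,
    trait: str,
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Covariate design frame for one trait (no intercept column)."""
    cols = spec.columns_for(trait)
    out = pd.DataFrame(index=traits.index)
    for c in cols:
        if c == "age2":
            out["age2"] = traits["age"] ** 2
        elif c.startswith("pc"):
            k = int(c[2:]) - 1
            if pcs is None:
                raise ValueError("PC covariates requested but no scores provided")
            out[c] = pcs[:, k]
        else:
            out[c] = traits[c]
    return out


def prefilter_variants(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    max_missing: float = 0.01,
) -> np.ndarray:
    """Association prefilter keep mask: MAF, HWE exact P, missing rate."""
    maf_ok = genotypes.minor_allele_frequency() >= maf_min
    miss_ok = genotypes.variant_missing_rate() <= max_missing
    hwe_ok = hwe_exact_many(genotypes.genotype_counts()) >= hwe_p_min
    return maf_ok & miss_ok & hwe_ok


def _check_collinear(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(f"collinear covariate columns among {names}")


def _linear_scan(
    dosages: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> pd.DataFrame:
    """Exact per-variant OLS via residualization; NaN dosages handled
    per-variant with complete-case refits."""
    n = len(y)
    x0 = np.column_stack([np.ones(n), covariates])
    p0 = x0.shape[1]
    q, _ = np.linalg.qr(x0)

    def residualize(v: np.ndarray) -> np.ndarray:
        return v - q @ (q.T @ v)

    y_r = residualize(y)
    m = dosages.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    stat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    nvec = np.zeros(m, dtype=int)

    has_missing = np.isnan(dosages).any(axis=0)
    complete = ~has_missing
    if complete.any():
        g = dosages[:, complete]
        g_r = g - q @ (q.T @ g)
        gg = (g_r**2).sum(axis=0)
        ok = gg > 1e-12
        gy = g_r.T @ y_r
        b = np.where(ok, gy / np.where(ok, gg, 1.0), np.nan)
        df = n - p0 - 1
        rss = (y_r**2).sum() - b**2 * gg
        sigma2 = np.maximum(rss, 0.0) / df
        s = np.sqrt(np.where(ok, sigma2 / np.where(ok, gg, 1.0), np.nan))
        t = b / s
        idx = np.flatnonzero(complete)
        beta[idx] = np.where(ok, b, np.nan)
        se[idx] = np.where(ok, s, np.nan)
        stat[idx] = np.where(ok, t, np.nan)
        pval[idx] = np.where(ok, 2 * stats.t.sf(np.abs(t), df), np.nan)
        nvec[idx] = n

    for j in np.flatnonzero(has_missing):
        g = dosages[:, j]
        use = ~np.isnan(g)
        nn = int(use.sum())
        if nn <= p0 + 1 or np.nanstd(g[use]) == 0:
            continue
        x = np.column_stack([x0[use], g[use]])
        yy = y[use]
        coef, _, rank, _ = np.linalg.lstsq(x, yy, rcond=None)
        if rank < x.shape[1]:
            continue
        resid = yy - x @ coef
        df = nn - x.shape[1]
        sigma2 = resid @ resid / df
        xtx_inv = np.linalg.inv(x.T @ x)
        s = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
        beta[j] = coef[-1]
        se[j] = s
        stat[j] = coef[-1] / s
        pval[j] = 2 * stats.t.sf(abs(stat[j]), df)
        nvec[j] = nn
    return pd.DataFrame(
        {"beta": beta, "se": se, "stat": stat, "p": pval, "n": nvec}
    )


def _logistic_fit(
    x: np.ndarray, y: np.ndarray, max_iter: int = 25, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS logistic regression; returns (coef, se, separated_flag)."""
    n, p = x.shape
    coef = np.zeros(p)
    separated = False
    for _ in range(max_iter):
        eta = np.clip(x @ coef, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        if w.max() < 1e-10:
            separated = True
            break
        z = eta + (y - mu) / np.maximum(w, 1e-10)
        wx = x * w[:, None]
        xtwx = x.T @ wx
        try:
            new = np.linalg.solve(xtwx, x.T @ (w * z))
        except np.linalg.LinAlgError:
            separated = True
            break
        if np.max(np.abs(new - coef)) < tol:
            coef = new
            break
        coef = new
    if np.max(np.abs(coef)) > 15:
        separated = True
    eta = np.clip(x @ coef, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1 - mu), 1e-12)
    cov = np.linalg.inv(x.T @ (x * w[:, None]))
    return coef, np.sqrt(np.diag(cov)), separated


def run_gwas(
    genotypes: GenotypeMatrix,
    trait_values: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    model: str = "linear",
    trait_name: str = "trait",
) -> pd.DataFrame:
    """Per-variant association scan.

    Samples missing the trait or any covariate are dropped globally;
    samples missing a genotype are dropped per variant (complete-case).
    Returns a frame keyed by variant with ``beta``, ``se``, ``stat``,
    ``p``, ``n`` (monomorphic-in-subsample variants yield NA rows).
    """
    y = np.asarray(trait_values, dtype=float)
    if covariates is None:
        cov = np.empty((len(y), 0))
        cov_names: list[str] = []
    else:
        cov_frame = pd.DataFrame(covariates)
        cov_names = [str(c) for c in cov_frame.columns]
        cov = cov_frame.to_numpy(dtype=float)
    use = ~np.isnan(y)
    if cov.shape[1]:
        use &= ~np.isnan(cov).any(axis=1)
    n_use = int(use.sum())
    if n_use < cov.shape[1] + 10:
        raise ValueError("too few non-missing samples for association")
    y = y[use]
    cov = cov[use]
    if cov.shape[1]:
        _check_collinear(np.column_stack([np.ones(len(y)), cov]), ["intercept"] + cov_names)

    d = genotypes.dosages[use].astype(float)
    d[d == MISSING] = np.nan

    if model == "linear":
        res = _linear_scan(d, y, cov)
    elif model == "logistic":
        vals = set(np.unique(y))
        if not vals <= {0.0, 1.0}:
            raise ValueError("logistic model requires a 0/1 trait")
        n = len(y)
        x0 = np.column_stack([np.ones(n), cov])
        m = d.shape[1]
        out = {k: np.full(m, np.nan) for k in ("beta", "se", "stat", "p")}
        nvec = np.zeros(m, dtype=int)
        for j in range(m):
            g = d[:, j]
            usej = ~np.isnan(g)
            nn = int(usej.sum())
            if nn <= x0.shape[1] + 1 or np.nanstd(g[usej]) == 0:
                continue
            x = np.column_stack([x0[usej], g[usej]])
            coef, ses, separated = _logistic_fit(x, y[usej])
            if separated:
                continue
            out["beta"][j] = coef[-1]
            out["se"][j] = ses[-1]
            out["stat"][j] = coef[-1] / ses[-1]
            out["p"][j] = 2 * stats.norm.sf(abs(out["stat"][j]))
            nvec[j] = nn
        res = pd.DataFrame({**out, "n": nvec})
    else:
        raise ValueError(f"unknown model {model!r}")

    res.insert(0, "key", genotypes.keys)
    res["trait"] = trait_name
    res["model"] = model
    # P of exactly 0 is floored at the smallest positive float (P in (0,1])
    tiny = np.nextafter(0, 1)
    res["p"] = res["p"].clip(lower=tiny)
    return res


def genomic_lambda(p_values: np.ndarray | pd.Series) -> float:
    """Genomic inflation factor: median association chi-square over the
    null chi-square(1 df) median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_NULL_MEDIAN)


def ld_clump(
    summary: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
    p1: float = 1.0,
    p2: float = 1.0,
) -> pd.DataFrame:
    """Greedy index-first LD clumping of summary statistics.

    Variants are visited by ascending P; each unassigned variant with
    P <= ``p1`` becomes a clump index and absorbs all unassigned variants
    with P <= ``p2`` within ``window_kb`` kilobases (same chromosome)
    whose squared dosage correlation with the index exceeds
    ``r2_threshold``.  Every variant ends up in exactly one clump (or
    alone if it never exceeds the thresholds).
    """
    keys = genotypes.keys
    order = summary.set_index("key").loc[keys]
    p = order["p"].to_numpy(dtype=float)
    z = standardized_dosages(genotypes)
    n = z.shape[0]
    chrom = genotypes.variant_meta["chrom"].to_numpy()
    pos = genotypes.variant_meta["pos"].to_numpy()
    window = window_kb * 1000.0

    assigned = np.zeros(len(keys), dtype=bool)
    rows = []
    for j in np.argsort(p, kind="stable"):
        if assigned[j] or not p[j] <= p1:
            continue
        assigned[j] = True
        members = [j]
        cand = np.flatnonzero(
            (~assigned)
            & (chrom == chrom[j])
            & (np.abs(pos - pos[j]) <= window)
            & (p <= p2)
        )
        if len(cand):
            r = (z[:, cand].T @ z[:, j]) / n
            hit = cand[r**2 > r2_threshold]
            assigned[hit] = True
            members.extend(hit.tolist())
        rows.append(
            {
                "index_key": keys[j],
                "index_p": p[j],
                "n_members": len(members),
                "members": ",".join(keys[k] for k in sorted(members)),
            }
        )
    # leftovers (above p1) become singleton clumps so the partition is total
    for j in np.flatnonzero(~assigned):
        rows.append(
            {
                "index_key": keys[j],
                "index_p": p[j],
                "n_members": 1,
                "members": keys[j],
            }
        )
    return pd.DataFrame(rows, columns=["index_key", "index_p", "n_members", "members"])


def bh_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
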