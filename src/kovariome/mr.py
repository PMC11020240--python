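"""Consensus two-sample Mendelian randomization.

Instruments are variants suggestively associated with the exposure trait
(P < 1e-5 by default), thinned to one per LD block by clumping.  Three
estimators of the causal effect gamma of exposure on outcome are run per
trait pair:

* IVW — inverse-variance-weighted regression of outcome effects on
  exposure effects through the origin, weights ``1 / se_y^2``;
* MR-Egger — the same regression with an intercept; the intercept tests
  directional pleiotropy, the slope is the causal estimate;
* MR-PRESSO — a residual-sum-of-squares global heterogeneity test with
  parametric resampling, per-instrument outlier detection, and IVW
  re-estimation after outlier removal.

A pair's causal call is a *consensus*: BH FDR is applied within each
method across all tested pairs, and the pair is consensus-significant
when at least 2 of the 3 methods pass FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GenotypeMatrix
from .gwas import SUGGESTIVE_P, bh_fdr, ld_clump


@dataclass
class MRMethodResult:
    estimate: float
    se: float
    p: float


@dataclass
class MRPair:
    """All-method MR output for one ordered exposure -> outcome pair."""

    exposure: str
    outcome: str
    n_instruments: int
    ivw: MRMethodResult | None = None
    egger: MRMethodResult | None = None
    presso: MRMethodResult | None = None
    egger_intercept: float = np.nan
    egger_intercept_p: float = np.nan
    presso_global_p: float = np.nan
    presso_outliers: list[str] = field(default_factory=list)
    skipped: bool = False
    reason: str = ""


def select_instruments(
    exposure_stats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    p_threshold: float = SUGGESTIVE_P,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
    min_instruments: int = 3,
) -> list[str]:
    """Independent suggestive variants for the exposure.

    Suggestive variants are clumped (r2 > ``r2_threshold`` within
    ``window_kb``); the smallest-P variant of each block is kept.  Returns
    an empty list (caller records a skip) when fewer than
    ``min_instruments`` remain.
    """
    sugg = exposure_stats[exposure_stats["p"] < p_threshold]
    if len(sugg) == 0:
        return []
    keys = set(sugg["key"])
    keep = genotypes.keys.isin(keys)
    sub = genotypes.take_variants(np.asarray(keep))
    clumps = ld_clump(
        sugg, sub, r2_threshold=r2_threshold, window_kb=window_kb
    )
    instruments = sorted(clumps["index_key"])
    return instruments if len(instruments) >= min_instruments else []


def mr_ivw(
    beta_x: np.ndarray, se_x: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray
) -> MRMethodResult:
    """Inverse-variance-weighted slope through the origin.

    With one instrument this reduces to the Wald ratio
    ``beta_y / beta_x``.  P is from the Wald z statistic.
    """
    beta_x = np.asarray(beta_x, float)
    beta_y = np.asarray(beta_y, float)
    se_y = np.asarray(se_y, float)
    if len(beta_x) < 1:
        raise ValueError("IVW needs at least one instrument")
    if np.all(beta_x == 0):
        raise ValueError("all exposure effects are zero; slope undefined")
    if len(beta_x) == 1:
        est = float(beta_y[0] / beta_x[0])
        se = float(abs(se_y[0] / beta_x[0]))
    else:
        w = 1.0 / se_y**2
        denom = float(np.sum(w * beta_x**2))
        est = float(np.sum(w * beta_x * beta_y) / denom)
        se = float(np.sqrt(1.0 / denom))
    se = max(se, np.finfo(float).tiny)
    z = est / se
    return MRMethodResult(est, se, float(2 * stats.norm.sf(abs(z))))


def mr_egger(
    beta_x: np.ndarray, se_x: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray
) -> tuple[MRMethodResult, float, float]:
    """Weighted regression with intercept; returns (slope result,
    intercept, intercept P).

    Instrument effects are sign-aligned so every ``beta_x`` is positive
    before fitting (the orientation convention Egger regression assumes).
    Inference uses t statistics on k - 2 degrees of freedom.
    """
    beta_x = np.asarray(beta_x, float).copy()
    beta_y = np.asarray(beta_y, float).copy()
    se_y = np.asarray(se_y, float)
    k = len(beta_x)
    if k < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    flip = np.sign(beta_x)
    flip[flip == 0] = 1.0
    bx, by = beta_x * flip, beta_y * flip
    w = 1.0 / se_y**2
    x = np.column_stack([np.ones(k), bx])
    xtwx = x.T @ (x * w[:, None])
    coef = np.linalg.solve(xtwx, x.T @ (w * by))
    resid = by - x @ coef
    df = k - 2
    s2 = float(np.sum(w * resid**2) / df)
    s2 = max(s2, 1.0)  # multiplicative random-effects floor
    cov = s2 * np.linalg.inv(xtwx)
    slope_se = float(np.sqrt(cov[1, 1]))
    int_se = float(np.sqrt(cov[0, 0]))
    slope_p = float(2 * stats.t.sf(abs(coef[1] / slope_se), df))
    int_p = float(2 * stats.t.sf(abs(coef[0] / int_se), df))
    return (
        MRMethodResult(float(coef[1]), slope_se, slope_p),
        float(coef[0]),
        int_p,
    )


def mr_presso(
    beta_x: np.ndarray,
    se_x: np.ndarray,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    nb_distribution: int = 10000,
    signif_threshold: float = 0.05,
    seed: int = 0,
    instrument_ids: list[str] | None = None,
) -> tuple[list[str], MRMethodResult, float]:
    """RSS-based global heterogeneity test and outlier removal.

    The observed statistic is the leave-one-out weighted residual sum of
    squares of the IVW fit; its null distribution comes from
    ``nb_distribution`` parametric resamples of the outcome effects around
    the fitted model.  Per-instrument outliers are instruments whose
    observed squared residual is extreme against its own simulated
    distribution (Bonferroni-adjusted at ``signif_threshold``).  Outliers
    are removed and IVW re-run; with no outliers the plain IVW estimate is
    returned.
    """
    beta_x = np.asarray(beta_x, float)
    beta_y = np.asarray(beta_y, float)
    se_y = np.asarray(se_y, float)
    k = len(beta_x)
    if k < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    ids = instrument_ids if instrument_ids is not None else [str(i) for i in range(k)]
    rng = np.random.default_rng(seed)
    w = 1.0 / se_y**2

    # leave-one-out slopes
    sw_xy = np.sum(w * beta_x * beta_y)
    sw_xx = np.sum(w * beta_x**2)
    loo_slope = (sw_xy - w * beta_x * beta_y) / (sw_xx - w * beta_x**2)
    obs_resid2 = w * (beta_y - loo_slope * beta_x) ** 2
    obs_rss = float(np.sum(obs_resid2))

    # parametric null: simulate outcome effects around the LOO fit
    sims = rng.normal(
        loc=loo_slope[None, :] * beta_x[None, :],
        scale=se_y[None, :],
        size=(nb_distribution, k),
    )
    sim_resid2 = w[None, :] * (sims - loo_slope[None, :] * beta_x[None, :]) ** 2
    sim_rss = sim_resid2.sum(axis=1)
    global_p = float((np.sum(sim_rss >= obs_rss) + 1) / (nb_distribution + 1))

    outliers: list[int] = []
    if global_p < signif_threshold:
        per_p = (np.sum(sim_resid2 >= obs_resid2[None, :], axis=0) + 1) / (
            nb_distribution + 1
        )
        outliers = [i for i in range(k) if per_p[i] < signif_threshold / k]
    keep = [i for i in range(k) if i not in outliers]
    if len(keep) < 2:
        raise ValueError("too few instruments remain after outlier removal")
    est = mr_ivw(beta_x[keep], se_x[keep] if se_x is not None else None,
                 beta_y[keep], se_y[keep])
    return [ids[i] for i in outliers], est, global_p


def run_mr_pair(
    exposure: str,
    outcome: str,
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    p_threshold: float = SUGGESTIVE_P,
    nb_distribution: int = 10000,
    signif_threshold: float = 0.05,
    seed: int = 0,
) -> MRPair:
    """Select instruments and run all three MR methods for one pair."""
    instruments = select_instruments(
        exposure_stats, genotypes, p_threshold=p_threshold
    )
    if not instruments:
        return MRPair(exposure, outcome, 0, skipped=True,
                      reason="fewer than 3 independent suggestive instruments")
    ex = exposure_stats.set_index("key").loc[instruments]
    ou = outcome_stats.set_index("key")
    instruments = [k for k in instruments if k in ou.index]
    if len(instruments) < 3:
        return MRPair(exposure, outcome, len(instruments), skipped=True,
                      reason="instruments missing from outcome statistics")
    ex = ex.loc[instruments]
    ou = ou.loc[instruments]
    bx, sx = ex["beta"].to_numpy(), ex["se"].to_numpy()
    by, sy = ou["beta"].to_numpy(), ou["se"].to_numpy()
    ok = np.isfinite(bx) & np.isfinite(by) & (sy > 0)
    bx, sx, by, sy = bx[ok], sx[ok], by[ok], sy[ok]
    ids = [k for k, o in zip(instruments, ok) if o]
    if len(bx) < 3:
        return MRPair(exposure, outcome, len(bx), skipped=True,
                      reason="fewer than 3 instruments with finite effects")

    pair = MRPair(exposure, outcome, len(bx))
    pair.ivw = mr_ivw(bx, sx, by, sy)
    egger, intercept, intercept_p = mr_egger(bx, sx, by, sy)
    pair.egger = egger
    pair.egger_intercept = intercept
    pair.egger_intercept_p = intercept_p
    if len(bx) >= 4:
        try:
            outliers, presso_est, global_p = mr_presso(
                bx, sx, by, sy,
                nb_distribution=nb_distribution,
                signif_threshold=signif_threshold,
                seed=seed,
                instrument_ids=ids,
            )
            pair.presso = presso_est
            pair.presso_global_p = global_p
            pair.presso_outliers = outliers
        except ValueError as exc:
            pair.reason = f"MR-PRESSO unavailable: {exc}"
    else:
        pair.reason = "MR-PRESSO needs at least 4 instruments"
    return pair


def consensus_mr(pairs: list[MRPair], fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Consensus causal calls and directionality across tested pairs.

    BH FDR is applied within each method across all non-skipped pairs;
    ``consensus_significant`` requires FDR < ``fdr_threshold`` in at least
    2 of the 3 methods.  When both orientations of a trait pair were
    tested, consensus pairs are labeled ``unidirectional`` or
    ``bidirectional`` accordingly.
    """
    rows = []
    for pr in pairs:
        rows.append(
            {
                "exposure": pr.exposure,
                "outcome": pr.outcome,
                "n_instruments": pr.n_instruments,
                "skipped": pr.skipped,
                "reason": pr.reason,
                "ivw_estimate": pr.ivw.estimate if pr.ivw else np.nan,
                "ivw_p": pr.ivw.p if pr.ivw else np.nan,
                "egger_estimate": pr.egger.estimate if pr.egger else np.nan,
                "egger_p": pr.egger.p if pr.egger else np.nan,
                "egger_intercept": pr.egger_intercept,
                "egger_intercept_p": pr.egger_intercept_p,
                "presso_estimate": pr.presso.estimate if pr.presso else np.nan,
                "presso_p": pr.presso.p if pr.presso else np.nan,
                "presso_global_p": pr.presso_global_p,
                "presso_outliers": ",".join(pr.presso_outliers),
            }
        )
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    for method in ("ivw", "egger", "presso"):
        out[f"{method}_fdr"] = bh_fdr(out[f"{method}_p"])
        out[f"{method}_significant"] = (out[f"{method}_fdr"] < fdr_threshold).fillna(
            False
        )
    n_sig = (
        out[["ivw_significant", "egger_significant", "presso_significant"]]
        .sum(axis=1)
        .astype(int)
    )
    out["n_methods_significant"] = n_sig
    out["consensus_significant"] = ~out["skipped"] & (n_sig >= 2)

    directed = {
        (r["exposure"], r["outcome"]): bool(r["consensus_significant"])
        for _, r in out.iterrows()
    }
    direction = []
    for _, r in out.iterrows():
        fwd = directed.get((r["exposure"], r["outcome"]), False)
        rev = directed.get((r["outcome"], r["exposure"]), False)
        if fwd and rev:
            direction.append("bidirectional")
        elif fwd:
            direction.append("unidirectional")
        else:
            direction.append("")
    out["direction"] = direction
    return out
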