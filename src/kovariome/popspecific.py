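"""Population-specific variant detection by chi-square allele-count tests.

A target-cohort variant is called population-specific when a 2x2 Pearson
chi-square test of its allele counts (alt/ref x population) is significant
against *every* reference population in a panel, at a stringent alpha
(default 5e-5).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def chi2_allele_test(
    ac1: np.ndarray, an1: np.ndarray, ac2: np.ndarray, an2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson chi-square on the 2x2 allele-count table, 1 df, no continuity
    correction.

    Rows are populations, columns alt/ref allele counts.  A zero margin
    (both populations monomorphic for the same allele) yields chi2 = 0,
    P = 1 by convention.  Accepts scalars or arrays.
    """
    ac1 = np.asarray(ac1, dtype=float)
    an1 = np.asarray(an1, dtype=float)
    ac2 = np.asarray(ac2, dtype=float)
    an2 = np.asarray(an2, dtype=float)
    if np.any(an1 <= 0) or np.any(an2 <= 0):
        raise ValueError("allele numbers must be positive")
    if np.any(ac1 > an1) or np.any(ac2 > an2) or np.any(ac1 < 0) or np.any(ac2 < 0):
        raise ValueError("require 0 <= ac <= an")
    a, b = ac1, an1 - ac1
    c, d = ac2, an2 - ac2
    n = an1 + an2
    margin = (a + c) * (b + d) * an1 * an2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(margin > 0, n * (a * d - b * c) ** 2 / np.where(margin > 0, margin, 1), 0.0)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(margin > 0, p, 1.0)
    if chi2.ndim == 0:
        return float(chi2), float(p)
    return chi2, p


def find_specific_variants(
    target: pd.DataFrame,
    references: dict[str, pd.DataFrame],
    alpha: float = 5e-5,
) -> pd.DataFrame:
    """Variants significant against every reference population.

    Each table has columns ``key``, ``alt_count``, ``total_count``.  A
    variant missing from any reference table is not testable and is
    excluded (conservative).  Returns per-variant per-population P values
    plus the ``specific`` flag.
    """
    for name, ref in references.items():
        odd = ref["total_count"] % 2 != 0
        if odd.any():
            warnings.warn(
                f"reference {name!r} has odd total allele counts", stacklevel=2
            )
    out = target[["key", "alt_count", "total_count"]].copy()
    testable = np.ones(len(out), dtype=bool)
    for name, ref in references.items():
        merged = out.merge(
            ref[["key", "alt_count", "total_count"]],
            on="key",
            how="left",
            suffixes=("", f"_{name}"),
        )
        present = merged[f"total_count_{name}"].notna().to_numpy()
        testable &= present
        p = np.full(len(out), np.nan)
        if present.any():
            _, p_sub = chi2_allele_test(
                merged.loc[present, "alt_count"].to_numpy(),
                merged.loc[present, "total_count"].to_numpy(),
                merged.loc[present, f"alt_count_{name}"].to_numpy(),
                merged.loc[present, f"total_count_{name}"].to_numpy(),
            )
            p[present] = np.atleast_1d(p_sub)
        out[f"p_{name}"] = p
    pcols = [f"p_{name}" for name in references]
    pmat = out[pcols].to_numpy()
    with np.errstate(invalid="ignore"):
        all_sig = np.all(pmat < alpha, axis=1)
    out["testable"] = testable
    out["specific"] = testable & all_sig
    if not testable.any():
        warnings.warn("no variants shared across all reference tables", stacklevel=2)
    return out
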