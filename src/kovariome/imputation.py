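"""Imputation-accuracy evaluation.

Accuracy is the squared Pearson correlation (R^2) between true genotypes
(0/1/2) and imputed dosages ([0, 2]) per variant, aggregated as the mean
R^2 within alternate-allele-frequency bins of the evaluation panel.  A
pooled-correlation aggregation mode (one correlation over all calls in the
bin) is available behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_BIN_EDGES = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.5)


def per_variant_r2(
    true_genotypes: np.ndarray, dosages: np.ndarray
) -> np.ndarray:
    """Squared Pearson correlation per variant (columns).

    Variants with a constant true genotype or constant dosage have an
    undefined correlation and come back NaN (they are counted but excluded
    from aggregation).
    """
    g = np.asarray(true_genotypes, dtype=float)
    d = np.asarray(dosages, dtype=float)
    if g.shape != d.shape:
        raise ValueError("genotype and dosage arrays must have the same shape")
    if g.ndim == 1:
        g = g[:, None]
        d = d[:, None]
    if g.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    gc = g - g.mean(axis=0)
    dc = d - d.mean(axis=0)
    num = (gc * dc).sum(axis=0)
    den = np.sqrt((gc**2).sum(axis=0) * (dc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return r**2


def aggregate_by_af(
    r2: np.ndarray,
    panel_af: np.ndarray,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    overlap_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean per-variant R^2 within alternate-AF bins.

    ``bin_edges`` are interior edges; bins are ``(0, e1], (e1, e2], ...,
    (ek, 1)``.  ``overlap_mask`` restricts to variants present in both
    panels when comparing two imputation panels.  Empty bins report NaN
    with a zero count; variants with undefined R^2 are excluded from the
    mean but tallied in ``n_undefined``.
    """
    r2 = np.asarray(r2, dtype=float)
    af = np.asarray(panel_af, dtype=float)
    if np.any((af <= 0) | (af >= 1)):
        raise ValueError("panel_af must lie strictly inside (0, 1)")
    if overlap_mask is not None:
        r2 = r2[overlap_mask]
        af = af[overlap_mask]
    edges = np.concatenate([[0.0], np.asarray(bin_edges, float), [1.0]])
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing inside (0, 1)")
    idx = np.searchsorted(edges, af, side="left") - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        vals = r2[sel]
        defined = vals[np.isfinite(vals)]
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n_variants": int(sel.sum()),
                "n_undefined": int(sel.sum() - len(defined)),
                "mean_r2": float(defined.mean()) if len(defined) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def pooled_r2_by_af(
    true_genotypes: np.ndarray,
    dosages: np.ndarray,
    panel_af: np.ndarray,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Alternative aggregation: one pooled correlation over all calls in a
    bin rather than the mean of per-variant R^2."""
    g = np.asarray(true_genotypes, dtype=float)
    d = np.asarray(dosages, dtype=float)
    af = np.asarray(panel_af, dtype=float)
    edges = np.concatenate([[0.0], np.asarray(bin_edges, float), [1.0]])
    idx = np.searchsorted(edges, af, side="left") - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() == 0:
            rows.append({"bin_low": edges[b], "bin_high": edges[b + 1],
                         "n_variants": 0, "pooled_r2": np.nan})
            continue
        gs = g[:, sel].ravel()
        ds = d[:, sel].ravel()
        if gs.std() == 0 or ds.std() == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(gs, ds)[0, 1] ** 2)
        rows.append({"bin_low": edges[b], "bin_high": edges[b + 1],
                     "n_variants": int(sel.sum()), "pooled_r2": r2})
    return pd.DataFrame(rows)
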