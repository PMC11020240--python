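"""Trait-level phenomics: trait screening, phenotypic correlation, and
pleiotropy via the Variant-Sharing Index (VSI).

The VSI between two traits is the Jaccard index of their
suggestive-association variant sets, reported on the percentage scale::

    VSI(i, j) = 100 * |S_i & S_j| / |S_i | S_j|

where ``S_t`` is the set of variants with association P below the
suggestive threshold (default 1e-5) for trait ``t``.  VSI = 0 means the
traits share no suggestive variants; 100 means the sets coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import SUGGESTIVE_P, bh_fdr


# ---------------------------------------------------------------------------
# trait screening
# ---------------------------------------------------------------------------

def filter_traits(
    table: pd.DataFrame,
    trait_cols: list[str] | None = None,
    max_missing: float = 0.90,
    min_minority_fraction: float = 0.20,
    id_col: str = "sample_id",
    time_col: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Screen traits and deduplicate repeated measurements.

    Drops quantitative traits missing in more than ``max_missing`` of
    samples and binary traits whose minority class holds less than
    ``min_minority_fraction`` of observations (class imbalance worse than
    1:4 at the default).  When ``time_col`` is given and a sample has
    several records, the most recent one is kept.

    Returns the (deduplicated) table and the list of retained trait
    columns.
    """
    if time_col is not None and table.duplicated(id_col).any():
        table = (
            table.sort_values(time_col)
            .drop_duplicates(id_col, keep="last")
            .sort_index()
            .reset_index(drop=True)
        )
    if trait_cols is None:
        reserved = {id_col, time_col, "sex", "age", "bmi"}
        trait_cols = [c for c in table.columns if c not in reserved]
    kept = []
    for col in trait_cols:
        vals = table[col]
        if vals.notna().mean() < 1.0 - max_missing:
            continue
        obs = vals.dropna()
        uniq = set(obs.unique())
        if uniq <= {0, 1, 0.0, 1.0} and len(uniq) <= 2:
            if len(uniq) < 2:
                continue
            minority = obs.value_counts(normalize=True).min()
            if minority < min_minority_fraction:
                continue
        kept.append(col)
    return table, kept


# ---------------------------------------------------------------------------
# phenotypic correlation
# ---------------------------------------------------------------------------

def phenotypic_correlation(
    table: pd.DataFrame,
    trait_cols: list[str],
    min_pairs: int = 10,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations with Fisher-z CIs and BH FDR.

    A pair is ``significant`` when its BH FDR is below ``fdr_threshold``
    and its 95% CI excludes zero.  Pairs with fewer than ``min_pairs``
    complete observations, or with a constant trait, come back as NA.
    """
    rows = []
    for a, b in combinations(trait_cols, 2):
        sub = table[[a, b]].dropna()
        n = len(sub)
        r = p = lo = hi = np.nan
        if n >= min_pairs and sub[a].std() > 0 and sub[b].std() > 0:
            r, p = stats.pearsonr(sub[a], sub[b])
            if abs(r) < 1.0:
                z = np.arctanh(r)
                zse = 1.0 / np.sqrt(n - 3)
                lo, hi = np.tanh(z - 1.96 * zse), np.tanh(z + 1.96 * zse)
            else:
                lo = hi = r
        rows.append(
            {"trait_i": a, "trait_j": b, "r": r, "n": n, "p": p,
             "ci_low": lo, "ci_high": hi}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"])
    out["significant"] = (
        (out["fdr"] < fdr_threshold) & ((out["ci_low"] > 0) | (out["ci_high"] < 0))
    ).fillna(False)
    return out


# ---------------------------------------------------------------------------
# pleiotropy / VSI
# ---------------------------------------------------------------------------

@dataclass
class VSIRecord:
    """Shared suggestive-variant accounting for one trait pair."""

    trait_i: str
    trait_j: str
    s_i: int
    s_j: int
    shared: int
    total: int
    vsi: float


def compute_vsi(s_i: int, s_j: int, shared: int,
                trait_i: str = "", trait_j: str = "") -> VSIRecord:
    """VSI from set sizes: total = |S_i| + |S_j| - shared (union identity),
    VSI = 100 * shared / total rounded to one decimal."""
    if shared > min(s_i, s_j):
        raise ValueError("shared cannot exceed either set size")
    total = s_i + s_j - shared
    if total == 0:
        raise ValueError("VSI undefined: both variant sets are empty")
    vsi = round(100.0 * shared / total, 1)
    return VSIRecord(trait_i, trait_j, s_i, s_j, shared, total, vsi)


def detect_pleiotropy(
    stats_by_trait: dict[str, pd.DataFrame],
    p_threshold: float = SUGGESTIVE_P,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Suggestive-variant sharing across traits.

    ``stats_by_trait`` maps trait name -> summary-statistics frame with
    ``key`` and ``p`` columns.  Returns (pleiotropic variant table with the
    traits each variant hits, VSI records for every pair sharing at least
    one variant).
    """
    if len(stats_by_trait) < 2:
        raise ValueError("pleiotropy needs at least 2 traits")
    sets = {
        t: set(df.loc[df["p"] < p_threshold, "key"])
        for t, df in stats_by_trait.items()
    }
    hit_count: dict[str, list[str]] = {}
    for t, s in sets.items():
        for key in s:
            hit_count.setdefault(key, []).append(t)
    pleio = pd.DataFrame(
        [
            {"key": k, "n_traits": len(ts), "traits": ",".join(sorted(ts))}
            for k, ts in sorted(hit_count.items())
            if len(ts) >= 2
        ],
        columns=["key", "n_traits", "traits"],
    )
    records = []
    for a, b in combinations(sorted(sets), 2):
        shared = len(sets[a] & sets[b])
        if shared == 0:
            continue
        rec = compute_vsi(len(sets[a]), len(sets[b]), shared, a, b)
        records.append(rec.__dict__)
    vsi = pd.DataFrame(
        records,
        columns=["trait_i", "trait_j", "s_i", "s_j", "shared", "total", "vsi"],
    )
    return pleio, vsi
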