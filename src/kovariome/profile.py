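"""Allele-frequency profiling: AF categories, novelty, saturation curves.

Polymorphic variants partition into six categories by alternate allele
count (AC) and frequency (AF):

=============  =========================================
singleton      AC = 1
doubleton      AC = 2
very_rare      AC > 2 and AF <= 0.001
rare           0.001 < AF <= 0.01
common         0.01 < AF <= 0.05
very_common    AF > 0.05
=============  =========================================

Saturation curves count, for random orderings of the samples, how many
distinct variants of each (full-cohort) category are carried by the first
k samples; the per-category sample count at which the curve first reaches
the category total measures how close the cohort is to exhausting that
frequency class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix

AF_CATEGORIES = [
    "singleton",
    "doubleton",
    "very_rare",
    "rare",
    "common",
    "very_common",
]


def classify_af(ac: np.ndarray, an: np.ndarray) -> np.ndarray:
    """Category label per variant from alternate allele count / number.

    Frequencies are alternate-allele frequencies (AC/AN); the boundary
    values 0.001, 0.01 and 0.05 belong to the lower category (``<=`` in
    each rule above).  Monomorphic variants (AC = 0 or AC = AN) get the
    empty label ``""`` and are excluded from category counts.
    """
    ac = np.asarray(ac)
    an = np.asarray(an)
    if np.any(ac < 0) or np.any(ac > an):
        raise ValueError("require 0 <= ac <= an")
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(an > 0, ac / an, np.nan)
    out = np.full(ac.shape, "", dtype=object)
    poly = (ac > 0) & (ac < an)
    out[poly & (ac == 1)] = "singleton"
    out[poly & (ac == 2)] = "doubleton"
    out[poly & (ac > 2) & (af <= 0.001)] = "very_rare"
    out[poly & (ac > 2) & (af > 0.001) & (af <= 0.01)] = "rare"
    out[poly & (ac > 2) & (af > 0.01) & (af <= 0.05)] = "common"
    out[poly & (ac > 2) & (af > 0.05)] = "very_common"
    return out


def profile_variants(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant AC, AN, AF and category table."""
    ac, an = genotypes.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(an > 0, ac / an, np.nan)
    return pd.DataFrame(
        {
            "key": genotypes.keys,
            "ac": ac,
            "an": an,
            "af": af,
            "category": classify_af(ac, an),
        }
    )


def annotate_novelty(
    variants: pd.DataFrame, known_sites: set[str] | pd.Index
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag variants present in a known-sites list; summarize per category.

    ``known_sites`` holds canonical ``chrom:pos:ref:alt`` keys; matching is
    exact.  Returns the annotated per-variant table and a per-category
    summary with the fraction known.
    """
    known = set(known_sites)
    annotated = variants.copy()
    annotated["known"] = annotated["key"].isin(known)
    poly = annotated[annotated["category"] != ""]
    summary = (
        poly.groupby("category", sort=False)
        .agg(n=("known", "size"), n_known=("known", "sum"))
        .reindex([c for c in AF_CATEGORIES if c in set(poly["category"])])
        .reset_index()
    )
    summary["fraction_known"] = summary["n_known"] / summary["n"]
    return annotated, summary


@dataclass
class SaturationCurve:
    """Averaged discovery curves and per-category saturation points.

    ``curves`` maps category -> mean cumulative distinct-variant count at
    each k (length n_samples); ``n_saturate`` maps category -> median (over
    permutations) of the smallest k at which the curve reaches the
    category total.
    """

    curves: dict[str, np.ndarray]
    n_saturate: dict[str, float]
    per_permutation_n_saturate: dict[str, np.ndarray]
    category_totals: dict[str, int]
    n_permutations: int
    seed: int


def saturation_curve(
    genotypes: GenotypeMatrix,
    categories: np.ndarray | None = None,
    n_permutations: int = 10,
    seed: int = 0,
) -> SaturationCurve:
    """Variant-discovery saturation by category.

    Category membership is fixed from the full cohort.  A variant is
    "discovered" at the first position (in a random sample ordering) of a
    sample carrying at least one alternate allele.  Curves are averaged
    over ``n_permutations`` random orderings.
    """
    if categories is None:
        ac, an = genotypes.allele_counts()
        categories = classify_af(ac, an)
    categories = np.asarray(categories, dtype=object)
    carrier = genotypes.dosages > 0  # (n, m); missing (-1) is non-carrier
    n = genotypes.n_samples
    rng = np.random.default_rng(seed)

    cats = [c for c in AF_CATEGORIES if (categories == c).any()]
    totals = {c: int(((categories == c) & carrier.any(axis=0)).sum()) for c in cats}
    sums = {c: np.zeros(n) for c in cats}
    n_sat = {c: [] for c in cats}
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        cperm = carrier[perm]
        any_carrier = cperm.any(axis=0)
        # first permuted sample carrying each variant (argmax finds first True)
        first = np.argmax(cperm, axis=0)
        for c in cats:
            mask = (categories == c) & any_carrier
            counts = np.bincount(first[mask], minlength=n)
            cum = np.cumsum(counts)
            sums[c] += cum
            reach = np.flatnonzero(cum >= totals[c])
            n_sat[c].append(int(reach[0]) + 1 if len(reach) else n)
    curves = {c: sums[c] / n_permutations for c in cats}
    return SaturationCurve(
        curves=curves,
        n_saturate={c: float(np.median(n_sat[c])) for c in cats},
        per_permutation_n_saturate={c: np.array(n_sat[c]) for c in cats},
        category_totals=totals,
        n_permutations=n_permutations,
        seed=seed,
    )
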