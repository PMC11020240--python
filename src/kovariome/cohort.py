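"""Core in-memory containers shared by every pipeline stage.

The backbone object is :class:`GenotypeMatrix`, a samples x variants dosage
matrix holding alternate-allele counts 0/1/2 with ``-1`` as the missing
sentinel, plus a per-variant metadata frame (chrom, pos, ref, alt, id).
Phenotypes travel as a plain :class:`pandas.DataFrame` (one row per sample,
``NA`` for missing) wrapped only by convention, not by a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

VARIANT_KEY_COLS = ["chrom", "pos", "ref", "alt"]


def variant_keys(meta: pd.DataFrame) -> pd.Index:
    """Canonical ``chrom:pos:ref:alt`` string key per variant."""
    return pd.Index(
        meta["chrom"].astype(str)
        + ":"
        + meta["pos"].astype(str)
        + ":"
        + meta["ref"].astype(str)
        + ":"
        + meta["alt"].astype(str)
    )


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` integer array with values in
        ``{0, 1, 2, MISSING}``.
    variant_meta
        Frame with columns ``chrom`` (label), ``pos`` (1-based), ``ref``,
        ``alt`` and optionally ``id``; one row per variant, no duplicate
        (chrom, pos, ref, alt) keys.
    sample_ids
        Sample labels, one per dosage row.
    """

    dosages: np.ndarray
    variant_meta: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.variant_meta) != m:
            raise ValueError("variant_meta length != number of variant columns")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:05d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length != number of sample rows")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages contain values outside {0,1,2,missing}")
        if (self.variant_meta["pos"] < 1).any():
            raise ValueError("variant positions must be 1-based (>= 1)")
        if self.variant_meta.duplicated(VARIANT_KEY_COLS).any():
            raise ValueError("duplicate (chrom,pos,ref,alt) variant keys")
        self.variant_meta = self.variant_meta.reset_index(drop=True)

    # -- basic shape -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def keys(self) -> pd.Index:
        return variant_keys(self.variant_meta)

    # -- per-variant summaries --------------------------------------------
    def called_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(alternate allele count AC, total called allele number AN)."""
        called = self.called_mask()
        d = np.where(called, self.dosages, 0)
        ac = d.sum(axis=0)
        an = 2 * called.sum(axis=0)
        return ac, an

    def alt_allele_frequency(self) -> np.ndarray:
        ac, an = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, ac / an, np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        af = self.alt_allele_frequency()
        return np.minimum(af, 1.0 - af)

    def variant_missing_rate(self) -> np.ndarray:
        return 1.0 - self.called_mask().mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return 1.0 - self.called_mask().mean(axis=1)

    def genotype_counts(self) -> np.ndarray:
        """(n_variants, 3) counts of genotypes 0/1/2 over called samples."""
        out = np.empty((self.n_variants, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.dosages == g).sum(axis=0)
        return out

    # -- slicing -----------------------------------------------------------
    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.variant_meta.iloc[index].reset_index(drop=True),
            list(self.sample_ids),
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[index, :],
            self.variant_meta.copy(),
            [self.sample_ids[i] for i in index],
        )

    def select_samples(self, ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.take_samples([pos[s] for s in ids])


def standardized_dosages(
    genotypes: GenotypeMatrix, impute_missing: bool = True
) -> np.ndarray:
    """Mean-imputed, column-standardized dosage matrix (float64).

    Columns with zero variance come back as all-zero rather than NaN so
    downstream covariance computations stay finite.
    """
    d = genotypes.dosages.astype(float)
    called = genotypes.called_mask()
    d[~called] = np.nan
    mean = np.nanmean(d, axis=0)
    if impute_missing:
        d = np.where(np.isnan(d), mean, d)
    sd = np.nanstd(d, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (d - mean) / sd
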