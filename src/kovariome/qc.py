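"""Sample- and variant-level quality control.

Implements the cohort-cleaning stages in their canonical order: per-sample
filters (missingness, het/hom outliers), kinship-based selection of an
unrelated subset, the allele-balance batch-effect filter, and variant-level
filters (genotyping rate, HWE, MAF).  Also houses the supporting
primitives: PLINK-style method-of-moments IBD estimation, the exact
Hardy-Weinberg test, sliding-window LD pruning and standardized-genotype
PCA.

The allele-balance (AB) statistic is the fraction of reads supporting the
alternate allele at a call.  At a true heterozygous call AB is expected to
concentrate around 0.5; variant-level departures of the mean AB from the
genome-wide average flag systematic artifacts such as sequencing batch
effects.  A variant is excluded when its mean heterozygous AB falls outside
mean +/- 1 SD of the genome-wide distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MISSING, GenotypeMatrix, standardized_dosages


# ---------------------------------------------------------------------------
# allele balance / batch-effect filter
# ---------------------------------------------------------------------------

@dataclass
class AlleleBalanceStats:
    """Per-variant mean heterozygous allele balance plus genome-wide moments.

    ``per_variant_mean_ab`` is NaN for variants with no usable heterozygous
    call; such variants never enter the genome-wide mean/SD.
    """

    per_variant_mean_ab: np.ndarray
    n_het_per_variant: np.ndarray
    genomewide_mean: float
    genomewide_sd: float


def compute_allele_balance(
    genotypes: GenotypeMatrix,
    read_counts: tuple[np.ndarray, np.ndarray],
) -> AlleleBalanceStats:
    """Mean alternate-read fraction over heterozygous calls, per variant.

    Only heterozygous calls with total depth > 0 contribute.  Homozygous
    calls are excluded: their expected AB is 0 or 1 and would swamp the
    statistic; restricting to hets makes the genome-wide mean interpretable
    (~0.5 in the absence of artifacts).
    """
    ref, alt = read_counts
    het = genotypes.dosages == 1
    depth = ref + alt
    usable = het & (depth > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(usable, alt / np.where(depth > 0, depth, 1), 0.0)
    n_het = usable.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_ab = np.where(n_het > 0, ab.sum(axis=0) / np.maximum(n_het, 1), np.nan)
    defined = n_het > 0
    if defined.sum() == 0:
        return AlleleBalanceStats(mean_ab, n_het, np.nan, np.nan)
    mu = float(np.mean(mean_ab[defined]))
    sd = float(np.std(mean_ab[defined], ddof=1)) if defined.sum() > 1 else 0.0
    return AlleleBalanceStats(mean_ab, n_het, mu, sd)


def filter_batch_effect(stats: AlleleBalanceStats) -> np.ndarray:
    """Per-variant keep mask: drop variants with mean AB outside mu +/- sd.

    The interval is closed: a variant sitting exactly on the boundary is
    kept.  Variants whose mean AB is undefined (no het calls) are kept.
    A degenerate SD of zero keeps every defined-mean variant and warns.
    """
    mean_ab = stats.per_variant_mean_ab
    keep = np.ones(mean_ab.shape[0], dtype=bool)
    defined = ~np.isnan(mean_ab)
    if not defined.any():
        return keep
    if stats.genomewide_sd == 0:
        warnings.warn(
            "genome-wide allele-balance SD is zero; batch filter keeps all variants",
            stacklevel=2,
        )
        return keep
    lo = stats.genomewide_mean - stats.genomewide_sd
    hi = stats.genomewide_mean + stats.genomewide_sd
    out = defined & ((mean_ab < lo) | (mean_ab > hi))
    keep[out] = False
    return keep


# ---------------------------------------------------------------------------
# sample-level QC
# ---------------------------------------------------------------------------

def sample_qc(
    genotypes: GenotypeMatrix,
    missing_threshold: float = 0.10,
    ratio_sd: float = 3.0,
) -> pd.DataFrame:
    """Per-sample missingness and het/hom-ratio outlier flags.

    Flags ``high_missing`` when the sample's missing-genotype rate exceeds
    ``missing_threshold`` and ``het_hom_outlier`` when its ratio of
    heterozygous to non-reference-homozygous calls falls outside the cohort
    mean +/- ``ratio_sd`` SDs.  A sample with zero hom-alt calls has an
    undefined ratio and is flagged ``ratio_undefined`` for manual review.
    """
    if genotypes.n_samples < 2:
        raise ValueError("sample QC requires at least 2 samples")
    missing_rate = genotypes.sample_missing_rate()
    n_het = (genotypes.dosages == 1).sum(axis=1)
    n_hom_alt = (genotypes.dosages == 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(n_hom_alt > 0, n_het / np.maximum(n_hom_alt, 1), np.nan)
    defined = ~np.isnan(ratio)
    outlier = np.zeros(genotypes.n_samples, dtype=bool)
    if defined.sum() >= 2:
        mu = ratio[defined].mean()
        sd = ratio[defined].std(ddof=1)
        if sd > 0:
            outlier = defined & (np.abs(ratio - mu) > ratio_sd * sd)
    high_missing = missing_rate > missing_threshold
    report = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "missing_rate": missing_rate,
            "het_hom_ratio": ratio,
            "high_missing": high_missing,
            "het_hom_outlier": outlier,
            "ratio_undefined": ~defined,
        }
    )
    report["kept"] = ~(high_missing | outlier)
    return report


# ---------------------------------------------------------------------------
# IBD / kinship
# ---------------------------------------------------------------------------

def estimate_ibd(
    genotypes: GenotypeMatrix,
    af: np.ndarray | None = None,
    maf_min: float = 0.01,
    min_variants: int = 100,
) -> pd.DataFrame:
    """Method-of-moments IBD-state estimation for every sample pair.

    Follows the PLINK approach: per pair, count identity-by-state (IBS)
    0/1/2 sharing over variants called in both samples, compare against the
    allele-frequency-based expectations under IBD states 0/1/2 and solve
    for the IBD-state proportions.  Estimates are truncated to [0, 1] and
    renormalized to sum to one; ``pi_hat = P(IBD=1)/2 + P(IBD=2)``.

    Expected IBS probabilities given IBD state are the hypergeometric
    (sampling-without-replacement) analogues of the familiar
    with-replacement forms ``P(IBS0|IBD0) = 2 p^2 q^2`` etc., evaluated on
    the cohort's allele counts; drawing the pair's non-shared alleles
    without replacement from the observed allele pool removes the
    finite-sample bias of plugging in estimated frequencies.

    Expectation sums are computed over all retained variants and scaled by
    each pair's fraction of jointly-called variants (missingness is assumed
    independent of genotype).
    """
    ac, an = genotypes.allele_counts()
    if af is None:
        af = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
    else:
        af = np.asarray(af, dtype=float)
        ac = af * an
    maf = np.minimum(af, 1 - af)
    use = np.isfinite(af) & (maf >= maf_min) & (an >= 4)
    if use.sum() < min_variants:
        raise ValueError(
            f"only {int(use.sum())} usable variants (< {min_variants}); "
            "IBD estimates would be unstable"
        )
    g = genotypes.dosages[:, use]
    m = g.shape[1]
    x = ac[use].astype(float)         # alt allele count
    y = (an[use] - ac[use]).astype(float)  # ref allele count
    t = an[use].astype(float)
    t2 = t * (t - 1)
    t4 = t2 * (t - 2) * (t - 3)

    ind = [(g == k).astype(np.float32) for k in (0, 1, 2)]
    called = (g != MISSING).astype(np.float32)
    valid = called @ called.T
    ibs2 = sum(i @ i.T for i in ind)
    ibs0 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    ibs1 = valid - ibs0 - ibs2

    e0_ibd0 = float(np.sum(2 * x * (x - 1) * y * (y - 1) / t4))
    e1_ibd0 = float(
        np.sum(4 * x * (x - 1) * (x - 2) * y / t4 + 4 * x * y * (y - 1) * (y - 2) / t4)
    )
    e2_ibd0 = float(
        np.sum(
            (
                x * (x - 1) * (x - 2) * (x - 3)
                + y * (y - 1) * (y - 2) * (y - 3)
                + 4 * x * (x - 1) * y * (y - 1)
            )
            / t4
        )
    )
    e1_ibd1 = float(np.sum(2 * x * y / t2))
    e2_ibd1 = float(np.sum((x * (x - 1) + y * (y - 1)) / t2))

    n = genotypes.n_samples
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            v = valid[i, j]
            if v <= 0:
                continue
            f = v / m
            p0 = ibs0[i, j] / (f * e0_ibd0) if e0_ibd0 > 0 else 0.0
            p1 = (ibs1[i, j] - p0 * f * e1_ibd0) / (f * e1_ibd1)
            p2 = (ibs2[i, j] - p0 * f * e2_ibd0 - p1 * f * e2_ibd1) / v
            est = np.clip([p0, p1, p2], 0.0, 1.0)
            total = est.sum()
            est = est / total if total > 0 else np.array([1.0, 0.0, 0.0])
            rows.append(
                {
                    "sample_i": genotypes.sample_ids[i],
                    "sample_j": genotypes.sample_ids[j],
                    "ibd0": est[0],
                    "ibd1": est[1],
                    "ibd2": est[2],
                    "pi_hat": est[1] / 2 + est[2],
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_i", "sample_j", "ibd0", "ibd1", "ibd2", "pi_hat"]
    )


def select_unrelated(
    pairs: pd.DataFrame,
    threshold: float = 0.05,
    all_samples: list[str] | None = None,
) -> list[str]:
    """Greedy unrelated-set selection.

    Repeatedly drops the sample participating in the most pairs with
    ``pi_hat > threshold`` (ties broken by lexicographic sample ID) until no
    related pair remains.  Returns kept sample IDs, sorted.
    """
    if all_samples is None:
        all_samples = sorted(
            set(pairs["sample_i"]).union(pairs["sample_j"]) if len(pairs) else set()
        )
    related = pairs[pairs["pi_hat"] > threshold] if len(pairs) else pairs
    edges: dict[str, set[str]] = {}
    for _, row in related.iterrows():
        edges.setdefault(row["sample_i"], set()).add(row["sample_j"])
        edges.setdefault(row["sample_j"], set()).add(row["sample_i"])
    removed: set[str] = set()
    while True:
        degrees = {
            s: len(nbrs - removed)
            for s, nbrs in edges.items()
            if s not in removed and len(nbrs - removed) > 0
        }
        if not degrees:
            break
        worst = min(degrees, key=lambda s: (-degrees[s], s))
        removed.add(worst)
    return sorted(s for s in all_samples if s not in removed)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test P for genotype counts (hom, het, hom).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations no more probable than the observed one
    (standard exact test, no mid-p correction).  Monomorphic input returns
    P = 1.  The result lies in (0, 1].
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if rare == 0:
        return 1.0
    # unnormalized probabilities over het counts with the parity of `rare`
    het_max = min(rare, 2 * n - rare)
    mode = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mode % 2 != rare % 2:
        mode += 1
    if mode > het_max:
        mode = het_max
    probs = {mode: 1.0}
    # downward recurrence: het -> het - 2
    het = mode
    val = 1.0
    while het >= 2:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        val *= het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
        probs[het] = val
    # upward recurrence: het -> het + 2
    het = mode
    val = 1.0
    while het + 2 <= het_max:
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        val *= 4.0 * hom_r * hom_c / ((het + 1) * (het + 2))
        het += 2
        probs[het] = val
    total = sum(probs.values())
    obs = n_ab
    if obs not in probs:
        raise ValueError("observed het count inconsistent with allele counts")
    p_obs = probs[obs]
    p = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_exact_many(genotype_counts: np.ndarray) -> np.ndarray:
    """Vectorized wrapper with caching over repeated count triples."""
    cache: dict[tuple[int, int, int], float] = {}
    out = np.empty(len(genotype_counts))
    for i, (a, b, c) in enumerate(np.asarray(genotype_counts, dtype=int)):
        key = (a, b, c)
        if key not in cache:
            cache[key] = hwe_exact_test(a, b, c)
        out[i] = cache[key]
    return out


# ---------------------------------------------------------------------------
# variant-level filters
# ---------------------------------------------------------------------------

def genotyping_rate_filter(
    genotypes: GenotypeMatrix, min_rate: float = 0.9
) -> np.ndarray:
    """Keep mask for variants genotyped in at least ``min_rate`` of samples."""
    return (1.0 - genotypes.variant_missing_rate()) >= min_rate


def variant_qc(
    genotypes: GenotypeMatrix,
    ab_keep: np.ndarray | None = None,
    min_genotyping_rate: float = 0.9,
) -> pd.DataFrame:
    """Variant-level report: genotyping rate, MAF, HWE P, AB exclusion."""
    rate = 1.0 - genotypes.variant_missing_rate()
    maf = genotypes.minor_allele_frequency()
    counts = genotypes.genotype_counts()
    hwe_p = hwe_exact_many(counts)
    ab_excluded = (
        ~np.asarray(ab_keep, bool)
        if ab_keep is not None
        else np.zeros(genotypes.n_variants, bool)
    )
    kept = (rate >= min_genotyping_rate) & ~ab_excluded
    return pd.DataFrame(
        {
            "key": genotypes.keys,
            "genotyping_rate": rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "ab_excluded": ab_excluded,
            "kept": kept,
        }
    )


# ---------------------------------------------------------------------------
# LD pruning and PCA
# ---------------------------------------------------------------------------

def ld_prune(
    genotypes: GenotypeMatrix,
    window: int = 200,
    step: int = 4,
    r2_threshold: float = 0.1,
) -> np.ndarray:
    """Sliding-window pairwise LD pruning; returns a keep mask.

    Within each window of ``window`` variants (per chromosome), pairs with
    squared dosage correlation above ``r2_threshold`` are resolved by
    removing the later variant; the window advances by ``step``.  Missing
    dosages are mean-imputed for the correlation computation only.
    """
    z = standardized_dosages(genotypes)
    n = z.shape[0]
    keep = np.ones(genotypes.n_variants, dtype=bool)
    chroms = genotypes.variant_meta["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            win = [j for j in idx[start : start + window] if keep[j]]
            for a_pos in range(len(win)):
                a = win[a_pos]
                if not keep[a]:
                    continue
                za = z[:, a]
                if za.std() == 0:
                    continue
                for b_pos in range(a_pos + 1, len(win)):
                    b = win[b_pos]
                    if not keep[b]:
                        continue
                    zb = z[:, b]
                    if zb.std() == 0:
                        continue
                    r = float(za @ zb) / n
                    if r * r > r2_threshold:
                        keep[b] = False
            start += step
    return keep


def pca(
    genotypes: GenotypeMatrix, n_components: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the standardized genotype matrix.

    Missing dosages are mean-imputed before standardization (for this
    computation only).  Returns per-sample scores ``(n, k)`` scaled by the
    square-root eigenvalues, and the explained-variance ratio of the top
    ``k`` components.  Score signs are arbitrary.
    """
    n = genotypes.n_samples
    if n_components > n - 1:
        raise ValueError("n_components must be at most n_samples - 1")
    z = standardized_dosages(genotypes)
    cov = (z @ z.T) / genotypes.n_variants
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:n_components]
    lam = np.maximum(eigvals[order], 0.0)
    scores = eigvecs[:, order] * np.sqrt(lam)
    total = eigvals[eigvals > 0].sum()
    explained = lam / total if total > 0 else np.zeros_like(lam)
    return scores, explained


def flag_pca_outliers(
    scores: np.ndarray,
    target_mask: np.ndarray | None = None,
    k: float = 6.0,
) -> np.ndarray:
    """Flag samples far from the target-population centroid on PC1-2.

    Distance is measured per-axis in SD units of the target samples; a
    sample is flagged when either axis deviates more than ``k`` SDs.
    """
    pc = scores[:, :2]
    if target_mask is None:
        target_mask = np.ones(pc.shape[0], dtype=bool)
    centroid = pc[target_mask].mean(axis=0)
    sd = pc[target_mask].std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    dev = np.abs(pc - centroid) / sd
    return (dev > k).any(axis=1)
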