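"""Synthetic cohort generator.

Emulates the statistical structure the downstream stages assume:
subpopulation-structured genotypes (Balding-Nichols), related sample pairs
produced by Mendelian gamete transmission, batch-biased read counts at
heterozygous sites, quantitative traits with prescribed heritability and
genetic correlation, pleiotropic variant sets, and exposure -> outcome
causal trait pairs.  Every draw is recorded in a ``truth`` block so that
parameter-recovery tests can compare estimates against the generating
values.

Model notes
-----------
Under Balding-Nichols, each subpopulation's allele frequency at a variant
with ancestral frequency ``p`` is drawn from
``Beta(p (1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and variance
``F p (1-p)``; ``F`` is the divergence (Fst) parameter.  Genotypes are
Hardy-Weinberg within subpopulation.  Relatives are built by transmitting
one allele from each designated founder parent, so parent-offspring pairs
have expected kinship PI_HAT = 0.5 exactly by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MISSING, GenotypeMatrix
from . import io as kio

RELATIONSHIPS = ("parent-offspring", "full-sib", "second-degree")

# expected PI_HAT per relationship class
EXPECTED_PI_HAT = {"parent-offspring": 0.5, "full-sib": 0.5, "second-degree": 0.25}


@dataclass
class CohortConfig:
    """Knobs for genotype and read-count generation.

    ``related_pairs`` is a list of ``(relationship, count)`` with
    relationship in {parent-offspring, full-sib, second-degree}; each pair
    consumes founders and appends non-founder offspring, all inside
    ``n_samples``.
    """

    n_samples: int = 500
    n_variants: int = 5000
    n_subpops: int = 1
    fst: float = 0.0
    ancestral_af_range: tuple[float, float] = (0.05, 0.95)
    related_pairs: list[tuple[str, int]] = field(default_factory=list)
    n_batches: int = 2
    batch_biased_fraction: float = 0.0
    batch_bias_ab: float = 0.65
    mean_depth: float = 30.0
    missing_rate: float = 0.005
    n_chromosomes: int = 2
    variant_spacing: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_variants <= 0:
            raise ValueError("n_samples and n_variants must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if not 0.0 <= self.batch_biased_fraction <= 1.0:
            raise ValueError("batch_biased_fraction must lie in [0, 1]")
        lo, hi = self.ancestral_af_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_af_range must be an interval inside (0,1)")
        for rel, count in self.related_pairs:
            if rel not in RELATIONSHIPS:
                raise ValueError(f"unknown relationship {rel!r}")
            if count < 0:
                raise ValueError("relationship counts must be nonnegative")


@dataclass
class TraitModel:
    """Generative model for quantitative traits.

    ``h2`` is per-trait narrow-sense heritability; ``rg`` the genetic
    correlation matrix used to draw causal effects jointly across traits.
    ``causal_edges`` lists ``(exposure_index, outcome_index, gamma)``
    trait-level causal effects applied after the genetic/environmental
    components are built.
    """

    n_traits: int = 2
    h2: list[float] = field(default_factory=lambda: [0.5, 0.5])
    rg: np.ndarray | None = None
    n_causal: int = 100
    causal_edges: list[tuple[int, int, float]] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.0, "age": 0.0, "age2": 0.0, "bmi": 0.0}
    )

    def __post_init__(self) -> None:
        if len(self.h2) != self.n_traits:
            raise ValueError("h2 must have one entry per trait")
        if any(not 0.0 <= h <= 1.0 for h in self.h2):
            raise ValueError("h2 entries must lie in [0, 1]")
        if self.rg is None:
            self.rg = np.eye(self.n_traits)
        self.rg = np.asarray(self.rg, dtype=float)
        if self.rg.shape != (self.n_traits, self.n_traits):
            raise ValueError("rg must be n_traits x n_traits")
        if not np.allclose(self.rg, self.rg.T):
            raise ValueError("rg must be symmetric")
        if np.abs(self.rg).max() > 1 + 1e-12:
            raise ValueError("rg entries must have magnitude <= 1")
        if np.linalg.eigvalsh(self.rg).min() < -1e-8:
            raise ValueError("rg must be positive semidefinite")
        for exp_i, out_i, gamma in self.causal_edges:
            if not np.isfinite(gamma):
                raise ValueError("causal effects must be finite")
            if not (0 <= exp_i < self.n_traits and 0 <= out_i < self.n_traits):
                raise ValueError("causal edge trait index out of range")


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    read_counts: tuple[np.ndarray, np.ndarray] | None
    traits: pd.DataFrame | None
    truth: dict


def _relationship_layout(config: CohortConfig) -> tuple[int, list[tuple[str, int]]]:
    """Number of founders and the expanded per-pair relationship list."""
    pairs: list[tuple[str, int]] = []
    n_offspring = 0
    for rel, count in config.related_pairs:
        for _ in range(count):
            pairs.append((rel, n_offspring))
            n_offspring += 2 if rel in ("full-sib", "second-degree") else 1
    founders_needed = 0
    for rel, _ in pairs:
        founders_needed += {"parent-offspring": 2, "full-sib": 2, "second-degree": 3}[rel]
    n_founders = config.n_samples - n_offspring
    if n_founders < founders_needed or n_founders < 1:
        raise ValueError(
            "related_pairs require more founders than n_samples allows"
        )
    return n_founders, pairs


def _gamete(parent_genotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per variant under Mendelian segregation."""
    g = parent_genotypes
    allele = np.where(g == 2, 1, 0).astype(np.int8)
    het = g == 1
    allele[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return allele


def simulate_genotypes(config: CohortConfig) -> tuple[GenotypeMatrix, dict]:
    """Draw structured genotypes; returns the matrix and the truth block.

    Truth holds realized allele frequencies (defined from the realized
    genotypes so that dosage-derived AF matches exactly), the per-subpop
    frequency draws, subpopulation labels, and the related-pair table.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_variants
    lo, hi = config.ancestral_af_range
    p_anc = rng.uniform(lo, hi, size=m)

    if config.fst > 0:
        F = config.fst
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        subpop_af = rng.beta(a[None, :], b[None, :], size=(config.n_subpops, m))
    else:
        subpop_af = np.tile(p_anc, (config.n_subpops, 1))

    n_founders, pair_layout = _relationship_layout(config)
    subpop = np.arange(n) % config.n_subpops
    dosages = np.empty((n, m), dtype=np.int8)
    for s in range(config.n_subpops):
        idx = np.flatnonzero(subpop[:n_founders] == s)
        dosages[idx] = rng.binomial(2, subpop_af[s], size=(len(idx), m)).astype(np.int8)

    # relatives overwrite trailing rows; founder pool indices are drawn from
    # the front without replacement so pairs stay independent of each other
    founder_pool = list(range(n_founders))
    pair_records = []
    cursor = n_founders
    for rel, _ in pair_layout:
        if rel == "parent-offspring":
            pa, pb = founder_pool.pop(0), founder_pool.pop(0)
            child = cursor
            cursor += 1
            dosages[child] = _gamete(dosages[pa], rng) + _gamete(dosages[pb], rng)
            subpop[child] = subpop[pa]
            pair_records.append((pa, child, rel))
        elif rel == "full-sib":
            pa, pb = founder_pool.pop(0), founder_pool.pop(0)
            c1, c2 = cursor, cursor + 1
            cursor += 2
            for c in (c1, c2):
                dosages[c] = _gamete(dosages[pa], rng) + _gamete(dosages[pb], rng)
                subpop[c] = subpop[pa]
            pair_records.append((c1, c2, rel))
        else:  # second-degree: half sibs sharing founder pa
            pa, pb, pc = founder_pool.pop(0), founder_pool.pop(0), founder_pool.pop(0)
            c1, c2 = cursor, cursor + 1
            cursor += 2
            dosages[c1] = _gamete(dosages[pa], rng) + _gamete(dosages[pb], rng)
            dosages[c2] = _gamete(dosages[pa], rng) + _gamete(dosages[pc], rng)
            subpop[c1] = subpop[c2] = subpop[pa]
            pair_records.append((c1, c2, rel))

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosages[miss] = MISSING

    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chrom = np.array(
        [f"chr{1 + j // per_chrom}" for j in range(m)], dtype=object
    )
    pos = np.array(
        [1 + (j % per_chrom) * config.variant_spacing for j in range(m)]
    )
    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "id": [f"var{j}" for j in range(m)],
        }
    )
    sample_ids = [f"S{i:05d}" for i in range(n)]
    gm = GenotypeMatrix(dosages, meta, sample_ids)

    truth = {
        "af": gm.alt_allele_frequency(),
        "subpop_af": subpop_af,
        "ancestral_af": p_anc,
        "subpop": subpop,
        "n_founders": n_founders,
        "related_pairs": pd.DataFrame(
            [
                {
                    "sample_i": sample_ids[i],
                    "sample_j": sample_ids[j],
                    "relationship": rel,
                    "expected_pi_hat": EXPECTED_PI_HAT[rel],
                }
                for i, j, rel in pair_records
            ],
            columns=["sample_i", "sample_j", "relationship", "expected_pi_hat"],
        ),
    }
    return gm, truth


def simulate_read_counts(
    genotypes: GenotypeMatrix, config: CohortConfig, seed: int | None = None
) -> tuple[tuple[np.ndarray, np.ndarray], dict]:
    """Per-call (ref_reads, alt_reads) with an optional batch-specific bias.

    Depth is Poisson(mean_depth); alt reads are Binomial(depth, p) with
    p = 0 / 0.5 / 1 for genotypes 0/1/2.  At biased variants the
    heterozygous success probability shifts to ``batch_bias_ab`` for samples
    in the affected batch (batch 0).  Missing genotypes get zero reads.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n, m = genotypes.n_samples, genotypes.n_variants
    depth = rng.poisson(config.mean_depth, size=(n, m))
    batch = np.arange(n) % config.n_batches
    n_biased = int(round(config.batch_biased_fraction * m))
    biased = rng.choice(m, size=n_biased, replace=False) if n_biased else np.array([], int)
    biased_mask = np.zeros(m, dtype=bool)
    biased_mask[biased] = True

    p = np.zeros((n, m))
    p[genotypes.dosages == 1] = 0.5
    p[genotypes.dosages == 2] = 1.0
    shift = (genotypes.dosages == 1) & biased_mask[None, :] & (batch == 0)[:, None]
    p[shift] = config.batch_bias_ab

    alt = rng.binomial(depth, p)
    ref = depth - alt
    uncalled = ~genotypes.called_mask()
    alt[uncalled] = 0
    ref[uncalled] = 0
    truth = {"biased_variants": np.sort(biased), "batch": batch}
    return (ref, alt), truth


def _covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Simple parametric draws; only the covariate role matters downstream."""
    sex = rng.integers(0, 2, size=n)
    age = rng.normal(50.0, 10.0, size=n)
    bmi = rng.normal(24.0, 3.0, size=n)
    return pd.DataFrame({"sex": sex, "age": age, "bmi": bmi})


def simulate_traits(
    genotypes: GenotypeMatrix, model: TraitModel, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Quantitative traits with target heritability and genetic correlation.

    All traits share one causal-variant set of size ``n_causal``; causal
    effects are drawn jointly across traits from N(0, rg), which makes the
    correlation of true genetic values converge to ``rg``.  Genetic values
    are rescaled to variance ``h2`` and environmental noise to ``1 - h2``,
    so on the standardized scale var(g)/var(y - covariate part) targets h2.
    Trait-level causal edges are applied last: outcome += gamma * exposure.
    """
    rng = np.random.default_rng(seed)
    n, m = genotypes.n_samples, genotypes.n_variants
    if model.n_causal > m:
        raise ValueError("n_causal exceeds number of variants")
    causal = np.sort(rng.choice(m, size=model.n_causal, replace=False))

    d = genotypes.dosages[:, causal].astype(float)
    d[d == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    sd = np.nanstd(d, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (np.where(np.isnan(d), mean, d) - mean) / sd

    k = model.n_traits
    chol = np.linalg.cholesky(model.rg + 1e-10 * np.eye(k))
    effects = rng.standard_normal((model.n_causal, k)) @ chol.T

    g = z @ effects  # (n, k)
    genetic = np.zeros((n, k))
    env = rng.standard_normal((n, k))
    y = np.empty((n, k))
    for t in range(k):
        h2 = model.h2[t]
        if h2 > 0 and g[:, t].std() > 0:
            genetic[:, t] = g[:, t] * np.sqrt(h2) / g[:, t].std()
        e = env[:, t]
        e = e - e.mean()
        scale = np.sqrt(1.0 - h2) / e.std() if e.std() > 0 else 0.0
        y[:, t] = genetic[:, t] + e * scale

    for exp_i, out_i, gamma in model.causal_edges:
        y[:, out_i] = y[:, out_i] + gamma * y[:, exp_i]

    cov = _covariates(n, rng)
    ce = model.covariate_effects
    cov_part = (
        ce.get("sex", 0.0) * cov["sex"].to_numpy()
        + ce.get("age", 0.0) * cov["age"].to_numpy()
        + ce.get("age2", 0.0) * cov["age"].to_numpy() ** 2
        + ce.get("bmi", 0.0) * cov["bmi"].to_numpy()
    )
    y = y + cov_part[:, None]

    table = pd.DataFrame({"sample_id": genotypes.sample_ids})
    table = pd.concat([table, cov], axis=1)
    for t in range(k):
        table[f"trait_{t + 1}"] = y[:, t]

    realized_rg = np.corrcoef(genetic.T) if k > 1 else np.ones((1, 1))
    truth = {
        "causal_variants": causal,
        "effects": effects,
        "genetic_values": genetic,
        "covariate_part": cov_part,
        "h2": list(model.h2),
        "rg": model.rg.copy(),
        "realized_rg": realized_rg,
        "causal_edges": list(model.causal_edges),
    }
    return table, truth


def simulate_cohort(
    config: CohortConfig, trait_model: TraitModel | None = None
) -> SyntheticCohort:
    """End-to-end generation: genotypes, read counts, and (optional) traits."""
    genotypes, truth = simulate_genotypes(config)
    read_counts, rc_truth = simulate_read_counts(genotypes, config)
    truth.update(rc_truth)
    traits = None
    if trait_model is not None:
        traits, trait_truth = simulate_traits(
            genotypes, trait_model, seed=config.seed + 2
        )
        truth.update({f"trait_{k}": v for k, v in trait_truth.items()})
    return SyntheticCohort(genotypes, read_counts, traits, truth)


def write_cohort(cohort: SyntheticCohort, directory: str | os.PathLike) -> None:
    """Persist as VCF (GT + AD), phenotype TSV and truth TSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    kio.write_vcf(cohort.genotypes, directory / "cohort.vcf", cohort.read_counts)
    if cohort.traits is not None:
        kio.write_trait_table(cohort.traits, directory / "traits.tsv")
    truth = cohort.truth
    pd.DataFrame({"af": truth["af"]}).to_csv(
        directory / "truth_af.tsv", sep="\t", index=False
    )
    truth["related_pairs"].to_csv(
        directory / "truth_related_pairs.tsv", sep="\t", index=False
    )
    if "biased_variants" in truth:
        pd.DataFrame({"variant_index": truth["biased_variants"]}).to_csv(
            directory / "truth_biased_variants.tsv", sep="\t", index=False
        )


def read_cohort(directory: str | os.PathLike) -> SyntheticCohort:
    directory = Path(directory)
    genotypes, read_counts = kio.read_vcf(directory / "cohort.vcf", with_read_counts=True)
    traits_path = directory / "traits.tsv"
    traits = kio.read_trait_table(traits_path) if traits_path.exists() else None
    truth: dict = {}
    af_path = directory / "truth_af.tsv"
    if af_path.exists():
        truth["af"] = pd.read_csv(af_path, sep="\t")["af"].to_numpy()
    rp = directory / "truth_related_pairs.tsv"
    if rp.exists():
        truth["related_pairs"] = pd.read_csv(rp, sep="\t")
    bv = directory / "truth_biased_variants.tsv"
    if bv.exists():
        truth["biased_variants"] = pd.read_csv(bv, sep="\t")["variant_index"].to_numpy()
    return SyntheticCohort(genotypes, read_counts, traits, truth)
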