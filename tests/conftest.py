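"""Shared fixtures: synthetic cohorts at the sizes the heavier
statistical checks need, generated once per session."""

import numpy as np
import pytest

from kovariome.greml import build_grm
from kovariome.synthetic import (
    CohortConfig,
    TraitModel,
    simulate_genotypes,
    simulate_read_counts,
)


@pytest.fixture(scope="session")
def small_cohort():
    """200 samples x 2,000 variants, no structure, default missingness."""
    cfg = CohortConfig(n_samples=200, n_variants=2000, seed=42)
    gm, truth = simulate_genotypes(cfg)
    return gm, truth, cfg


@pytest.fixture(scope="session")
def big_cohort():
    """2,000 samples x 5,000 variants for REML parameter recovery."""
    cfg = CohortConfig(n_samples=2000, n_variants=5000, missing_rate=0.0, seed=7)
    gm, truth = simulate_genotypes(cfg)
    return gm, truth, cfg


@pytest.fixture(scope="session")
def big_grm(big_cohort):
    gm, _, _ = big_cohort
    grm = build_grm(gm)
    grm.eigen()  # cache the eigendecomposition for every consumer
    return grm


@pytest.fixture(scope="session")
def biased_readcount_cohort():
    """500 samples, depth 30, 5% of variants batch-biased at AB 0.65."""
    cfg = CohortConfig(
        n_samples=500,
        n_variants=2000,
        batch_biased_fraction=0.05,
        batch_bias_ab=0.65,
        mean_depth=30.0,
        seed=11,
    )
    gm, truth = simulate_genotypes(cfg)
    rc, rc_truth = simulate_read_counts(gm, cfg)
    truth = {**truth, **rc_truth}
    return gm, rc, truth


@pytest.fixture(scope="session")
def related_cohort():
    """Cohort with 40 parent-offspring pairs over 5,000 common variants."""
    cfg = CohortConfig(
        n_samples=200,
        n_variants=5000,
        related_pairs=[("parent-offspring", 40)],
        seed=3,
    )
    gm, truth = simulate_genotypes(cfg)
    return gm, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
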