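"""QC checks: allele-balance filter, sample filters, kinship,
Hardy-Weinberg exact test, LD pruning and PCA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from kovariome import qc
from kovariome.cohort import MISSING, GenotypeMatrix
from kovariome.qc import AlleleBalanceStats
from kovariome.synthetic import CohortConfig, simulate_genotypes


def toy_matrix(dosages, spacing=1000):
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    meta = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, m + 1) * spacing,
         "ref": "A", "alt": "G", "id": [f"v{j}" for j in range(m)]}
    )
    return GenotypeMatrix(dosages, meta)


class TestAlleleBalance:
    def test_balanced_reads_give_half(self):
        gm = toy_matrix([[1], [1]])
        ref = np.array([[5], [7]])
        alt = np.array([[5], [7]])
        stats = qc.compute_allele_balance(gm, (ref, alt))
        assert stats.per_variant_mean_ab[0] == pytest.approx(0.5)

    def test_hand_computed_mean(self):
        # het calls with (ref,alt) = (3,7) and (5,5): mean of {0.7, 0.5}
        gm = toy_matrix([[1], [1]])
        stats = qc.compute_allele_balance(
            gm, (np.array([[3], [5]]), np.array([[7], [5]]))
        )
        assert stats.per_variant_mean_ab[0] == pytest.approx(0.6)

    def test_no_het_calls_marked_undefined(self):
        gm = toy_matrix([[0], [2]])
        stats = qc.compute_allele_balance(
            gm, (np.array([[10], [0]]), np.array([[0], [10]]))
        )
        assert np.isnan(stats.per_variant_mean_ab[0])

    def test_genomewide_mean_near_half_unbiased(self, biased_readcount_cohort):
        gm, rc, truth = biased_readcount_cohort
        unbiased = np.setdiff1d(np.arange(gm.n_variants), truth["biased_variants"])
        stats = qc.compute_allele_balance(
            gm.take_variants(unbiased), (rc[0][:, unbiased], rc[1][:, unbiased])
        )
        assert abs(stats.genomewide_mean - 0.5) < 0.01


class TestBatchEffectFilter:
    def test_excludes_outside_one_sd(self):
        stats = AlleleBalanceStats(
            per_variant_mean_ab=np.array([0.45, 0.50, 0.49]),
            n_het_per_variant=np.array([10, 10, 10]),
            genomewide_mean=0.5, genomewide_sd=0.03,
        )
        keep = qc.filter_batch_effect(stats)
        assert list(keep) == [False, True, True]

    def test_boundary_is_kept(self):
        stats = AlleleBalanceStats(
            per_variant_mean_ab=np.array([0.47, 0.53, 0.5]),
            n_het_per_variant=np.array([10, 10, 10]),
            genomewide_mean=0.5, genomewide_sd=0.03,
        )
        assert qc.filter_batch_effect(stats).all()

    def test_undefined_mean_kept(self):
        stats = AlleleBalanceStats(
            per_variant_mean_ab=np.array([np.nan, 0.2]),
            n_het_per_variant=np.array([0, 10]),
            genomewide_mean=0.5, genomewide_sd=0.03,
        )
        assert list(qc.filter_batch_effect(stats)) == [True, False]

    def test_zero_sd_keeps_all_with_warning(self):
        stats = AlleleBalanceStats(
            per_variant_mean_ab=np.array([0.5, 0.5]),
            n_het_per_variant=np.array([5, 5]),
            genomewide_mean=0.5, genomewide_sd=0.0,
        )
        with pytest.warns(UserWarning, match="SD is zero"):
            assert qc.filter_batch_effect(stats).all()

    def test_recovers_injected_batch_bias(self, biased_readcount_cohort):
        gm, rc, truth = biased_readcount_cohort
        stats = qc.compute_allele_balance(gm, rc)
        keep = qc.filter_batch_effect(stats)
        recovered = (~keep[truth["biased_variants"]]).mean()
        assert recovered >= 0.90

    def test_invariant_to_sample_and_variant_order(self, biased_readcount_cohort):
        gm, rc, _ = biased_readcount_cohort
        stats = qc.compute_allele_balance(gm, rc)
        keep = qc.filter_batch_effect(stats)
        rng = np.random.default_rng(1)
        sperm = rng.permutation(gm.n_samples)
        vperm = rng.permutation(gm.n_variants)
        gm2 = gm.take_samples(sperm).take_variants(vperm)
        rc2 = (rc[0][sperm][:, vperm], rc[1][sperm][:, vperm])
        keep2 = qc.filter_batch_effect(qc.compute_allele_balance(gm2, rc2))
        np.testing.assert_array_equal(keep[vperm], keep2)


class TestSampleQC:
    def test_high_missing_flagged(self):
        d = np.zeros((3, 100), dtype=np.int8)
        d[1, 2] = 1  # avoid an all-constant cohort
        d[0, :11] = MISSING  # 11% missing
        rep = qc.sample_qc(toy_matrix(d))
        assert bool(rep.loc[0, "high_missing"])
        assert not rep.loc[1:, "high_missing"].any()

    def test_identical_samples_have_no_outliers(self):
        d = np.tile(np.array([0, 1, 2, 1] * 25, dtype=np.int8), (10, 1))
        rep = qc.sample_qc(toy_matrix(d))
        assert not rep["het_hom_outlier"].any()

    def test_doubled_het_sample_flagged(self, rng):
        # 200 background samples with het/hom ratio ~2, one with ratio ~4
        d = rng.choice([0, 1, 2], size=(200, 2000), p=[0.55, 0.30, 0.15]).astype(np.int8)
        spiked = rng.choice([0, 1, 2], size=2000, p=[0.25, 0.60, 0.15]).astype(np.int8)
        d = np.vstack([d, spiked])
        rep = qc.sample_qc(toy_matrix(d))
        assert bool(rep.iloc[-1]["het_hom_outlier"])

    def test_zero_hom_alt_marked_for_review(self):
        d = np.array([[1, 1, 0, 0], [2, 1, 0, 1], [2, 1, 1, 0]], dtype=np.int8)
        rep = qc.sample_qc(toy_matrix(d))
        assert bool(rep.loc[0, "ratio_undefined"])


class TestIBD:
    def test_duplicate_pair_pi_hat_near_one(self):
        cfg = CohortConfig(n_samples=50, n_variants=5000, missing_rate=0.0, seed=4)
        gm, _ = simulate_genotypes(cfg)
        d = gm.dosages.copy()
        d[1] = d[0]
        gm2 = GenotypeMatrix(d, gm.variant_meta, gm.sample_ids)
        pairs = qc.estimate_ibd(gm2)
        dup = pairs[(pairs.sample_i == "S00000") & (pairs.sample_j == "S00001")]
        assert float(dup["pi_hat"].iloc[0]) >= 0.95

    def test_parent_offspring_pi_hat_in_expected_band(self, related_cohort):
        gm, truth = related_cohort
        pairs = qc.estimate_ibd(gm)
        merged = pairs.merge(truth["related_pairs"], on=["sample_i", "sample_j"])
        assert len(merged) == 40
        in_band = merged["pi_hat"].between(0.45, 0.55).mean()
        assert in_band >= 0.95

    def test_unrelated_pairs_concentrate_near_zero(self, related_cohort):
        gm, truth = related_cohort
        pairs = qc.estimate_ibd(gm)
        rel = set(truth["related_pairs"]["sample_i"]) | set(
            truth["related_pairs"]["sample_j"]
        )
        unrel = pairs[~(pairs.sample_i.isin(rel) | pairs.sample_j.isin(rel))]
        # truncation at zero leaves a small positive mean and a tail that
        # crosses 0.05 for a few percent of pairs at M=5,000 markers
        assert unrel["pi_hat"].mean() < 0.03
        assert (unrel["pi_hat"] < 0.05).mean() >= 0.90

    def test_too_few_variants_refused(self):
        cfg = CohortConfig(n_samples=20, n_variants=50, seed=5)
        gm, _ = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="unstable"):
            qc.estimate_ibd(gm)


class TestSelectUnrelated:
    def test_no_related_pairs_keeps_all(self):
        pairs = pd.DataFrame(
            {"sample_i": ["a"], "sample_j": ["b"], "pi_hat": [0.01]}
        )
        kept = qc.select_unrelated(pairs, all_samples=["a", "b", "c"])
        assert kept == ["a", "b", "c"]

    def test_single_pair_removes_exactly_one(self):
        pairs = pd.DataFrame(
            {"sample_i": ["a"], "sample_j": ["b"], "pi_hat": [0.5]}
        )
        kept = qc.select_unrelated(pairs, all_samples=["a", "b", "c"])
        assert len(kept) == 2 and "c" in kept

    def test_star_family_matches_brute_force_minimum_cover(self):
        # parent p related to offspring o1..o3; offspring mutually related
        members = ["o1", "o2", "o3", "p"]
        edges = [("p", "o1"), ("p", "o2"), ("p", "o3"),
                 ("o1", "o2"), ("o1", "o3"), ("o2", "o3")]
        pairs = pd.DataFrame(
            [{"sample_i": a, "sample_j": b, "pi_hat": 0.5} for a, b in edges]
        )
        kept = qc.select_unrelated(pairs, all_samples=members)
        # brute force: largest subset with no edge inside
        best = max(
            (
                set(sub)
                for r in range(len(members) + 1)
                for sub in itertools.combinations(members, r)
                if not any(a in sub and b in sub for a, b in edges)
            ),
            key=len,
        )
        assert len(kept) == len(best)

    def test_result_contains_no_related_pair(self, related_cohort):
        gm, _ = related_cohort
        pairs = qc.estimate_ibd(gm)
        kept = set(qc.select_unrelated(pairs, all_samples=gm.sample_ids))
        bad = pairs[
            (pairs.pi_hat > 0.05)
            & pairs.sample_i.isin(kept)
            & pairs.sample_j.isin(kept)
        ]
        assert len(bad) == 0


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Direct enumeration of the conditional distribution of het counts."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    if min(na, 2 * n - na) == 0:
        return 1.0

    def log_prob(h):
        a = (na - h) // 2
        b = (2 * n - na - h) // 2
        return (
            math.lgamma(n + 1) - math.lgamma(a + 1) - math.lgamma(h + 1)
            - math.lgamma(b + 1) + h * math.log(2)
            + math.lgamma(na + 1) + math.lgamma(2 * n - na + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(na % 2, min(na, 2 * n - na) + 1, 2)
    probs = {h: math.exp(log_prob(h)) for h in hets}
    p_obs = probs[n_ab]
    return min(1.0, sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)))


class TestHWE:
    def test_expectation_case_maximally_consistent(self):
        assert qc.hwe_exact_test(25, 50, 25) >= 0.5

    def test_monomorphic_returns_one(self):
        assert qc.hwe_exact_test(100, 0, 0) == 1.0

    def test_small_table_matches_enumeration(self):
        assert qc.hwe_exact_test(10, 10, 10) == pytest.approx(
            hwe_enumeration_oracle(10, 10, 10), abs=1e-12
        )

    def test_all_tables_up_to_total_50_match_oracle(self):
        for n in range(1, 51):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    assert qc.hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                        hwe_enumeration_oracle(n_aa, n_ab, n_bb), abs=1e-12
                    ), (n_aa, n_ab, n_bb)


class TestLDPrune:
    def test_duplicated_column_loses_one(self, rng):
        col = rng.choice([0, 1, 2], size=500, p=[0.25, 0.5, 0.25])
        d = np.column_stack([col, col, rng.integers(0, 3, 500)]).astype(np.int8)
        keep = qc.ld_prune(toy_matrix(d))
        assert keep[0] and not keep[1] and keep[2]

    def test_independent_variants_rarely_removed(self):
        cfg = CohortConfig(n_samples=1000, n_variants=300, missing_rate=0.0, seed=6)
        gm, _ = simulate_genotypes(cfg)
        keep = qc.ld_prune(gm)
        assert (~keep).mean() < 0.05

    def test_three_variant_toy_matches_exhaustive_rule(self, rng):
        # construct v0, v1 correlated (r2 ~ 0.5), v2 independent
        n = 2000
        v0 = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25])
        noise = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25])
        mix = rng.random(n) < 0.75
        v1 = np.where(mix, v0, noise)
        v2 = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25])
        d = np.column_stack([v0, v1, v2]).astype(np.int8)
        gm = toy_matrix(d)
        z = (d - d.mean(0)) / d.std(0)
        r2 = (z.T @ z / n) ** 2
        keep = qc.ld_prune(gm, r2_threshold=0.1)
        # oracle: scan pairs in order, drop the later of any offending pair
        expect = np.ones(3, bool)
        for a in range(3):
            for b in range(a + 1, 3):
                if expect[a] and expect[b] and r2[a, b] > 0.1:
                    expect[b] = False
        np.testing.assert_array_equal(keep, expect)


class TestPCA:
    def test_two_subpopulations_separate_on_pc1(self):
        cfg = CohortConfig(
            n_samples=300, n_variants=2000, n_subpops=2, fst=0.1,
            missing_rate=0.0, seed=8,
        )
        gm, truth = simulate_genotypes(cfg)
        scores, _ = qc.pca(gm, n_components=2)
        labels = truth["subpop"]
        side = scores[:, 0] > np.median(scores[:, 0])
        acc = max((side == labels).mean(), (side == (1 - labels)).mean())
        assert acc >= 0.99

    def test_homogeneous_population_has_no_structure(self, small_cohort):
        gm, _, _ = small_cohort
        scores, _ = qc.pca(gm, n_components=2)
        rng = np.random.default_rng(0)
        accs = []
        for _ in range(20):
            half = rng.permutation(gm.n_samples) < gm.n_samples // 2
            side = scores[:, 0] > np.median(scores[:, 0])
            accs.append(max((side == half).mean(), (side == ~half).mean()))
        assert np.mean(accs) < 0.60

    def test_score_orthogonality(self, small_cohort):
        gm, _, _ = small_cohort
        scores, _ = qc.pca(gm, n_components=3)
        r = np.corrcoef(scores[:, 0], scores[:, 1])[0, 1]
        assert abs(r) < 1e-8

    def test_too_many_components_rejected(self, small_cohort):
        gm, _, _ = small_cohort
        with pytest.raises(ValueError):
            qc.pca(gm, n_components=gm.n_samples)

    def test_outlier_flagging(self, small_cohort):
        gm, _, _ = small_cohort
        scores, _ = qc.pca(gm, n_components=2)
        scores = scores.copy()
        scores[0, 0] += 100 * scores[:, 0].std()
        flags = qc.flag_pca_outliers(scores, k=6.0)
        assert flags[0] and flags[1:].sum() == 0
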