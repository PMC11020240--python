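"""Mendelian randomization: instrument selection, IVW, Egger, PRESSO,
consensus calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from kovariome.cohort import GenotypeMatrix
from kovariome.mr import (
    consensus_mr,
    mr_egger,
    mr_ivw,
    mr_presso,
    run_mr_pair,
    select_instruments,
)
from kovariome.synthetic import CohortConfig, simulate_genotypes


def toy_matrix(dosages, pos=None):
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    meta = pd.DataFrame(
        {"chrom": "chr1",
         "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
         "ref": "A", "alt": "G", "id": [f"v{j}" for j in range(m)]}
    )
    return GenotypeMatrix(dosages, meta)


class TestSelectInstruments:
    def test_perfect_ld_pair_collapses_to_one(self, rng):
        col = rng.binomial(2, 0.4, 600)
        d = np.column_stack([col, col, rng.binomial(2, 0.4, 600)]).astype(np.int8)
        gm = toy_matrix(d)
        stats = pd.DataFrame({"key": gm.keys, "p": [1e-8, 1e-7, 1e-9],
                              "beta": [0.3, 0.3, 0.2], "se": [0.05] * 3})
        inst = select_instruments(stats, gm, min_instruments=1)
        assert len(inst) == 2  # one per LD block

    def test_no_suggestive_variants_returns_empty(self, rng):
        d = rng.binomial(2, 0.4, size=(100, 5)).astype(np.int8)
        gm = toy_matrix(d)
        stats = pd.DataFrame({"key": gm.keys, "p": [0.5] * 5,
                              "beta": [0.0] * 5, "se": [0.05] * 5})
        assert select_instruments(stats, gm) == []

    def test_eight_variant_toy_matches_hand_selection(self, rng):
        n = 2000
        b1 = rng.binomial(2, 0.5, n)
        b2 = rng.binomial(2, 0.5, n)
        mix = lambda b: np.where(rng.random(n) < 0.9, b, rng.binomial(2, 0.5, n))
        d = np.column_stack(
            [b1, mix(b1), mix(b1), b2, mix(b2), rng.binomial(2, 0.5, n),
             rng.binomial(2, 0.5, n), rng.binomial(2, 0.5, n)]
        ).astype(np.int8)
        gm = toy_matrix(d)
        p = np.array([1e-9, 1e-7, 1e-6, 1e-8, 1e-6, 1e-7, 0.5, 1e-6])
        stats = pd.DataFrame({"key": gm.keys, "p": p,
                              "beta": [0.3] * 8, "se": [0.05] * 8})
        inst = select_instruments(stats, gm, min_instruments=1)
        keys = list(gm.keys)
        # hand selection: block {0,1,2} -> v0; block {3,4} -> v3; v5, v7 alone;
        # v6 is not suggestive
        assert sorted(inst) == sorted([keys[0], keys[3], keys[5], keys[7]])


class TestIVW:
    def test_exact_proportionality_recovers_slope(self):
        bx = np.array([0.2, 0.3, -0.1, 0.4])
        res = mr_ivw(bx, None, 2.0 * bx, np.full(4, 0.05))
        assert res.estimate == pytest.approx(2.0, abs=1e-12)
        assert res.p < 1e-100

    def test_single_instrument_is_wald_ratio(self):
        res = mr_ivw(np.array([0.4]), None, np.array([0.2]), np.array([0.1]))
        assert res.estimate == pytest.approx(0.5)
        assert res.se == pytest.approx(0.25)

    def test_five_instrument_closed_form(self, rng):
        bx = rng.normal(0.3, 0.1, 5)
        by = rng.normal(0.15, 0.1, 5)
        sy = rng.uniform(0.02, 0.1, 5)
        res = mr_ivw(bx, None, by, sy)
        w = 1 / sy**2
        expected = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert res.estimate == pytest.approx(expected, abs=1e-12)

    def test_all_zero_exposure_effects_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            mr_ivw(np.zeros(3), None, np.ones(3), np.ones(3))


class TestEgger:
    def test_exact_line_recovers_slope_and_zero_intercept(self):
        bx = np.array([0.2, 0.3, 0.15, 0.4, 0.25])
        res, intercept, _ = mr_egger(bx, None, 1.5 * bx, np.full(5, 0.05))
        assert res.estimate == pytest.approx(1.5, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_fewer_than_three_instruments_rejected(self):
        with pytest.raises(ValueError, match="3 instruments"):
            mr_egger(np.ones(2), None, np.ones(2), np.ones(2))

    def test_directional_pleiotropy_recovered(self, rng):
        gammas, intercepts, cover = [], [], 0
        n_reps = 20
        c = 0.05
        for _ in range(n_reps):
            k = 30
            bx = rng.normal(0.3, 0.1, k)
            sy = np.full(k, 0.02)
            by = 0.5 * bx + c + rng.normal(0, sy)
            res, intercept, int_p = mr_egger(bx, None, by, sy)
            gammas.append(res.estimate)
            intercepts.append(intercept)
        assert abs(np.mean(intercepts) - c) < 0.02
        assert abs(np.mean(gammas) - 0.5) < 0.1  # within 20% of truth

    def test_no_pleiotropy_intercept_covers_zero(self, rng):
        cover = 0
        n_reps = 20
        for _ in range(n_reps):
            k = 30
            bx = rng.normal(0.3, 0.1, k)
            sy = np.full(k, 0.02)
            by = 0.5 * bx + rng.normal(0, sy)
            _, intercept, int_p = mr_egger(bx, None, by, sy)
            cover += int_p > 0.05
        assert cover >= 0.9 * n_reps


class TestPresso:
    def test_clean_simulation_rarely_flags_outliers(self, rng):
        clean = 0
        n_reps = 20
        for rep in range(n_reps):
            k = 20
            bx = rng.normal(0.3, 0.1, k)
            sy = np.full(k, 0.05)
            by = 0.5 * bx + rng.normal(0, sy)
            outliers, _, _ = mr_presso(
                bx, None, by, sy, nb_distribution=1000, seed=rep
            )
            clean += len(outliers) == 0
        assert clean >= 0.9 * n_reps

    def test_spiked_instrument_flagged(self, rng):
        flagged = 0
        n_reps = 20
        for rep in range(n_reps):
            k = 20
            bx = rng.normal(0.3, 0.1, k)
            sy = np.full(k, 0.05)
            by = 0.5 * bx + rng.normal(0, sy)
            by[7] += 10 * sy[7]
            outliers, est, global_p = mr_presso(
                bx, None, by, sy, nb_distribution=1000, seed=rep
            )
            flagged += "7" in outliers
        assert flagged >= 0.9 * n_reps

    def test_removing_non_outlier_barely_moves_estimate(self, rng):
        k = 30
        bx = rng.normal(0.3, 0.1, k)
        sy = np.full(k, 0.05)
        by = 0.5 * bx + rng.normal(0, sy)
        full = mr_ivw(bx, None, by, sy)
        drop = mr_ivw(np.delete(bx, 3), None, np.delete(by, 3), np.delete(sy, 3))
        assert abs(full.estimate - drop.estimate) < full.se

    def test_global_p_uniform_under_null(self, rng):
        ps = []
        for rep in range(200):
            k = 20
            bx = rng.normal(0.3, 0.1, k)
            sy = np.full(k, 0.05)
            by = 0.4 * bx + rng.normal(0, sy)
            _, _, global_p = mr_presso(
                bx, None, by, sy, nb_distribution=500, seed=1000 + rep
            )
            ps.append(global_p)
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.01


class TestConsensus:
    @staticmethod
    def _pair(exposure, outcome, p_ivw, p_egger, p_presso):
        from kovariome.mr import MRMethodResult, MRPair

        pr = MRPair(exposure, outcome, 10)
        pr.ivw = MRMethodResult(0.5, 0.1, p_ivw)
        pr.egger = MRMethodResult(0.5, 0.2, p_egger)
        pr.presso = MRMethodResult(0.5, 0.1, p_presso)
        return pr

    def test_single_method_is_not_consensus(self):
        out = consensus_mr([self._pair("a", "b", 1e-6, 0.9, 0.9)])
        assert not bool(out.loc[0, "consensus_significant"])

    def test_two_methods_make_consensus(self):
        out = consensus_mr([self._pair("a", "b", 1e-6, 0.9, 1e-5)])
        assert bool(out.loc[0, "consensus_significant"])

    def test_direction_labels(self):
        out = consensus_mr(
            [
                self._pair("a", "b", 1e-6, 0.9, 1e-5),   # consensus forward
                self._pair("b", "a", 0.9, 0.9, 0.9),     # reverse not
                self._pair("c", "d", 1e-6, 1e-6, 1e-6),  # consensus forward
                self._pair("d", "c", 1e-6, 1e-6, 1e-6),  # and reverse
            ]
        )
        by_pair = out.set_index(["exposure", "outcome"])["direction"]
        assert by_pair[("a", "b")] == "unidirectional"
        assert by_pair[("c", "d")] == "bidirectional"
        assert by_pair[("d", "c")] == "bidirectional"

    def test_causal_chain_direction_recovery(self):
        # individual-level simulation: exposure with 30 causal variants,
        # outcome = 0.5 * exposure + noise; both scanned genome-wide
        from kovariome.gwas import run_gwas

        fwd_hits, rev_hits = 0, 0
        n_reps = 20
        for rep in range(n_reps):
            rng = np.random.default_rng(300 + rep)
            cfg = CohortConfig(
                n_samples=1200, n_variants=400, missing_rate=0.0,
                n_chromosomes=4, variant_spacing=600_000, seed=300 + rep,
            )
            gm, _ = simulate_genotypes(cfg)
            causal = rng.choice(400, 30, replace=False)
            z = gm.dosages[:, causal].astype(float)
            z = (z - z.mean(0)) / np.where(z.std(0) > 0, z.std(0), 1)
            gx = z @ rng.normal(0, 1, 30)
            x = gx * np.sqrt(0.3) / gx.std() + rng.standard_normal(1200) * np.sqrt(0.7)
            y = 0.5 * x + rng.standard_normal(1200)
            ssx = run_gwas(gm, x, trait_name="exposure")
            ssy = run_gwas(gm, y, trait_name="outcome")
            fwd = run_mr_pair("exposure", "outcome", ssx, ssy, gm, seed=rep,
                              nb_distribution=1000)
            rev = run_mr_pair("outcome", "exposure", ssy, ssx, gm, seed=rep,
                              nb_distribution=1000)
            res = consensus_mr([fwd, rev]).set_index("exposure")
            fwd_hits += bool(res.loc["exposure", "consensus_significant"])
            rev_hits += bool(res.loc["outcome", "consensus_significant"])
        assert fwd_hits >= 0.8 * n_reps
        assert rev_hits < 0.2 * n_reps
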