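"""Windowed statistics against textbook-formula oracles, boundary exactness,
quantile candidate calling and interval extension/merging."""

import math

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import make_matrix
from sweepscan.scan import (
    WindowSpec,
    call_candidates,
    compute_window_stats,
    extend_and_merge,
    make_windows,
    pi_ratio,
    pi_window,
    sites_in_windows,
    tajimas_d_window,
    wc_fst_window,
)
from sweepscan.sim import SimConfig, simulate_two_pop
from sweepscan.types import MISSING


def _random_window(rng, n1=20, n2=20, n_sites=50, missing=0.05):
    d = rng.integers(0, 3, size=(n1 + n2, n_sites)).astype(np.int8)
    d[rng.random(d.shape) < missing] = MISSING
    return d


class TestMakeWindows:
    def test_tiling_arithmetic(self):
        w = make_windows({"chr1": 250_000}, WindowSpec(100_000, 10_000))
        assert len(w) == 25
        assert (w.iloc[0][["start", "end"]] == [0, 100_000]).all()
        assert (w.iloc[-1][["start", "end"]] == [240_000, 250_000]).all()

    def test_short_chromosome_single_clipped_window(self):
        w = make_windows({"c": 5_000}, WindowSpec(100_000, 10_000))
        assert len(w) == 1
        assert w.iloc[0]["end"] == 5_000

    def test_interior_snp_in_exactly_ten_windows(self):
        w = make_windows({"chr1": 1_000_000}, WindowSpec(100_000, 10_000))
        pos = 500_000  # 1-based
        hits = ((w["start"] <= pos - 1) & (pos - 1 < w["end"])).sum()
        assert hits == 10


class TestWcFst:
    def test_identical_populations_near_zero(self):
        """Two independent samples from one undifferentiated population: the
        window estimate is ~0 (the bias correction cancels sampling noise)."""
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, 500)
        d = rng.binomial(2, p, size=(40, 500)).astype(np.int8)
        fst = wc_fst_window(d, np.arange(20), np.arange(20, 40))
        assert abs(fst) < 0.02

    def test_duplicated_columns_show_known_negative_bias(self):
        """Literally duplicating the same genotype columns into both
        populations makes s^2 exactly 0, so the estimator goes slightly
        negative by its finite-sample correction term — a property, not a
        bug (negative F_ST is deliberately not clamped)."""
        rng = np.random.default_rng(1)
        half = rng.integers(0, 3, size=(20, 200)).astype(np.int8)
        d = np.vstack([half, half])
        fst = wc_fst_window(d, np.arange(20), np.arange(20, 40))
        assert -0.06 < fst < 0.0

    def test_fixed_differences_give_one(self):
        d = np.vstack([np.zeros((20, 50)), np.full((20, 50), 2)]).astype(np.int8)
        fst = wc_fst_window(d, np.arange(20), np.arange(20, 40))
        assert fst == pytest.approx(1.0)

    def test_matches_oracle_on_random_windows(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            d = _random_window(rng)
            i1, i2 = np.arange(20), np.arange(20, 40)
            ours = wc_fst_window(d, i1, i2)
            ref = oracles.wc_fst_window(
                [d[i1, j].tolist() for j in range(d.shape[1])],
                [d[i2, j].tolist() for j in range(d.shape[1])],
            )
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_invariant_to_population_label_swap(self):
        rng = np.random.default_rng(3)
        d = _random_window(rng)
        i1, i2 = np.arange(20), np.arange(20, 40)
        assert wc_fst_window(d, i1, i2) == pytest.approx(
            wc_fst_window(d, i2, i1), abs=1e-12
        )


class TestPi:
    def test_hand_expansion_half_frequency(self):
        # 2 diploids with doses {0, 2}: 4 chromosomes at p = 0.5, k sites
        k = 7
        d = np.vstack([np.zeros((1, k)), np.full((1, k), 2)]).astype(np.int8)
        got = pi_window(d, np.arange(2), 100_000)
        assert got == pytest.approx((2.0 * k / 3.0) / 100_000)

    def test_monomorphic_window_zero(self):
        d = np.full((10, 20), 2, dtype=np.int8)
        assert pi_window(d, np.arange(10), 100_000) == 0.0

    def test_matches_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            d = _random_window(rng)
            ours = pi_window(d, np.arange(20), 50_000)
            ref = oracles.pi_window(
                [d[:20, j].tolist() for j in range(d.shape[1])], 50_000
            )
            assert ours == pytest.approx(ref, abs=1e-10)


class TestPiRatio:
    def test_equal_diversity_gives_one(self):
        assert pi_ratio(0.01, 0.01) == 1.0

    def test_zero_target_is_plus_infinity(self):
        assert pi_ratio(0.0, 0.01) == math.inf

    def test_zero_zero_invalid(self):
        assert math.isnan(pi_ratio(0.0, 0.0))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        d = np.zeros((20, 30), dtype=np.int8)
        assert math.isnan(tajimas_d_window(d, np.arange(20)))

    def test_too_few_chromosomes_undefined(self):
        d = np.array([[0, 1, 0], [1, 0, 1]], dtype=np.int8)
        d[1, :] = MISSING  # one diploid left -> 2 chromosomes < 4
        assert math.isnan(tajimas_d_window(d, np.arange(2)))

    def test_matches_constants_from_scratch_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            d = _random_window(rng)
            ours = tajimas_d_window(d, np.arange(20))
            ref = oracles.tajimas_d(
                [d[:20, j].tolist() for j in range(d.shape[1])]
            )
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_invariant_to_site_and_sample_order(self):
        rng = np.random.default_rng(6)
        d = _random_window(rng)
        idx = np.arange(20)
        base = tajimas_d_window(d, idx)
        perm_sites = rng.permutation(d.shape[1])
        perm_samples = rng.permutation(20)
        assert tajimas_d_window(d[:, perm_sites], idx) == pytest.approx(base, abs=1e-12)
        assert tajimas_d_window(d[perm_samples][:, perm_sites], np.arange(20)) == \
            pytest.approx(base, abs=1e-12)


class TestWindowScanIntegration:
    def test_sweep_signature_in_all_three_statistics(self, sweep_cohort):
        _, g, pops, truth, sweep = sweep_cohort
        stats = compute_window_stats(g, pops, "pop1", WindowSpec())
        valid = stats[stats["valid"]]
        inside = valid[
            (valid["chrom"] == sweep.chrom)
            & (valid["start"] < sweep.end)
            & (valid["end"] > sweep.start - 1)
        ]
        outside = valid.drop(inside.index)
        assert inside["fst"].mean() > outside["fst"].mean()
        finite_ratio = inside["pi_ratio"].replace(np.inf, np.nan).dropna()
        assert (
            np.nanmean(finite_ratio) > np.nanmedian(outside["pi_ratio"])
            or np.isinf(inside["pi_ratio"]).any()
        )
        assert inside["tajima_d"].mean() < valid["tajima_d"].mean()

    def test_pi_ratio_inverts_under_target_swap(self, small_cohort):
        _, g, pops, _ = small_cohort
        s1 = compute_window_stats(g, pops, "pop1", WindowSpec())
        s2 = compute_window_stats(g, pops, "pop2", WindowSpec())
        assert np.allclose(s1["fst"], s2["fst"], equal_nan=True)
        m = s1["valid"] & (s1["pi_ratio"] > 0) & np.isfinite(s1["pi_ratio"]) \
            & np.isfinite(s2["pi_ratio"])
        assert np.allclose(
            s1.loc[m, "pi_ratio"], 1.0 / s2.loc[m, "pi_ratio"], rtol=1e-9
        )

    def test_sample_order_invariance(self, small_cohort):
        _, g, pops, _ = small_cohort
        rng = np.random.default_rng(8)
        perm = rng.permutation(g.n_samples)
        g2 = g.take_samples(perm)
        s1 = compute_window_stats(g, pops, "pop1", WindowSpec())
        s2 = compute_window_stats(g2, pops, "pop1", WindowSpec())
        pd.testing.assert_frame_equal(s1, s2)


class TestCallCandidates:
    def _stats_frame(self, fst, ratio, taj):
        n = len(fst)
        return pd.DataFrame({
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * 10_000,
            "end": np.arange(n) * 10_000 + 100_000,
            "n_snps": [50] * n,
            "fst": fst, "pi_pop1": 0.01, "pi_pop2": 0.01,
            "pi_ratio": ratio, "tajima_d": taj, "valid": True,
        })

    def _matrix_for(self, n_windows):
        # one SNP per window start to make site bookkeeping trivial
        pos = np.arange(n_windows) * 10_000 + 1
        d = np.zeros((4, n_windows), dtype=np.int8)
        d[0] = 1
        return make_matrix(d, positions=pos, chrom_length=n_windows * 10_000 + 200_000)

    def test_identical_rankings_select_exactly_top_k(self):
        vals = np.arange(100, dtype=float)
        stats = self._stats_frame(vals, vals, vals)
        g = self._matrix_for(100)
        joint, taj = call_candidates(stats, g, q=0.05)
        assert len(joint.windows) == 5
        assert set(joint.windows["fst"]) == set(vals[-5:])
        assert len(taj.windows) == 5
        assert set(taj.windows["tajima_d"]) == set(vals[:5])

    def test_constant_statistic_ties_select_all(self):
        vals = np.ones(40)
        stats = self._stats_frame(vals, vals, vals)
        g = self._matrix_for(40)
        joint, taj = call_candidates(stats, g, q=0.05)
        assert len(joint.windows) == 40
        assert len(taj.windows) == 40

    def test_infinite_pi_ratio_ranks_top(self):
        fst = np.arange(40, dtype=float)
        ratio = np.ones(40)
        ratio[39] = np.inf
        taj = np.arange(40, dtype=float)
        stats = self._stats_frame(fst, ratio, taj)
        g = self._matrix_for(40)
        joint, _ = call_candidates(stats, g, q=0.025)
        assert len(joint.windows) == 1
        assert np.isinf(joint.windows["pi_ratio"]).all()

    def test_candidate_sites_lie_in_candidate_windows(self, sweep_cohort):
        _, g, pops, _, _ = sweep_cohort
        stats = compute_window_stats(g, pops, "pop1", WindowSpec())
        joint, taj = call_candidates(stats, g, q=0.05)
        for cs in (joint, taj):
            assert len(cs.sites) > 0
            recovered = sites_in_windows(g, cs.windows)
            pd.testing.assert_frame_equal(cs.sites, recovered)


class TestExtendAndMerge:
    def _candidates(self, positions, chrom_length=10_000_000):
        from sweepscan.scan import CandidateSet

        sites = pd.DataFrame({"chrom": ["chr1"] * len(positions), "pos": positions})
        return CandidateSet("fst_pi_joint", "pop1", pd.DataFrame(), sites), \
            {"chr1": chrom_length}

    def test_two_sites_60kb_apart_merge(self):
        cand, lengths = self._candidates([100_000, 160_000])
        regions = extend_and_merge(cand, lengths, flank=50_000)
        assert len(regions) == 1
        row = regions.iloc[0]
        assert (row["start"], row["end"]) == (49_999, 210_000)
        assert row["end"] - row["start"] == 160_001

    def test_single_site_region_length(self):
        cand, lengths = self._candidates([5_000_000])
        regions = extend_and_merge(cand, lengths, flank=50_000)
        assert regions.iloc[0]["end"] - regions.iloc[0]["start"] == 100_001

    def test_clipping_at_chromosome_edges(self):
        cand, lengths = self._candidates([10_000], chrom_length=30_000)
        regions = extend_and_merge(cand, lengths, flank=50_000)
        assert regions.iloc[0]["start"] == 0
        assert regions.iloc[0]["end"] == 30_000

    def test_distant_sites_stay_separate_and_sorted(self):
        cand, lengths = self._candidates([200_000, 1_000_000])
        regions = extend_and_merge(cand, lengths, flank=50_000)
        assert len(regions) == 2
        assert (regions["start"].to_numpy()[1:] >= regions["end"].to_numpy()[:-1]).all()


class TestNullCalibration:
    def test_joint_fraction_near_q_squared(self):
        """Under F = 0 the joint top-5% fraction should sit near q^2 and the
        Tajima bottom-5% fraction near q (bounds use the ~window/step-fold
        correlation of overlapping windows)."""
        q = 0.05
        joint_n = taj_n = valid_n = 0
        n_reps = 20
        for rep in range(n_reps):
            cfg = SimConfig(chrom_lengths={"chr1": 2_000_000}, baseline_F=0.0,
                            missing_rate=0.02, seed=9000 + rep)
            g, pops, _ = simulate_two_pop(cfg)
            stats = compute_window_stats(g, pops, "pop1", WindowSpec())
            joint, taj = call_candidates(stats, g, q=q)
            valid_n += int(stats["valid"].sum())
            joint_n += len(joint.windows)
            taj_n += len(taj.windows)
        # ~20 effectively independent windows per 2 Mb replicate
        n_eff = n_reps * 20
        for frac, p in ((joint_n / valid_n, q * q), (taj_n / valid_n, q)):
            se = math.sqrt(p * (1 - p) / n_eff)
            assert abs(frac - p) <= 4 * se + 1e-9, (frac, p)
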