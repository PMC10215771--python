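import dataclasses

import numpy as np
import pytest

import rohkit as rk
from rohkit.genotype_io import MISSING
from rohkit.roh import ROHSegment, segments_to_frame

from conftest import make_matrix
from oracles import call_roh_bruteforce, hit_fractions_bruteforce


def random_instance(rng, n_snps):
    """Genotype vector mixing homozygous tracts, het noise and missingness."""
    calls = rng.choice([0, 2], size=n_snps).astype(np.int8)
    n_tracts = rng.integers(0, 4)
    boundaries = np.sort(rng.integers(0, n_snps, size=2 * n_tracts))
    het_mask = rng.random(n_snps) < rng.uniform(0.05, 0.5)
    for k in range(n_tracts):
        het_mask[boundaries[2 * k] : boundaries[2 * k + 1]] = False
    calls[het_mask] = 1
    calls[rng.random(n_snps) < 0.03] = MISSING
    pos = np.sort(rng.choice(np.arange(1, 3_000_000, 7), size=n_snps, replace=False))
    return calls, pos


class TestWindowScan:
    def test_all_homozygous_gives_fraction_one(self):
        frac = rk.window_scan(np.zeros(60, dtype=np.int8))
        assert (frac == 1.0).all()

    def test_all_het_gives_fraction_zero(self):
        frac = rk.window_scan(np.ones(60, dtype=np.int8))
        assert (frac == 0.0).all()

    def test_short_chromosome_gives_zeros(self):
        assert (rk.window_scan(np.zeros(10, dtype=np.int8)) == 0.0).all()

    def test_matches_window_enumeration_oracle(self):
        calls = np.zeros(120, dtype=np.int8)
        calls[[10, 55, 90]] = 1
        params = rk.ROHParams()
        expected = hit_fractions_bruteforce(calls, 50, 1, 5)
        assert np.allclose(rk.window_scan(calls, params), expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        calls, _ = random_instance(rng, 150)
        params = rk.ROHParams(window_snps=20, window_max_het=1, window_max_missing=2)
        expected = hit_fractions_bruteforce(calls, 20, 1, 2)
        assert np.allclose(rk.window_scan(calls, params), expected)


CHROM_LENGTHS = {"1": 5_000_000}


class TestCallROH:
    def test_fully_homozygous_individual_single_run(self):
        pos = np.linspace(1_000, 250_000, 60).astype(int)
        m = make_matrix(np.zeros((1, 60), dtype=np.int8), positions=pos)
        segs = rk.call_roh(m, CHROM_LENGTHS)
        assert len(segs) == 1
        (s,) = segs
        assert (s.start, s.end, s.n_snps) == (1_000, 250_000, 60)
        assert s.length == 249_001

    def test_fully_heterozygous_individual_no_runs(self):
        pos = np.linspace(1_000, 250_000, 60).astype(int)
        m = make_matrix(np.ones((1, 60), dtype=np.int8), positions=pos)
        assert rk.call_roh(m, CHROM_LENGTHS) == []

    def test_large_gap_splits_segment(self):
        # two homozygous tracts separated by a 2 Mb SNP desert
        pos = np.concatenate(
            [np.arange(1_000, 601_000, 10_000), np.arange(2_601_000, 3_201_000, 10_000)]
        )
        calls = np.zeros((1, pos.size), dtype=np.int8)
        m = make_matrix(calls, positions=pos)
        segs = rk.call_roh(m, CHROM_LENGTHS)
        assert len(segs) == 2
        assert [(s.start, s.end) for s in segs] == [(1_000, 591_000), (2_601_000, 3_191_000)]
        expected = call_roh_bruteforce(calls[0], pos, rk.ROHParams())
        assert [(s.start, s.end, s.n_snps) for s in segs] == expected

    def test_missing_chromosome_length_rejected(self):
        m = make_matrix(np.zeros((1, 60), dtype=np.int8), chroms=["7"] * 60)
        with pytest.raises(KeyError):
            rk.call_roh(m, CHROM_LENGTHS)

    @pytest.mark.parametrize("seed", range(20))
    def test_set_equality_with_bruteforce_caller(self, seed):
        rng = np.random.default_rng(1_000 + seed)
        n_snps = int(rng.integers(40, 300))
        calls, pos = random_instance(rng, n_snps)
        params = rk.ROHParams(
            window_snps=int(rng.choice([10, 20, 50])),
            min_snps=int(rng.choice([10, 30, 50])),
            min_length=int(rng.choice([50_000, 100_000])),
            window_max_het=int(rng.choice([0, 1, 2])),
            window_max_missing=int(rng.choice([1, 5])),
        )
        m = make_matrix(calls[None, :], positions=pos)
        got = {(s.start, s.end, s.n_snps) for s in rk.call_roh(m, CHROM_LENGTHS, params)}
        expected = set(call_roh_bruteforce(calls, pos, params))
        assert got == expected

    def test_raising_thresholds_only_removes_segments(self):
        rng = np.random.default_rng(9)
        calls, pos = random_instance(rng, 280)
        m = make_matrix(calls[None, :], positions=pos)
        base = rk.ROHParams(window_snps=20, min_snps=20, min_length=50_000)
        loose = {(s.start, s.end) for s in rk.call_roh(m, CHROM_LENGTHS, base)}
        for stricter in (
            dataclasses.replace(base, min_snps=40),
            dataclasses.replace(base, min_length=200_000),
        ):
            tight = {(s.start, s.end) for s in rk.call_roh(m, CHROM_LENGTHS, stricter)}
            assert tight <= loose


class TestClassification:
    @staticmethod
    def seg(length, ind="a"):
        return ROHSegment(ind, "1", 1, length, max(1, length // 5_000))

    def test_one_segment_per_class(self):
        segs = [self.seg(int(mb * 1e6)) for mb in (0.5, 1.5, 2.5, 3.5)]
        t = rk.classify_lengths(segs).table
        assert t.loc[["0-1 Mb", "1-2 Mb", "2-3 Mb", ">3 Mb"], "count"].tolist() == [1, 1, 1, 1]
        assert t.loc["0-1 Mb", "pct_count"] == pytest.approx(25.0)

    def test_exact_megabase_falls_in_upper_class(self):
        t = rk.classify_lengths([self.seg(1_000_000)]).table
        assert t.loc["1-2 Mb", "count"] == 1 and t.loc["0-1 Mb", "count"] == 0

    def test_single_short_segment_holds_everything(self):
        t = rk.classify_lengths([self.seg(900_000)]).table
        assert t.loc["0-1 Mb", "pct_count"] == pytest.approx(100.0)
        assert t.loc["0-1 Mb", "pct_cum_length"] == pytest.approx(100.0)

    def test_counts_match_histogram_oracle(self):
        rng = np.random.default_rng(10)
        lengths = rng.integers(100_000, 5_000_000, size=1_000)
        t = rk.classify_lengths([self.seg(int(l)) for l in lengths]).table
        edges = [0, 1e6, 2e6, 3e6, np.inf]
        for (label, lo, hi) in zip(["0-1 Mb", "1-2 Mb", "2-3 Mb", ">3 Mb"], edges[:-1], edges[1:]):
            assert t.loc[label, "count"] == np.sum((lengths >= lo) & (lengths < hi))
        assert t.loc["total", "count"] == 1_000
        assert t["count"].drop("total").sum() == t.loc["total", "count"]

    def test_empty_segment_list_gives_zero_summary(self):
        t = rk.classify_lengths([]).table
        assert (t["count"] == 0).all()


class TestCoverage:
    def test_direct_ratio(self):
        segs = [ROHSegment("a", "1", 1, 250_000, 50)]
        cov = rk.chromosome_coverage(segs, {"1": 1_000_000}, n_individuals=1)
        assert cov["1"] == pytest.approx(0.25)

    def test_chromosome_without_segments_is_zero(self):
        cov = rk.chromosome_coverage([], {"1": 1_000_000}, n_individuals=3)
        assert cov["1"] == 0.0

    def test_equals_mean_of_per_individual_coverage(self):
        rng = np.random.default_rng(11)
        segs = []
        for ind in ("a", "b", "c"):
            start = 1
            for _ in range(rng.integers(1, 4)):
                start += int(rng.integers(10_000, 200_000))
                end = start + int(rng.integers(100_000, 400_000))
                segs.append(ROHSegment(ind, "1", start, end, 60))
                start = end
        cl = {"1": 5_000_000}
        cov = rk.chromosome_coverage(segs, cl, n_individuals=3)
        per_ind = [
            sum(s.length for s in segs if s.individual == ind) / cl["1"]
            for ind in ("a", "b", "c")
        ]
        assert cov["1"] == pytest.approx(np.mean(per_ind))


class TestSweepAndRecovery:
    def test_degenerate_grid_equals_single_run(self, mixed_cohort):
        m, cl = mixed_cohort["matrix"], mixed_cohort["chrom_lengths"]
        sw = rk.sensitivity_sweep(m, cl, window_snps_grid=(50,))
        single = rk.classify_lengths(mixed_cohort["segments"]).table
        for label in single.index:
            got = sw[(sw["window_snps"] == 50) & (sw["class"] == label)]["count"].iloc[0]
            assert got == single.loc[label, "count"]

    def test_all_homozygous_fixture_stable_across_grid(self):
        pos = np.arange(1, 1_500_000, 5_000)
        m = make_matrix(np.zeros((2, pos.size), dtype=np.int8), positions=pos)
        sw = rk.sensitivity_sweep(m, CHROM_LENGTHS, window_snps_grid=(50, 100))
        totals = sw[sw["class"] == "total"].set_index("window_snps")["count"]
        assert totals[50] == totals[100] == 2

    def test_true_autozygous_tracts_recovered(self, mixed_cohort):
        """>=90% of truth tracts >=0.5 Mb have a called segment overlapping
        them >=80% reciprocally."""
        truth = mixed_cohort["truth"].segments
        truth = truth[(truth["end"] - truth["start"] + 1) >= 500_000]
        called = segments_to_frame(mixed_cohort["segments"])
        n_hit = 0
        for t in truth.itertuples(index=False):
            t_len = t.end - t.start + 1
            sub = called[(called["individual"] == t.individual) & (called["chrom"] == t.chrom)]
            for c in sub.itertuples(index=False):
                ov = min(t.end, c.end) - max(t.start, c.start) + 1
                if ov >= 0.8 * t_len and ov >= 0.8 * c.length_bp:
                    n_hit += 1
                    break
        assert n_hit >= 0.9 * len(truth)
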