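"""Somatic filtering and the windowed exact binomial LOH test."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hicphaser import preprocess
from hicphaser.io_formats import SnpRecord
from hicphaser.preprocess import (LohRegion, NormalProfile, call_loh,
                                  drop_loh_snps, filter_somatic, loh_test,
                                  non_loh_stretches)


def binom_tail_oracle(n, k, p):
    """Independent brute-force lower-tail summation of the binomial pmf."""
    total = 0.0
    for i in range(k + 1):
        total += math.comb(n, i) * p ** i * (1 - p) ** (n - i)
    return total


def _snp(pos, genotype="het", chrom="chr1"):
    return SnpRecord(chrom, pos, "A", "G", genotype)


class TestFilterSomatic:
    def test_set_membership(self):
        snps = [_snp(p) for p in (10, 20, 30, 40, 50)]
        known = {("chr1", p, "A", "G") for p in (10, 30, 50)}
        kept, removed = filter_somatic(snps, known)
        assert [s.pos for s in kept] == [10, 30, 50]
        assert removed == 2
        assert all(s.is_known_germline for s in kept)

    def test_empty_known_sites_removes_all(self):
        kept, removed = filter_somatic([_snp(10)], set())
        assert kept == [] and removed == 1

    def test_key_includes_alleles(self):
        snps = [_snp(10)]
        known = {("chr1", 10, "A", "T")}  # same position, other alt
        kept, _ = filter_somatic(snps, known)
        assert kept == []


class TestLohTest:
    def test_full_cdf_is_one(self):
        assert loh_test(100, 100, 0.6) == pytest.approx(1.0)

    def test_non_loh_example(self):
        # at the null expectation, the lower tail sits near 0.5
        p = loh_test(100, 60, 0.6)
        assert p == pytest.approx(binom_tail_oracle(100, 60, 0.6), abs=1e-12)
        assert p > 0.05

    def test_depleted_window_is_significant(self):
        p = loh_test(100, 45, 0.6)
        assert p == pytest.approx(binom_tail_oracle(100, 45, 0.6), abs=1e-12)
        assert p < 0.05

    def test_matches_bruteforce_on_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 400))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            assert loh_test(n, k, p) == pytest.approx(
                binom_tail_oracle(n, k, p), abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_profile_rejected(self, p):
        with pytest.raises(ValueError):
            loh_test(100, 10, p)

    @given(st.integers(2, 200), st.floats(0.05, 0.95))
    def test_monotone_in_n_het(self, n, p):
        vals = [loh_test(n, k, p) for k in range(n + 1)]
        assert all(a <= b + 1e-15 for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.0)


def _window_snps(window_specs, window_bp=1000):
    """window_specs: list of (n_total, n_het) per consecutive window."""
    snps = []
    for w, (n_total, n_het) in enumerate(window_specs):
        start = w * window_bp
        for i in range(n_total):
            geno = "het" if i < n_het else "hom_alt"
            snps.append(_snp(start + i + 1, geno))
    return snps


class TestCallLoh:
    def test_run_merging(self):
        # windows: non, LOH, LOH, non  ->  one merged region over 2-3
        snps = _window_snps([(50, 30), (50, 2), (50, 2), (50, 30)])
        profile = NormalProfile(default_p=0.6)
        windows, regions = call_loh(snps, profile, window_bp=1000,
                                    min_snps=10)
        assert [w.label for w in windows] == \
            ["non-LOH", "LOH", "LOH", "non-LOH"]
        assert [(r.start, r.end) for r in regions] == [(1000, 3000)]

    def test_all_non_loh(self):
        snps = _window_snps([(50, 30), (50, 31)])
        _, regions = call_loh(snps, NormalProfile(default_p=0.6),
                              window_bp=1000, min_snps=10)
        assert regions == []

    def test_window_union_equals_region_union(self):
        snps = _window_snps([(50, 2), (50, 30), (50, 2), (50, 2), (50, 30)])
        windows, regions = call_loh(snps, NormalProfile(default_p=0.6),
                                    window_bp=1000, min_snps=10)
        loh_windows = {(w.start, w.end) for w in windows
                       if w.label == "LOH"}
        covered = set()
        for r in regions:
            for s in range(r.start, r.end, 1000):
                covered.add((s, s + 1000))
        assert covered == loh_windows

    def test_insufficient_windows_inherit_nearest_label(self):
        # sparse middle window inherits; tie between LOH/non goes to LOH
        snps = _window_snps([(50, 2), (3, 3), (50, 30)])
        windows, _ = call_loh(snps, NormalProfile(default_p=0.6),
                              window_bp=1000, min_snps=10)
        assert windows[1].label == "LOH"

    def test_sparse_chromosome_end_inherits(self):
        snps = _window_snps([(50, 2), (2, 1)])
        windows, regions = call_loh(snps, NormalProfile(default_p=0.6),
                                    window_bp=1000, min_snps=10)
        assert [w.label for w in windows] == ["LOH", "LOH"]
        assert [(r.start, r.end) for r in regions] == [(0, 2000)]

    def test_missing_chromosome_raises(self):
        snps = [_snp(10)]
        with pytest.raises(KeyError):
            call_loh(snps, NormalProfile(table={("chr2", 0): 0.5}))

    def test_planted_loh_recovered_at_window_resolution(self, small_truth):
        """Synthetic truth: LOH interval recovered window-exactly."""
        snps = [s for s in small_truth.snp_records()
                if s.is_known_germline]
        profile = NormalProfile(default_p=0.6)
        _, regions = call_loh(snps, profile, window_bp=1_000_000,
                              min_snps=10,
                              chrom_length=small_truth.params.length_bp)
        assert [(r.start, r.end) for r in regions] == \
            small_truth.loh_intervals


class TestDropAndStretches:
    def test_boundary_conventions(self):
        region = LohRegion("chr1", 1000, 2000)
        snps = [_snp(1000), _snp(1001), _snp(2000), _snp(2001)]
        kept = drop_loh_snps(snps, [region])
        # pos 1001 is the first base inside [1000, 2000); pos 2001 is out
        assert [s.pos for s in kept] == [1000, 2001]

    def test_no_regions_identity(self):
        snps = [_snp(5), _snp(10)]
        assert drop_loh_snps(snps, []) == snps

    def test_stretch_partitioning(self):
        snps = [_snp(p) for p in (100, 200, 3100, 3200)]
        regions = [LohRegion("chr1", 1000, 3000)]
        stretches = non_loh_stretches([0, 1, 2, 3], snps, regions)
        assert stretches == [[0, 1], [2, 3]]


class TestNullCalibration:
    def test_type_i_error_conservative(self):
        """Exact lower-tail test never exceeds its nominal level."""
        rng = np.random.default_rng(99)
        n, p, alpha = 100, 0.6, 0.05
        k = rng.binomial(n, p, size=2000)
        crit = np.array([loh_test(n, int(x), p) for x in range(n + 1)])
        rate = float((crit[k] < alpha).mean())
        assert rate <= alpha
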