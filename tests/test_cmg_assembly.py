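"""Coverage matching graph, edge weights and Min-Multi-Cut solvers."""

import itertools
import math

import numpy as np
import pytest

from hicphaser.cmg_assembly import (CmGraph, allele_coverage_by_haplotype,
                                    apply_cut, brute_force_min_multi_cut,
                                    build_association_graph, build_cmg,
                                    candidate_pairs, edge_weights,
                                    edge_weights_unnormalized,
                                    maxcut_solution_from_cut, reduce_maxcut,
                                    reliability_filter, solve_min_multi_cut)
from hicphaser.io_formats import HicFragment, SnpRecord
from hicphaser.phasing import HaplotypeBlock


def frag(fid, *calls):
    return HicFragment(fid, [(i, a, 30) for i, a in calls])


def random_instance(rng, n_pairs, p_edge=0.6):
    bundles = {}
    for i in range(n_pairs):
        for j in range(i + 1, n_pairs):
            if rng.random() < p_edge:
                w = rng.random(4)
                w = w / w.sum()
                bundles[(i, j)] = {("a", "a"): w[0], ("a", "b"): w[1],
                                   ("b", "a"): w[2], ("b", "b"): w[3]}
    return CmGraph(snps=list(range(n_pairs)), bundles=bundles)


class TestAlleleCoverage:
    def test_tally_respects_phase(self):
        block = HaplotypeBlock("b", [0], [1])  # h1 carries alt at SNP 0
        frags = [frag(f"a{k}", (0, 1), (5, 0)) for k in range(30)] + \
            [frag(f"b{k}", (0, 0), (5, 0)) for k in range(10)]
        cov = allele_coverage_by_haplotype(frags, [block])
        assert cov[0] == (30, 10)

    def test_zero_call_snp_has_zero_counts(self):
        block = HaplotypeBlock("b", [3], [1])
        assert allele_coverage_by_haplotype([], [block]) == {3: (0, 0)}

    def test_imbalanced_simulation_mean_share(self):
        """2:1 allelic copy ratio shows up as mean a-share near 2/3.

        Uses an LOH-free instance: near LOH boundaries the surviving
        haplotype is over-represented, which would bias the genome-wide
        share."""
        from hicphaser.synthetic_data import (GenomeParams, simulate_genome,
                                              simulate_hic)

        truth = simulate_genome(GenomeParams(length_bp=3_000_000,
                                             loh_intervals=[]), seed=23)
        frags = simulate_hic(truth, 60_000, eps=0.0, seed=23)
        het = [i for i in range(truth.n_snps)
               if truth.genotype[i] == "het"]
        blocks = [HaplotypeBlock(f"s{i}", [i], [int(truth.allele_h1[i])])
                  for i in het]
        cov = allele_coverage_by_haplotype(frags, blocks)
        shares = [c[0] / (c[0] + c[1]) for c in cov.values()
                  if c[0] + c[1] >= 20]
        mean = float(np.mean(shares))
        sem = float(np.std(shares) / math.sqrt(len(shares)))
        assert abs(mean - 2 / 3) < 3 * max(sem, 1e-3)


class TestCandidatePairs:
    def _setup(self, positions, block_sizes, cov_value=(20, 20)):
        snps = [SnpRecord("chr1", p, "A", "G", "het") for p in positions]
        blocks, k = [], 0
        for b, size in enumerate(block_sizes):
            idx = list(range(k, k + size))
            blocks.append(HaplotypeBlock(f"b{b}", idx, [1] * size, 0))
            k += size
        coverage = {i: cov_value for i in range(len(positions))}
        return snps, blocks, coverage

    def test_distance_threshold(self):
        snps, blocks, cov = self._setup([100, 1_300_000], [1, 1])
        blocks[0] = HaplotypeBlock("b0", [0], [1])
        assert candidate_pairs(snps, blocks, cov, min_block=1) == []

    def test_min_coverage_strictly_above(self):
        snps, blocks, cov = self._setup([100, 200], [1, 1])
        cov[1] = (20, 8)
        assert candidate_pairs(snps, blocks, cov, min_block=1) == []
        cov[1] = (20, 11)
        assert candidate_pairs(snps, blocks, cov, min_block=1) == [(0, 1)]

    def test_min_block_needs_one_large_side(self):
        snps, blocks, cov = self._setup([100 * (i + 1) for i in range(6)],
                                        [3, 3])
        assert candidate_pairs(snps, blocks, cov, min_block=4) == []
        assert candidate_pairs(snps, blocks, cov, min_block=3) != []

    def test_matches_bruteforce_eligibility(self):
        rng = np.random.default_rng(17)
        positions = np.sort(rng.choice(np.arange(1, 3_000_000), size=60,
                                       replace=False))
        snps = [SnpRecord("chr1", int(p), "A", "G", "het")
                for p in positions]
        block_of = rng.integers(0, 4, size=60)
        blocks = []
        for b in range(4):
            idx = [i for i in range(60) if block_of[i] == b]
            blocks.append(HaplotypeBlock(f"b{b}", idx, [1] * len(idx), 0))
        coverage = {i: (int(rng.integers(5, 40)), int(rng.integers(5, 40)))
                    for i in range(60)}
        kw = dict(max_dist=500_000, n_nearest=3, min_block=12, min_cov=10)
        got = set(candidate_pairs(snps, blocks, coverage, **kw))

        def brute_nearest(i):
            others = [(abs(int(positions[j]) - int(positions[i])), j)
                      for j in range(60)
                      if block_of[j] != block_of[i]
                      and abs(int(positions[j]) - int(positions[i]))
                      <= kw["max_dist"]]
            others.sort()
            return {j for _, j in others[:kw["n_nearest"]]}

        near = {i: brute_nearest(i) for i in range(60)}
        expected = set()
        for i in range(60):
            for j in range(i + 1, 60):
                if block_of[i] == block_of[j]:
                    continue
                if abs(int(positions[j]) - int(positions[i])) \
                        > kw["max_dist"]:
                    continue
                if j not in near[i] or i not in near[j]:
                    continue
                if max(len(blocks[block_of[i]].snp_indices),
                       len(blocks[block_of[j]].snp_indices)) \
                        < kw["min_block"]:
                    continue
                if min(coverage[i] + coverage[j]) <= kw["min_cov"]:
                    continue
                expected.add((i, j))
        assert got == expected


class TestEdgeWeights:
    def test_as_printed_worked_example(self):
        raw = edge_weights_unnormalized((30, 10), (60, 20))
        assert raw[("a", "a")] == pytest.approx(9.26948, abs=1e-4)
        assert raw[("b", "b")] == pytest.approx(5.77078, abs=1e-4)
        assert raw[("a", "b")] == pytest.approx(14.86603, abs=1e-4)
        assert raw[("b", "a")] == pytest.approx(14.86603, abs=1e-4)
        norm = edge_weights((30, 10), (60, 20), "as-printed")
        assert sum(norm.values()) == pytest.approx(1.0, abs=1e-9)
        assert norm[("a", "a")] == pytest.approx(0.2070, abs=1e-4)

    def test_matched_support_worked_example(self):
        w = edge_weights((30, 10), (60, 20), "matched-support")
        assert w[("a", "a")] == pytest.approx(0.375, abs=1e-12)
        assert w[("b", "b")] == pytest.approx(0.375, abs=1e-12)
        assert w[("a", "b")] == pytest.approx(0.125, abs=1e-12)

    @pytest.mark.parametrize("mode", ["as-printed", "matched-support"])
    def test_symmetric_coverage_gives_quarter_weights(self, mode):
        w = edge_weights((20, 20), (15, 15), mode)
        for v in w.values():
            assert v == pytest.approx(0.25, abs=1e-12)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            edge_weights((0, 10), (5, 5))


class TestReliabilityFilter:
    def test_clear_orientation_kept(self):
        w = edge_weights((30, 10), (60, 20), "matched-support")
        assert reliability_filter(w) is True  # sums 0.75/0.25, ratio 1/3

    def test_even_split_removed(self):
        w = {("a", "a"): 0.25, ("b", "b"): 0.25,
             ("a", "b"): 0.25, ("b", "a"): 0.25}
        assert reliability_filter(w) is False

    def test_as_printed_worked_example_removed(self):
        w = edge_weights((30, 10), (60, 20), "as-printed")
        # sums 0.336 / 0.664 -> ratio ~0.506 > 0.4
        assert reliability_filter(w) is False


class TestBuildCmg:
    def _instance(self, rng=None):
        positions = list(range(1000, 1000 + 250 * 100, 100))
        snps = [SnpRecord("chr1", p, "A", "G", "het") for p in positions]
        b0 = HaplotypeBlock("b0", list(range(120)), [1] * 120, 0)
        b1 = HaplotypeBlock("b1", list(range(120, 250)), [0] * 130, 0)
        coverage = {i: (33, 11) for i in range(250)}  # 3:1 imbalance
        return snps, [b0, b1], coverage

    def test_construction_counts(self):
        snps, blocks, coverage = self._instance()
        g = build_cmg(snps, blocks, coverage)
        g.validate()
        assert len(g.inf_edges) == (120 - 1) + (130 - 1)
        assert len(g.bundles) > 0
        for bundle in g.bundles.values():
            assert sum(bundle.values()) == pytest.approx(1.0, abs=1e-9)

    def test_no_eligible_pairs_leaves_blocks_as_components(self):
        snps, blocks, coverage = self._instance()
        coverage = {i: (5, 5) for i in range(250)}  # below min_cov
        g = build_cmg(snps, blocks, coverage)
        assert g.bundles == {}
        sol = solve_min_multi_cut(g, M=1, seed=0)
        assert sorted(len(c) for c in sol.components) == [120, 130]


class TestAssociationGraph:
    @pytest.mark.parametrize("r1,expected", [
        (0.5, 1 / math.log(2)), (0.75, 1.77830)])
    def test_inverse_entropy_weight(self, r1, expected):
        g = CmGraph(snps=[0, 1], bundles={(0, 1): {
            ("a", "a"): r1 / 2, ("b", "b"): r1 / 2,
            ("a", "b"): (1 - r1) / 2, ("b", "a"): (1 - r1) / 2}})
        a = build_association_graph(g)
        assert a.edges[(0, 1)] == pytest.approx(expected, abs=1e-4)

    def test_extreme_r1_clamped_finite(self):
        g = CmGraph(snps=[0, 1], bundles={(0, 1): {
            ("a", "a"): 0.5, ("b", "b"): 0.5,
            ("a", "b"): 0.0, ("b", "a"): 0.0}})
        a = build_association_graph(g)
        assert math.isfinite(a.edges[(0, 1)])
        assert a.edges[(0, 1)] > 0


class TestSolvers:
    def two_pair_instance(self):
        return CmGraph(snps=[1, 2], bundles={(1, 2): {
            ("a", "a"): 5.0, ("b", "b"): 5.0,
            ("a", "b"): 1.0, ("b", "a"): 1.0}})

    def test_two_pair_optimum(self):
        g = self.two_pair_instance()
        for sol in (brute_force_min_multi_cut(g),
                    solve_min_multi_cut(g, M=20, seed=0)):
            assert sol.cut_weight == pytest.approx(2.0)
            assert sol.assignment[1] == sol.assignment[2]  # {1a,2a}|{1b,2b}

    def test_single_pair_no_edges(self):
        g = CmGraph(snps=[0])
        assert brute_force_min_multi_cut(g).cut_weight == 0.0

    def test_heuristic_never_beats_bruteforce(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            g = random_instance(rng, int(rng.integers(2, 8)))
            bf = brute_force_min_multi_cut(g)
            sol = solve_min_multi_cut(g, M=50,
                                      seed=int(rng.integers(2 ** 31)))
            assert sol.cut_weight >= bf.cut_weight - 1e-9

    def test_seed_determinism(self):
        rng = np.random.default_rng(8)
        g = random_instance(rng, 6)
        a = solve_min_multi_cut(g, M=25, seed=123)
        b = solve_min_multi_cut(g, M=25, seed=123)
        assert a.assignment == b.assignment
        assert a.cut_weight == b.cut_weight

    def test_solution_respects_inf_edges_and_pairs(self):
        rng = np.random.default_rng(9)
        g = random_instance(rng, 6)
        g.inf_edges = [(0, 1), (2, 3)]
        sol = solve_min_multi_cut(g, M=30, seed=4)
        # INF edges keep same-haplotype vertices on one side
        assert sol.assignment[0] == sol.assignment[1]
        assert sol.assignment[2] == sol.assignment[3]
        assert set(sol.assignment.values()) <= {0, 1}

    def test_m_validation(self):
        with pytest.raises(ValueError):
            solve_min_multi_cut(self.two_pair_instance(), M=0)


class TestMaxCutReduction:
    def brute_maxcut(self, edges, n):
        best = 0.0
        for bits in itertools.product((0, 1), repeat=n):
            cut = sum(w for i, j, w in edges if bits[i] != bits[j])
            best = max(best, cut)
        return best

    def test_triangle(self):
        edges = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)]
        g = reduce_maxcut(edges)
        assert brute_force_min_multi_cut(g).cut_weight == pytest.approx(1.0)

    def test_single_edge(self):
        g = reduce_maxcut([(0, 1, 3.0)])
        assert brute_force_min_multi_cut(g).cut_weight == pytest.approx(0.0)

    def test_empty_graph(self):
        g = reduce_maxcut([], vertices=[0, 1, 2])
        assert brute_force_min_multi_cut(g).cut_weight == 0.0

    def test_equivalence_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            edges = [(i, j, float(rng.integers(1, 10)))
                     for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.7]
            g = reduce_maxcut(edges, vertices=range(n))
            total = sum(w for _, _, w in edges)
            expect = total - self.brute_maxcut(edges, n)
            sol = brute_force_min_multi_cut(g)
            assert sol.cut_weight == pytest.approx(expect, abs=1e-9)
            # the recovered side set realises the same max cut
            side = maxcut_solution_from_cut(sol)
            cut = sum(w for i, j, w in edges
                      if (i in side) != (j in side))
            assert cut == pytest.approx(total - sol.cut_weight, abs=1e-9)


class TestApplyCut:
    def test_merged_orientation_matches_heavier_bundle(self):
        b0 = HaplotypeBlock("b0", [0, 1], [1, 0], 0)
        b1 = HaplotypeBlock("b1", [2, 3], [0, 1], 0)
        g = CmGraph(snps=[0, 1, 2, 3],
                    bundles={(1, 2): {("a", "a"): 0.4, ("b", "b"): 0.4,
                                      ("a", "b"): 0.1, ("b", "a"): 0.1}},
                    inf_edges=[(0, 1), (2, 3)])
        sol = solve_min_multi_cut(g, M=10, seed=0)
        (merged,) = apply_cut([b0, b1], sol)
        assert merged.snp_indices == [0, 1, 2, 3]
        # aligned orientation: block phases kept or both flipped together
        assert merged.phase in ([1, 0, 0, 1], [0, 1, 1, 0])

    def test_no_finite_edges_leaves_blocks(self):
        b0 = HaplotypeBlock("b0", [0, 1], [1, 0], 0)
        b1 = HaplotypeBlock("b1", [2, 3], [0, 1], 0)
        g = CmGraph(snps=[0, 1, 2, 3], inf_edges=[(0, 1), (2, 3)])
        sol = solve_min_multi_cut(g, M=5, seed=0)
        merged = apply_cut([b0, b1], sol)
        assert sorted(b.snp_indices for b in merged) == [[0, 1], [2, 3]]
        for blk, orig in zip(merged, (b0, b1)):
            assert blk.phase in (orig.phase, orig.flipped().phase)

    def test_planted_truth_merge_at_3_to_1(self):
        """Fragmented blocks over a 3:1-imbalanced region merge into phase
        assignments matching the planted truth up to a global flip.

        At 3:1 the pair posterior (0.75) clears the 0.4 reliability filter;
        see test_matched_2_to_1_pairs_are_filtered for why exactly-2:1
        regions do not assemble under the published thresholds."""
        from hicphaser.evaluation import compute_aer
        from hicphaser.synthetic_data import (GenomeParams, simulate_genome,
                                              simulate_hic)

        truth = simulate_genome(
            GenomeParams(length_bp=2_000_000, loh_intervals=[],
                         copy_ratio=(3, 1), somatic_frac=0.0), seed=31)
        frags = simulate_hic(truth, 60_000, eps=0.01, seed=31)
        het = [i for i in range(truth.n_snps)
               if truth.genotype[i] == "het"]
        # two planted truth fragments, the second globally flipped
        mid = len(het) // 2
        b0 = HaplotypeBlock("b0", het[:mid],
                            [int(truth.allele_h1[i]) for i in het[:mid]], 0)
        b1 = HaplotypeBlock(
            "b1", het[mid:],
            [1 - int(truth.allele_h1[i]) for i in het[mid:]], 0)
        snps = truth.snp_records()
        coverage = allele_coverage_by_haplotype(frags, [b0, b1])
        g = build_cmg(snps, [b0, b1], coverage)
        assert g.bundles, "expected surviving boundary bundles at 3:1"
        sol = solve_min_multi_cut(g, M=100, seed=2)
        (merged,) = apply_cut([b0, b1], sol)
        truth_phase = {i: int(truth.allele_h1[i]) for i in het}
        assert compute_aer(merged, truth_phase) <= 0.02

    def test_matched_2_to_1_pairs_are_filtered(self):
        """A coverage-matched pair at exactly 2:1 has posterior ~0.614, so
        the published 0.4 reliability threshold removes its bundle — the
        documented limit of proportion-normalised weights in moderately
        imbalanced regions."""
        w = edge_weights((70, 35), (70, 35), "matched-support")
        assert reliability_filter(w, 0.4) is False
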