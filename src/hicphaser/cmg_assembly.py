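"""Haplotype-fragment assembly via the coverage matching graph (CMG).

In allelically imbalanced regions, the per-haplotype read-coverage
proportion of a SNP is informative about which haplotypes of nearby blocks
lie on the same chromosome copy: coverage-matched orientations are likelier.
We build a graph with two vertices per SNP (its two haplotype alleles),
4-edge bundles between eligible cross-block SNP pairs weighted by binomial
coverage likelihoods, and infinite-weight edges chaining same-haplotype
vertices inside each block.  Assembling blocks then reduces to the Minimum
Multiple s-t Cut problem: split the vertices into two sides, exactly one
vertex of each SNP's pair per side, minimising the cut weight.  The problem
is NP-hard (executable Max-Cut reduction below), so it is solved by a
revised Karger contraction heuristic ordered by a weighted random
permutation of an inverse-entropy association graph, with an exact
brute-force solver as the small-instance oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import HicFragment, SnpRecord
from .phasing import HaplotypeBlock

EdgeKey = Tuple[str, str]  # ('a'|'b', 'a'|'b')
Bundle = Dict[EdgeKey, float]

ALL_KEYS: Tuple[EdgeKey, ...] = (("a", "a"), ("a", "b"),
                                 ("b", "a"), ("b", "b"))


def _aligned_cross(bundle: Bundle) -> Tuple[float, float]:
    aligned = bundle.get(("a", "a"), 0.0) + bundle.get(("b", "b"), 0.0)
    cross = bundle.get(("a", "b"), 0.0) + bundle.get(("b", "a"), 0.0)
    return aligned, cross


@dataclass
class CmGraph:
    """Coverage matching graph: two vertices (sides a/b) per SNP.

    ``bundles`` maps an ordered SNP pair (i < j) to its finite-weight edges;
    ``inf_edges`` are the intra-block same-haplotype links (a-a and b-b, of
    infinite weight, stored once per adjacent SNP pair).
    """

    snps: List[int]
    bundles: Dict[Tuple[int, int], Bundle] = field(default_factory=dict)
    inf_edges: List[Tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        sset = set(self.snps)
        for (i, j), bundle in self.bundles.items():
            if i == j:
                raise ValueError("no edge may join the two vertices of one "
                                 "SNP")
            if i not in sset or j not in sset:
                raise ValueError("bundle endpoint not registered")
            if set(bundle) == set(ALL_KEYS):
                total = sum(bundle.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"bundle {(i, j)} weights sum to {total}, not 1")
            if any(w < 0 for w in bundle.values()):
                raise ValueError("negative edge weight")
        for i, j in self.inf_edges:
            if i not in sset or j not in sset:
                raise ValueError("INF edge endpoint not registered")


@dataclass
class AssocGraph:
    """Pair-level association graph ordering contraction decisions."""

    edges: Dict[Tuple[int, int], float] = field(default_factory=dict)


@dataclass
class CutSolution:
    """Two-sided partition: ``assignment[snp]`` = 0 if the SNP's a-vertex is
    in S else 1; ``components`` are the connected components of the graph."""

    assignment: Dict[int, int]
    cut_weight: float
    components: List[List[int]] = field(default_factory=list)


class _ParityDSU:
    """Union-find tracking each SNP's side parity relative to its root."""

    def __init__(self, items: Iterable[int]) -> None:
        self.parent = {i: i for i in items}
        self.parity = {i: 0 for i in self.parent}
        self.size = {i: 1 for i in self.parent}

    def find(self, x: int) -> Tuple[int, int]:
        path = []
        p = 0
        while self.parent[x] != x:
            path.append(x)
            p ^= self.parity[x]
            x = self.parent[x]
        # path compression, re-rooting parities
        acc = p
        for node in path:
            np_ = self.parity[node]
            self.parent[node] = x
            self.parity[node], acc = acc, acc ^ np_
        return x, p

    def union(self, x: int, y: int, rel: int) -> Tuple[int, int, int]:
        """Merge so that parity(x) xor parity(y) == rel.

        Returns (kept_root, absorbed_root, parity shift of the absorbed
        root's group); raises if already joined with conflicting parity.
        """
        rx, px = self.find(x)
        ry, py = self.find(y)
        if rx == ry:
            if px ^ py != rel:
                raise ValueError("conflicting merge")
            return rx, ry, 0
        if self.size[rx] < self.size[ry]:
            rx, ry = ry, rx
            px, py = py, px
        shift = px ^ py ^ rel
        self.parent[ry] = rx
        self.parity[ry] = shift
        self.size[rx] += self.size[ry]
        return rx, ry, shift


# --- coverage and eligibility -------------------------------------------

def allele_coverage_by_haplotype(fragments: Iterable[HicFragment],
                                 blocks: Sequence[HaplotypeBlock],
                                 ) -> Dict[int, Tuple[int, int]]:
    """Tally fragment calls per SNP onto its block-defined a/b sides.

    Side a carries the allele block h1 assigns the SNP (for singleton
    blocks: a = alt).  Returns {snp_index: (c_a, c_b)}; SNPs with zero calls
    keep (0, 0) and are ineligible for CMG edges (proportions undefined).
    """
    side_a_allele: Dict[int, int] = {}
    for blk in blocks:
        for snp, ph in zip(blk.snp_indices, blk.phase):
            side_a_allele[snp] = ph
    counts = {snp: [0, 0] for snp in side_a_allele}
    for frag in fragments:
        for snp, allele, _q in frag.calls:
            a_allele = side_a_allele.get(snp)
            if a_allele is None:
                continue
            counts[snp][0 if allele == a_allele else 1] += 1
    return {snp: (c[0], c[1]) for snp, c in counts.items()}


def candidate_pairs(snps: Sequence[SnpRecord],
                    blocks: Sequence[HaplotypeBlock],
                    coverage: Dict[int, Tuple[int, int]],
                    max_dist: int = 1_000_000,
                    n_nearest: int = 5,
                    min_block: int = 100,
                    min_cov: int = 10) -> List[Tuple[int, int]]:
    """Cross-block SNP pairs satisfying the four eligibility conditions.

    (1) genomic distance <= ``max_dist``; (2) each SNP is one of the other's
    ``n_nearest`` closest cross-block SNPs; (3) at least one of the two
    belongs to a block of >= ``min_block`` SNPs; (4) every one of the four
    a/b coverages is strictly above ``min_cov``.
    """
    block_of: Dict[int, int] = {}
    block_size: Dict[int, int] = {}
    for b, blk in enumerate(blocks):
        for snp in blk.snp_indices:
            block_of[snp] = b
        block_size[b] = blk.size
    members = sorted(block_of)
    pos = {i: snps[i].pos for i in members}

    def nearest(k: int) -> List[int]:
        """n nearest cross-block SNPs (by |pos| distance) within max_dist."""
        i = members[k]
        out: List[Tuple[int, int]] = []
        lo, hi = k - 1, k + 1
        while len(out) < n_nearest * 4 and (lo >= 0 or hi < len(members)):
            dl = pos[i] - pos[members[lo]] if lo >= 0 else None
            dh = pos[members[hi]] - pos[i] if hi < len(members) else None
            if dh is None or (dl is not None and dl <= dh):
                j, d = members[lo], dl
                lo -= 1
            else:
                j, d = members[hi], dh
                hi += 1
            if d > max_dist:
                break
            if block_of[j] != block_of[i]:
                out.append((d, j))
        out.sort()
        return [j for _, j in out[:n_nearest]]

    near = {members[k]: set(nearest(k)) for k in range(len(members))}
    pairs: List[Tuple[int, int]] = []
    for i in members:
        for j in near[i]:
            if j <= i or i not in near[j]:
                continue
            if max(block_size[block_of[i]], block_size[block_of[j]]) \
                    < min_block:
                continue
            ci, cj = coverage.get(i, (0, 0)), coverage.get(j, (0, 0))
            if min(ci + cj) <= min_cov:
                continue
            pairs.append((i, j))
    return pairs


# --- edge weights --------------------------------------------------------

def edge_weights(cov_i: Tuple[int, int], cov_j: Tuple[int, int],
                 mode: str = "matched-support") -> Bundle:
    """Four normalized edge weights for one cross-block SNP pair.

    mode "as-printed": each edge takes the sum of the two reciprocal
    normalized log-likelihood terms -1/[p(s_j^y) log(p_i^x)] (natural log),
    then all four weights are scaled to sum to 1.

    mode "matched-support": pair-level posterior of "aa|bb" vs "ab|ba" from
    the same coverage-normalised binomial log-likelihoods,
    W = 1/(1 + exp(L(ab|ba) - L(aa|bb))), split equally over each
    hypothesis's two edges.
    """
    ca_i, cb_i = cov_i
    ca_j, cb_j = cov_j
    if min(ca_i, cb_i, ca_j, cb_j) <= 0:
        raise ValueError("edge_weights requires all four coverages > 0 "
                         "(proportions of 0 or 1 are degenerate)")
    pia = ca_i / (ca_i + cb_i)
    pib = 1.0 - pia
    pja = ca_j / (ca_j + cb_j)
    pjb = 1.0 - pja
    if mode == "as-printed":
        raw = {
            ("a", "a"): -1.0 / (pja * math.log(pia))
                        - 1.0 / (pia * math.log(pja)),
            ("b", "b"): -1.0 / (pjb * math.log(pib))
                        - 1.0 / (pib * math.log(pjb)),
            ("a", "b"): -1.0 / (pjb * math.log(pia))
                        - 1.0 / (pia * math.log(pjb)),
            ("b", "a"): -1.0 / (pja * math.log(pib))
                        - 1.0 / (pib * math.log(pja)),
        }
        total = sum(raw.values())
        return {k: w / total for k, w in raw.items()}
    if mode == "matched-support":
        l_aa = (pja * math.log(pia) + pjb * math.log(pib)
                + pia * math.log(pja) + pib * math.log(pjb))
        l_ab = (pja * math.log(pib) + pjb * math.log(pia)
                + pia * math.log(pjb) + pib * math.log(pja))
        w = 1.0 / (1.0 + math.exp(l_ab - l_aa))
        return {("a", "a"): w / 2, ("b", "b"): w / 2,
                ("a", "b"): (1 - w) / 2, ("b", "a"): (1 - w) / 2}
    raise ValueError(f"unknown weight mode {mode!r}")


def edge_weights_unnormalized(cov_i: Tuple[int, int],
                              cov_j: Tuple[int, int]) -> Bundle:
    """As-printed reciprocal weights before the sum-to-1 normalization."""
    norm = edge_weights(cov_i, cov_j, "as-printed")
    # recover the scale from one term
    ca_i, cb_i = cov_i
    ca_j, cb_j = cov_j
    pia = ca_i / (ca_i + cb_i)
    pja = ca_j / (ca_j + cb_j)
    waa = -1.0 / (pja * math.log(pia)) - 1.0 / (pia * math.log(pja))
    scale = waa / norm[("a", "a")]
    return {k: w * scale for k, w in norm.items()}


def reliability_filter(weights: Bundle, thresh: float = 0.4) -> bool:
    """Keep a bundle only if one orientation clearly dominates.

    Compares the "aa|bb" and "ab|ba" weight sums; the bundle is removed
    (returns False) iff min/max exceeds ``thresh``.
    """
    aligned, cross = _aligned_cross(weights)
    mx = max(aligned, cross)
    if mx == 0:
        return False
    return (min(aligned, cross) / mx) <= thresh


# --- graph construction --------------------------------------------------

def build_cmg(snps: Sequence[SnpRecord],
              blocks: Sequence[HaplotypeBlock],
              coverage: Dict[int, Tuple[int, int]],
              max_dist: int = 1_000_000,
              n_nearest: int = 5,
              min_block: int = 100,
              min_cov: int = 10,
              reliability_thresh: float = 0.4,
              weight_mode: str = "matched-support") -> CmGraph:
    """Assemble the CMG: surviving 4-edge bundles + intra-block INF chains."""
    vertices = sorted({s for blk in blocks for s in blk.snp_indices})
    graph = CmGraph(snps=vertices)
    for blk in blocks:
        for i, j in zip(blk.snp_indices, blk.snp_indices[1:]):
            graph.inf_edges.append((i, j))
    for i, j in candidate_pairs(snps, blocks, coverage, max_dist,
                                n_nearest, min_block, min_cov):
        bundle = edge_weights(coverage[i], coverage[j], weight_mode)
        if reliability_filter(bundle, reliability_thresh):
            graph.bundles[(i, j)] = bundle
    return graph


def build_association_graph(graph: CmGraph,
                            clamp: float = 1e-12) -> AssocGraph:
    """Inverse-entropy weights over SNP pairs holding finite CMG edges.

    r1 is the proportion of bundle weight supporting the aligned
    orientation (missing edges count as 0); r1 is clamped into
    [clamp, 1-clamp] before the natural-log entropy.
    """
    assoc = AssocGraph()
    for pair, bundle in graph.bundles.items():
        aligned, cross = _aligned_cross(bundle)
        total = aligned + cross
        if total == 0:
            continue
        r1 = min(max(aligned / total, clamp), 1.0 - clamp)
        r2 = 1.0 - r1
        assoc.edges[pair] = 1.0 / (-r1 * math.log(r1) - r2 * math.log(r2))
    return assoc


# --- solvers -------------------------------------------------------------

def _premerge(graph: CmGraph) -> _ParityDSU:
    dsu = _ParityDSU(graph.snps)
    for i, j in graph.inf_edges:
        dsu.union(i, j, 0)  # same-haplotype vertices stay on one side
    return dsu


def _cut_weight_from_parity(graph: CmGraph, dsu: _ParityDSU) -> float:
    total = 0.0
    for (i, j), bundle in graph.bundles.items():
        ri, pi = dsu.find(i)
        rj, pj = dsu.find(j)
        if ri != rj:
            # disconnected in the association graph: sides independent,
            # count the cheaper orientation
            aligned, cross = _aligned_cross(bundle)
            total += min(aligned, cross)
            continue
        aligned, cross = _aligned_cross(bundle)
        total += cross if pi ^ pj == 0 else aligned
    return total


def _components(graph: CmGraph) -> List[List[int]]:
    dsu = _ParityDSU(graph.snps)
    for i, j in graph.inf_edges:
        dsu.union(i, j, 0)
    for i, j in graph.bundles:
        ri, _ = dsu.find(i)
        rj, pj = dsu.find(j)
        if ri != rj:
            dsu.union(i, j, 0)
    comps: Dict[int, List[int]] = {}
    for s in graph.snps:
        r, _ = dsu.find(s)
        comps.setdefault(r, []).append(s)
    return [sorted(c) for c in comps.values()]


def solve_min_multi_cut(graph: CmGraph, assoc: Optional[AssocGraph] = None,
                        M: int = 100,
                        seed: int = 0) -> CutSolution:
    """Revised Karger heuristic for Minimum Multiple s-t Cut.

    Runs ``M`` weighted random permutations of the association-graph edges
    (exponential races realise sampling without replacement proportional to
    edge weight).  Each permutation is consumed in order: a contraction
    merges the two endpoint pair-groups in the orientation with the larger
    current inter-group supporting weight (ties random); contractions whose
    endpoints were already merged are skipped.  INF edges pre-merge their
    groups.  Returns the minimum-weight solution over the runs.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if assoc is None:
        assoc = build_association_graph(graph)
    rng = np.random.default_rng(seed)
    edges = sorted(assoc.edges)
    weights = np.array([assoc.edges[e] for e in edges], dtype=float)
    best: Optional[CutSolution] = None
    for _run in range(M):
        dsu = _premerge(graph)
        # inter-group supporting weights, keyed by (root, root) -> [w0, w1]
        adj: Dict[int, Dict[int, List[float]]] = {}
        for (i, j), bundle in graph.bundles.items():
            ri, pi = dsu.find(i)
            rj, pj = dsu.find(j)
            if ri == rj:
                continue
            aligned, cross = _aligned_cross(bundle)
            rel = pi ^ pj
            w = adj.setdefault(ri, {}).setdefault(rj, [0.0, 0.0])
            w[rel] += aligned
            w[rel ^ 1] += cross
            w2 = adj.setdefault(rj, {}).setdefault(ri, [0.0, 0.0])
            w2[rel] += aligned
            w2[rel ^ 1] += cross
        if len(edges) > 0:
            order = np.argsort(rng.exponential(1.0, size=len(edges))
                               / weights)
        else:
            order = []
        for e in order:
            i, j = edges[e]
            ri, _ = dsu.find(i)
            rj, _ = dsu.find(j)
            if ri == rj:
                continue  # conflicts with an existing merge: skip
            w = adj.get(ri, {}).get(rj, [0.0, 0.0])
            if w[0] > w[1]:
                rel = 0
            elif w[1] > w[0]:
                rel = 1
            else:
                rel = int(rng.integers(2))
            keep, gone, shift = dsu.union(ri, rj, rel)
            # fold the absorbed group's adjacency into the kept root
            gone_adj = adj.pop(gone, {})
            keep_adj = adj.setdefault(keep, {})
            keep_adj.pop(gone, None)
            for nbr, wpair in gone_adj.items():
                if nbr == keep:
                    continue
                shifted = [wpair[shift], wpair[shift ^ 1]]
                tgt = keep_adj.setdefault(nbr, [0.0, 0.0])
                tgt[0] += shifted[0]
                tgt[1] += shifted[1]
                nadj = adj.setdefault(nbr, {})
                nadj.pop(gone, None)
                t2 = nadj.setdefault(keep, [0.0, 0.0])
                t2[0] += shifted[0]
                t2[1] += shifted[1]
        weight = _cut_weight_from_parity(graph, dsu)
        if best is None or weight < best.cut_weight - 1e-12:
            assignment = {}
            for s in graph.snps:
                _, p = dsu.find(s)
                assignment[s] = p
            best = CutSolution(assignment, weight)
    assert best is not None
    best.components = _components(graph)
    return best


def brute_force_min_multi_cut(graph: CmGraph) -> CutSolution:
    """Exact Min-Multi-Cut by enumerating 2^(groups-1) side assignments.

    INF edges pre-merge pairs into groups; at most 15 groups are accepted.
    Ties broken by the lexicographically smallest group-parity vector.
    """
    dsu = _premerge(graph)
    roots = sorted({dsu.find(s)[0] for s in graph.snps})
    if len(roots) > 15:
        raise ValueError(f"{len(roots)} pair-groups exceed the brute-force "
                         "limit of 15")
    ridx = {r: k for k, r in enumerate(roots)}
    # fold bundles onto group-relative parities
    folded: Dict[Tuple[int, int], List[float]] = {}
    const = 0.0
    for (i, j), bundle in graph.bundles.items():
        ri, pi = dsu.find(i)
        rj, pj = dsu.find(j)
        aligned, cross = _aligned_cross(bundle)
        rel = pi ^ pj
        if ri == rj:
            const += cross if rel == 0 else aligned
            continue
        a, b = sorted((ridx[ri], ridx[rj]))
        w = folded.setdefault((a, b), [0.0, 0.0])
        w[rel] += aligned      # weight supporting group parity == rel
        w[rel ^ 1] += cross
    best_bits: Optional[Tuple[int, ...]] = None
    best_w = math.inf
    n = len(roots)
    for mask in range(2 ** max(0, n - 1)):
        bits = tuple((mask >> (n - 1 - k)) & 1 if k > 0 else 0
                     for k in range(n))
        w = const
        for (a, b), (w0, w1) in folded.items():
            w += w1 if bits[a] ^ bits[b] == 0 else w0
        if w < best_w - 1e-12:
            best_w, best_bits = w, bits
    assert best_bits is not None
    assignment = {}
    for s in graph.snps:
        r, p = dsu.find(s)
        assignment[s] = best_bits[ridx[r]] ^ p
    return CutSolution(assignment, best_w, _components(graph))


def reduce_maxcut(edges: Iterable[Tuple[int, int, float]],
                  vertices: Optional[Iterable[int]] = None) -> CmGraph:
    """Max-Cut -> Min-Multi-Cut reduction (the NP-hardness construction).

    Each source vertex becomes one SNP pair; each source edge (i, j), i < j,
    with weight w becomes the single CMG edge (i^a, j^b) of weight w.  A
    Max-Cut solution S' maps to S = {v_i^a : i in S'} + {v_i^b : i not in
    S'}, and min-multi-cut(reduced) == total weight - max-cut(source).
    """
    verts = set(vertices) if vertices is not None else set()
    bundles: Dict[Tuple[int, int], Bundle] = {}
    for i, j, w in edges:
        if i == j:
            raise ValueError("self-loops are not allowed in Max-Cut input")
        if w < 0:
            raise ValueError("Max-Cut reduction needs non-negative weights")
        a, b = min(i, j), max(i, j)
        verts.update((a, b))
        bundle = bundles.setdefault((a, b), {})
        bundle[("a", "b")] = bundle.get(("a", "b"), 0.0) + w
    return CmGraph(snps=sorted(verts), bundles=bundles)


def maxcut_solution_from_cut(solution: CutSolution) -> set:
    """Map a Min-Multi-Cut solution back to a Max-Cut side set S'."""
    return {v for v, side in solution.assignment.items() if side == 0}


def apply_cut(blocks: Sequence[HaplotypeBlock], solution: CutSolution
              ) -> List[HaplotypeBlock]:
    """Merge blocks per connected component, honouring the cut orientation.

    Each component becomes one block whose h1 allele at a SNP is the
    original block's h1 allele when the SNP's a-vertex sits in S (side 0),
    else the complement; internal block phasings are preserved exactly
    because INF edges are never cut.
    """
    phase_of: Dict[int, int] = {}
    region_of: Dict[int, int] = {}
    for blk in blocks:
        for snp, ph in zip(blk.snp_indices, blk.phase):
            phase_of[snp] = ph
            region_of[snp] = blk.region_id
    merged: List[HaplotypeBlock] = []
    for comp in solution.components:
        idx = sorted(comp)
        phase = [phase_of[s] if solution.assignment[s] == 0
                 else 1 - phase_of[s] for s in idx]
        merged.append(HaplotypeBlock(f"asm_{len(merged)}", idx, phase,
                                     region_of[idx[0]]))
    merged.sort(key=lambda b: b.snp_indices[0])
    return merged
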