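"""Chromosome-level completion: connect LOH sequences and haplotypes.

A chromosome alternates LOH regions (single surviving sequence) and
non-LOH regions (two phased haplotypes).  Hi-C pairs spanning a boundary —
one mate inside an LOH region, the other calling a SNP allele of one
haplotype — vote on which haplotype shares the LOH region's chromosome
copy.  On a small support graph (one vertex per LOH region, two per
non-LOH region, edges only LOH-to-haplotype) the two chromosome-level
haplotypes are the bipartition that keeps the most support: all side
assignments are enumerated and the one removing minimum edge weight wins.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .io_formats import HicFragment, SnpRecord
from .phasing import HaplotypeBlock
from .preprocess import LohRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Segment:
    """One tile of a chromosome haplotype line."""

    kind: str       # "loh" | "hap"
    start: int      # bp, for genomic ordering
    end: int
    region: int     # LOH index or non-LOH region index
    hap: Optional[int] = None  # 1 or 2 for kind == "hap"


@dataclass
class CompletionGraph:
    """Support graph between LOH regions and non-LOH haplotypes.

    ``loh`` lists LOH intervals; ``regions`` lists, per non-LOH region,
    its (start, end) span.  ``weights[(l, r, h)]`` counts read pairs
    linking LOH region l to haplotype h (1 or 2) of region r.
    """

    loh: List[Tuple[int, int]] = field(default_factory=list)
    regions: List[Tuple[int, int]] = field(default_factory=list)
    weights: Dict[Tuple[int, int, int], int] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.loh) + 2 * len(self.regions)

    def weight(self, l: int, r: int, h: int) -> int:
        return self.weights.get((l, r, h), 0)


@dataclass
class ChromosomeHaplotypes:
    """Two ordered segment lists tiling the chromosome."""

    hap1: List[Segment]
    hap2: List[Segment]
    removed_weight: float = 0.0
    # orientation[r] == 0 means region r's h1 sits on the hap1 line
    orientation: Dict[int, int] = field(default_factory=dict)
    loh_side: Dict[int, int] = field(default_factory=dict)


def count_link_support(fragments: Iterable[HicFragment],
                       loh_regions: Sequence[LohRegion],
                       blocks: Sequence[HaplotypeBlock],
                       snps: Sequence[SnpRecord],
                       ) -> CompletionGraph:
    """Tally Hi-C pairs with one end in an LOH region, one on a haplotype.

    A pair votes for edge (L, h) when one mate maps inside L and the other
    mate's calls match haplotype h's alleles at SNPs of a block (majority
    over the mate's matching calls; an exact tie votes for neither).  Blocks
    stand in for their non-LOH regions, ordered along the chromosome.
    """
    graph = CompletionGraph(
        loh=[(r.start, r.end) for r in loh_regions],
        regions=[(snps[b.snp_indices[0]].pos - 1,
                  snps[b.snp_indices[-1]].pos) for b in blocks])
    phase_of: Dict[int, Tuple[int, int]] = {}  # snp -> (block idx, h1 allele)
    for bi, blk in enumerate(blocks):
        for snp, ph in zip(blk.snp_indices, blk.phase):
            phase_of[snp] = (bi, ph)

    def loh_of(pos: int) -> Optional[int]:
        for li, (s, e) in enumerate(graph.loh):
            if s <= pos - 1 < e:
                return li
        return None

    for frag in fragments:
        if frag.end_positions is None:
            continue
        lis = [loh_of(p) for p in frag.end_positions]
        hits = [li for li in lis if li is not None]
        if len(hits) != 1:
            continue  # need exactly one end inside an LOH region
        li = hits[0]
        votes: Dict[Tuple[int, int], int] = {}
        for snp, allele, _q in frag.calls:
            entry = phase_of.get(snp)
            if entry is None:
                continue
            bi, h1_allele = entry
            h = 1 if allele == h1_allele else 2
            votes[(bi, h)] = votes.get((bi, h), 0) + 1
        for bi in {b for b, _ in votes}:
            v1, v2 = votes.get((bi, 1), 0), votes.get((bi, 2), 0)
            if v1 > v2:
                h = 1
            elif v2 > v1:
                h = 2
            else:
                continue  # matches neither haplotype decisively
            key = (li, bi, h)
            graph.weights[key] = graph.weights.get(key, 0) + 1
    return graph


def _tiling(graph: CompletionGraph, orientation: Dict[int, int],
            loh_side: Dict[int, int]) -> Tuple[List[Segment], List[Segment]]:
    segs: List[Tuple[Segment, int]] = []
    for li, (s, e) in enumerate(graph.loh):
        segs.append((Segment("loh", s, e, li), loh_side.get(li, 0)))
    for r, (s, e) in enumerate(graph.regions):
        o = orientation.get(r, 0)
        segs.append((Segment("hap", s, e, r, hap=1), o))
        segs.append((Segment("hap", s, e, r, hap=2), o ^ 1))
    segs.sort(key=lambda t: (t[0].start, t[0].kind, t[0].hap or 0))
    hap1 = [s for s, side in segs if side == 0]
    hap2 = [s for s, side in segs if side == 1]
    return hap1, hap2


def complete_chromosome(graph: CompletionGraph,
                        enumeration_limit: int = 2 ** 19,
                        M: int = 200, seed: int = 0
                        ) -> ChromosomeHaplotypes:
    """Minimum-removed-weight bipartition of the completion graph.

    Enumerates one orientation bit per non-LOH region (the first region is
    pinned to break the global flip symmetry) and one side bit per LOH
    vertex, and keeps the assignment whose removed (cross-side) weight is
    minimal; ties resolve to the lexicographically smallest assignment.
    Beyond ``enumeration_limit`` assignments it falls back to the
    contraction heuristic on an equivalent pairing (logged).
    """
    n_r, n_l = len(graph.regions), len(graph.loh)
    if n_r == 0 and n_l == 0:
        return ChromosomeHaplotypes([], [])
    free_bits = max(0, n_r - 1) + n_l
    if 2 ** free_bits > enumeration_limit:
        return _complete_by_contraction(graph, M=M, seed=seed)

    total = sum(graph.weights.values())
    best: Optional[Tuple[float, Tuple[int, ...]]] = None
    for bits in itertools.product((0, 1), repeat=free_bits):
        orient = (0,) + bits[:max(0, n_r - 1)] if n_r else ()
        lside = bits[max(0, n_r - 1):]
        kept = 0
        for (li, r, h), w in graph.weights.items():
            hap_side = orient[r] ^ (h - 1)
            if hap_side == lside[li]:
                kept += w
        removed = total - kept
        cand = (removed, orient + lside)
        if best is None or removed < best[0] - 1e-12:
            best = cand
    assert best is not None
    removed, assign = best
    orientation = {r: assign[r] for r in range(n_r)}
    loh_side = {li: assign[n_r + li] for li in range(n_l)}
    hap1, hap2 = _tiling(graph, orientation, loh_side)
    return ChromosomeHaplotypes(hap1, hap2, float(removed),
                                orientation, loh_side)


def _complete_by_contraction(graph: CompletionGraph, M: int, seed: int
                             ) -> ChromosomeHaplotypes:
    """Large-graph fallback: map to Min-Multi-Cut and run the heuristic.

    Every non-LOH region is already a vertex pair (h1, h2); every LOH
    region becomes a pair with an isolated dummy partner, so that "exactly
    one vertex per pair in S" reproduces the completion constraints.
    """
    from .cmg_assembly import CmGraph, solve_min_multi_cut

    logger.info("completion: %d vertices, falling back to the contraction "
                "heuristic", graph.n_vertices)
    n_r = len(graph.regions)
    bundles: Dict[Tuple[int, int], Dict[Tuple[str, str], float]] = {}
    for (li, r, h), w in graph.weights.items():
        pair = tuple(sorted((r, n_r + li)))
        bundle = bundles.setdefault(pair, {})
        flipped = pair[0] != r
        # side a of region-pair == h1; side a of loh-pair == the LOH vertex
        key = ("a", "a") if h == 1 else ("b", "a")
        if flipped:
            key = (key[1], key[0])
        bundle[key] = bundle.get(key, 0.0) + w
    cm = CmGraph(snps=list(range(n_r + len(graph.loh))), bundles=bundles)
    sol = solve_min_multi_cut(cm, M=M, seed=seed)
    orientation = {r: sol.assignment[r] for r in range(n_r)}
    loh_side = {li: sol.assignment[n_r + li]
                for li in range(len(graph.loh))}
    total = sum(graph.weights.values())
    kept = sum(w for (li, r, h), w in graph.weights.items()
               if orientation[r] ^ (h - 1) == loh_side[li])
    hap1, hap2 = _tiling(graph, orientation, loh_side)
    return ChromosomeHaplotypes(hap1, hap2, float(total - kept),
                                orientation, loh_side)
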