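"""Phasing of non-LOH stretches into haplotype blocks.

Two engines share one output contract (:class:`HaplotypeBlock`): an adapter
around an external HAPCUT2 executable, and a self-contained fallback that
phases along a maximum-weight spanning tree of the pairwise allele-linkage
graph.  Downstream modules depend only on the block contract.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import networkx as nx

from .io_formats import HicFragment, SnpRecord

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeBlock:
    """An ordered set of phased SNPs.

    ``phase[k]`` is haplotype h1's allele (0 ref / 1 alt) at the block's k-th
    SNP; h2 carries the complement.  ``snp_indices`` are strictly increasing
    0-based indices into the chromosome's master SNP list.
    """

    block_id: str
    snp_indices: List[int]
    phase: List[int]
    region_id: int = 0

    def __post_init__(self) -> None:
        if len(self.snp_indices) != len(self.phase):
            raise ValueError("snp_indices and phase must be aligned")
        if any(b >= a for a, b in zip(self.snp_indices[1:],
                                      self.snp_indices)):
            raise ValueError("snp_indices must be strictly increasing")
        if any(p not in (0, 1) for p in self.phase):
            raise ValueError("phase values must be 0/1")

    @property
    def size(self) -> int:
        return len(self.snp_indices)

    @property
    def span(self) -> Tuple[int, int]:
        return self.snp_indices[0], self.snp_indices[-1]

    def phase_of(self, snp_index: int) -> int:
        import bisect
        k = bisect.bisect_left(self.snp_indices, snp_index)
        if k == len(self.snp_indices) or self.snp_indices[k] != snp_index:
            raise KeyError(snp_index)
        return self.phase[k]

    def flipped(self) -> "HaplotypeBlock":
        return HaplotypeBlock(self.block_id, list(self.snp_indices),
                              [1 - p for p in self.phase], self.region_id)


def save_blocks(blocks: Sequence[HaplotypeBlock], path: str) -> None:
    """Serialise blocks as JSON (the CLI's stage interchange format)."""
    import json

    with open(path, "w") as fh:
        json.dump({"blocks": [
            {"block_id": b.block_id, "snp_indices": b.snp_indices,
             "phase": b.phase, "region_id": b.region_id}
            for b in blocks]}, fh)


def load_blocks(path: str) -> List[HaplotypeBlock]:
    import json

    with open(path) as fh:
        data = json.load(fh)
    return [HaplotypeBlock(d["block_id"], d["snp_indices"], d["phase"],
                           d.get("region_id", 0))
            for d in data["blocks"]]


def phase_with_hapcut2(fragment_file: str, vcf: str, workdir: str,
                       executable: str = "HAPCUT2",
                       ) -> List[HaplotypeBlock]:
    """Run an external HAPCUT2 binary and parse its haplotype block file.

    Raises ``FileNotFoundError`` with a pointer to the builtin fallback when
    the executable is not discoverable.
    """
    exe = shutil.which(executable)
    if exe is None:
        raise FileNotFoundError(
            f"HAPCUT2 executable {executable!r} not found on PATH; use the "
            "builtin engine (phase_fallback / --engine builtin) instead")
    out = f"{workdir}/hapcut2.blocks"
    subprocess.run([exe, "--fragments", fragment_file, "--VCF", vcf,
                    "--output", out, "--hic", "1"], check=True)
    return parse_hapcut2_blocks(out)


def parse_hapcut2_blocks(path: str) -> List[HaplotypeBlock]:
    """Parse HAPCUT2 block-format output (pruned '-' entries omitted)."""
    blocks: List[HaplotypeBlock] = []
    idx: List[int] = []
    ph: List[int] = []

    def close() -> None:
        nonlocal idx, ph
        if idx:
            order = sorted(range(len(idx)), key=idx.__getitem__)
            blocks.append(HaplotypeBlock(f"hapcut2_{len(blocks)}",
                                         [idx[k] for k in order],
                                         [ph[k] for k in order]))
        idx, ph = [], []

    with open(path) as fh:
        for line in fh:
            if line.startswith("BLOCK"):
                close()
            elif line.startswith("****") or not line.strip():
                continue
            else:
                parts = line.split()
                if parts[1] == "-" or parts[2] == "-":
                    continue  # pruned by HAPCUT2
                idx.append(int(parts[0]) - 1)
                ph.append(int(parts[1]))
    close()
    return blocks


def linkage_votes(fragments: Iterable[HicFragment],
                  eligible: Optional[set] = None,
                  ) -> Dict[Tuple[int, int], List[int]]:
    """Count cis/trans co-observations for every co-covered SNP pair.

    For SNPs i < j observed in one fragment with alleles (a_i, a_j), the
    relation a_i XOR a_j is 0 for cis (same haplotype-allele parity) and 1
    for trans; both haplotypes of origin produce the same relation, so the
    vote is phase-informative.  Returns {(i, j): [cis, trans]}.
    """
    votes: Dict[Tuple[int, int], List[int]] = {}
    for frag in fragments:
        calls = frag.calls if eligible is None else \
            [c for c in frag.calls if c[0] in eligible]
        n = len(calls)
        if n < 2:
            continue
        for x in range(n - 1):
            i, ai, _ = calls[x]
            for y in range(x + 1, n):
                j, aj, _ = calls[y]
                rel = ai ^ aj
                votes.setdefault((i, j), [0, 0])[rel] += 1
    return votes


def phase_fallback(fragments: Iterable[HicFragment],
                   snp_indices: Sequence[int],
                   min_support: int = 2,
                   region_id: int = 0) -> List[HaplotypeBlock]:
    """Self-contained phaser: majority-vote linkage graph + spanning tree.

    Each co-observed SNP pair votes cis vs trans; edges with majority margin
    >= ``min_support`` enter a graph weighted by the margin (ties dropped).
    Every connected component is phased along its maximum-weight spanning
    tree; isolated SNPs become singleton blocks.
    """
    eligible = set(snp_indices)
    votes = linkage_votes(fragments, eligible)
    return blocks_from_votes(votes, snp_indices, min_support, region_id)


def blocks_from_votes(votes: Dict[Tuple[int, int], List[int]],
                      snp_indices: Sequence[int],
                      min_support: int = 2,
                      region_id: int = 0) -> List[HaplotypeBlock]:
    """Phase a SNP set from precomputed cis/trans votes (see
    :func:`phase_fallback`); votes touching SNPs outside the set are
    ignored."""
    eligible = set(snp_indices)
    votes = {(i, j): v for (i, j), v in votes.items()
             if i in eligible and j in eligible}
    G = nx.Graph()
    G.add_nodes_from(snp_indices)
    n_conflict = 0
    for (i, j), (cis, trans) in votes.items():
        margin = abs(cis - trans)
        if margin < max(1, min_support):
            continue
        if min(cis, trans) > 0:
            n_conflict += 1
        G.add_edge(i, j, weight=margin, rel=int(trans > cis))
    if n_conflict:
        logger.debug("phase_fallback: %d edges carry minority conflict "
                     "votes", n_conflict)

    blocks: List[HaplotypeBlock] = []
    for comp in nx.connected_components(G):
        comp = sorted(comp)
        if len(comp) == 1:
            blocks.append(HaplotypeBlock(f"blk_{region_id}_{len(blocks)}",
                                         comp, [1], region_id))
            continue
        tree = nx.maximum_spanning_tree(G.subgraph(comp), weight="weight")
        root = comp[0]
        phase = {root: 1}
        for u, v in nx.bfs_edges(tree, root):
            phase[v] = phase[u] ^ tree[u][v]["rel"]
        blocks.append(HaplotypeBlock(f"blk_{region_id}_{len(blocks)}",
                                     comp, [phase[i] for i in comp],
                                     region_id))
    blocks.sort(key=lambda b: b.snp_indices[0])
    return blocks
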