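"""Gap filling in coverage-balanced regions via seed-guided LD phasing.

Tiny fragments that coverage imbalance could not place mostly sit in
allelically balanced regions, so they are clustered to the nearest main
haplotype by genomic distance and handed, together with the main haplotype
as a phased "seed", to a statistical phasing engine (e.g. Beagle with a
reference panel).  The engine is an adapter boundary: its LD model is out
of scope here, and when no engine is configured the affected SNPs simply
stay unphased.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Protocol, Sequence, Tuple

from .io_formats import SnpRecord
from .phasing import HaplotypeBlock

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """tiny block id -> (main block id, genomic distance in bp)."""

    assigned: Dict[str, Tuple[str, int]] = field(default_factory=dict)
    unassigned: List[str] = field(default_factory=list)


@dataclass
class SeedInput:
    """Engine input: phased seed sites plus unphased target sites."""

    seed_sites: Dict[int, int]    # snp index -> h1 allele (phased)
    target_sites: List[int]       # snp indices to be phased


class PhasingEngine(Protocol):
    """Adapter contract for an external statistical phasing engine."""

    def phase(self, seed: SeedInput, snps: Sequence[SnpRecord]
              ) -> Dict[int, int]:
        """Return h1 alleles for (a subset of) seed+target sites."""
        ...


class BeagleEngine:
    """Shell-out adapter for a Beagle jar with a reference panel.

    Only the process boundary lives here; input/output VCF conversion is
    delegated to the caller's workdir.  Raises when java or the jar is
    missing so the pipeline can skip the cluster with a warning.
    """

    def __init__(self, jar_path: str, panel_path: str,
                 java: str = "java") -> None:
        if shutil.which(java) is None:
            raise FileNotFoundError("java runtime not found for Beagle")
        self.jar_path = jar_path
        self.panel_path = panel_path
        self.java = java

    def run(self, vcf_in: str, out_prefix: str) -> None:
        subprocess.run(
            [self.java, "-jar", self.jar_path, f"gt={vcf_in}",
             f"ref={self.panel_path}", f"out={out_prefix}"],
            check=True)


def cluster_tiny_blocks(blocks: Sequence[HaplotypeBlock],
                        snps: Sequence[SnpRecord],
                        min_main: int = 100) -> ClusterAssignment:
    """Assign every tiny block to the closest main block of its stretch.

    Main blocks (cluster centers) hold >= ``min_main`` SNPs; the distance
    between two blocks is the minimum pairwise SNP-position difference.
    Ties go to the leftmost center; stretches without a center leave their
    tiny blocks unassigned (logged).
    """
    out = ClusterAssignment()
    by_region: Dict[int, List[HaplotypeBlock]] = {}
    for blk in blocks:
        by_region.setdefault(blk.region_id, []).append(blk)
    for region, blks in by_region.items():
        centers = [b for b in blks if b.size >= min_main]
        centers.sort(key=lambda b: snps[b.snp_indices[0]].pos)
        tiny = [b for b in blks if b.size < min_main]
        if not centers:
            if tiny:
                logger.warning("gapfill: stretch %d has no main block; %d "
                               "tiny blocks left unassigned", region,
                               len(tiny))
                out.unassigned.extend(b.block_id for b in tiny)
            continue
        for t in tiny:
            tpos = [snps[i].pos for i in t.snp_indices]
            best: Optional[Tuple[int, int]] = None  # (dist, center order)
            for k, c in enumerate(centers):
                cpos = [snps[i].pos for i in c.snp_indices]
                d = min(abs(tp - cp) for tp in tpos for cp in cpos)
                if best is None or d < best[0]:
                    best = (d, k)
            assert best is not None
            out.assigned[t.block_id] = (centers[best[1]].block_id, best[0])
    return out


def build_seed_input(main_block: HaplotypeBlock,
                     tiny_blocks: Sequence[HaplotypeBlock]) -> SeedInput:
    """Seed sites phased from the main block; tiny-block sites unphased."""
    seed = dict(zip(main_block.snp_indices, main_block.phase))
    targets = sorted({i for t in tiny_blocks for i in t.snp_indices})
    return SeedInput(seed_sites=seed, target_sites=targets)


def merge_imputed(engine_phase: Dict[int, int],
                  seed: SeedInput,
                  main_block: HaplotypeBlock) -> HaplotypeBlock:
    """Fold engine output into the main block, trusting the seed phase.

    If the engine returned the seeds globally inverted, the whole output is
    flipped back so every seed SNP keeps its input phase.  Sites missing
    from the engine output stay unphased; no SNP is ever removed from the
    main block.
    """
    agree = flip = 0
    for i, ph in seed.seed_sites.items():
        got = engine_phase.get(i)
        if got is None:
            continue
        if got == ph:
            agree += 1
        else:
            flip += 1
    invert = flip > agree
    phased: Dict[int, int] = dict(zip(main_block.snp_indices,
                                      main_block.phase))
    for i in seed.target_sites:
        got = engine_phase.get(i)
        if got is None:
            continue  # engine did not phase the site
        phased[i] = (1 - got) if invert else got
    idx = sorted(phased)
    return HaplotypeBlock(main_block.block_id, idx,
                          [phased[i] for i in idx], main_block.region_id)
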