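"""Switch-error correction from allelic read-coverage imbalance.

In aneuploid (allelically imbalanced) regions the two haplotypes attract
unequal read coverage.  A switch error inside a block reverses which
haplotype looks better covered, so we scan every inter-SNP position: count
how many SNPs before/after it have h1-coverage above (c1) or below (c2)
h2-coverage, form r_before = c1_before/c2_before and r_after =
c1_after/c2_after, and call a position a candidate switch point when one
ratio exceeds ``hi`` while the other falls below ``lo``.  The candidate with
the smallest ratio-of-ratios min(r)/max(r) is flipped; the scan repeats
until no candidate remains.

Conventions: position i lies between SNP i-1 and SNP i; "before" counts
indices < i and "after" counts indices >= i; coverage ties count in neither
c1 nor c2; a zero denominator yields a +inf ratio and a position with both
ratios infinite never qualifies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .phasing import HaplotypeBlock

logger = logging.getLogger(__name__)


@dataclass
class AlleleCoverage:
    """Per-SNP fragment-call counts on the block's two haplotypes."""

    cov1: np.ndarray  # calls supporting h1's allele, per block SNP
    cov2: np.ndarray

    def __post_init__(self) -> None:
        self.cov1 = np.asarray(self.cov1, dtype=np.int64)
        self.cov2 = np.asarray(self.cov2, dtype=np.int64)
        if self.cov1.shape != self.cov2.shape or self.cov1.ndim != 1:
            raise ValueError("cov1/cov2 must be aligned 1-d vectors")
        if (self.cov1 < 0).any() or (self.cov2 < 0).any():
            raise ValueError("coverage counts must be non-negative")

    def __len__(self) -> int:
        return len(self.cov1)

    def swapped_after(self, position: int) -> "AlleleCoverage":
        c1, c2 = self.cov1.copy(), self.cov2.copy()
        c1[position:], c2[position:] = self.cov2[position:], \
            self.cov1[position:]
        return AlleleCoverage(c1, c2)


@dataclass
class SwitchScan:
    c1_before: np.ndarray
    c1_after: np.ndarray
    c2_before: np.ndarray
    c2_after: np.ndarray


def dp_counts(coverage: AlleleCoverage) -> SwitchScan:
    """Prefix/suffix counts of coverage-dominance indicators.

    c1_before[i] counts indices j < i with cov1[j] > cov2[j];
    c1_after[i] counts indices j >= i with cov1[j] > cov2[j]; c2_* likewise
    with "<".  Computed by the forward/backward recurrences, equivalent to a
    brute-force recount at every i.
    """
    if len(coverage) < 2:
        raise ValueError("switch scan needs a block of length >= 2")
    gt = (coverage.cov1 > coverage.cov2).astype(np.int64)
    lt = (coverage.cov1 < coverage.cov2).astype(np.int64)
    c1_before = np.concatenate([[0], np.cumsum(gt)[:-1]])
    c2_before = np.concatenate([[0], np.cumsum(lt)[:-1]])
    c1_after = np.cumsum(gt[::-1])[::-1]
    c2_after = np.cumsum(lt[::-1])[::-1]
    return SwitchScan(c1_before, c1_after, c2_before, c2_after)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.inf


def find_switch_point(scan: SwitchScan, hi: float = 2.0, lo: float = 0.5
                      ) -> Optional[int]:
    """Best candidate switch position, or None.

    A position qualifies iff one of (r_before, r_after) exceeds ``hi`` while
    the other is below ``lo``; among qualifiers the argmin of the
    ratio-of-ratios min(r)/max(r) is returned.  Equal r^r values (common
    when a zero count makes one ratio infinite, so r^r collapses to 0) are
    broken by the largest total dominance support
    max(c1,c2)_before + max(c1,c2)_after, which uniquely selects the true
    boundary on clean data; any remaining tie keeps the leftmost position.
    """
    n = len(scan.c1_before)
    best_pos = None
    best_key: Tuple[float, float] = (math.inf, math.inf)
    for i in range(1, n):
        rb = _ratio(scan.c1_before[i], scan.c2_before[i])
        ra = _ratio(scan.c1_after[i], scan.c2_after[i])
        if not ((rb > hi and ra < lo) or (ra > hi and rb < lo)):
            continue
        mn, mx = min(rb, ra), max(rb, ra)
        rr = 0.0 if math.isinf(mx) else mn / mx  # qualifier => mn is finite
        support = max(scan.c1_before[i], scan.c2_before[i]) \
            + max(scan.c1_after[i], scan.c2_after[i])
        key = (rr, -float(support))
        if key < best_key:
            best_pos, best_key = i, key
    return best_pos


def correct_switches(block: HaplotypeBlock, coverage: AlleleCoverage,
                     hi: float = 2.0, lo: float = 0.5,
                     max_iter: Optional[int] = None,
                     ) -> Tuple[HaplotypeBlock, List[int]]:
    """Iteratively flip the best switch point until none qualifies.

    Each applied switch flips the phase of (and swaps the coverage vectors
    for) every SNP at or after the chosen position.  Never alters which SNPs
    belong to the block.  Returns the corrected block and the positions
    flipped, in order.
    """
    if block.size != len(coverage):
        raise ValueError("block and coverage must be aligned")
    if max_iter is None:
        max_iter = block.size
    phase = list(block.phase)
    cov = AlleleCoverage(coverage.cov1.copy(), coverage.cov2.copy())
    applied: List[int] = []
    if block.size >= 2:
        for _ in range(max_iter):
            pos = find_switch_point(dp_counts(cov), hi, lo)
            if pos is None:
                break
            for k in range(pos, block.size):
                phase[k] = 1 - phase[k]
            cov = cov.swapped_after(pos)
            applied.append(pos)
        else:
            logger.warning("correct_switches: stopped at max_iter=%d on "
                           "block %s", max_iter, block.block_id)
    corrected = HaplotypeBlock(block.block_id, list(block.snp_indices),
                               phase, block.region_id)
    return corrected, applied
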