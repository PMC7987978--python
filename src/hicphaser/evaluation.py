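"""Evaluation metrics: AER, large-block completeness, LOH accuracy."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .phasing import HaplotypeBlock
from .preprocess import LohRegion


@dataclass
class EvalReport:
    chrom: str
    n_large_blocks: int = 0
    pct_snps_in_large_blocks: float = 0.0
    aer_largest_block: Optional[float] = None
    loh_precision: Optional[float] = None
    loh_sensitivity: Optional[float] = None
    length_call: int = 0
    length_truth: int = 0
    length_overlap: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_tsv(self) -> str:
        d = asdict(self)
        keys = list(d)
        fmt = ["" if d[k] is None else str(d[k]) for k in keys]
        return "\t".join(keys) + "\n" + "\t".join(fmt) + "\n"


def compute_aer(phased: HaplotypeBlock,
                truth_phase: Dict[int, int]) -> Optional[float]:
    """Absolute error rate of a phased block against truth.

    Over the intersection S of phased and truth SNPs, count^o is the number
    of SNPs whose ordered allele pair matches the truth and count^r the
    number matching the reversed pair; AER = min(count^o, count^r) /
    (count^o + count^r).  Flip-invariant; None (NA) when S is empty.
    """
    count_o = count_r = 0
    for snp, ph in zip(phased.snp_indices, phased.phase):
        t = truth_phase.get(snp)
        if t is None:
            continue
        if ph == t:
            count_o += 1
        else:
            count_r += 1
    if count_o + count_r == 0:
        return None
    return min(count_o, count_r) / (count_o + count_r)


def block_stats(blocks: Sequence[HaplotypeBlock],
                non_loh_snps: Iterable[int],
                min_size: int = 100) -> Tuple[int, float]:
    """(number of large blocks, % of non-LOH SNPs inside them).

    Large means >= ``min_size`` SNPs; the denominator is the supplied set
    of phasable non-LOH SNP indices.
    """
    universe = set(non_loh_snps)
    large = [b for b in blocks if b.size >= min_size]
    covered = {s for b in large for s in b.snp_indices if s in universe}
    pct = 100.0 * len(covered) / len(universe) if universe else 0.0
    return len(large), pct


def _merged(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap_len(a: Sequence[Tuple[int, int]],
                 b: Sequence[Tuple[int, int]]) -> int:
    a, b = _merged(a), _merged(b)
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            total += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def loh_eval(calls: Sequence[LohRegion], truth: Sequence[Tuple[int, int]]
             ) -> Tuple[Optional[float], Optional[float], int, int, int]:
    """Interval precision/sensitivity of called LOH regions.

    Returns (precision, sensitivity, length_call, length_truth,
    length_overlap); precision = overlap/call, sensitivity = overlap/truth,
    None where the denominator is empty.
    """
    call_iv = [(r.start, r.end) for r in calls]
    length_call = sum(e - s for s, e in _merged(call_iv))
    length_truth = sum(e - s for s, e in _merged(truth))
    length_overlap = _overlap_len(call_iv, truth)
    precision = length_overlap / length_call if length_call else None
    sensitivity = length_overlap / length_truth if length_truth else None
    return precision, sensitivity, length_call, length_truth, length_overlap
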