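"""Somatic-SNP filtering and LOH detection.

A cancer genome loses heterozygosity where one parental copy of a region is
gone.  We partition each chromosome into fixed windows (default 1 Mbp) and,
in each window holding N SNPs of which k are heterozygous, test k against a
Binomial(N, p) null where p is the heterozygous proportion observed in the
same window of a normal genome.  The one-tailed exact lower-tail probability
P(X <= k) below ``alpha`` flags the window as LOH.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binom

from .io_formats import SnpRecord

logger = logging.getLogger(__name__)

LABEL_LOH = "LOH"
LABEL_NON = "non-LOH"
LABEL_INSUFFICIENT = "insufficient"


@dataclass
class LohWindow:
    chrom: str
    start: int          # bp, 0-based half-open window
    end: int
    n_total: int        # N: SNPs in the window on the cancer genome
    n_het: int          # heterozygous among them
    p_het_normal: float
    p_value: float      # lower-tail exact binomial probability (nan if untested)
    label: str


@dataclass
class LohRegion:
    """Maximal run of LOH-labelled windows (bp, 0-based half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("LohRegion end must exceed start")

    def contains(self, pos: int) -> bool:
        """Membership of a 1-based SNP position (half-open in bp)."""
        return self.start <= pos - 1 < self.end


def filter_somatic(snps: Sequence[SnpRecord], known_sites: set
                   ) -> Tuple[List[SnpRecord], int]:
    """Keep only SNPs present in the known-germline site list.

    Sites are keyed by (chrom, pos, ref, alt); anything absent is treated as
    somatic and removed.  Returns (germline records, removed count).
    """
    if not known_sites:
        logger.warning("filter_somatic: empty known-site list, all %d SNPs "
                       "removed", len(snps))
    kept = [s for s in snps if s.key in known_sites]
    for s in kept:
        s.is_known_germline = True
    return kept, len(snps) - len(kept)


def loh_test(n_total: int, n_het: int, p_het_normal: float) -> float:
    """Exact one-tailed binomial test: P(X <= n_het), X ~ Bin(n_total, p).

    Computed exactly (regularized-incomplete-beta CDF, no normal
    approximation).  Degenerate reference proportions 0 and 1 are rejected.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_het <= n_total:
        raise ValueError("n_het must lie in [0, n_total]")
    if not 0.0 < p_het_normal < 1.0:
        raise ValueError("degenerate reference profile: p_het_normal must be "
                         "strictly inside (0, 1)")
    return float(binom.cdf(n_het, n_total, p_het_normal))


class NormalProfile:
    """Per-window heterozygous proportions of a normal genome.

    Backed by a table of (chrom, start, end, p_het) rows; a genome-wide
    ``default_p`` may stand in for chromosomes missing from the table.
    """

    def __init__(self, table: Optional[Dict[Tuple[str, int], float]] = None,
                 default_p: Optional[float] = None) -> None:
        self.table = table or {}
        self.default_p = default_p

    @classmethod
    def from_tsv(cls, path: str,
                 default_p: Optional[float] = None) -> "NormalProfile":
        table: Dict[Tuple[str, int], float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, start, _end, p = line.split("\t")[:4]
                table[(chrom, int(start))] = float(p)
        return cls(table, default_p)

    def lookup(self, chrom: str, start: int) -> float:
        p = self.table.get((chrom, start))
        if p is None:
            if self.default_p is None:
                raise KeyError(
                    f"no normal-profile entry for {chrom}:{start} and no "
                    "genome-wide default proportion supplied")
            p = self.default_p
        return p

    def has_chrom(self, chrom: str) -> bool:
        return self.default_p is not None or \
            any(c == chrom for c, _ in self.table)


def call_loh(snps: Sequence[SnpRecord],
             normal_profile: NormalProfile,
             window_bp: int = 1_000_000,
             alpha: float = 0.05,
             min_snps: int = 10,
             chrom_length: Optional[int] = None,
             ) -> Tuple[List[LohWindow], List[LohRegion]]:
    """Label fixed windows LOH / non-LOH and merge LOH runs into regions.

    Windows with fewer than ``min_snps`` SNPs are labelled ``insufficient``
    and then inherit the label of the nearest tested window (ties -> LOH).
    """
    if not snps:
        return [], []
    chrom = snps[0].chrom
    if not normal_profile.has_chrom(chrom):
        raise KeyError(f"chromosome {chrom} absent from normal profile")
    last = chrom_length if chrom_length is not None else snps[-1].pos
    n_windows = max(1, -(-last // window_bp))
    pos0 = np.array([s.pos - 1 for s in snps])
    het = np.array([s.genotype == "het" for s in snps])
    widx = pos0 // window_bp

    windows: List[LohWindow] = []
    for w in range(n_windows):
        mask = widx == w
        n_total = int(mask.sum())
        n_het = int(het[mask].sum())
        p = normal_profile.lookup(chrom, w * window_bp)
        if n_total >= min_snps:
            pval = loh_test(n_total, n_het, p)
            label = LABEL_LOH if pval < alpha else LABEL_NON
        else:
            pval, label = float("nan"), LABEL_INSUFFICIENT
        windows.append(LohWindow(chrom, w * window_bp,
                                 (w + 1) * window_bp, n_total, n_het,
                                 p, pval, label))

    tested = [i for i, w in enumerate(windows)
              if w.label != LABEL_INSUFFICIENT]
    if tested:
        for i, w in enumerate(windows):
            if w.label != LABEL_INSUFFICIENT:
                continue
            best = min(abs(i - j) for j in tested)
            cands = {windows[j].label for j in tested if abs(i - j) == best}
            w.label = LABEL_LOH if LABEL_LOH in cands else LABEL_NON
    else:
        logger.warning("call_loh: %s has no window with >= %d SNPs; "
                       "labelling all non-LOH", chrom, min_snps)
        for w in windows:
            w.label = LABEL_NON

    regions: List[LohRegion] = []
    for w in windows:
        if w.label != LABEL_LOH:
            continue
        if regions and regions[-1].end == w.start:
            regions[-1].end = w.end
        else:
            regions.append(LohRegion(chrom, w.start, w.end))
    return windows, regions


def drop_loh_snps(snps: Sequence[SnpRecord], regions: Sequence[LohRegion]
                  ) -> List[SnpRecord]:
    """Remove SNPs inside LOH regions (half-open bp intervals)."""
    if not regions:
        return list(snps)
    starts = sorted(r.start for r in regions)
    by_start = {r.start: r for r in regions}
    out = []
    for s in snps:
        i = bisect.bisect_right(starts, s.pos - 1) - 1
        if i >= 0 and by_start[starts[i]].contains(s.pos):
            continue
        out.append(s)
    return out


def non_loh_stretches(snp_indices: Sequence[int],
                      snps: Sequence[SnpRecord],
                      regions: Sequence[LohRegion]) -> List[List[int]]:
    """Partition SNP indices into maximal runs uninterrupted by LOH regions.

    ``snp_indices`` index the master per-chromosome SNP list; SNPs separated
    by one or more LOH regions land in different stretches (phasing units).
    """
    bounds = sorted(r.start for r in regions)
    out: List[List[int]] = []
    prev_seg = None
    for i in snp_indices:
        seg = bisect.bisect_right(bounds, snps[i].pos - 1)
        if prev_seg is None or seg != prev_seg:
            out.append([])
        out[-1].append(i)
        prev_seg = seg
    return out
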