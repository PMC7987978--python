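"""Ground-truthed synthetic cancer-genome phasing instances.

The generator emulates the pipeline's four inputs — cancer SNP calls (VCF),
Hi-C fragments (fragment file / SAM), a known-germline site list and a
normal-genome heterozygosity profile — for a single chromosome with planted
LOH segments, a global allelic copy-number imbalance (e.g. 2:1, the
near-triploid situation) and per-call error rate.

Hi-C pairs are simulated at SNP resolution: each pair anchors its first
read on a uniformly chosen SNP, places the second end at a genomic distance
drawn from a truncated power law (contact-decay exponent ~1) snapped to the
nearest SNP, draws the haplotype of origin proportionally to the local
allelic copy numbers, and reports the haplotype's allele (flipped with
probability eps) at every SNP within the read span of each end.  ``n_pairs``
therefore counts SNP-informative pairs; pairs covering no SNP carry no
phasing signal and are not materialised.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import HicFragment, SnpRecord
from .phasing import HaplotypeBlock


@dataclass
class GenomeParams:
    chrom: str = "chr1"
    length_bp: int = 20_000_000
    mean_gap_bp: float = 2_000.0
    p_het: float = 0.6                 # germline heterozygous proportion
    residual_het_frac: float = 0.08    # het survival inside LOH
    somatic_frac: float = 0.03         # sites absent from the known list
    copy_ratio: Tuple[int, int] = (2, 1)   # copies of h1, h2 outside LOH
    loh_intervals: Optional[List[Tuple[int, int]]] = None  # bp, half-open
    window_bp: int = 1_000_000

    def default_loh(self) -> List[Tuple[int, int]]:
        """Two disjoint window-aligned segments (~25-40% and ~70-80%)."""
        w = self.window_bp
        n_w = self.length_bp // w
        if n_w < 8:
            return []
        a = (round(0.25 * n_w) * w, round(0.40 * n_w) * w)
        b = (round(0.70 * n_w) * w, round(0.80 * n_w) * w)
        return [iv for iv in (a, b) if iv[1] > iv[0]]


@dataclass
class TruthModel:
    """Planted ground truth for one simulated chromosome."""

    params: GenomeParams
    seed: int
    positions: np.ndarray          # 1-based, strictly increasing
    genotype: List[str]            # cancer genotype per SNP
    germline_het: np.ndarray       # bool, normal-genome het status
    is_somatic: np.ndarray         # bool
    allele_h1: np.ndarray          # 0/1 per SNP on haplotype 1
    allele_h2: np.ndarray
    loh_intervals: List[Tuple[int, int]]
    loh_survivor: List[int]        # 1 or 2 per LOH interval

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    def in_loh(self, pos: int) -> bool:
        return any(s <= pos - 1 < e for s, e in self.loh_intervals)

    def truth_phase(self) -> Dict[int, int]:
        """h1 allele for every phasable (cancer-het, germline) SNP."""
        return {i: int(self.allele_h1[i]) for i in range(self.n_snps)
                if self.genotype[i] == "het" and not self.is_somatic[i]}

    def phasable_non_loh(self) -> List[int]:
        return [i for i in range(self.n_snps)
                if self.genotype[i] == "het" and not self.is_somatic[i]
                and not self.in_loh(int(self.positions[i]))]

    def copy_numbers_at(self, pos: np.ndarray
                        ) -> Tuple[np.ndarray, np.ndarray]:
        c1 = np.full(len(pos), self.params.copy_ratio[0], dtype=np.int64)
        c2 = np.full(len(pos), self.params.copy_ratio[1], dtype=np.int64)
        for (s, e), surv in zip(self.loh_intervals, self.loh_survivor):
            inside = (pos - 1 >= s) & (pos - 1 < e)
            if surv == 1:
                c2[inside] = 0
            else:
                c1[inside] = 0
        return c1, c2

    # --- emission -------------------------------------------------------

    def snp_records(self) -> List[SnpRecord]:
        recs = []
        for i in range(self.n_snps):
            recs.append(SnpRecord(self.params.chrom, int(self.positions[i]),
                                  "A", "G", self.genotype[i],
                                  not bool(self.is_somatic[i])))
        return recs

    def known_sites(self) -> set:
        return {(self.params.chrom, int(self.positions[i]), "A", "G")
                for i in range(self.n_snps) if not self.is_somatic[i]}

    def write_vcf(self, path: str) -> None:
        gt = {"het": "0/1", "hom_ref": "0/0", "hom_alt": "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={self.params.chrom},"
                     f"length={self.params.length_bp}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
                     "FORMAT\tTUMOR\n")
            for i in range(self.n_snps):
                fh.write(f"{self.params.chrom}\t{int(self.positions[i])}\t."
                         f"\tA\tG\t.\t.\t.\tGT\t{gt[self.genotype[i]]}\n")

    def write_known_sites(self, path: str) -> None:
        with open(path, "w") as fh:
            for i in range(self.n_snps):
                if not self.is_somatic[i]:
                    fh.write(f"{self.params.chrom}\t"
                             f"{int(self.positions[i])}\tA\tG\n")

    def write_normal_profile(self, path: str) -> None:
        """Per-window germline heterozygous proportion (Laplace-smoothed).

        The normal genome shares the cancer genome's germline sites, so the
        profile is computed from germline het status over non-somatic sites;
        empty windows fall back to the genome-wide proportion.
        """
        w = self.params.window_bp
        n_w = max(1, -(-self.params.length_bp // w))
        germ = ~self.is_somatic
        widx = (self.positions - 1) // w
        global_p = ((self.germline_het & germ).sum() + 1) / (germ.sum() + 2)
        with open(path, "w") as fh:
            for k in range(n_w):
                mask = germ & (widx == k)
                n = int(mask.sum())
                if n == 0:
                    p = global_p
                else:
                    p = (int(self.germline_het[mask].sum()) + 1) / (n + 2)
                fh.write(f"{self.params.chrom}\t{k * w}\t{(k + 1) * w}\t"
                         f"{p:.8f}\n")

    def write_truth_json(self, path: str) -> None:
        obj = {
            "chrom": self.params.chrom,
            "length_bp": self.params.length_bp,
            "seed": self.seed,
            "copy_ratio": list(self.params.copy_ratio),
            "loh_intervals": [list(iv) for iv in self.loh_intervals],
            "loh_survivor": self.loh_survivor,
            "positions": [int(p) for p in self.positions],
            "genotype": self.genotype,
            "is_somatic": [bool(b) for b in self.is_somatic],
            "allele_h1": [int(a) for a in self.allele_h1],
            "allele_h2": [int(a) for a in self.allele_h2],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def simulate_genome(params: GenomeParams = GenomeParams(),
                    seed: int = 0) -> TruthModel:
    """Plant SNPs, phases, LOH segments and somatic sites; deterministic."""
    rng = np.random.default_rng(seed)
    n_guess = int(params.length_bp / params.mean_gap_bp * 1.3) + 50
    gaps = rng.exponential(params.mean_gap_bp, size=n_guess)
    positions = np.unique(np.ceil(np.cumsum(gaps)).astype(np.int64))
    positions = positions[(positions >= 1)
                          & (positions <= params.length_bp)]
    n = len(positions)
    loh = params.loh_intervals if params.loh_intervals is not None \
        else params.default_loh()
    for (s1, e1), (s2, e2) in zip(loh, loh[1:]):
        if s2 < e1:
            raise ValueError("LOH intervals must be disjoint and sorted")
    if params.copy_ratio[0] <= 0 or params.copy_ratio[1] <= 0:
        raise ValueError("copy ratios outside LOH must be positive")

    germline_het = rng.random(n) < params.p_het
    is_somatic = rng.random(n) < params.somatic_frac
    phase = rng.integers(0, 2, size=n)  # h1 allele where het
    survivor = [int(rng.integers(1, 3)) for _ in loh]

    in_loh_idx = np.zeros(n, dtype=np.int64) - 1
    for k, (s, e) in enumerate(loh):
        in_loh_idx[(positions - 1 >= s) & (positions - 1 < e)] = k

    genotype: List[str] = []
    allele_h1 = np.zeros(n, dtype=np.int64)
    allele_h2 = np.zeros(n, dtype=np.int64)
    retained = rng.random(n) < params.residual_het_frac
    for i in range(n):
        if not germline_het[i]:
            genotype.append("hom_alt")
            allele_h1[i] = allele_h2[i] = 1
            continue
        k = in_loh_idx[i]
        if k < 0 or retained[i]:
            genotype.append("het")
            allele_h1[i] = phase[i]
            allele_h2[i] = 1 - phase[i]
        else:
            surv_allele = phase[i] if survivor[k] == 1 else 1 - phase[i]
            genotype.append("hom_alt" if surv_allele == 1 else "hom_ref")
            allele_h1[i] = allele_h2[i] = surv_allele
    return TruthModel(params, seed, positions, genotype, germline_het,
                      is_somatic, allele_h1, allele_h2,
                      [tuple(iv) for iv in loh], survivor)


def simulate_hic(truth: TruthModel, n_pairs: int,
                 distance_exponent: float = 1.0,
                 eps: float = 0.01, seed: int = 0,
                 read_len: int = 150,
                 min_dist: int = 1_000) -> List[HicFragment]:
    """Draw Hi-C read pairs from the planted haplotypes.

    See the module docstring for the pair model.  Fragments retain their
    two mates' 1-based leftmost positions for the completion step; pairs
    whose two ends collapse onto fewer than two distinct SNP calls are
    redrawn, so exactly ``n_pairs`` informative fragments return.
    """
    if n_pairs == 0:
        return []
    rng = np.random.default_rng(seed)
    pos = truth.positions
    n = truth.n_snps
    L = truth.params.length_bp
    if n < 2:
        raise ValueError("need at least two SNPs to simulate Hi-C pairs")

    frags: List[HicFragment] = []
    serial = 0
    log_ratio = np.log(max(L / min_dist, 1.000001))
    while len(frags) < n_pairs:
        m = int((n_pairs - len(frags)) * 1.4) + 32
        a1 = rng.integers(0, n, size=m)
        p1 = pos[a1]
        if abs(distance_exponent - 1.0) < 1e-9:
            d = min_dist * np.exp(rng.random(m) * log_ratio)
        else:
            # inverse-CDF for density ∝ d^-k on [min_dist, L]
            k = distance_exponent
            u = rng.random(m)
            lo, hi = min_dist ** (1 - k), L ** (1 - k)
            d = (lo + u * (hi - lo)) ** (1.0 / (1 - k))
        sign = np.where(rng.random(m) < 0.5, -1.0, 1.0)
        p2_point = np.clip(p1 + sign * d, 1, L)
        a2 = np.clip(np.searchsorted(pos, p2_point), 0, n - 1)
        left = np.clip(a2 - 1, 0, n - 1)
        a2 = np.where(np.abs(pos[left] - p2_point)
                      <= np.abs(pos[a2] - p2_point), left, a2)
        # haplotype of origin ∝ copy number at the first end; pairs whose
        # chosen copy is absent at the other end (LOH boundary) are invalid
        c1a, c2a = truth.copy_numbers_at(p1)
        c1b, c2b = truth.copy_numbers_at(pos[a2])
        hap = np.where(rng.random(m) * (c1a + c2a) < c1a, 1, 2)
        valid = (a1 != a2) & np.where(hap == 1, c1b > 0, c2b > 0) \
            & np.where(hap == 1, c1a > 0, c2a > 0)
        off1 = rng.integers(0, read_len, size=m)
        off2 = rng.integers(0, read_len, size=m)
        start1 = np.clip(p1 - off1, 1, L - read_len + 1)
        start2 = np.clip(pos[a2] - off2, 1, L - read_len + 1)
        lo1 = np.searchsorted(pos, start1)
        hi1 = np.searchsorted(pos, start1 + read_len)
        lo2 = np.searchsorted(pos, start2)
        hi2 = np.searchsorted(pos, start2 + read_len)
        n_cov = (hi1 - lo1) + (hi2 - lo2)
        flips = rng.random(int(n_cov[valid].sum())) < eps
        fi = 0
        h1, h2 = truth.allele_h1, truth.allele_h2
        for r in np.nonzero(valid)[0]:
            src = h1 if hap[r] == 1 else h2
            calls: Dict[int, int] = {}
            for lo_i, hi_i in ((lo1[r], hi1[r]), (lo2[r], hi2[r])):
                for si in range(lo_i, hi_i):
                    al = int(src[si]) ^ int(flips[fi])
                    fi += 1
                    calls.setdefault(int(si), al)
            if len(calls) < 2:
                continue
            frag = HicFragment(
                f"sim{seed}_{serial}",
                [(i, calls[i], 40) for i in sorted(calls)],
                end_positions=(int(min(start1[r], start2[r])),
                               int(max(start1[r], start2[r]))))
            frags.append(frag)
            serial += 1
            if len(frags) == n_pairs:
                break
    return frags


def write_sam(truth: TruthModel, fragments: Sequence[HicFragment],
              path: str, read_len: int = 150, mapq: int = 60) -> None:
    """Emit the simulated pairs as a minimal text SAM against a synthetic
    reference (reference base 'A' everywhere, so ref allele reads are 'A'
    and alt allele reads are 'G' at SNP sites).

    Each fragment's two mates are placed at its recorded end positions;
    every call the fragment carries falls inside one of the mates.
    """
    chrom = truth.params.chrom
    pos = truth.positions
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{truth.params.length_bp}\n")
        for frag in fragments:
            if frag.end_positions is None:
                continue
            s1, s2 = frag.end_positions
            for mate, (start, flag) in enumerate(((s1, 0x1 | 0x40),
                                                  (s2, 0x1 | 0x80))):
                seq = ["A"] * read_len
                for si, allele, _q in frag.calls:
                    off = int(pos[si]) - start
                    if 0 <= off < read_len:
                        seq[off] = "G" if allele == 1 else "A"
                fh.write(f"{frag.fragment_id}\t{flag | 0x2}\t{chrom}\t"
                         f"{start}\t{mapq}\t{read_len}M\t=\t"
                         f"{s2 if mate == 0 else s1}\t0\t"
                         f"{''.join(seq)}\t{'I' * read_len}\n")


def plant_switch(block: HaplotypeBlock, position: int) -> HaplotypeBlock:
    """Invert the phase of every SNP at or after ``position`` (block index).

    An involution: planting twice at the same position is the identity;
    a position at or beyond the block end leaves the block unchanged.
    """
    phase = [1 - p if k >= position else p
             for k, p in enumerate(block.phase)]
    return HaplotypeBlock(block.block_id, list(block.snp_indices), phase,
                          block.region_id)


def write_outputs(truth: TruthModel, fragments: Sequence[HicFragment],
                  outdir: str) -> Dict[str, str]:
    """Write the full input set (VCF, known sites, profile, fragments,
    pair positions, truth JSON) and return the path map."""
    from .io_formats import write_fragment_file, write_pair_positions

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": os.path.join(outdir, "tumor.vcf"),
        "known_sites": os.path.join(outdir, "known_sites.tsv"),
        "profile": os.path.join(outdir, "normal_profile.tsv"),
        "fragments": os.path.join(outdir, "fragments.txt"),
        "pairs": os.path.join(outdir, "pair_positions.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    truth.write_vcf(paths["vcf"])
    truth.write_known_sites(paths["known_sites"])
    truth.write_normal_profile(paths["profile"])
    write_fragment_file(fragments, paths["fragments"])
    write_pair_positions(fragments, paths["pairs"])
    truth.write_truth_json(paths["truth"])
    return paths
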