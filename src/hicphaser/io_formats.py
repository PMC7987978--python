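"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions: VCF positions and in-memory :class:`SnpRecord.pos` are
1-based inclusive; BED output is 0-based half-open; all internal SNP *indices*
are 0-based positions into a chromosome's SNP list.  The fragment file is the
HAPCUT2 dialect (1-based SNP indices in-file, converted to 0-based in memory).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam

logger = logging.getLogger(__name__)

GENOTYPES = ("het", "hom_ref", "hom_alt")


@dataclass
class SnpRecord:
    """One biallelic SNP site."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotype: str  # het | hom_ref | hom_alt
    is_known_germline: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("SNPs only: ref and alt must be single bases")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"bad genotype {self.genotype!r}")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class HicFragment:
    """Alleles observed by one read pair at covered SNPs.

    ``calls`` holds ``(snp_index, allele, base_quality)`` triples sorted by
    0-based ``snp_index`` with no duplicates; ``allele`` is 0 (ref) / 1 (alt).
    ``end_positions`` optionally records the two mates' 1-based leftmost
    mapping positions (used to link LOH regions to haplotypes in completion).
    """

    fragment_id: str
    calls: List[Tuple[int, int, int]]
    end_positions: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        idx = [c[0] for c in self.calls]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError(f"fragment {self.fragment_id}: calls must be "
                             "sorted by snp_index without duplicates")

    @property
    def n_calls(self) -> int:
        return len(self.calls)


def read_snps(vcf_path: str,
              chrom_filter: Optional[Iterable[str]] = None,
              ) -> Dict[str, List[SnpRecord]]:
    """Read biallelic SNP records per chromosome from a VCF 4.x file.

    Multi-allelic records, indels and records without GT are skipped (counted
    in the log).  Genotype classification: 0/1 or 1/0 -> het, 0/0 -> hom_ref,
    1/1 -> hom_alt.  Raises on an unsorted or duplicated position.
    """
    wanted = set(chrom_filter) if chrom_filter is not None else None
    out: Dict[str, List[SnpRecord]] = {}
    skipped = 0
    with pysam.VariantFile(vcf_path) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if wanted is not None and rec.chrom not in wanted:
                continue
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1 \
                    or alts[0] not in "ACGT":
                skipped += 1
                continue
            if not rec.samples:
                skipped += 1
                continue
            gt = rec.samples[0].get("GT")
            if gt is None or None in gt or len(gt) != 2:
                skipped += 1
                continue
            if set(gt) == {0, 1}:
                genotype = "het"
            elif set(gt) == {0}:
                genotype = "hom_ref"
            elif set(gt) == {1}:
                genotype = "hom_alt"
            else:
                skipped += 1  # involves an allele index we do not model
                continue
            snp = SnpRecord(rec.chrom, rec.pos, rec.ref, alts[0], genotype)
            lst = out.setdefault(rec.chrom, [])
            if lst and snp.pos <= lst[-1].pos:
                raise ValueError(
                    f"VCF not sorted / duplicate position at "
                    f"{rec.chrom}:{snp.pos}")
            lst.append(snp)
    if skipped:
        logger.info("read_snps: skipped %d non-SNP/multi-allelic/no-GT "
                    "records", skipped)
    return out


def _read_calls(read: "pysam.AlignedSegment",
                positions: Sequence[int],
                pos_index: Dict[int, int],
                snps: Sequence[SnpRecord]) -> List[Tuple[int, int, int]]:
    """Match read bases to ref/alt at covered SNPs; no call on mismatch."""
    import bisect
    calls: List[Tuple[int, int, int]] = []
    start, end = read.reference_start, read.reference_end
    if end is None:
        return calls
    lo = bisect.bisect_left(positions, start + 1)   # SnpRecord.pos is 1-based
    hi = bisect.bisect_right(positions, end)
    if lo >= hi:
        return calls
    ref2query = {rpos: qpos for qpos, rpos in
                 read.get_aligned_pairs(matches_only=True)}
    seq = read.query_sequence
    quals = read.query_qualities
    for k in range(lo, hi):
        rpos0 = positions[k] - 1
        qpos = ref2query.get(rpos0)
        if qpos is None or seq is None:
            continue
        base = seq[qpos]
        snp = snps[pos_index[positions[k]]]
        if base == snp.ref_allele:
            allele = 0
        elif base == snp.alt_allele:
            allele = 1
        else:
            continue  # matches neither: sequencing error, no call
        q = int(quals[qpos]) if quals is not None else 30
        calls.append((k, allele, q))
    return calls


def extract_fragments(alignment_path: str,
                      snps: Dict[str, List[SnpRecord]],
                      mapq_min: int = 30) -> Dict[str, List[HicFragment]]:
    """Extract per-pair phasing fragments from SAM/BAM alignments.

    Both mates of a read pair contribute calls to one fragment.  Alignments
    with MAPQ <= ``mapq_min`` (strictly-higher-than filter), secondary,
    supplementary, duplicate or unmapped flags are excluded.
    Inter-chromosomal pairs and fragments with fewer than two calls are
    dropped.  Returns fragments per chromosome.
    """
    positions = {c: [s.pos for s in lst] for c, lst in snps.items()}
    pos_index = {c: {p: i for i, p in enumerate(ps)}
                 for c, ps in positions.items()}
    # qname -> (chrom set, calls, end positions)
    pending: Dict[str, Tuple[set, dict, list]] = {}
    mode = "rb" if alignment_path.endswith(".bam") else "r"
    with pysam.AlignmentFile(alignment_path, mode) as af:
        for read in af:
            if (read.is_unmapped or read.is_secondary
                    or read.is_supplementary or read.is_duplicate):
                continue
            if read.mapping_quality <= mapq_min:
                continue
            chrom = read.reference_name
            if chrom not in snps:
                continue
            entry = pending.setdefault(read.query_name, (set(), {}, []))
            entry[0].add(chrom)
            entry[2].append(read.reference_start + 1)
            for call in _read_calls(read, positions[chrom],
                                    pos_index[chrom], snps[chrom]):
                k, allele, q = call
                prev = entry[1].get(k)
                if prev is None:
                    entry[1][k] = (allele, q)
                elif prev[0] != allele:
                    entry[1][k] = None  # mates disagree: discard the call
        out: Dict[str, List[HicFragment]] = {c: [] for c in snps}
        for qname, (chroms, calldict, ends) in pending.items():
            if len(chroms) != 1:
                continue  # inter-chromosomal pair
            chrom = next(iter(chroms))
            calls = sorted((k, v[0], v[1]) for k, v in calldict.items()
                           if v is not None)
            if len(calls) < 2:
                continue
            ep = (min(ends), max(ends)) if ends else None
            out[chrom].append(HicFragment(qname, calls, end_positions=ep))
    return out


# --- HAPCUT2 fragment file dialect --------------------------------------

def _runs(calls: Sequence[Tuple[int, int, int]]
          ) -> List[Tuple[int, List[Tuple[int, int, int]]]]:
    runs: List[Tuple[int, List[Tuple[int, int, int]]]] = []
    for c in calls:
        if runs and c[0] == runs[-1][0] + len(runs[-1][1]):
            runs[-1][1].append(c)
        else:
            runs.append((c[0], [c]))
    return runs


def write_fragment_file(fragments: Iterable[HicFragment], path: str) -> None:
    """Write fragments in the HAPCUT2 fragment format (1-based indices)."""
    with open(path, "w") as fh:
        for frag in fragments:
            runs = _runs(frag.calls)
            fields = [str(len(runs)), frag.fragment_id]
            quals = []
            for start, items in runs:
                fields.append(str(start + 1))
                fields.append("".join(str(a) for _, a, _ in items))
                quals.extend(q for _, _, q in items)
            fields.append("".join(chr(min(q, 93) + 33) for q in quals))
            fh.write(" ".join(fields) + "\n")


def read_fragment_file(path: str) -> List[HicFragment]:
    """Read a HAPCUT2-dialect fragment file; inverse of write_fragment_file."""
    frags: List[HicFragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            try:
                n_runs = int(parts[0])
                frag_id = parts[1]
                if len(parts) != 2 + 2 * n_runs + 1:
                    raise ValueError("field count mismatch")
                qualstr = parts[-1]
                calls: List[Tuple[int, int, int]] = []
                qi = 0
                for r in range(n_runs):
                    start = int(parts[2 + 2 * r]) - 1
                    alleles = parts[3 + 2 * r]
                    for off, ch in enumerate(alleles):
                        if ch not in "01":
                            raise ValueError(f"bad allele {ch!r}")
                        calls.append((start + off, int(ch),
                                      ord(qualstr[qi]) - 33))
                        qi += 1
                if qi != len(qualstr):
                    raise ValueError("quality string length mismatch")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed fragment line "
                                 f"{lineno}: {exc}") from exc
            frags.append(HicFragment(frag_id, calls))
    return frags


def write_pair_positions(fragments: Iterable[HicFragment], path: str) -> None:
    """Write a TSV of fragment end positions (completion-step side channel)."""
    with open(path, "w") as fh:
        for frag in fragments:
            if frag.end_positions is None:
                continue
            p1, p2 = frag.end_positions
            fh.write(f"{frag.fragment_id}\t{p1}\t{p2}\n")


def read_pair_positions(path: str) -> Dict[str, Tuple[int, int]]:
    out: Dict[str, Tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fid, p1, p2 = line.split("\t")
            out[fid] = (int(p1), int(p2))
    return out


# --- phased VCF / BED output --------------------------------------------

def write_phased_vcf(haplotypes, snps: List[SnpRecord], path: str,
                     sample: str = "SAMPLE") -> None:
    """Write phased genotypes with PS tags (block's first SNP position).

    ``haplotypes`` maps a 0-based snp index to ``(phase, phase_set)`` where
    ``phase`` is the h1 allele (1 -> "1|0", 0 -> "0|1").  Heterozygous SNPs
    without an assignment are written unphased "0/1".
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description='
                 '"Phase set">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for i, snp in enumerate(snps):
            if snp.genotype == "hom_ref":
                gt, fmt = "0/0", "GT"
            elif snp.genotype == "hom_alt":
                gt, fmt = "1/1", "GT"
            elif i in haplotypes:
                phase, ps = haplotypes[i]
                gt = f"{phase}|{1 - phase}:{ps}"
                fmt = "GT:PS"
            else:
                gt, fmt = "0/1", "GT"
            fh.write(f"{snp.chrom}\t{snp.pos}\t.\t{snp.ref_allele}\t"
                     f"{snp.alt_allele}\t.\t.\t.\t{fmt}\t{gt}\n")


def write_loh_bed(regions, path: str) -> None:
    """Write LOH regions as sorted BED (0-based half-open)."""
    with open(path, "w") as fh:
        for reg in sorted(regions, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{reg.chrom}\t{reg.start}\t{reg.end}\n")


def read_phased_vcf(path: str) -> Dict[str, List[Tuple[int, int, int]]]:
    """Read phased heterozygous genotypes: per chromosome, a list of
    (pos, h1 allele, phase set) for records carrying GT x|y with PS."""
    out: Dict[str, List[Tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            fmt = parts[8].split(":")
            sample = parts[9].split(":")
            gt = sample[fmt.index("GT")]
            if "|" not in gt or "PS" not in fmt:
                continue
            a, b = gt.split("|")
            if a == b:
                continue
            ps = int(sample[fmt.index("PS")])
            out.setdefault(parts[0], []).append(
                (int(parts[1]), int(a), ps))
    return out


def read_loh_bed(path: str):
    """Read LOH regions back from BED (inverse of write_loh_bed)."""
    from .preprocess import LohRegion

    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end = line.split()[:3]
            regions.append(LohRegion(chrom, int(start), int(end)))
    return regions


def read_known_sites(path: str) -> set:
    """Read a known-germline site table: chrom, pos, ref, alt (TSV)."""
    sites = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, ref, alt = line.split("\t")[:4]
            sites.add((chrom, int(pos), ref, alt))
    return sites
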