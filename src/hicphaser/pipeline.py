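"""End-to-end orchestration of the four pipeline steps.

Per chromosome: somatic filtering -> windowed LOH detection -> phasing of
each continuous non-LOH stretch -> coverage-imbalance switch correction ->
CMG assembly of fragmented blocks -> (optional) LD gap filling ->
chromosome-level completion -> evaluation.  Fully deterministic given the
configured seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import cmg_assembly, completing, evaluation, gapfill_ld, io_formats, \
    phasing, preprocess, switch_correct
from .io_formats import HicFragment, SnpRecord
from .phasing import HaplotypeBlock
from .preprocess import LohRegion, NormalProfile

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs
    vcf: str = ""
    known_sites: str = ""
    normal_profile: str = ""
    fragments: Optional[str] = None       # HAPCUT2-dialect fragment file
    pair_positions: Optional[str] = None  # side-channel mate positions
    alignments: Optional[str] = None      # SAM/BAM alternative to fragments
    truth: Optional[str] = None           # simulator truth JSON (optional)
    outdir: str = "hicphaser_out"
    # thresholds (defaults follow the method's published parenthesised
    # values: 1 Mbp window, alpha 0.05, MAPQ 30, switch ratios 2 / 0.5,
    # pair distance 1 Mbp, 5 nearest, 100-SNP blocks, coverage 10,
    # reliability 0.4)
    window_bp: int = 1_000_000
    alpha: float = 0.05
    min_snps: int = 10
    mapq: int = 30
    min_support: int = 2
    switch_hi: float = 2.0
    switch_lo: float = 0.5
    max_dist: int = 1_000_000
    n_nearest: int = 5
    min_block: int = 100
    min_cov: int = 10
    reliability_thresh: float = 0.4
    weight_mode: str = "matched-support"
    M: int = 100
    seed: int = 0
    engine: str = "builtin"               # builtin | hapcut2
    gapfill_engine: Optional[object] = None  # PhasingEngine adapter or None
    default_p_het: Optional[float] = None

    def validate(self) -> None:
        positives = {"window_bp": self.window_bp, "min_snps": self.min_snps,
                     "max_dist": self.max_dist, "n_nearest": self.n_nearest,
                     "min_block": self.min_block, "M": self.M,
                     "switch_hi": self.switch_hi}
        for name, v in positives.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.switch_lo < self.switch_hi:
            raise ValueError("need 0 < switch_lo < switch_hi")
        if not 0 < self.reliability_thresh <= 1:
            raise ValueError("reliability_thresh must lie in (0, 1]")
        if self.min_cov < 0 or self.mapq < 0 or self.min_support < 0:
            raise ValueError("min_cov, mapq and min_support must be >= 0")
        if self.weight_mode not in ("matched-support", "as-printed"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.engine not in ("builtin", "hapcut2"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.fragments is None and self.alignments is None:
            raise ValueError("either fragments or alignments must be given")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class ChromosomeResult:
    chrom: str
    n_input_snps: int = 0
    n_somatic_removed: int = 0
    n_loh_snps_removed: int = 0
    loh_regions: List[LohRegion] = field(default_factory=list)
    blocks: List[HaplotypeBlock] = field(default_factory=list)
    switch_positions: List[int] = field(default_factory=list)
    completion: Optional[completing.ChromosomeHaplotypes] = None
    report: Optional[evaluation.EvalReport] = None
    phased: Dict[int, Tuple[int, int]] = field(default_factory=dict)
    unphased: List[int] = field(default_factory=list)


def _coverage_vectors(block: HaplotypeBlock,
                      coverage: Dict[int, Tuple[int, int]]
                      ) -> switch_correct.AlleleCoverage:
    c1 = [coverage.get(s, (0, 0))[0] for s in block.snp_indices]
    c2 = [coverage.get(s, (0, 0))[1] for s in block.snp_indices]
    return switch_correct.AlleleCoverage(c1, c2)


def _load_fragments(config: PipelineConfig,
                    snps: Dict[str, List[SnpRecord]]
                    ) -> Dict[str, List[HicFragment]]:
    if config.alignments is not None:
        return io_formats.extract_fragments(config.alignments, snps,
                                            config.mapq)
    frags = io_formats.read_fragment_file(config.fragments)
    if config.pair_positions:
        pp = io_formats.read_pair_positions(config.pair_positions)
        for f in frags:
            f.end_positions = pp.get(f.fragment_id)
    if len(snps) != 1:
        raise ValueError("a fragment file carries no chromosome labels; "
                         "supply a single-chromosome VCF or SAM/BAM input")
    return {next(iter(snps)): frags}


def run_pipeline(config: PipelineConfig) -> Dict[str, ChromosomeResult]:
    """Execute the full pipeline; returns one result per chromosome.

    Writes ``phased.vcf``, ``loh.bed``, ``chromosome_map.tsv`` and
    ``report.json`` under ``config.outdir``.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    snps_by_chrom = io_formats.read_snps(config.vcf)
    known = io_formats.read_known_sites(config.known_sites)
    profile = NormalProfile.from_tsv(config.normal_profile,
                                     default_p=config.default_p_het)
    frags_by_chrom = _load_fragments(config, snps_by_chrom)
    truth = None
    if config.truth:
        with open(config.truth) as fh:
            truth = json.load(fh)

    results: Dict[str, ChromosomeResult] = {}
    all_regions: List[LohRegion] = []
    for chrom in sorted(snps_by_chrom):
        res = _run_chromosome(config, chrom, snps_by_chrom[chrom],
                              frags_by_chrom.get(chrom, []), known,
                              profile, truth)
        results[chrom] = res
        all_regions.extend(res.loh_regions)

    io_formats.write_loh_bed(all_regions,
                             os.path.join(config.outdir, "loh.bed"))
    _write_outputs(config, snps_by_chrom, results)
    return results


def _run_chromosome(config: PipelineConfig, chrom: str,
                    snps: List[SnpRecord],
                    fragments: List[HicFragment],
                    known: set, profile: NormalProfile,
                    truth: Optional[dict]) -> ChromosomeResult:
    res = ChromosomeResult(chrom, n_input_snps=len(snps))
    master_index = {s.pos: i for i, s in enumerate(snps)}

    # Step 1: pre-phasing processing
    germline, res.n_somatic_removed = preprocess.filter_somatic(snps, known)
    logger.info("%s: %d SNPs in, %d somatic removed", chrom, len(snps),
                res.n_somatic_removed)
    chrom_len = None
    starts = [st for (c, st) in profile.table if c == chrom]
    if starts:
        chrom_len = max(starts) + config.window_bp
    windows, regions = preprocess.call_loh(
        germline, profile, config.window_bp, config.alpha,
        config.min_snps, chrom_length=chrom_len)
    res.loh_regions = regions
    kept = preprocess.drop_loh_snps(germline, regions)
    res.n_loh_snps_removed = len(germline) - len(kept)
    logger.info("%s: %d LOH regions, %d SNPs dropped inside them", chrom,
                len(regions), res.n_loh_snps_removed)
    phasable = [master_index[s.pos] for s in kept if s.genotype == "het"]
    if not phasable:
        logger.info("%s: entirely LOH, nothing to phase", chrom)
        res.unphased = []
        return res
    stretches = preprocess.non_loh_stretches(phasable, snps, regions)

    # Step 2: phasing each continuous non-LOH stretch
    if config.engine == "hapcut2":
        frag_path = os.path.join(config.outdir, f"{chrom}.frags")
        io_formats.write_fragment_file(fragments, frag_path)
        blocks = phasing.phase_with_hapcut2(frag_path, config.vcf,
                                            config.outdir)
        for blk in blocks:  # restrict to non-LOH het SNPs per stretch
            blk.region_id = 0
    else:
        votes = phasing.linkage_votes(fragments, set(phasable))
        blocks = []
        for rid, stretch in enumerate(stretches):
            sset = set(stretch)
            sub = {p: v for p, v in votes.items()
                   if p[0] in sset and p[1] in sset}
            blocks.extend(phasing.blocks_from_votes(
                sub, stretch, config.min_support, rid))
    logger.info("%s: %d stretches phased into %d blocks", chrom,
                len(stretches), len(blocks))

    # Step 3a: switch-error correction from allelic coverage imbalance
    coverage = cmg_assembly.allele_coverage_by_haplotype(fragments, blocks)
    corrected: List[HaplotypeBlock] = []
    for blk in blocks:
        if blk.size < 2:
            corrected.append(blk)
            continue
        fixed, applied = switch_correct.correct_switches(
            blk, _coverage_vectors(blk, coverage),
            config.switch_hi, config.switch_lo)
        corrected.append(fixed)
        res.switch_positions.extend(applied)
    blocks = corrected
    if res.switch_positions:
        logger.info("%s: corrected %d switch points", chrom,
                    len(res.switch_positions))

    # Step 3b: CMG assembly of fragmented blocks
    coverage = cmg_assembly.allele_coverage_by_haplotype(fragments, blocks)
    graph = cmg_assembly.build_cmg(
        snps, blocks, coverage, config.max_dist, config.n_nearest,
        config.min_block, config.min_cov, config.reliability_thresh,
        config.weight_mode)
    if graph.bundles:
        solution = cmg_assembly.solve_min_multi_cut(graph, M=config.M,
                                                    seed=config.seed)
        blocks = cmg_assembly.apply_cut(blocks, solution)
        logger.info("%s: CMG with %d bundles -> %d blocks (cut weight "
                    "%.3f)", chrom, len(graph.bundles), len(blocks),
                    solution.cut_weight)

    # Step 3c: LD gap filling (adapter; skipped without an engine)
    if config.gapfill_engine is not None:
        blocks = _gapfill(config, blocks, snps)
    res.blocks = blocks

    # Step 4: completion against LOH regions
    main_blocks = _main_blocks(blocks)
    if regions and main_blocks:
        support = completing.count_link_support(fragments, regions,
                                                main_blocks, snps)
        res.completion = completing.complete_chromosome(
            support, M=config.M, seed=config.seed)
        for r, blk in enumerate(main_blocks):
            if res.completion.orientation.get(r):
                flipped = blk.flipped()
                for k, b in enumerate(blocks):
                    if b is blk:
                        blocks[k] = flipped
                        break
                main_blocks[r] = flipped
        res.blocks = blocks

    # final per-SNP assignment: blocks of >= 2 SNPs are emitted phased
    for blk in blocks:
        if blk.size < 2:
            res.unphased.extend(blk.snp_indices)
            continue
        ps = snps[blk.snp_indices[0]].pos
        for s, ph in zip(blk.snp_indices, blk.phase):
            res.phased[s] = (ph, ps)
    already = set(res.unphased)
    res.unphased.extend(s for s in phasable
                        if s not in res.phased and s not in already)

    res.report = _evaluate(config, chrom, res, snps, truth)
    return res


def _main_blocks(blocks: Sequence[HaplotypeBlock]) -> List[HaplotypeBlock]:
    """Largest block per non-LOH region, ordered by region."""
    best: Dict[int, HaplotypeBlock] = {}
    for blk in blocks:
        cur = best.get(blk.region_id)
        if cur is None or blk.size > cur.size:
            best[blk.region_id] = blk
    return [best[r] for r in sorted(best)]


def _gapfill(config: PipelineConfig, blocks: List[HaplotypeBlock],
             snps: Sequence[SnpRecord]) -> List[HaplotypeBlock]:
    assignment = gapfill_ld.cluster_tiny_blocks(blocks, snps,
                                                config.min_block)
    by_id = {b.block_id: b for b in blocks}
    grouped: Dict[str, List[HaplotypeBlock]] = {}
    for tiny_id, (main_id, _d) in assignment.assigned.items():
        grouped.setdefault(main_id, []).append(by_id[tiny_id])
    out = [b for b in blocks
           if b.block_id not in assignment.assigned]
    for main_id, tinies in grouped.items():
        main = by_id[main_id]
        seed_in = gapfill_ld.build_seed_input(main, tinies)
        try:
            engine_phase = config.gapfill_engine.phase(seed_in, snps)
        except Exception as exc:  # engine unavailable: skip the cluster
            logger.warning("gapfill engine failed (%s); cluster around %s "
                           "left unphased", exc, main_id)
            out.extend(tinies)
            continue
        merged = gapfill_ld.merge_imputed(engine_phase, seed_in, main)
        out[out.index(main)] = merged
    return out


def _evaluate(config: PipelineConfig, chrom: str, res: ChromosomeResult,
              snps: Sequence[SnpRecord],
              truth: Optional[dict]) -> evaluation.EvalReport:
    report = evaluation.EvalReport(chrom)
    non_loh_het = [i for i, s in enumerate(snps) if s.genotype == "het"
                   and s.is_known_germline
                   and not any(r.contains(s.pos) for r in res.loh_regions)]
    report.n_large_blocks, report.pct_snps_in_large_blocks = \
        evaluation.block_stats(res.blocks, non_loh_het, config.min_block)
    if truth is not None and truth.get("chrom") == chrom:
        pos_to_master = {s.pos: i for i, s in enumerate(snps)}
        truth_phase = {}
        for k, p in enumerate(truth["positions"]):
            if truth["genotype"][k] == "het" and not truth["is_somatic"][k]:
                m = pos_to_master.get(p)
                if m is not None:
                    truth_phase[m] = truth["allele_h1"][k]
        largest = max(res.blocks, key=lambda b: b.size, default=None)
        if largest is not None and largest.size >= 2:
            report.aer_largest_block = evaluation.compute_aer(largest,
                                                              truth_phase)
        truth_iv = [tuple(iv) for iv in truth["loh_intervals"]]
        (report.loh_precision, report.loh_sensitivity, report.length_call,
         report.length_truth, report.length_overlap) = \
            evaluation.loh_eval(res.loh_regions, truth_iv)
    return report


def _write_outputs(config: PipelineConfig,
                   snps_by_chrom: Dict[str, List[SnpRecord]],
                   results: Dict[str, ChromosomeResult]) -> None:
    vcf_path = os.path.join(config.outdir, "phased.vcf")
    map_path = os.path.join(config.outdir, "chromosome_map.tsv")
    with open(vcf_path, "w") as out, open(map_path, "w") as cmap:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                  'Description="Genotype">\n')
        out.write('##FORMAT=<ID=PS,Number=1,Type=Integer,'
                  'Description="Phase set">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                  "\tSAMPLE\n")
        cmap.write("chrom\thaplotype\torder\tkind\tstart\tend\tregion"
                   "\thap_of_region\n")
        for chrom in sorted(results):
            res = results[chrom]
            snps = snps_by_chrom[chrom]
            for i, snp in enumerate(snps):
                if snp.genotype == "hom_ref":
                    gt, fmt = "0/0", "GT"
                elif snp.genotype == "hom_alt":
                    gt, fmt = "1/1", "GT"
                elif i in res.phased:
                    ph, ps = res.phased[i]
                    gt, fmt = f"{ph}|{1 - ph}:{ps}", "GT:PS"
                else:
                    gt, fmt = "0/1", "GT"
                out.write(f"{chrom}\t{snp.pos}\t.\t{snp.ref_allele}\t"
                          f"{snp.alt_allele}\t.\t.\t.\t{fmt}\t{gt}\n")
            if res.completion is not None:
                for hap_no, segs in ((1, res.completion.hap1),
                                     (2, res.completion.hap2)):
                    for k, seg in enumerate(segs):
                        cmap.write(f"{chrom}\t{hap_no}\t{k}\t{seg.kind}\t"
                                   f"{seg.start}\t{seg.end}\t{seg.region}"
                                   f"\t{seg.hap if seg.hap else ''}\n")
    reports = {c: asdict(r.report) for c, r in results.items()
               if r.report is not None}
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(reports, fh, indent=2)
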