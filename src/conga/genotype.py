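"""Orchestration and I/O: read candidates, filter, profile depth, score and
call every candidate, write TSV/VCF output."""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pysam

from . import filters as _filters
from .depth import GCProfile, build_gc_profile, expected_diploid_depth, interval_read_count
from .filters import MappabilityTrack
from .model import (
    Call,
    CallThresholds,
    CandidateCNV,
    CNVType,
    GenotypeCall,
    LikelihoodSet,
    ZygositySource,
    call_genotype,
    compute_likelihoods,
    expected_depths_for,
)
from .splitread import SplitReadParams, duplication_read_pair_support

logger = logging.getLogger(__name__)

FILTER_PASS = "PASS"
FILTER_LOW_MAPPABILITY = "LOW_MAPPABILITY"
FILTER_OVERLAP = "OVERLAP_REMOVED"
FILTER_TOO_SMALL = "TOO_SMALL"
FILTER_NO_DATA = "NO_DATA"


@dataclass
class RunConfig:
    """All tunables of one genotyping run; serialized into output headers."""

    mapq_min: int = 30
    min_mappability: float = 0.9
    min_size: int = 1000
    del_call: float = 0.5
    ref_call: float = 2.0
    dup_call: float = 0.5
    dup_rescue_cscore: float = 10.0
    dup_rescue_rp: int = 10
    gc_window: int = 1000
    gc_step: int = 1000
    loess_span: float = 0.3
    epsilon_floor: float = 0.01
    splitread: bool = True
    seed: int = 0

    def thresholds(self) -> CallThresholds:
        return CallThresholds(
            del_call=self.del_call,
            ref_call=self.ref_call,
            dup_call=self.dup_call,
            dup_rescue_cscore=self.dup_rescue_cscore,
            dup_rescue_rp=self.dup_rescue_rp,
        )

    def header_line(self) -> str:
        items = " ".join(f"{k}={v}" for k, v in asdict(self).items())
        return f"# conga config: {items}"


@dataclass
class GenotypeRecord:
    """Per-candidate assembly of depth, likelihoods and the final call."""

    candidate: CandidateCNV
    observed: Optional[int] = None
    e0: float = float("nan")
    e1: float = float("nan")
    e2: float = float("nan")
    log_l0: float = float("nan")
    log_l1: float = float("nan")
    log_l2: float = float("nan")
    c_score: float = float("nan")
    read_pair_support: int = 0
    call: Call = Call.MISSING
    zygosity_source: Optional[ZygositySource] = None
    filter_status: str = FILTER_PASS

    @property
    def is_variant_call(self) -> bool:
        return self.call in (Call.HET, Call.HOM)


def read_candidates(path: str) -> List[CandidateCNV]:
    """Parse a BED-like candidate file: chrom, start, end, svtype[, id].

    0-based half-open coordinates; '#'-prefixed comment lines are skipped;
    ids are auto-generated as chrom_start_end_type when absent.  Returns
    candidates sorted by (chrom, start).
    """
    candidates: List[CandidateCNV] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 4 tab-separated columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            try:
                cnv_type = CNVType(fields[3].upper())
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unknown svtype {fields[3]!r} (expected DEL or DUP)"
                ) from exc
            cid = fields[4] if len(fields) > 4 and fields[4] else f"{chrom}_{start}_{end}_{cnv_type.value}"
            candidates.append(CandidateCNV(cid, chrom, start, end, cnv_type))
    candidates.sort(key=lambda c: (c.chrom, c.b_left))
    return candidates


def genotype_all(
    bam_path: str,
    ref_path: str,
    candidates: Sequence[CandidateCNV],
    mappability: Optional[MappabilityTrack] = None,
    config: Optional[RunConfig] = None,
    satellite_mask=None,
    gc_profile: Optional[GCProfile] = None,
) -> List[GenotypeRecord]:
    """Run the full genotyping pipeline and return one record per input
    candidate (filtered candidates keep their filter status, call NA).

    Pipeline: minimum-size filter -> mappability filter (when a track is
    given) -> same-type overlap removal -> GC profile (once per BAM) ->
    per candidate: contained-read count, GC-normalised diploid expectation,
    three-state Poisson likelihoods, optional duplication split-read
    support, threshold calling.
    """
    config = config or RunConfig()
    records: Dict[str, GenotypeRecord] = {
        c.id: GenotypeRecord(candidate=c) for c in candidates
    }
    if len(records) != len(candidates):
        raise ValueError("candidate ids are not unique")

    # canonical filter order: size -> mappability -> overlap
    kept = _filters.filter_min_size(candidates, config.min_size)
    for c in set(candidates) - set(kept):
        records[c.id].filter_status = FILTER_TOO_SMALL
    if mappability is not None:
        before = kept
        kept = _filters.filter_by_mappability(kept, mappability, config.min_mappability)
        for c in set(before) - set(kept):
            records[c.id].filter_status = FILTER_LOW_MAPPABILITY
    before = kept
    kept = _filters.filter_overlapping(before)
    for c in set(before) - set(kept):
        records[c.id].filter_status = FILTER_OVERLAP

    with pysam.AlignmentFile(bam_path) as bam, pysam.FastaFile(ref_path) as ref:
        missing = [c for c in bam.references if c not in ref.references]
        if missing:
            raise ValueError(
                f"chromosomes present in BAM but absent from reference: {missing}"
            )
        if gc_profile is None:
            gc_profile = build_gc_profile(
                bam,
                ref,
                window=config.gc_window,
                step=config.gc_step,
                loess_span=config.loess_span,
                mapq_min=config.mapq_min,
            )
        split_params = SplitReadParams(mapq_min=config.mapq_min)
        claimed: Set[str] = set()
        n_called = 0
        for cand in kept:
            rec = records[cand.id]
            observed = interval_read_count(bam, cand, config.mapq_min)
            if observed is None:
                rec.filter_status = FILTER_NO_DATA
                continue
            e0 = expected_diploid_depth(cand, gc_profile, ref, config.epsilon_floor)
            depths = expected_depths_for(cand.cnv_type, e0, config.epsilon_floor)
            lik = compute_likelihoods(observed, depths)
            rp = 0
            if config.splitread and cand.cnv_type is CNVType.DUP:
                rp = duplication_read_pair_support(
                    bam,
                    cand,
                    ref,
                    split_params,
                    satellite_mask=satellite_mask,
                    median_read_length=gc_profile.mean_read_length,
                    claimed_reads=claimed,
                )
            gt = call_genotype(lik, cand.cnv_type, rp, config.thresholds())
            rec.observed = observed
            rec.e0, rec.e1, rec.e2 = depths.e0, depths.e1, depths.e2
            rec.log_l0, rec.log_l1, rec.log_l2 = lik.log_l0, lik.log_l1, lik.log_l2
            rec.c_score = lik.c_score
            rec.read_pair_support = rp
            rec.call = gt.call
            rec.zygosity_source = gt.zygosity_source
            if rec.is_variant_call:
                n_called += 1
    out = [records[c.id] for c in candidates]
    n_pass = sum(1 for r in out if r.filter_status == FILTER_PASS)
    logger.info(
        "genotyped %d candidates: %d pass filters, %d variant calls",
        len(out), n_pass, n_called,
    )
    if n_pass == 0:
        logger.warning("zero candidates passed filtering; empty call set")
    return out


_TSV_COLUMNS = [
    "chrom", "start", "end", "id", "svtype", "observed_rd", "expected_rd",
    "c_score", "rp_support", "genotype", "filter_status",
]


def _fmt(x: float) -> str:
    return "NA" if math.isnan(x) else f"{x:.6g}"


def write_calls(
    records: Sequence[GenotypeRecord],
    path_tsv: str,
    path_vcf: Optional[str] = None,
    config: Optional[RunConfig] = None,
    reference_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write the per-candidate table as TSV and optionally as VCF 4.2.

    Missing genotypes are encoded "NA" in the TSV and "./." in the VCF.
    The TSV header repeats the run configuration so a run is
    self-describing; no timestamp is written, keeping reruns byte-identical.
    """
    config = config or RunConfig()
    with open(path_tsv, "w") as fh:
        fh.write(config.header_line() + "\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in records:
            c = r.candidate
            fh.write(
                "\t".join(
                    [
                        c.chrom, str(c.b_left), str(c.b_right), c.id, c.cnv_type.value,
                        "NA" if r.observed is None else str(r.observed),
                        _fmt(r.e0), _fmt(r.c_score), str(r.read_pair_support),
                        r.call.value, r.filter_status,
                    ]
                )
                + "\n"
            )
    if path_vcf is not None:
        _write_vcf(records, path_vcf, reference_lengths or {})


def _write_vcf(
    records: Sequence[GenotypeRecord], path: str, contig_lengths: Dict[str, int]
) -> None:
    chroms = []
    for r in records:
        if r.candidate.chrom not in chroms:
            chroms.append(r.candidate.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=conga\n")
        for chrom in chroms:
            length = contig_lengths.get(chrom)
            if length:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="CNV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End of the variant">\n')
        fh.write('##FILTER=<ID=LOW_MAPPABILITY,Description="Mean mappability below threshold">\n')
        fh.write('##FILTER=<ID=OVERLAP_REMOVED,Description="Overlapping smaller candidate removed">\n')
        fh.write('##FILTER=<ID=TOO_SMALL,Description="Candidate below minimum size">\n')
        fh.write('##FILTER=<ID=NO_DATA,Description="No alignment data for chromosome">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=CS,Number=1,Type=Float,Description="C-score">\n')
        fh.write('##FORMAT=<ID=RP,Number=1,Type=Integer,Description="Split-read pair support">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for r in records:
            c = r.candidate
            gt = "./." if r.call is Call.MISSING else r.call.value
            cs = "." if math.isnan(r.c_score) else f"{r.c_score:.4f}"
            filt = "PASS" if r.filter_status == FILTER_PASS else r.filter_status
            fh.write(
                f"{c.chrom}\t{c.b_left + 1}\t{c.id}\tN\t<{c.cnv_type.value}>\t.\t{filt}\t"
                f"SVTYPE={c.cnv_type.value};END={c.b_right}\tGT:CS:RP\t"
                f"{gt}:{cs}:{r.read_pair_support}\n"
            )


def read_calls_tsv(path: str) -> List[GenotypeRecord]:
    """Parse a TSV produced by :func:`write_calls` back into records
    (numeric fields at printed precision)."""
    records: List[GenotypeRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("chrom\t"):
                continue
            f = line.rstrip("\n").split("\t")
            cand = CandidateCNV(f[3], f[0], int(f[1]), int(f[2]), CNVType(f[4]))
            rec = GenotypeRecord(
                candidate=cand,
                observed=None if f[5] == "NA" else int(f[5]),
                e0=float("nan") if f[6] == "NA" else float(f[6]),
                c_score=float("nan") if f[7] == "NA" else float(f[7]),
                read_pair_support=int(f[8]),
                call=Call(f[9]),
                filter_status=f[10],
            )
            records.append(rec)
    return records
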