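"""Synthetic ancient-genome fixture generator.

Builds, from a seeded random stream: (1) a synthetic reference with
block-wise GC structure, (2) a diploid donor carrying implanted
non-overlapping deletions and tandem duplications in three size classes
(small 100 bp-1 kb, medium 1-10 kb, large 10-100 kb), (3) single-end
ancient-like reads — fragment lengths 34-139 bp with mean 69 and median 66,
terminal C->T / G->A deamination damage with exponentially decaying
per-position probability, uniform sequencing error — emitted directly as
coordinate-sorted aligned BAM records, and (4) a candidate list mixing the
implanted (true) events with ~10x background (false) events of matched type
and size distribution.

Reads are placed by sampling fragments uniformly from the two donor
haplotypes and projecting them back to reference coordinates through the
implant coordinate map; a fragment that crosses a novel junction is emitted
with its longest reference-contiguous run aligned and the remainder
soft-clipped, emulating what a short-read mapper produces at CNV
breakpoints.  This bypasses an actual aligner while preserving exactly the
containment read-depth and junction split-read statistics the genotyper
consumes.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_left, insort
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .model import CandidateCNV, CNVType

logger = logging.getLogger(__name__)

FRAG_LO, FRAG_HI = 34, 139
FRAG_MEAN = 69.0
# Discretized lognormal truncated to [FRAG_LO, FRAG_HI], moment-matched to
# mean 69 bp / median 66 bp on the integer grid.
_FRAG_MU = 4.189655
_FRAG_SIGMA = 0.302438

SIZE_CLASSES: Dict[str, Tuple[int, int]] = {
    "small": (100, 1_000),
    "medium": (1_000, 10_000),
    "large": (10_000, 100_000),
}


def size_class(length: int) -> str:
    if length < 1_000:
        return "small"
    if length < 10_000:
        return "medium"
    return "large"


def fragment_length_distribution() -> Tuple[np.ndarray, np.ndarray]:
    """Integer support and pmf of the ancient fragment-length model."""
    xs = np.arange(FRAG_LO, FRAG_HI + 1)
    logpdf = -np.log(xs) - 0.5 * ((np.log(xs) - _FRAG_MU) / _FRAG_SIGMA) ** 2
    p = np.exp(logpdf - logpdf.max())
    return xs, p / p.sum()


@dataclass
class SimSpec:
    """Study conditions for one simulated dataset."""

    ref_length: int = 10_000_000
    chrom: str = "chr1"
    gc_block: int = 5_000          # bp; reference GC varies block-to-block
    n_del_small: int = 0
    n_del_medium: int = 0
    n_del_large: int = 0
    n_dup_small: int = 0
    n_dup_medium: int = 0
    n_dup_large: int = 0
    het_fraction: float = 0.5      # fraction of implanted events heterozygous
    coverage: float = 1.0          # diploid depth of coverage
    damage_rate: float = 0.2       # terminal C->T / G->A probability
    damage_decay: float = 0.3      # per-base exponential decay from read ends
    seq_error: float = 0.001       # uniform per-base sequencing error
    background_ratio: float = 10.0 # false:true candidate ratio
    min_gap: int = 1_000           # bp between implanted events
    seed: int = 0

    def event_plan(self) -> List[Tuple[CNVType, str]]:
        plan: List[Tuple[CNVType, str]] = []
        for cls in ("small", "medium", "large"):
            plan += [(CNVType.DEL, cls)] * getattr(self, f"n_del_{cls}")
            plan += [(CNVType.DUP, cls)] * getattr(self, f"n_dup_{cls}")
        return plan


@dataclass(frozen=True)
class TruthEvent:
    """One implanted CNV in reference coordinates."""

    chrom: str
    b_left: int
    b_right: int
    cnv_type: CNVType
    zygosity: str          # "HET" or "HOM"
    haplotypes: Tuple[bool, bool] = (True, True)

    @property
    def length(self) -> int:
        return self.b_right - self.b_left


def synth_reference(length: int, gc_block: int, rng: np.random.Generator) -> str:
    """Random reference with block-wise GC content ~ N(0.41, 0.08) clipped
    to [0.20, 0.70], emulating isochore-like GC heterogeneity."""
    n_blocks = (length + gc_block - 1) // gc_block
    gc = np.clip(rng.normal(0.41, 0.08, size=n_blocks), 0.20, 0.70)
    out = np.empty(length, dtype=np.uint8)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(n_blocks):
        lo = i * gc_block
        hi = min(lo + gc_block, length)
        g = gc[i]
        probs = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
        out[lo:hi] = rng.choice(bases, size=hi - lo, p=probs)
    return out.tobytes().decode("ascii")


def _sample_size(cls: str, rng: np.random.Generator) -> int:
    lo, hi = SIZE_CLASSES[cls]
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def implant_cnvs(
    ref_length: int, spec: SimSpec, rng: np.random.Generator, max_attempts: int = 100_000
) -> List[TruthEvent]:
    """Place the spec's events non-overlapping with >= min_gap bp between
    any two, sizes log-uniform within each class, by rejection sampling.
    Returns events sorted by position."""
    plan = spec.event_plan()
    placed: List[Tuple[int, int]] = []   # sorted (start, end) incl. gap margin
    events: List[TruthEvent] = []
    attempts = 0
    for cnv_type, cls in plan:
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not place {len(plan)} events in {ref_length} bp "
                    f"after {max_attempts} attempts"
                )
            size = _sample_size(cls, rng)
            if size + 2 * spec.min_gap >= ref_length:
                continue
            start = int(rng.integers(spec.min_gap, ref_length - size - spec.min_gap))
            end = start + size
            i = bisect_left(placed, (start, end))
            ok = True
            if i > 0 and placed[i - 1][1] + spec.min_gap > start:
                ok = False
            if ok and i < len(placed) and end + spec.min_gap > placed[i][0]:
                ok = False
            if not ok:
                continue
            insort(placed, (start, end))
            het = rng.random() < spec.het_fraction
            if het:
                hap = int(rng.integers(0, 2))
                haps = (hap == 0, hap == 1)
            else:
                haps = (True, True)
            events.append(
                TruthEvent(
                    chrom=spec.chrom,
                    b_left=start,
                    b_right=end,
                    cnv_type=cnv_type,
                    zygosity="HET" if het else "HOM",
                    haplotypes=haps,
                )
            )
            break
    return sorted(events, key=lambda e: e.b_left)


@dataclass
class HaplotypeMap:
    """Donor haplotype as reference-coordinate blocks.

    ``ref_starts[i]`` / ``lengths[i]`` describe the i-th reference slice in
    donor order; ``donor_starts`` are their donor-coordinate prefix offsets.
    Deletions omit a slice; tandem duplications repeat one.
    """

    ref_starts: np.ndarray
    lengths: np.ndarray
    donor_starts: np.ndarray
    total_length: int


def build_haplotype_map(
    events: Sequence[TruthEvent], ref_length: int, hap_index: int
) -> HaplotypeMap:
    ref_starts: List[int] = []
    lengths: List[int] = []
    cursor = 0
    for ev in events:
        if not ev.haplotypes[hap_index]:
            continue
        if ev.cnv_type is CNVType.DEL:
            if ev.b_left > cursor:
                ref_starts.append(cursor)
                lengths.append(ev.b_left - cursor)
            cursor = ev.b_right
        else:  # tandem duplication: reference up to b_right, then the copy
            ref_starts.append(cursor)
            lengths.append(ev.b_right - cursor)
            ref_starts.append(ev.b_left)
            lengths.append(ev.b_right - ev.b_left)
            cursor = ev.b_right
    if cursor < ref_length:
        ref_starts.append(cursor)
        lengths.append(ref_length - cursor)
    lengths_arr = np.asarray(lengths, dtype=np.int64)
    donor_starts = np.concatenate(([0], np.cumsum(lengths_arr)))
    return HaplotypeMap(
        ref_starts=np.asarray(ref_starts, dtype=np.int64),
        lengths=lengths_arr,
        donor_starts=donor_starts[:-1],
        total_length=int(donor_starts[-1]),
    )


def _project_fragment(
    hap: HaplotypeMap, donor_start: int, frag_len: int
) -> List[Tuple[int, int]]:
    """Reference-contiguous runs (ref_start, length) covering the fragment,
    in read order, merging adjacent blocks that happen to be collinear."""
    runs: List[Tuple[int, int]] = []
    i = int(np.searchsorted(hap.donor_starts, donor_start, side="right")) - 1
    pos = donor_start
    remaining = frag_len
    while remaining > 0:
        off = pos - hap.donor_starts[i]
        take = int(min(hap.lengths[i] - off, remaining))
        rstart = int(hap.ref_starts[i] + off)
        if runs and runs[-1][0] + runs[-1][1] == rstart:
            runs[-1] = (runs[-1][0], runs[-1][1] + take)
        else:
            runs.append((rstart, take))
        pos += take
        remaining -= take
        i += 1
    return runs


def _apply_damage_and_error(
    seq: bytearray, spec: SimSpec, rng: np.random.Generator
) -> None:
    """Terminal deamination (C->T at the left end, G->A at the right end,
    exponentially decaying inward) plus uniform sequencing error, in place.

    With equal 5' and 3' rates the pattern is strand-symmetric in reference
    orientation, so it is applied identically to both strands.
    """
    n = len(seq)
    if spec.damage_rate > 0:
        p = spec.damage_rate * np.exp(-spec.damage_decay * np.arange(n))
        hit5 = rng.random(n) < p
        hit3 = rng.random(n) < p
        for i in np.flatnonzero(hit5):
            if seq[i] == ord("C"):
                seq[i] = ord("T")
        for j in np.flatnonzero(hit3):
            i = n - 1 - int(j)
            if seq[i] == ord("G"):
                seq[i] = ord("A")
    if spec.seq_error > 0:
        n_err = rng.binomial(n, spec.seq_error)
        if n_err:
            bases = b"ACGT"
            for i in rng.integers(0, n, size=n_err):
                cur = seq[i]
                alt = bases[rng.integers(0, 4)]
                while alt == cur:
                    alt = bases[rng.integers(0, 4)]
                seq[i] = alt


def generate_reads(
    reference_seq: str,
    haplotypes: Sequence[HaplotypeMap],
    spec: SimSpec,
    rng: np.random.Generator,
    bam_path: str,
    fastq_path: Optional[str] = None,
    mapq: int = 37,
) -> int:
    """Emit ``coverage * ref_length / 69`` single-end reads as a sorted,
    indexed BAM (and optional FASTQ).  Returns the number of reads."""
    ref_length = len(reference_seq)
    n_reads = int(round(spec.coverage * ref_length / FRAG_MEAN))
    hap_lens = np.array([h.total_length for h in haplotypes], dtype=float)
    hap_choice = rng.choice(len(haplotypes), size=n_reads, p=hap_lens / hap_lens.sum())
    xs, pmf = fragment_length_distribution()
    frag_lens = rng.choice(xs, size=n_reads, p=pmf)
    starts = rng.random(n_reads)

    records: List[Tuple[int, int, int, int, bytes, int]] = []
    # (pos, left_clip, match_len, right_clip, seq, flag); name index = list order
    for ridx in range(n_reads):
        hap = haplotypes[hap_choice[ridx]]
        flen = int(frag_lens[ridx])
        if hap.total_length <= flen:
            continue
        dstart = int(starts[ridx] * (hap.total_length - flen))
        runs = _project_fragment(hap, dstart, flen)
        seq = bytearray()
        for rstart, rlen in runs:
            seq += reference_seq[rstart : rstart + rlen].encode("ascii")
        _apply_damage_and_error(seq, spec, rng)
        # align the longest reference-contiguous run, soft-clip the rest
        longest = max(range(len(runs)), key=lambda i: runs[i][1])
        left_clip = sum(r[1] for r in runs[:longest])
        right_clip = sum(r[1] for r in runs[longest + 1 :])
        pos = runs[longest][0]
        flag = 16 if rng.random() < 0.5 else 0
        records.append((pos, left_clip, runs[longest][1], right_clip, bytes(seq), flag))

    records.sort(key=lambda r: r[0])
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": spec.chrom, "LN": ref_length}],
    }
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for idx, (pos, lc, mlen, rc, seq, flag) in enumerate(records):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{idx}"
            a.query_sequence = seq.decode("ascii")
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            cigar = []
            if lc:
                cigar.append((4, lc))
            cigar.append((0, mlen))
            if rc:
                cigar.append((4, rc))
            a.cigartuples = cigar
            out.write(a)
    pysam.index(bam_path)
    if fastq_path is not None:
        with open(fastq_path, "w") as fq:
            for idx, (_, _, _, _, seq, _) in enumerate(records):
                s = seq.decode("ascii")
                fq.write(f"@r{idx}\n{s}\n+\n{'I' * len(s)}\n")
    return len(records)


def _overlap_len(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


class _IntervalPool:
    """Sorted interval pool supporting the >50%-of-the-smaller overlap test."""

    def __init__(self) -> None:
        self.items: List[Tuple[int, int]] = []

    def violates(self, start: int, end: int) -> bool:
        size = end - start
        i = bisect_left(self.items, (start - 200_000, 0))
        for s, e in self.items[i:]:
            if s >= end:
                break
            ov = _overlap_len((start, end), (s, e))
            if ov > 0.5 * min(size, e - s):
                return True
        return False

    def add(self, start: int, end: int) -> None:
        insort(self.items, (start, end))


def make_candidate_list(
    truth: Sequence[TruthEvent],
    ref_length: int,
    rng: np.random.Generator,
    ratio: float = 10.0,
    max_attempts_per_event: int = 500,
) -> Tuple[List[CandidateCNV], List[bool]]:
    """Truth events plus ``ratio`` times as many background events of
    matched type and size class, placed uniformly at random such that no
    event overlaps another candidate by more than 50% of the smaller
    event's length.  Returns (shuffled candidates, is_true flags).

    Placement is rejection-sampled; when the genome is too crowded to
    reach the full ratio, the achieved ratio is logged (an error is raised
    only below half the requested count).
    """
    if ratio < 0:
        raise ValueError(f"background ratio must be >= 0, got {ratio}")
    pool = _IntervalPool()
    for ev in truth:
        pool.add(ev.b_left, ev.b_right)
    entries: List[Tuple[CandidateCNV, bool]] = [
        (
            CandidateCNV(
                id="", chrom=ev.chrom, b_left=ev.b_left, b_right=ev.b_right,
                cnv_type=ev.cnv_type,
            ),
            True,
        )
        for ev in truth
    ]
    n_background = int(round(ratio * len(truth)))
    placed = 0
    for _ in range(n_background):
        template = truth[int(rng.integers(0, len(truth)))]
        cls = size_class(template.length)
        for _attempt in range(max_attempts_per_event):
            size = _sample_size(cls, rng)
            if size >= ref_length:
                continue
            start = int(rng.integers(0, ref_length - size))
            if not pool.violates(start, start + size):
                pool.add(start, start + size)
                entries.append(
                    (
                        CandidateCNV(
                            id="", chrom=template.chrom, b_left=start,
                            b_right=start + size, cnv_type=template.cnv_type,
                        ),
                        False,
                    )
                )
                placed += 1
                break
    if n_background and placed < n_background:
        logger.warning(
            "placed %d of %d background candidates (achieved ratio %.1f:1)",
            placed, n_background, placed / max(len(truth), 1),
        )
        if placed < 0.5 * n_background:
            raise RuntimeError(
                f"background placement infeasible: {placed}/{n_background} placed"
            )
    order = rng.permutation(len(entries))
    candidates, flags = [], []
    for rank, i in enumerate(order):
        cand, is_true = entries[int(i)]
        candidates.append(
            CandidateCNV(
                id=f"cand_{rank:05d}", chrom=cand.chrom, b_left=cand.b_left,
                b_right=cand.b_right, cnv_type=cand.cnv_type,
            )
        )
        flags.append(is_true)
    return candidates, flags


@dataclass
class SimOutput:
    """Paths and in-memory objects for one simulated dataset."""

    ref_fasta: str
    bam: str
    truth_bed: str
    candidates_bed: str
    spec_json: str
    truth: List[TruthEvent]
    candidates: List[CandidateCNV]
    is_true: List[bool]
    n_reads: int


def write_fasta(path: str, chrom: str, seq: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")
    pysam.faidx(path)


def write_truth_bed(path: str, truth: Sequence[TruthEvent]) -> None:
    with open(path, "w") as fh:
        for ev in truth:
            fh.write(
                f"{ev.chrom}\t{ev.b_left}\t{ev.b_right}\t{ev.cnv_type.value}\t{ev.zygosity}\n"
            )


def read_truth_bed(path: str) -> List[TruthEvent]:
    truth = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, svtype, zyg = line.rstrip("\n").split("\t")[:5]
            truth.append(
                TruthEvent(chrom, int(start), int(end), CNVType(svtype), zyg)
            )
    return truth


def write_candidates_bed(path: str, candidates: Sequence[CandidateCNV]) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.chrom}\t{c.b_left}\t{c.b_right}\t{c.cnv_type.value}\t{c.id}\n")


def simulate_dataset(spec: SimSpec, out_dir: str) -> SimOutput:
    """Run the full generator and write every artifact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ref_seq = synth_reference(spec.ref_length, spec.gc_block, rng)
    truth = implant_cnvs(spec.ref_length, spec, rng)
    haps = [build_haplotype_map(truth, spec.ref_length, h) for h in (0, 1)]

    ref_fasta = str(out / "reference.fa")
    write_fasta(ref_fasta, spec.chrom, ref_seq)
    bam = str(out / "reads.bam")
    n_reads = generate_reads(ref_seq, haps, spec, rng, bam)
    truth_bed = str(out / "truth.bed")
    write_truth_bed(truth_bed, truth)
    candidates, is_true = make_candidate_list(
        truth, spec.ref_length, rng, ratio=spec.background_ratio
    )
    candidates_bed = str(out / "candidates.bed")
    write_candidates_bed(candidates_bed, candidates)
    spec_json = str(out / "simspec.json")
    with open(spec_json, "w") as fh:
        json.dump(asdict(spec), fh, indent=1, default=str)
    logger.info(
        "simulated %d reads, %d truth events, %d candidates",
        n_reads, len(truth), len(candidates),
    )
    return SimOutput(
        ref_fasta=ref_fasta, bam=bam, truth_bed=truth_bed,
        candidates_bed=candidates_bed, spec_json=spec_json,
        truth=truth, candidates=candidates, is_true=is_true, n_reads=n_reads,
    )
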