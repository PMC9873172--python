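"""Emulated paired-end evidence for tandem duplications from single-end reads.

Ancient-DNA libraries are effectively single-end (short fragments, merged
pairs), so no insert-size signal exists.  A read that crosses the novel
junction of a tandem duplication of ``[b_left, b_right)`` carries the
signature anyway: its 5' part matches the sequence just left of ``b_right``
and its 3' part matches the sequence starting at ``b_left`` — an everted
placement spanning the event "backwards".  To recover this from single-end
alignments, each qualifying read near a candidate breakpoint is split at
its midpoint; the half covered by the existing alignment keeps its mapping
(the *anchor*) and the other half (the *segment*) is remapped locally with
an exact k-mer seed and ungapped extension.  Anchor and segment are then
treated as a read pair and counted as support when their placements form
the everted tandem-duplication configuration.

Deletion genotyping ignores this channel entirely: at these fragment sizes
split-read evidence adds nothing for deletions, and read depth alone is the
deletion signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pysam

from .depth import read_qualifies
from .model import CandidateCNV, CNVType

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SplitReadParams:
    """Tuning constants for harvesting, remapping and pairing."""

    mapq_min: int = 30
    flank: int = 100                 # bp around each breakpoint to harvest from
    min_half_length: int = 17        # bp; reads < 2x this are skipped
    seed_k: int = 13                 # exact-match seed length
    min_score_frac: float = 0.9      # full-segment placements need >= frac * length
    min_local_score: int = 17        # chimeric segments: accept a matched run scoring this
    search_radius_reads: int = 10    # remap window = this x median read length
    breakpoint_tolerance: int = 1000 # bp slack when matching placements to breakpoints


DEFAULT_SPLIT_PARAMS = SplitReadParams()


@dataclass(frozen=True)
class SplitHalf:
    """Anchor placement plus the unmapped half awaiting remapping."""

    read_id: str
    chrom: str
    anchor_start: int
    anchor_end: int
    anchor_is_prefix: bool   # True when the anchor is the 5' half of SEQ
    segment_seq: str


def _overlaps_mask(
    mask: Optional[Dict[str, Sequence[Tuple[int, int]]]],
    chrom: str,
    start: int,
    end: int,
) -> bool:
    if not mask:
        return False
    for s, e in mask.get(chrom, ()):
        if s < end and start < e:
            return True
    return False


def harvest_split_reads(
    bam: pysam.AlignmentFile,
    candidate: CandidateCNV,
    params: SplitReadParams = DEFAULT_SPLIT_PARAMS,
    satellite_mask: Optional[Dict[str, Sequence[Tuple[int, int]]]] = None,
) -> List[SplitHalf]:
    """Collect breakpoint-local reads and split each at its midpoint.

    A read qualifies when it passes the depth-model quality gate, does not
    overlap the optional satellite mask, overlaps either breakpoint's
    ±flank window and is at least ``2 * min_half_length`` long.  The half
    covered by the alignment becomes the anchor; the other half's sequence
    is returned for remapping.  Reads whose alignment covers neither half
    cleanly (clipped on both sides past the midpoint) are skipped.
    """
    if candidate.chrom not in bam.references:
        return []
    chrom_len = bam.get_reference_length(candidate.chrom)
    halves: List[SplitHalf] = []
    seen: Set[str] = set()
    for bp in (candidate.b_left, candidate.b_right):
        lo = max(0, bp - params.flank)
        hi = min(chrom_len, bp + params.flank)
        if lo >= hi:
            continue
        for read in bam.fetch(candidate.chrom, lo, hi):
            if not read_qualifies(read, params.mapq_min):
                continue
            if read.query_name in seen:
                continue
            seq = read.query_sequence
            if seq is None or len(seq) < 2 * params.min_half_length:
                continue
            if _overlaps_mask(
                satellite_mask, candidate.chrom, read.reference_start, read.reference_end
            ):
                continue
            mid = len(seq) // 2
            qs = read.query_alignment_start
            qe = read.query_alignment_end
            rs = read.reference_start
            re_ = read.reference_end
            if qs == 0 and qe >= mid:
                # alignment covers the 5' half: prefix is the anchor
                half = SplitHalf(
                    read_id=read.query_name,
                    chrom=candidate.chrom,
                    anchor_start=rs,
                    anchor_end=rs + mid,
                    anchor_is_prefix=True,
                    segment_seq=seq[mid:],
                )
            elif qe == len(seq) and qs <= mid:
                # alignment covers the 3' half: suffix is the anchor
                half = SplitHalf(
                    read_id=read.query_name,
                    chrom=candidate.chrom,
                    anchor_start=re_ - (len(seq) - mid),
                    anchor_end=re_,
                    anchor_is_prefix=False,
                    segment_seq=seq[:mid],
                )
            else:
                continue
            seen.add(read.query_name)
            halves.append(half)
    return halves


class RegionIndex:
    """Exact k-mer index over one or more reference windows, reusable
    across many remap calls for the same candidate."""

    def __init__(
        self,
        reference: pysam.FastaFile,
        regions: Sequence[Tuple[str, int, int]],
        k: int,
    ) -> None:
        self.k = k
        self.windows: List[Tuple[str, int, np.ndarray]] = []
        self.index: Dict[str, List[Tuple[int, int]]] = {}  # kmer -> (window, pos)
        for chrom, lo, hi in regions:
            lo = max(0, lo)
            hi = min(reference.get_reference_length(chrom), hi)
            if hi - lo < k:
                continue
            region = reference.fetch(chrom, lo, hi).upper()
            widx = len(self.windows)
            self.windows.append(
                (chrom, lo, np.frombuffer(region.encode("ascii"), dtype=np.uint8))
            )
            for p in range(len(region) - k + 1):
                self.index.setdefault(region[p : p + k], []).append((widx, p))


def _extend_seed(
    q: np.ndarray, reg: np.ndarray, off: int, p: int, k: int
) -> Tuple[int, int, int]:
    """Ungapped +1/-2 extension of an exact seed in both directions.

    Returns (score, query_run_start, query_run_end) of the best-scoring
    matched run containing the seed.
    """
    best_left, left_len = 0, 0
    run = 0
    i, j = off - 1, p - 1
    while i >= 0 and j >= 0:
        run += 1 if q[i] == reg[j] else -2
        if run > best_left:
            best_left, left_len = run, off - i
        if run < best_left - 6:  # X-drop
            break
        i -= 1
        j -= 1
    best_right, right_len = 0, 0
    run = 0
    i, j = off + k, p + k
    while i < len(q) and j < len(reg):
        run += 1 if q[i] == reg[j] else -2
        if run > best_right:
            best_right, right_len = run, i - (off + k) + 1
        if run < best_right - 6:
            break
        i += 1
        j += 1
    return k + best_left + best_right, off - left_len, off + k + right_len


def remap_segment(
    segment: str,
    reference: pysam.FastaFile,
    search_regions: Sequence[Tuple[str, int, int]],
    params: SplitReadParams = DEFAULT_SPLIT_PARAMS,
    region_index: Optional[RegionIndex] = None,
) -> Optional[Tuple[str, int, int, str]]:
    """Best local ungapped placement of ``segment`` within the search
    regions, or ``None``.

    Exact k-mer seeds (every query offset) are extended ungapped in both
    directions with +1 match / -2 mismatch scoring; the reported placement
    is the span of the best matched run.  Because a midpoint-split half of
    a junction-spanning read is typically a chimera of the two breakpoint
    sides, a placement is accepted either when its score reaches
    ``min_score_frac`` of the full segment length (a clean full-length hit)
    or when the matched run alone scores at least ``min_local_score`` (one
    side of a chimeric half).  Both strands are tried; ties break to the
    leftmost placement, forward strand first.
    """
    k = params.seed_k
    if len(segment) < k:
        return None
    idx = region_index or RegionIndex(reference, search_regions, k)
    best: Optional[Tuple[str, int, int, str]] = None
    best_key: Optional[Tuple[float, int, int]] = None
    for strand_rank, (strand, query) in enumerate(
        (("+", segment.upper()), ("-", revcomp(segment).upper()))
    ):
        q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        seen: set = set()
        for off in range(0, len(query) - k + 1):
            for widx, p in idx.index.get(query[off : off + k], ()):
                key = (widx, p - off)
                if key in seen:
                    continue
                seen.add(key)
                chrom, lo, reg = idx.windows[widx]
                score, q_run_start, q_run_end = _extend_seed(q, reg, off, p, k)
                run_ref_start = lo + p - (off - q_run_start)
                run_ref_end = run_ref_start + (q_run_end - q_run_start)
                cand_key = (-score, strand_rank, run_ref_start)
                if best_key is None or cand_key < best_key:
                    best_key = cand_key
                    best = (chrom, run_ref_start, run_ref_end, strand)
    if best is None or best_key is None:
        return None
    score = -best_key[0]
    if score >= params.min_score_frac * len(segment) or score >= params.min_local_score:
        return best
    return None


def duplication_read_pair_support(
    bam: pysam.AlignmentFile,
    candidate: CandidateCNV,
    reference: pysam.FastaFile,
    params: SplitReadParams = DEFAULT_SPLIT_PARAMS,
    satellite_mask: Optional[Dict[str, Sequence[Tuple[int, int]]]] = None,
    median_read_length: float = 66.0,
    claimed_reads: Optional[Set[str]] = None,
) -> int:
    """Number of split pairs consistent with a tandem duplication of
    ``[b_left, b_right)``.

    A pair supports the event when anchor and segment lie on the same
    chromosome and, taken in read (5'->3') order, the first element ends
    within ``breakpoint_tolerance`` of ``b_right``, the second starts
    within tolerance of ``b_left``, and the everted span between them
    covers at least half the event (which excludes collinear placements of
    ordinary fully-mapped reads).  Each source read counts once; reads in
    ``claimed_reads`` (already attributed to another candidate) are
    skipped and newly counted reads are added to it.  Deletion candidates
    always return 0.
    """
    if candidate.cnv_type is not CNVType.DUP:
        return 0
    radius = int(params.search_radius_reads * median_read_length)
    regions = [
        (candidate.chrom, candidate.b_left - radius, candidate.b_left + radius),
        (candidate.chrom, candidate.b_right - radius, candidate.b_right + radius),
    ]
    tol = params.breakpoint_tolerance
    bl, br = candidate.b_left, candidate.b_right
    support = 0
    halves = harvest_split_reads(bam, candidate, params, satellite_mask)
    if not halves:
        return 0
    region_index = RegionIndex(reference, regions, params.seed_k)
    for half in halves:
        if claimed_reads is not None and half.read_id in claimed_reads:
            continue
        placement = remap_segment(
            half.segment_seq, reference, regions, params, region_index=region_index
        )
        if placement is None:
            continue
        seg_chrom, seg_start, seg_end, _strand = placement
        if seg_chrom != half.chrom:
            continue
        if half.anchor_is_prefix:
            first_end, second_start = half.anchor_end, seg_start
        else:
            first_end, second_start = seg_end, half.anchor_start
        everted_span = first_end - second_start
        if (
            abs(first_end - br) <= tol
            and abs(second_start - bl) <= tol
            and everted_span >= 0.5 * candidate.length
        ):
            support += 1
            if claimed_reads is not None:
                claimed_reads.add(half.read_id)
    return support
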