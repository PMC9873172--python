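"""Pre-genotyping candidate hygiene.

Three filters run, in this canonical order, before any likelihood is
computed: a minimum event size (events below ~1 kb carry too little depth
signal at low coverage), a minimum mean mappability over the interval
(low-mappability loci mimic deletions in MAPQ-filtered data), and removal
of overlapping same-type candidates (nested or near-duplicate input events
would otherwise be genotyped as multiple calls from one signal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .model import CandidateCNV

logger = logging.getLogger(__name__)


@dataclass
class MappabilityTrack:
    """Per-chromosome sorted, non-overlapping intervals with values in [0,1].

    Stored as parallel arrays (starts, ends, values), 0-based half-open.
    Bases not covered by any interval have mappability 0.
    """

    intervals: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]

    @classmethod
    def from_bed(cls, path: str) -> "MappabilityTrack":
        """Load a 4-column BED (chrom, start, end, value)."""
        raw: Dict[str, List[Tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"{path}:{lineno}: mappability {value} outside [0,1]")
                raw.setdefault(chrom, []).append((start, end, value))
        intervals = {}
        for chrom, rows in raw.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{path}: overlapping mappability intervals on {chrom}")
            intervals[chrom] = (starts, ends, np.array([r[2] for r in rows]))
        return cls(intervals)


def mean_mappability(track: MappabilityTrack, candidate: CandidateCNV) -> float:
    """Length-weighted mean mappability over ``[b_left, b_right)``;
    uncovered bases count as 0."""
    entry = track.intervals.get(candidate.chrom)
    if entry is None:
        logger.warning(
            "chromosome %s absent from mappability track; candidate %s scored 0",
            candidate.chrom,
            candidate.id,
        )
        return 0.0
    starts, ends, values = entry
    lo = np.maximum(starts, candidate.b_left)
    hi = np.minimum(ends, candidate.b_right)
    overlap = np.clip(hi - lo, 0, None)
    return float(np.dot(overlap, values) / candidate.length)


def filter_by_mappability(
    candidates: Sequence[CandidateCNV],
    track: MappabilityTrack,
    min_map: float = 0.9,
) -> List[CandidateCNV]:
    """Keep candidates whose mean mappability is at least ``min_map``."""
    kept = [c for c in candidates if mean_mappability(track, c) >= min_map]
    logger.info("mappability filter: removed %d of %d", len(candidates) - len(kept), len(candidates))
    return kept


def _overlap(a: CandidateCNV, b: CandidateCNV) -> int:
    return max(0, min(a.b_right, b.b_right) - max(a.b_left, b.b_left))


def filter_overlapping(candidates: Sequence[CandidateCNV]) -> List[CandidateCNV]:
    """Remove, from each same-type pair overlapping by more than 50% of the
    smaller event's length, the smaller event (on a length tie, the later in
    (chrom, b_left) sort order).  Re-scanned until stable so the result
    contains no violating pair regardless of removal order."""
    order = sorted(range(len(candidates)), key=lambda i: (candidates[i].chrom, candidates[i].b_left))
    alive = [True] * len(candidates)
    changed = True
    while changed:
        changed = False
        for oi in range(len(order)):
            i = order[oi]
            if not alive[i]:
                continue
            a = candidates[i]
            for oj in range(oi + 1, len(order)):
                j = order[oj]
                if not alive[j]:
                    continue
                b = candidates[j]
                if b.chrom != a.chrom:
                    break
                if b.b_left >= a.b_right:
                    break
                if b.cnv_type != a.cnv_type:
                    continue
                smaller = min(a.length, b.length)
                if _overlap(a, b) > 0.5 * smaller:
                    # drop the smaller; on tie the later in sort order
                    victim = i if a.length < b.length else j
                    alive[victim] = False
                    changed = True
                    if victim == i:
                        break
            else:
                continue
    kept = [c for k, c in zip(alive, candidates) if k]
    logger.info("overlap filter: removed %d of %d", len(candidates) - len(kept), len(candidates))
    return kept


def filter_min_size(
    candidates: Sequence[CandidateCNV], min_size: int = 1000
) -> List[CandidateCNV]:
    """Keep candidates of length at least ``min_size`` bp (default 1 kb)."""
    kept = [c for c in candidates if c.length >= min_size]
    logger.info("size filter: removed %d of %d", len(candidates) - len(kept), len(candidates))
    return kept
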