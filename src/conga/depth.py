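"""Observed read-depth extraction and GC-normalised expected diploid depth.

The observed statistic for a candidate interval is the number of qualifying
reads (mapped, primary, non-duplicate, MAPQ above a cutoff) whose alignment
falls *fully within* the interval.  The expected diploid count is derived
from a per-chromosome GC profile: sliding windows of fixed size are binned
by integer GC percentile, the mean contained-read count per percentile is
converted to a per-base rate, and the rate-vs-percentile curve is smoothed
with LOESS.  An interval's expectation is then

    rate(chrom, GC percentile of interval) * (length - mean_read_length + 1)

i.e. the rate times the number of positions at which a read of average
length can start and still be fully contained.  Window counts are
normalised by the same effective length, which makes the window statistic
and the interval statistic the same estimator and keeps the expectation
unbiased for intervals much longer than a read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

import numpy as np
import pysam
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model import EPSILON_FLOOR, CandidateCNV

logger = logging.getLogger(__name__)

_GC_BASES = frozenset(b"GCgc")


def read_qualifies(read: pysam.AlignedSegment, mapq_min: int) -> bool:
    """Quality gate shared by observed counts and the GC profile."""
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and not read.is_duplicate
        and read.mapping_quality >= mapq_min
    )


def interval_read_count(
    bam: pysam.AlignmentFile, candidate: CandidateCNV, mapq_min: int = 30
) -> Optional[int]:
    """Count qualifying reads fully contained in ``[b_left, b_right)``.

    Returns ``None`` (with a warning) when the chromosome is absent from the
    alignment header; the candidate is reported as missing downstream.
    """
    if candidate.chrom not in bam.references:
        logger.warning(
            "chromosome %s absent from alignment header; candidate %s has no data",
            candidate.chrom,
            candidate.id,
        )
        return None
    n = 0
    for read in bam.fetch(candidate.chrom, candidate.b_left, candidate.b_right):
        if (
            read_qualifies(read, mapq_min)
            and read.reference_start >= candidate.b_left
            and read.reference_end is not None
            and read.reference_end <= candidate.b_right
        ):
            n += 1
    return n


def gc_percentile(seq: str) -> Optional[int]:
    """Integer GC percentile of a sequence, N bases excluded from both
    numerator and denominator.  ``None`` when the sequence is entirely N."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    valid = gc + s.count("A") + s.count("T")
    if valid == 0:
        return None
    return int(np.floor(100.0 * gc / valid + 0.5))


@dataclass
class GCProfile:
    """Per-chromosome GC-percentile -> per-base contained-read rate.

    ``rates[chrom]`` is a length-101 array with unpopulated percentiles
    filled from the nearest populated bin; chromosomes without qualifying
    reads fall back to ``genome_rate`` everywhere.
    """

    rates: Dict[str, np.ndarray]
    genome_rate: float
    mean_read_length: float
    window: int
    step: int

    def rate_for(self, chrom: str, percentile: Optional[int]) -> float:
        if percentile is None:
            return self.genome_rate
        arr = self.rates.get(chrom)
        if arr is None:
            return self.genome_rate
        return float(arr[int(np.clip(percentile, 0, 100))])

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                "# GC profile: per-chromosome per-bp contained-read rate by GC percentile\n"
                f"# genome_rate={self.genome_rate!r} mean_read_length={self.mean_read_length!r} "
                f"window={self.window} step={self.step}\n"
                "chrom\tgc_percentile\trate\n"
            )
            for chrom in sorted(self.rates):
                for pct, rate in enumerate(self.rates[chrom]):
                    fh.write(f"{chrom}\t{pct}\t{float(rate)!r}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "GCProfile":
        rates: Dict[str, np.ndarray] = {}
        genome_rate = mean_rl = window = step = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "genome_rate=" in line:
                        parts = dict(
                            tok.split("=", 1) for tok in line[1:].split() if "=" in tok
                        )
                        genome_rate = float(parts["genome_rate"])
                        mean_rl = float(parts["mean_read_length"])
                        window = int(parts["window"])
                        step = int(parts["step"])
                    continue
                if line.startswith("chrom\t"):
                    continue
                chrom, pct, rate = line.rstrip("\n").split("\t")
                rates.setdefault(chrom, np.zeros(101))[int(pct)] = float(rate)
        if genome_rate is None:
            raise ValueError(f"{path}: missing GC-profile header line")
        return cls(rates, genome_rate, mean_rl, window, step)


def _fill_nearest(values: np.ndarray, populated: np.ndarray) -> np.ndarray:
    """Fill unpopulated percentile bins from the nearest populated bin."""
    out = np.empty(101)
    idx = np.flatnonzero(populated)
    for p in range(101):
        nearest = idx[np.argmin(np.abs(idx - p))]
        out[p] = values[nearest]
    return out


def build_gc_profile(
    bam: pysam.AlignmentFile,
    reference: pysam.FastaFile,
    window: int = 1000,
    step: int = 1000,
    loess_span: float = 0.3,
    mapq_min: int = 30,
    max_length_sample: int = 100_000,
) -> GCProfile:
    """Scan every chromosome shared by BAM and reference and build the
    smoothed GC-percentile rate profile.

    Per window the statistic is the number of qualifying reads fully
    contained in the window, normalised by the window's effective length
    ``window - mean_read_length + 1``.  A read with span ``[s, e)`` is
    contained in window start ``w`` iff ``e - window <= w <= s``, so each
    read contributes to a contiguous run of window indices, accumulated with
    a difference array (exact for any step size).
    """
    if window < 100:
        raise ValueError(f"window must be >= 100 bp, got {window}")
    shared = [c for c in bam.references if c in reference.references]
    if not shared:
        raise ValueError("BAM and reference share no chromosome names")

    lengths: list[int] = []
    per_chrom_reads: Dict[str, tuple[np.ndarray, np.ndarray]] = {}
    total_reads = 0
    for chrom in shared:
        starts, ends = [], []
        for read in bam.fetch(chrom):
            if read_qualifies(read, mapq_min):
                starts.append(read.reference_start)
                ends.append(read.reference_end)
                if len(lengths) < max_length_sample:
                    lengths.append(read.query_length or (read.reference_end - read.reference_start))
        per_chrom_reads[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
        total_reads += len(starts)
    if total_reads == 0:
        raise ValueError("no qualifying reads genome-wide; cannot build GC profile")
    mean_rl = float(np.mean(lengths))

    genome_eff_len = sum(
        max(reference.get_reference_length(c) - mean_rl + 1, 1.0) for c in shared
    )
    genome_rate = total_reads / genome_eff_len
    eff_window = max(window - mean_rl + 1, 1.0)

    rates: Dict[str, np.ndarray] = {}
    for chrom in shared:
        chrom_len = reference.get_reference_length(chrom)
        if chrom_len < window:
            continue
        starts, ends = per_chrom_reads[chrom]
        if starts.size == 0:
            logger.warning("no qualifying reads on %s; using genome rate", chrom)
            rates[chrom] = np.full(101, genome_rate)
            continue
        n_windows = (chrom_len - window) // step + 1
        win_starts = np.arange(n_windows, dtype=np.int64) * step

        # contained-read count per window via difference array
        lo = np.ceil((ends - window) / step).astype(np.int64)
        hi = starts // step
        np.clip(lo, 0, None, out=lo)
        np.clip(hi, None, n_windows - 1, out=hi)
        valid = lo <= hi
        diff = np.zeros(n_windows + 1, dtype=np.int64)
        np.add.at(diff, lo[valid], 1)
        np.add.at(diff, hi[valid] + 1, -1)
        counts = np.cumsum(diff[:-1])

        # GC percentile per window via cumulative base counts
        seq = np.frombuffer(reference.fetch(chrom).upper().encode("ascii"), dtype=np.uint8)
        is_gc = ((seq == ord("G")) | (seq == ord("C"))).astype(np.int64)
        is_acgt = (is_gc | (seq == ord("A")) | (seq == ord("T"))).astype(np.int64)
        cgc = np.concatenate(([0], np.cumsum(is_gc)))
        cvalid = np.concatenate(([0], np.cumsum(is_acgt)))
        gc_counts = cgc[win_starts + window] - cgc[win_starts]
        valid_counts = cvalid[win_starts + window] - cvalid[win_starts]
        ok = valid_counts > 0
        pct = np.zeros(n_windows, dtype=np.int64)
        pct[ok] = np.floor(100.0 * gc_counts[ok] / valid_counts[ok] + 0.5).astype(np.int64)

        sums = np.bincount(pct[ok], weights=counts[ok], minlength=101)
        nwin = np.bincount(pct[ok], minlength=101)
        populated = nwin > 0
        raw = np.zeros(101)
        raw[populated] = sums[populated] / nwin[populated] / eff_window

        pops = np.flatnonzero(populated)
        if pops.size >= 3:
            smoothed = lowess(
                raw[pops], pops.astype(float), frac=loess_span, return_sorted=False
            )
            raw[pops] = np.clip(smoothed, 0.0, None)
        rates[chrom] = _fill_nearest(raw, populated)

    return GCProfile(
        rates=rates,
        genome_rate=genome_rate,
        mean_read_length=mean_rl,
        window=window,
        step=step,
    )


def expected_diploid_depth(
    candidate: CandidateCNV,
    profile: GCProfile,
    reference: pysam.FastaFile,
    epsilon_floor: float = EPSILON_FLOOR,
) -> float:
    """Expected count of fully contained reads under the diploid state.

    Uses the interval's GC percentile to look up the chromosome's smoothed
    rate (genome rate when the interval is entirely N), times the effective
    length ``length - mean_read_length + 1``; clamped below at
    ``epsilon_floor``.
    """
    seq = reference.fetch(candidate.chrom, candidate.b_left, candidate.b_right)
    pct = gc_percentile(seq)
    rate = profile.rate_for(candidate.chrom, pct)
    eff_len = candidate.length - profile.mean_read_length + 1
    if eff_len <= 0:
        logger.warning(
            "candidate %s shorter than the mean read; expectation floored", candidate.id
        )
        return epsilon_floor
    return max(rate * eff_len, epsilon_floor)
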