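"""Shared simulated fixtures.

Everything is generated at test time from seeded generators; the heavier
datasets are session-scoped so several test modules can share them.
"""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from conga.simulate import SimSpec, simulate_dataset


@pytest.fixture(scope="session")
def null_2mb(tmp_path_factory):
    """CNV-free 2 Mb diploid genome at 1x: the calibration null."""
    spec = SimSpec(ref_length=2_000_000, coverage=1.0, seed=42)
    return simulate_dataset(spec, str(tmp_path_factory.mktemp("null2mb")))


@pytest.fixture(scope="session")
def cnv_small(tmp_path_factory):
    """2 Mb genome with medium/large deletions and duplications at 1x,
    with a 3:1 background candidate mix — the pipeline smoke fixture."""
    spec = SimSpec(
        ref_length=2_000_000,
        coverage=1.0,
        n_del_medium=10,
        n_del_large=5,
        n_dup_medium=4,
        n_dup_large=2,
        background_ratio=3.0,
        seed=7,
    )
    return simulate_dataset(spec, str(tmp_path_factory.mktemp("cnvsmall")))


@pytest.fixture(scope="session")
def dup_hom_5x(tmp_path_factory):
    """1 Mb genome with homozygous tandem duplications at 5x coverage."""
    spec = SimSpec(
        ref_length=1_000_000,
        coverage=5.0,
        n_dup_medium=5,
        n_dup_large=5,
        het_fraction=0.0,
        background_ratio=0.0,
        seed=3,
    )
    return simulate_dataset(spec, str(tmp_path_factory.mktemp("dup5x")))


@pytest.fixture(scope="session")
def dup_hom_005x(tmp_path_factory):
    """Same duplication layout as dup_hom_5x but starved at 0.05x."""
    spec = SimSpec(
        ref_length=1_000_000,
        coverage=0.05,
        n_dup_medium=5,
        n_dup_large=5,
        het_fraction=0.0,
        background_ratio=0.0,
        seed=3,
    )
    return simulate_dataset(spec, str(tmp_path_factory.mktemp("dup005x")))


def make_bam(path: str, chrom: str, chrom_len: int, reads):
    """Write a small coordinate-sorted, indexed BAM.

    ``reads`` is an iterable of dicts with keys: name, start, seq (or
    length), and optional mapq, flag, cigar (defaults to full-length match).
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": chrom_len}]}
    reads = sorted(reads, key=lambda r: r["start"])
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r["name"]
            seq = r.get("seq") or "A" * r["length"]
            a.query_sequence = seq
            a.flag = r.get("flag", 0)
            a.reference_id = 0
            a.reference_start = r["start"]
            a.mapping_quality = r.get("mapq", 60)
            a.cigartuples = r.get("cigar", [(0, len(seq))])
            out.write(a)
    pysam.index(path)
    return path


def make_fasta(path: str, chrom: str, seq: str):
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(path)
    return path


def random_seq(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
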