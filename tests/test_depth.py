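"""Observed-depth extraction, GC profiling and expected-depth calibration."""

import numpy as np
import pysam
import pytest
from scipy import stats

from conga.depth import (
    GCProfile,
    build_gc_profile,
    expected_diploid_depth,
    gc_percentile,
    interval_read_count,
)
from conga.model import CandidateCNV, CNVType

from conftest import make_bam, make_fasta, random_seq


def _cand(chrom, start, end, cnv_type=CNVType.DEL, cid="c1"):
    return CandidateCNV(cid, chrom, start, end, cnv_type)


class TestIntervalReadCount:
    @pytest.fixture()
    def tiny_bam(self, tmp_path):
        reads = [
            {"name": "in1", "start": 1100, "length": 60},
            {"name": "in2", "start": 1500, "length": 60},
            {"name": "in3", "start": 1930, "length": 70},     # ends exactly at 2000
            {"name": "straddle", "start": 1980, "length": 60}, # crosses b_right
            {"name": "lowq", "start": 1200, "length": 60, "mapq": 5},
            {"name": "dup", "start": 1300, "length": 60, "flag": 1024},
            {"name": "secondary", "start": 1400, "length": 60, "flag": 256},
        ]
        return pysam.AlignmentFile(make_bam(str(tmp_path / "t.bam"), "chr1", 10_000, reads))

    def test_containment_rule(self, tiny_bam):
        assert interval_read_count(tiny_bam, _cand("chr1", 1000, 2000)) == 3

    def test_quality_flags_excluded(self, tiny_bam):
        assert interval_read_count(tiny_bam, _cand("chr1", 1000, 2000), mapq_min=0) == 4

    def test_empty_region(self, tiny_bam):
        assert interval_read_count(tiny_bam, _cand("chr1", 5000, 6000)) == 0

    def test_absent_chromosome_returns_none(self, tiny_bam):
        assert interval_read_count(tiny_bam, _cand("chr9", 1000, 2000)) is None

    def test_containment_never_exceeds_overlap(self, tiny_bam):
        contained = interval_read_count(tiny_bam, _cand("chr1", 1000, 2000), mapq_min=0)
        overlap = sum(
            1
            for r in tiny_bam.fetch("chr1", 1000, 2000)
            if not r.is_secondary and not r.is_duplicate
        )
        assert contained <= overlap


class TestGCPercentile:
    def test_counts_gc_excluding_n(self):
        assert gc_percentile("GGCC") == 100
        assert gc_percentile("ATAT") == 0
        assert gc_percentile("GCATNNNN") == 50
        assert gc_percentile("NNNN") is None


@pytest.fixture(scope="module")
def uniform_profile(null_2mb):
    with pysam.AlignmentFile(null_2mb.bam) as bam, pysam.FastaFile(null_2mb.ref_fasta) as ref:
        return build_gc_profile(bam, ref)


class TestBuildGCProfile:
    def test_uniform_reads_give_flat_profile(self, null_2mb, uniform_profile):
        """GC-independent reads must yield near-constant rates across the
        percentile bins the genome actually populates."""
        profile = uniform_profile
        with pysam.FastaFile(null_2mb.ref_fasta) as ref:
            seq = ref.fetch("chr1")
        pcts = [gc_percentile(seq[w : w + 1000]) for w in range(0, len(seq) - 1000, 1000)]
        counts = np.bincount(pcts, minlength=101)
        well_populated = np.flatnonzero(counts >= 30)
        rates = profile.rates["chr1"][well_populated]
        assert np.all(np.abs(rates / profile.genome_rate - 1) < 0.10)

    def test_gc_biased_reads_recover_monotone_profile(self, tmp_path):
        """Reads drawn with start rate proportional to (0.5 + GC) must
        produce a profile increasing in GC percentile."""
        rng = np.random.default_rng(9)
        n_tiles, tile = 1000, 1000
        gc_levels = np.linspace(0.25, 0.65, 9)
        tile_gc = rng.choice(gc_levels, size=n_tiles)
        seq = "".join(random_seq(tile, rng, gc=g) for g in tile_gc)
        fasta = make_fasta(str(tmp_path / "gc.fa"), "chr1", seq)
        weights = np.repeat(0.5 + tile_gc, tile)[: len(seq) - 70]
        weights /= weights.sum()
        starts = rng.choice(len(weights), size=40_000, p=weights)
        reads = [
            {"name": f"r{i}", "start": int(s), "length": 69}
            for i, s in enumerate(starts)
        ]
        bam_path = make_bam(str(tmp_path / "gc.bam"), "chr1", len(seq), reads)
        with pysam.AlignmentFile(bam_path) as bam, pysam.FastaFile(fasta) as ref:
            profile = build_gc_profile(bam, ref)
        pcts = sorted({gc_percentile(seq[w : w + 1000]) for w in range(0, len(seq) - 1000, 1000)})
        rates = [profile.rate_for("chr1", p) for p in pcts]
        rho, _ = stats.spearmanr(pcts, rates)
        assert rho > 0.9

    def test_step_size_robustness(self, tmp_path):
        """Tiling windows vs maximally overlapping windows agree per bin."""
        rng = np.random.default_rng(21)
        seq = "".join(random_seq(1000, rng, gc=g) for g in rng.uniform(0.3, 0.6, 1000))
        fasta = make_fasta(str(tmp_path / "s.fa"), "chr1", seq)
        starts = rng.integers(0, len(seq) - 70, size=15_000)
        reads = [{"name": f"r{i}", "start": int(s), "length": 69} for i, s in enumerate(starts)]
        bam_path = make_bam(str(tmp_path / "s.bam"), "chr1", len(seq), reads)
        with pysam.AlignmentFile(bam_path) as bam, pysam.FastaFile(fasta) as ref:
            tiled = build_gc_profile(bam, ref, step=1000)
            dense = build_gc_profile(bam, ref, step=1)
        pcts = [gc_percentile(seq[w : w + 1000]) for w in range(0, len(seq) - 1000, 1000)]
        counts = np.bincount(pcts, minlength=101)
        for p in np.flatnonzero(counts >= 30):
            a, b = tiled.rate_for("chr1", p), dense.rate_for("chr1", p)
            assert a == pytest.approx(b, rel=0.05)

    def test_deterministic(self, null_2mb, uniform_profile):
        with pysam.AlignmentFile(null_2mb.bam) as bam, pysam.FastaFile(null_2mb.ref_fasta) as ref:
            again = build_gc_profile(bam, ref)
        assert again.genome_rate == uniform_profile.genome_rate
        assert np.array_equal(again.rates["chr1"], uniform_profile.rates["chr1"])

    def test_tsv_round_trip(self, uniform_profile, tmp_path):
        path = str(tmp_path / "profile.tsv")
        uniform_profile.to_tsv(path)
        back = GCProfile.from_tsv(path)
        assert back.genome_rate == uniform_profile.genome_rate
        assert back.mean_read_length == uniform_profile.mean_read_length
        assert np.array_equal(back.rates["chr1"], uniform_profile.rates["chr1"])

    def test_no_reads_is_fatal(self, tmp_path, null_2mb):
        bam_path = make_bam(str(tmp_path / "empty.bam"), "chr1", 2_000_000, [])
        with pysam.AlignmentFile(bam_path) as bam, pysam.FastaFile(null_2mb.ref_fasta) as ref:
            with pytest.raises(ValueError):
                build_gc_profile(bam, ref)


class TestExpectedDiploidDepth:
    def test_rate_times_effective_length(self, tmp_path):
        rng = np.random.default_rng(1)
        seq = random_seq(20_000, rng, gc=0.40)
        fasta = make_fasta(str(tmp_path / "r.fa"), "chr1", seq)
        profile = GCProfile(
            rates={"chr1": np.full(101, 0.01)}, genome_rate=0.01,
            mean_read_length=69.0, window=1000, step=1000,
        )
        with pysam.FastaFile(fasta) as ref:
            e0 = expected_diploid_depth(_cand("chr1", 1000, 6069), profile, ref)
        assert e0 == pytest.approx(0.01 * (5069 - 69 + 1))

    def test_all_n_interval_uses_genome_rate(self, tmp_path):
        rng = np.random.default_rng(2)
        seq = random_seq(5_000, rng) + "N" * 5_000 + random_seq(5_000, rng)
        fasta = make_fasta(str(tmp_path / "n.fa"), "chr1", seq)
        profile = GCProfile(
            rates={"chr1": np.full(101, 0.02)}, genome_rate=0.005,
            mean_read_length=69.0, window=1000, step=1000,
        )
        with pysam.FastaFile(fasta) as ref:
            e0 = expected_diploid_depth(_cand("chr1", 6000, 9000), profile, ref)
        assert e0 == pytest.approx(0.005 * (3000 - 69 + 1))

    def test_short_interval_floored(self, tmp_path):
        rng = np.random.default_rng(3)
        fasta = make_fasta(str(tmp_path / "f.fa"), "chr1", random_seq(1000, rng))
        profile = GCProfile(
            rates={"chr1": np.full(101, 0.01)}, genome_rate=0.01,
            mean_read_length=69.0, window=1000, step=1000,
        )
        with pysam.FastaFile(fasta) as ref:
            assert expected_diploid_depth(_cand("chr1", 100, 150), profile, ref) == 0.01

    def test_calibration_against_simulation(self, null_2mb, uniform_profile):
        """Under the diploid null, observed/expected over >=200 random
        medium intervals must centre on 1 and scatter like Poisson."""
        rng = np.random.default_rng(17)
        with pysam.AlignmentFile(null_2mb.bam) as bam, pysam.FastaFile(null_2mb.ref_fasta) as ref:
            ratios = []
            obs_fixed = []
            exp_fixed = []
            for i in range(500):
                length = int(rng.integers(1000, 10_000)) if i >= 250 else 5000
                start = int(rng.integers(0, 2_000_000 - length))
                cand = _cand("chr1", start, start + length, cid=f"i{i}")
                obs = interval_read_count(bam, cand)
                exp = expected_diploid_depth(cand, uniform_profile, ref)
                ratios.append(obs / exp)
                if i < 250:
                    obs_fixed.append(obs)
                    exp_fixed.append(exp)
            assert 0.9 <= np.mean(ratios) <= 1.1
            # equal-length intervals: index of dispersion consistent with Poisson
            dispersion = np.var(obs_fixed) / np.mean(obs_fixed)
            assert 0.8 <= dispersion <= 1.3
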