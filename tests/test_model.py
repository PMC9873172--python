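"""Likelihood engine: Poisson pmf, expected depths, C-score, calling rules."""

import math
from fractions import Fraction

import numpy as np
import pytest

from conga.model import (
    Call,
    CallThresholds,
    CNVType,
    LikelihoodSet,
    ZygositySource,
    call_genotype,
    compute_likelihoods,
    expected_depths_for,
    poisson_log_pmf,
    EPSILON_FLOOR,
)


def naive_log_pmf(observed: int, expected: float) -> float:
    """Multiplicative Poisson pmf with exact factorial — the independent
    oracle for the log-gamma implementation (valid for small counts)."""
    return math.log(expected**observed * math.exp(-expected) / math.factorial(observed))


class TestPoissonLogPmf:
    @pytest.mark.parametrize(
        "observed,expected,value",
        [
            (0, 4.0, -4.0),
            (2, 4.0, math.log(4.0**2 * math.exp(-4.0) / 2)),
            (20, 20.0, naive_log_pmf(20, 20.0)),
        ],
    )
    def test_reference_values(self, observed, expected, value):
        assert poisson_log_pmf(observed, expected) == pytest.approx(value, rel=1e-12)

    def test_matches_naive_oracle(self):
        for observed in range(31):
            for expected in [0.01, 0.5, 1.0, 3.7, 10.0, 30.0]:
                assert poisson_log_pmf(observed, expected) == pytest.approx(
                    naive_log_pmf(observed, expected), rel=1e-9
                )

    @pytest.mark.parametrize("expected", [0.1, 1.0, 10.0, 50.0])
    def test_normalization(self, expected):
        upper = int(np.ceil(expected + 40 * np.sqrt(expected)))
        total = sum(
            math.exp(poisson_log_pmf(o, expected)) for o in range(upper + 1)
        )
        assert 1 - 1e-8 <= total <= 1 + 1e-12

    def test_large_count_stability(self):
        # mode of Poisson(1e6) has log-pmf ~ -0.5*log(2*pi*1e6)
        val = poisson_log_pmf(10**6, 1e6)
        assert val == pytest.approx(-0.5 * math.log(2 * math.pi * 1e6), rel=1e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            poisson_log_pmf(3, 0.0)
        with pytest.raises(ValueError):
            poisson_log_pmf(3, -1.0)
        with pytest.raises(ValueError):
            poisson_log_pmf(-1, 2.0)
        with pytest.raises(ValueError):
            poisson_log_pmf(2.5, 2.0)


class TestExpectedDepths:
    def test_deletion_halves_and_floors(self):
        d = expected_depths_for(CNVType.DEL, 10.0)
        assert (d.e0, d.e1, d.e2) == (10.0, 5.0, EPSILON_FLOOR)

    def test_duplication_scales(self):
        d = expected_depths_for(CNVType.DUP, 10.0)
        assert (d.e0, d.e1, d.e2) == (10.0, 15.0, 20.0)

    def test_floor_clamps_ordering(self):
        # at e0 = 2*floor the het expectation sits exactly on the floor
        d = expected_depths_for(CNVType.DEL, 2 * EPSILON_FLOOR)
        assert d.e2 == EPSILON_FLOOR == d.e1
        d = expected_depths_for(CNVType.DEL, 3 * EPSILON_FLOOR)
        assert d.e2 == EPSILON_FLOOR < d.e1

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            expected_depths_for("INV", 10.0)
        with pytest.raises(ValueError):
            expected_depths_for(CNVType.DEL, 0.0)


class TestCScore:
    def test_het_deletion_example(self):
        lik = compute_likelihoods(5, expected_depths_for(CNVType.DEL, 10.0))
        assert lik.log_l0 == pytest.approx(naive_log_pmf(5, 10.0), rel=1e-9)
        assert lik.log_l1 == pytest.approx(naive_log_pmf(5, 5.0), rel=1e-9)
        assert lik.c_score == pytest.approx(0.5315, abs=2e-4)

    def test_low_count_deletion_argmax_het(self):
        lik = compute_likelihoods(3, expected_depths_for(CNVType.DEL, 10.0))
        assert lik.c_score == pytest.approx(0.4021, abs=2e-4)
        assert lik.variant_argmax is Call.HET

    def test_high_count_duplication_argmax_hom(self):
        lik = compute_likelihoods(20, expected_depths_for(CNVType.DUP, 10.0))
        assert lik.c_score == pytest.approx(0.3853, abs=2e-4)
        assert lik.variant_argmax is Call.HOM

    def test_cscore_below_one_iff_variant_likelier(self):
        for observed in range(0, 25):
            for e0 in [2.0, 8.0, 15.0]:
                for t in (CNVType.DEL, CNVType.DUP):
                    lik = compute_likelihoods(observed, expected_depths_for(t, e0))
                    assert lik.c_score >= 0
                    assert (lik.c_score < 1) == (
                        max(lik.log_l1, lik.log_l2) > lik.log_l0
                    )

    def test_monotone_evidence_for_deletion(self):
        """Less observed depth strengthens deletion evidence.

        The raw ratio is non-increasing from O=10 down to its minimum at
        O=3; below that the shrinking diploid denominator produces small
        inversions (exhaustively computed: c(3)=0.4020 < c(2)=0.4064 <
        c(1)=0.4405), after which the floored homozygous state drives c(0)
        to near zero.  What calling relies on is asserted exactly:
        monotonicity over 10..3, the global minimum at O=0, and downward
        closure of the called region {O : C < cutoff} at the calling
        cutoffs actually used.
        """
        depths = expected_depths_for(CNVType.DEL, 10.0)
        scores = {o: compute_likelihoods(o, depths).c_score for o in range(11)}
        desc = [scores[o] for o in range(10, 2, -1)]
        assert all(a >= b for a, b in zip(desc, desc[1:]))
        assert scores[3] == pytest.approx(0.4020, abs=2e-4)
        assert scores[2] == pytest.approx(0.4064, abs=2e-4)
        assert scores[1] == pytest.approx(0.4405, abs=2e-4)
        assert scores[0] == min(scores.values())
        for cutoff in (0.3, 0.5, 1.0, 2.0):
            called = [o for o in range(11) if scores[o] < cutoff]
            assert called == list(range(len(called)))  # downward-closed


def _lik(c: float, argmax_het: bool = True) -> LikelihoodSet:
    """LikelihoodSet with a prescribed C-score for decision-table tests."""
    l1, l2 = (-1.0, -2.0) if argmax_het else (-2.0, -1.0)
    return LikelihoodSet(log_l0=-1.0, log_l1=l1, log_l2=l2, c_score=c)


class TestCallGenotype:
    # hand-written truth table over the decision grid
    DEL_TABLE = {
        0.0: Call.HET, 0.49: Call.HET,
        0.5: Call.MISSING, 2.0: Call.MISSING,
        2.01: Call.REF_HOM, 9.99: Call.REF_HOM, 10.0: Call.REF_HOM,
    }

    @pytest.mark.parametrize("c,expected", sorted(DEL_TABLE.items()))
    @pytest.mark.parametrize("rp", [0, 10, 11])
    def test_deletion_table_ignores_read_pairs(self, c, expected, rp):
        got = call_genotype(_lik(c), CNVType.DEL, read_pair_support=rp)
        assert got.call is expected

    @pytest.mark.parametrize("rp", [0, 10, 11])
    @pytest.mark.parametrize("c", [0.0, 0.49, 0.5, 2.0, 2.01, 9.99, 10.0])
    def test_duplication_table(self, c, rp):
        got = call_genotype(_lik(c), CNVType.DUP, read_pair_support=rp)
        rescued = c < 10.0 and rp > 10
        if c < 0.5:
            assert got.call is Call.HET
            assert got.zygosity_source is ZygositySource.READ_DEPTH
        elif rescued:
            assert got.call is Call.HET
            assert got.zygosity_source is ZygositySource.READ_PAIR
        elif c >= 10.0:
            assert got.call is Call.REF_HOM
        else:
            assert got.call is Call.MISSING

    def test_rescued_duplication_uses_argmax(self):
        got = call_genotype(_lik(5.0, argmax_het=False), CNVType.DUP, read_pair_support=12)
        assert got.call is Call.HOM
        assert got.zygosity_source is ZygositySource.READ_PAIR

    def test_unrescued_band_is_missing(self):
        got = call_genotype(_lik(5.0), CNVType.DUP, read_pair_support=3)
        assert got.call is Call.MISSING

    def test_exact_tie_reports_het(self):
        lik = LikelihoodSet(log_l0=-1.0, log_l1=-2.0, log_l2=-2.0, c_score=0.1)
        assert lik.variant_argmax is Call.HET

    def test_thresholds_configurable(self):
        strict = CallThresholds(del_call=0.3)
        got = call_genotype(_lik(0.4), CNVType.DEL, thresholds=strict)
        assert got.call is Call.MISSING

    def test_negative_read_pair_support_rejected(self):
        with pytest.raises(ValueError):
            call_genotype(_lik(0.1), CNVType.DUP, read_pair_support=-1)
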