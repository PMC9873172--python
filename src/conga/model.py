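"""Poisson read-depth likelihood model, C-score statistic and genotype calling.

A candidate CNV locus :math:`S_i` with breakpoints :math:`(B_l, B_r)` is
genotyped by comparing the observed count of reads fully contained in the
interval against the expected counts under three copy-number states
``k = 0`` (no event), ``k = 1`` (heterozygous) and ``k = 2`` (homozygous).
Counts are modelled as Poisson with state-dependent rates derived from the
GC-normalised diploid expectation ``e0``:

* deletions:    ``e1 = e0 / 2``, ``e2 -> 0`` (clamped to a small floor)
* duplications: ``e1 = 1.5 * e0``, ``e2 = 2 * e0``

The decision statistic is the C-score,

.. math:: C(S_i) = \\frac{\\max(\\log L_1, \\log L_2)}{\\log L_0},

which lies in ``[0, inf)``; values below 1 indicate that a variant state
explains the data better than the diploid state, and small values indicate
strong evidence for a real CNV.  Copy numbers above 2 are not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from scipy.special import gammaln

#: Default floor applied to every expected depth so the homozygous-deletion
#: state (expectation zero) keeps a finite log-likelihood.
EPSILON_FLOOR = 0.01

#: Log-likelihoods are clamped below this value before forming the C-score
#: ratio, keeping the denominator away from zero.
LOG_LIKELIHOOD_CEILING = -1e-9


class CNVType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"


class Call(str, Enum):
    """Diploid genotype call for one candidate."""

    REF_HOM = "0/0"
    HET = "0/1"
    HOM = "1/1"
    MISSING = "NA"


class ZygositySource(str, Enum):
    """Which evidence channel triggered a variant call."""

    READ_DEPTH = "read_depth"
    READ_PAIR = "read_pair"


@dataclass(frozen=True)
class CandidateCNV:
    """One input locus: breakpoints ``[b_left, b_right)`` (0-based, half-open)
    plus the event type."""

    id: str
    chrom: str
    b_left: int
    b_right: int
    cnv_type: CNVType

    def __post_init__(self) -> None:
        if self.b_left < 0 or self.b_left >= self.b_right:
            raise ValueError(
                f"invalid breakpoints for {self.id}: "
                f"[{self.b_left}, {self.b_right})"
            )

    @property
    def length(self) -> int:
        return self.b_right - self.b_left


@dataclass(frozen=True)
class ExpectedDepths:
    """Expected fully-contained read counts under the three copy states."""

    e0: float
    e1: float
    e2: float

    def __post_init__(self) -> None:
        if min(self.e0, self.e1, self.e2) <= 0:
            raise ValueError("expected depths must be strictly positive")


@dataclass(frozen=True)
class LikelihoodSet:
    """Clamped natural-log Poisson likelihoods and the derived C-score."""

    log_l0: float
    log_l1: float
    log_l2: float
    c_score: float

    @property
    def variant_argmax(self) -> Call:
        """HET vs HOM by likelihood argmax; exact ties resolve to HET
        (the more conservative copy-number change)."""
        return Call.HET if self.log_l1 >= self.log_l2 else Call.HOM


@dataclass(frozen=True)
class GenotypeCall:
    call: Call
    zygosity_source: Optional[ZygositySource] = None


@dataclass(frozen=True)
class CallThresholds:
    """C-score / read-pair cutoffs.

    Defaults: deletions and duplications are called below a C-score of 0.5;
    C-scores above 2 support the reference-homozygous genotype; duplications
    with weak depth evidence are rescued when the C-score stays below 10 and
    more than 10 split-read pairs support a tandem junction.
    """

    del_call: float = 0.5
    ref_call: float = 2.0
    dup_call: float = 0.5
    dup_rescue_cscore: float = 10.0
    dup_rescue_rp: int = 10


DEFAULT_THRESHOLDS = CallThresholds()


def poisson_log_pmf(observed: int, expected: float) -> float:
    """Natural-log Poisson pmf ``O*ln(E) - E - ln(O!)`` via log-gamma.

    Stable for counts well beyond 10**6.  ``expected`` must be positive and
    ``observed`` a non-negative integer.
    """
    if expected <= 0:
        raise ValueError(f"expected rate must be positive, got {expected}")
    if observed < 0 or int(observed) != observed:
        raise ValueError(f"observed count must be a non-negative integer, got {observed}")
    observed = int(observed)
    return observed * math.log(expected) - expected - float(gammaln(observed + 1))


def expected_depths_for(
    cnv_type: CNVType, e0: float, epsilon_floor: float = EPSILON_FLOOR
) -> ExpectedDepths:
    """Expected counts under k=0,1,2 for a deletion or duplication.

    Every value is clamped below at ``epsilon_floor`` so that the degenerate
    homozygous-deletion expectation (zero reads) stays a valid Poisson rate.
    """
    if e0 <= 0:
        raise ValueError(f"diploid expectation must be positive, got {e0}")
    cnv_type = CNVType(cnv_type)
    if cnv_type is CNVType.DEL:
        e1, e2 = e0 / 2.0, 0.0
    else:
        e1, e2 = 1.5 * e0, 2.0 * e0
    clamp = lambda x: max(x, epsilon_floor)
    return ExpectedDepths(clamp(e0), clamp(e1), clamp(e2))


def compute_likelihoods(observed: int, depths: ExpectedDepths) -> LikelihoodSet:
    """Log-likelihoods of the observed count under the three states and the
    C-score ratio max(log L1, log L2) / log L0.

    All log-likelihoods are clamped to at most ``LOG_LIKELIHOOD_CEILING`` so
    the ratio is always finite and non-negative.
    """
    l0 = min(poisson_log_pmf(observed, depths.e0), LOG_LIKELIHOOD_CEILING)
    l1 = min(poisson_log_pmf(observed, depths.e1), LOG_LIKELIHOOD_CEILING)
    l2 = min(poisson_log_pmf(observed, depths.e2), LOG_LIKELIHOOD_CEILING)
    c_score = max(l1, l2) / l0
    return LikelihoodSet(log_l0=l0, log_l1=l1, log_l2=l2, c_score=c_score)


def call_genotype(
    likelihoods: LikelihoodSet,
    cnv_type: CNVType,
    read_pair_support: int = 0,
    thresholds: CallThresholds = DEFAULT_THRESHOLDS,
) -> GenotypeCall:
    """Threshold-based diploid genotype call for one candidate.

    Deletions: C below ``del_call`` yields a variant call (HET/HOM by
    argmax); C above ``ref_call`` yields 0/0; the band in between is
    indeterminate and coded missing.

    Duplications: a variant call fires either on depth evidence
    (C below ``dup_call``) or on the split-read rescue clause
    (C below ``dup_rescue_cscore`` and read-pair support above
    ``dup_rescue_rp``).  Because the rescue clause keeps the locus in play
    up to C = ``dup_rescue_cscore``, the reference-homozygous call requires
    the C-score to clear that bound as well; otherwise the locus is coded
    missing.
    """
    if read_pair_support < 0:
        raise ValueError(f"read-pair support must be non-negative, got {read_pair_support}")
    cnv_type = CNVType(cnv_type)
    c = likelihoods.c_score
    if cnv_type is CNVType.DEL:
        if c < thresholds.del_call:
            return GenotypeCall(likelihoods.variant_argmax, ZygositySource.READ_DEPTH)
        if c > thresholds.ref_call:
            return GenotypeCall(Call.REF_HOM)
        return GenotypeCall(Call.MISSING)
    # duplications
    if c < thresholds.dup_call:
        return GenotypeCall(likelihoods.variant_argmax, ZygositySource.READ_DEPTH)
    if c < thresholds.dup_rescue_cscore and read_pair_support > thresholds.dup_rescue_rp:
        return GenotypeCall(likelihoods.variant_argmax, ZygositySource.READ_PAIR)
    if c > thresholds.ref_call and c >= thresholds.dup_rescue_cscore:
        return GenotypeCall(Call.REF_HOM)
    return GenotypeCall(Call.MISSING)
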