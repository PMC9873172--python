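"""Benchmarking calls against a simulated truth set.

Two events match when they are the same type, on the same chromosome and
their reciprocal overlap — min(overlap/|A|, overlap/|B|) — reaches the
threshold (default 0.5).  Matching is greedy one-to-one, best overlap
first, so a single call can never be credited against several nested truth
events.  Metrics follow the usual definitions: recall (TPR) = TP / n_truth,
precision = TP / n_called, FDR = 1 - precision and
F = 2 * precision * recall / (precision + recall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .genotype import GenotypeRecord
from .model import Call, CandidateCNV, CNVType
from .simulate import TruthEvent, size_class


def reciprocal_overlap(
    a: Tuple[str, int, int], b: Tuple[str, int, int]
) -> Tuple[Fraction, Fraction]:
    """(overlap/|a|, overlap/|b|) as exact rationals; (0, 0) across
    chromosomes."""
    if a[0] != b[0]:
        return Fraction(0), Fraction(0)
    ov = max(0, min(a[2], b[2]) - max(a[1], b[1]))
    return Fraction(ov, a[2] - a[1]), Fraction(ov, b[2] - b[1])


@dataclass
class Matching:
    """One-to-one truth/call assignment."""

    pairs: List[Tuple[int, int]]            # (truth index, call index)
    truth: Sequence[TruthEvent]
    calls: Sequence[GenotypeRecord]

    @property
    def matched_truth(self) -> set:
        return {t for t, _ in self.pairs}

    @property
    def matched_calls(self) -> set:
        return {c for _, c in self.pairs}


def match_calls(
    truth: Sequence[TruthEvent],
    calls: Sequence[GenotypeRecord],
    threshold: float = 0.5,
) -> Matching:
    """Greedy one-to-one matching of variant calls (HET/HOM only) to truth.

    Same-type pairs whose reciprocal overlap reaches ``threshold`` are
    ranked by decreasing min reciprocal fraction (ties: leftmost truth
    event, then leftmost call) and assigned greedily; each truth event and
    each call matches at most once.
    """
    thr = Fraction(threshold).limit_denominator(10**9)
    scored: List[Tuple[Fraction, int, int, int, int]] = []
    for ti, t in enumerate(truth):
        for ci, rec in enumerate(calls):
            if not rec.is_variant_call:
                continue
            c = rec.candidate
            if c.cnv_type != t.cnv_type:
                continue
            fa, fb = reciprocal_overlap(
                (t.chrom, t.b_left, t.b_right), (c.chrom, c.b_left, c.b_right)
            )
            m = min(fa, fb)
            if m >= thr:
                scored.append((m, t.b_left, c.b_left, ti, ci))
    scored.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_t, used_c = set(), set()
    pairs = []
    for _, _, _, ti, ci in scored:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        pairs.append((ti, ci))
    return Matching(pairs=pairs, truth=truth, calls=calls)


def f_score(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Per-stratum counts and rates plus the zygosity confusion matrix."""

    table: pd.DataFrame                      # one row per (type, size class) + totals
    zygosity_confusion: pd.DataFrame         # truth HET/HOM x called HET/HOM

    def overall(self, cnv_type: Optional[str] = None) -> pd.Series:
        key = cnv_type if cnv_type else "ALL"
        rows = self.table[(self.table["cnv_type"] == key) & (self.table["size_class"] == "all")]
        return rows.iloc[0]

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _metric_row(cnv_type: str, cls: str, n_truth: int, n_called: int, tp: int) -> dict:
    recall = tp / n_truth if n_truth else 0.0
    precision = tp / n_called if n_called else 0.0
    return {
        "cnv_type": cnv_type,
        "size_class": cls,
        "n_truth": n_truth,
        "n_called": n_called,
        "true_positives": tp,
        "false_positives": n_called - tp,
        "missed": n_truth - tp,
        "recall": recall,
        "precision": precision,
        "fdr": 1.0 - precision if n_called else 1.0,
        "f_score": f_score(precision, recall),
    }


def compute_metrics(matching: Matching) -> EvalReport:
    """TPR / FDR / precision / recall / F per CNV type and size class
    (size class taken from the truth event's length), plus a zygosity
    confusion matrix over matched pairs."""
    truth, calls = matching.truth, matching.calls
    tp_truth = matching.matched_truth
    called_idx = [ci for ci, r in enumerate(calls) if r.is_variant_call]

    rows = []
    classes = ["small", "medium", "large"]
    for cnv_type in [CNVType.DEL.value, CNVType.DUP.value, "ALL"]:
        t_sel = [
            ti for ti, t in enumerate(truth)
            if cnv_type == "ALL" or t.cnv_type.value == cnv_type
        ]
        c_sel = [
            ci for ci in called_idx
            if cnv_type == "ALL" or calls[ci].candidate.cnv_type.value == cnv_type
        ]
        tp_pairs = [
            (ti, ci) for ti, ci in matching.pairs
            if cnv_type == "ALL" or truth[ti].cnv_type.value == cnv_type
        ]
        rows.append(_metric_row(cnv_type, "all", len(t_sel), len(c_sel), len(tp_pairs)))
        for cls in classes:
            tc = [ti for ti in t_sel if size_class(truth[ti].length) == cls]
            if not tc:
                continue
            # calls stratified by the matched truth length where matched,
            # by their own length otherwise
            matched_by_call = {ci: ti for ti, ci in matching.pairs}
            cc = []
            for ci in c_sel:
                ti = matched_by_call.get(ci)
                length = truth[ti].length if ti is not None else calls[ci].candidate.length
                if size_class(length) == cls:
                    cc.append(ci)
            tp = sum(1 for ti, ci in tp_pairs if size_class(truth[ti].length) == cls)
            rows.append(_metric_row(cnv_type, cls, len(tc), len(cc), tp))

    zyg = pd.DataFrame(0, index=["HET", "HOM"], columns=["HET", "HOM"])
    for ti, ci in matching.pairs:
        called = calls[ci].call
        if called in (Call.HET, Call.HOM):
            pred = "HET" if called is Call.HET else "HOM"
            zyg.loc[truth[ti].zygosity, pred] += 1
    return EvalReport(table=pd.DataFrame(rows), zygosity_confusion=zyg)


def evaluate_calls(
    truth: Sequence[TruthEvent],
    records: Sequence[GenotypeRecord],
    threshold: float = 0.5,
) -> EvalReport:
    """Convenience wrapper: match then compute metrics."""
    return compute_metrics(match_calls(truth, records, threshold))


def zygosity_f_score(
    truth: Sequence[TruthEvent],
    records: Sequence[GenotypeRecord],
    threshold: float = 0.5,
) -> float:
    """F-score for diploid genotype (HET vs HOM) classification.

    A prediction counts as true only when the call both matches a truth
    event at the reciprocal-overlap threshold and assigns the correct
    zygosity; precision is over all variant calls and recall over all
    truth events.
    """
    matching = match_calls(truth, records, threshold)
    n_called = sum(1 for r in records if r.is_variant_call)
    n_truth = len(truth)
    correct = 0
    for ti, ci in matching.pairs:
        pred = "HET" if records[ci].call is Call.HET else "HOM"
        if pred == truth[ti].zygosity:
            correct += 1
    precision = correct / n_called if n_called else 0.0
    recall = correct / n_truth if n_truth else 0.0
    return f_score(precision, recall)
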