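"""Variant-calling accuracy against a truth set.

Calls are matched to truth by exact normalized allele key (chrom, pos,
ref, alt) — a deterministic, oracle-checkable divergence from
haplotype-aware matchers.  Precision, recall and F-score are reported for
SNVs, indels and combined, and the ensemble-quality threshold is swept
over the distinct observed scores to find the F-optimal operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .model import AlleleKey, PmlseqError, VariantCall

KeyLike = Union[VariantCall, AlleleKey]


def _keys(items: Iterable[KeyLike]) -> set[AlleleKey]:
    return {v.key if isinstance(v, VariantCall) else tuple(v) for v in items}


def match_to_truth(
    calls: Iterable[KeyLike], truth: Iterable[KeyLike]
) -> tuple[set[AlleleKey], set[AlleleKey], set[AlleleKey]]:
    """Partition into (tp, fp, fn) by exact allele-key matching.

    Inputs must be normalized (left-aligned, multiallelic split); then
    tp | fp = calls and tp | fn = truth.
    """
    call_keys, truth_keys = _keys(calls), _keys(truth)
    tp = call_keys & truth_keys
    return tp, call_keys - truth_keys, truth_keys - call_keys


def precision_recall(
    tp: Union[int, set], fp: Union[int, set], fn: Union[int, set]
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(precision, recall, F-score); an undefined denominator yields None."""
    ntp = tp if isinstance(tp, int) else len(tp)
    nfp = fp if isinstance(fp, int) else len(fp)
    nfn = fn if isinstance(fn, int) else len(fn)
    precision = ntp / (ntp + nfp) if (ntp + nfp) > 0 else None
    recall = ntp / (ntp + nfn) if (ntp + nfn) > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f_score = None
    else:
        f_score = 2 * precision * recall / (precision + recall)
    return precision, recall, f_score


@dataclass
class BenchmarkReport:
    tp: set[AlleleKey]
    fp: set[AlleleKey]
    fn: set[AlleleKey]
    precision: Optional[float]
    recall: Optional[float]
    f_score: Optional[float]
    curve: pd.DataFrame = field(default_factory=pd.DataFrame)
    optimal_threshold: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "tp": len(self.tp),
                    "fp": len(self.fp),
                    "fn": len(self.fn),
                    "precision": self.precision,
                    "recall": self.recall,
                    "f_score": self.f_score,
                    "optimal_threshold": self.optimal_threshold,
                }
            ]
        )

    @classmethod
    def from_sets(
        cls, tp: set, fp: set, fn: set, **extra
    ) -> "BenchmarkReport":
        p, r, f = precision_recall(tp, fp, fn)
        return cls(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f_score=f, **extra)


def evaluate(calls: Iterable[KeyLike], truth: Iterable[KeyLike]) -> BenchmarkReport:
    tp, fp, fn = match_to_truth(calls, truth)
    return BenchmarkReport.from_sets(tp, fp, fn)


def _is_snv_key(key: AlleleKey) -> bool:
    return len(key[2]) == 1 == len(key[3])


def evaluate_by_class(
    calls: Iterable[KeyLike], truth: Iterable[KeyLike]
) -> dict[str, BenchmarkReport]:
    """Separate SNV / indel / combined reports."""
    call_keys, truth_keys = _keys(calls), _keys(truth)
    out = {"combined": evaluate(call_keys, truth_keys)}
    for name, pred in (("snv", _is_snv_key), ("indel", lambda k: not _is_snv_key(k))):
        out[name] = evaluate(
            {k for k in call_keys if pred(k)}, {k for k in truth_keys if pred(k)}
        )
    return out


def optimize_threshold(
    calls: Sequence[VariantCall], truth: Iterable[KeyLike]
) -> BenchmarkReport:
    """Sweep the ensemble-quality threshold over the distinct observed
    scores; at each threshold t, calls scoring >= t are retained.

    The optimum is the threshold maximizing F (ties resolved toward the
    lowest threshold, i.e. the most inclusive call set).  The returned
    report carries the confusion sets at the optimum plus the full curve.
    """
    truth_keys = _keys(truth)
    if not truth_keys:
        raise PmlseqError("optimize_threshold: empty truth set")
    scored = [v for v in calls if v.ensemble_quality is not None]
    if len(scored) != len(calls):
        raise PmlseqError("optimize_threshold: every call must carry a score")
    thresholds = sorted({v.ensemble_quality for v in scored})
    if not thresholds:
        thresholds = [0.0]
    rows = []
    best: Optional[tuple[float, float]] = None  # (f, -threshold)
    best_report: Optional[BenchmarkReport] = None
    for t in thresholds:
        retained = {v.key for v in scored if v.ensemble_quality >= t}
        tp, fp, fn = match_to_truth(retained, truth_keys)
        p, r, f = precision_recall(tp, fp, fn)
        rows.append(
            {"threshold": t, "tp": len(tp), "fp": len(fp), "fn": len(fn),
             "precision": p, "recall": r, "f_score": f}
        )
        f_cmp = f if f is not None else -1.0
        if best is None or (f_cmp, -t) > best:
            best = (f_cmp, -t)
            best_report = BenchmarkReport.from_sets(tp, fp, fn, optimal_threshold=t)
    curve = pd.DataFrame(rows)
    best_report.curve = curve
    return best_report
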