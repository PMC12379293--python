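"""Performance evaluation: confusion counts, classification metrics, and
filter-level detection rates.

Classification is scored with accuracy, precision, recall, F1 (harmonic
mean of precision and recall) and false positive rate FP/(TN+FP).  For
the click branch, regular clicks and buzzes are merged into a single
positive "click train" category before counting, since both originate
from the target animal; the vessel branch's positive class is
``vessel``.

The rule-based filter itself is evaluated by event counting: the
detection rate is the fraction of manually confirmed target events
recovered by the filter, and the false-positive proportion is the
fraction of filter detections that match no annotation.  (The FP
proportion -- FP among detections -- is deliberately distinct from the
FPR above.)  Detections and annotations are paired by a greedy,
earliest-first, one-to-one span-overlap match.

Metrics with an undefined denominator surface as the explicit
:data:`UNDEFINED` marker, never as a silent zero: small validation sets
make degenerate denominators a realistic occurrence.  Integer-percent
rendering rounds half up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "UNDEFINED",
    "ConfusionCounts",
    "MetricsReport",
    "FilterEvaluation",
    "confusion_counts",
    "metrics_report",
    "f1_from_pr",
    "match_events",
    "filter_evaluation",
    "percent",
]


class _Undefined:
    """Marker for a metric whose denominator is zero."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False


#: Singleton returned where a metric's denominator is zero.
UNDEFINED = _Undefined()


def percent(value: float, digits: int = 0) -> float:
    """Render a proportion as a percentage, rounding half up.

    ``percent(0.94989)`` is ``95.0``; half-up (not banker's) rounding
    matches how rates are conventionally printed in reports.
    """
    scaled = value * 100.0 * 10**digits
    return math.floor(scaled + 0.5) / 10**digits


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five classification metrics as proportions in [0, 1].

    Fields hold :data:`UNDEFINED` where the denominator is zero.
    """

    accuracy: float | _Undefined
    precision: float | _Undefined
    recall: float | _Undefined
    f1: float | _Undefined
    fpr: float | _Undefined

    def as_percent(self, digits: int = 0) -> dict:
        """Integer-percent rendering (half-up); UNDEFINED stays a string."""
        out = {}
        for name in ("accuracy", "precision", "recall", "f1", "fpr"):
            value = getattr(self, name)
            out[name] = "undefined" if value is UNDEFINED else percent(value, digits)
        return out


def confusion_counts(
    predicted: Sequence[str],
    truth: Sequence[str],
    positive_classes: Sequence[str] | set,
) -> ConfusionCounts:
    """Count TP/TN/FP/FN after collapsing labels onto positive vs not.

    A pair counts TP iff both predicted and true labels are in
    ``positive_classes`` (so a buzz predicted as a regular click is a
    true positive once both are merged into the click-train category),
    TN iff neither is, FP/FN for the two mixed cases.
    """
    if len(predicted) != len(truth):
        raise ValueError(
            f"{len(predicted)} predictions but {len(truth)} truth labels"
        )
    positives = set(positive_classes)
    if not positives:
        raise ValueError("positive_classes must be non-empty")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, truth):
        if p in positives:
            if t in positives:
                tp += 1
            else:
                fp += 1
        elif t in positives:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float | _Undefined:
    return num / den if den else UNDEFINED


def metrics_report(cc: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, F1 and FPR from confusion counts."""
    if cc.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    precision = _ratio(cc.tp, cc.tp + cc.fp)
    recall = _ratio(cc.tp, cc.tp + cc.fn)
    if precision is UNDEFINED or recall is UNDEFINED:
        f1: float | _Undefined = UNDEFINED
    else:
        f1 = f1_from_pr(precision, recall)
    return MetricsReport(
        accuracy=_ratio(cc.tp + cc.tn, cc.total),
        precision=precision,
        recall=recall,
        f1=f1,
        fpr=_ratio(cc.fp, cc.tn + cc.fp),
    )


def f1_from_pr(precision: float, recall: float) -> float | _Undefined:
    """Harmonic mean 2pr/(p+r); UNDEFINED when both inputs are zero."""
    for name, value in (("precision", precision), ("recall", recall)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name}={value} outside [0, 1]")
    if precision + recall == 0.0:
        return UNDEFINED
    return 2.0 * precision * recall / (precision + recall)


def _span(event) -> tuple[float, float]:
    return float(event.t_start_ms), float(event.t_end_ms)


def match_events(
    detections: Sequence,
    annotations: Sequence,
    min_overlap_fraction: float = 0.0,
) -> list[tuple[int, int]]:
    """Greedy one-to-one pairing of detections with annotations.

    Both sequences must be time-sorted and expose ``t_start_ms`` /
    ``t_end_ms``.  Detections are visited in time order; each takes the
    earliest still-unmatched annotation whose span overlaps its own.
    With the default ``min_overlap_fraction=0`` any span intersection
    (down to a single shared 0.5 ms pulse slot) qualifies; a positive
    fraction requires the overlap to cover at least that share of the
    annotation's duration.  Returns ``(detection_idx, annotation_idx)``
    pairs; never more than ``min(len(detections), len(annotations))``.
    """
    matched_annotations: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for di, det in enumerate(detections):
        ds, de = _span(det)
        for ai, ann in enumerate(annotations):
            if ai in matched_annotations:
                continue
            as_, ae = _span(ann)
            if as_ > de:
                break  # annotations are time-sorted; nothing later overlaps
            overlap = min(de, ae) - max(ds, as_)
            if overlap < 0:
                continue
            if min_overlap_fraction > 0.0:
                needed = min_overlap_fraction * (ae - as_)
                if overlap < needed:
                    continue
            matched_annotations.add(ai)
            pairs.append((di, ai))
            break
    return pairs


@dataclass(frozen=True)
class FilterEvaluation:
    """Event-count evaluation of a rule-based filter.

    ``n_manual`` manually annotated target events, ``n_detected``
    filter-emitted passed candidates, ``n_true_detected`` detections
    matched one-to-one to an annotation.
    """

    n_manual: int
    n_detected: int
    n_true_detected: int

    def __post_init__(self) -> None:
        if self.n_true_detected > self.n_detected:
            raise ValueError("n_true_detected cannot exceed n_detected")
        if self.n_true_detected > self.n_manual:
            raise ValueError("n_true_detected cannot exceed n_manual")

    @property
    def detection_rate(self) -> float | _Undefined:
        """Fraction of manually confirmed events the filter recovered."""
        return _ratio(self.n_true_detected, self.n_manual)

    @property
    def fp_proportion(self) -> float | _Undefined:
        """Fraction of filter detections matching no annotation."""
        return _ratio(self.n_detected - self.n_true_detected, self.n_detected)

    def as_percent(self, digits: int = 0) -> dict:
        out = {}
        for name in ("detection_rate", "fp_proportion"):
            value = getattr(self, name)
            out[name] = "undefined" if value is UNDEFINED else percent(value, digits)
        return out

    @classmethod
    def from_counts(
        cls, n_manual: int, n_detected: int, n_true_detected: int
    ) -> "FilterEvaluation":
        return cls(n_manual, n_detected, n_true_detected)


def filter_evaluation(
    detections: Sequence,
    annotations: Sequence,
    min_overlap_fraction: float = 0.0,
) -> FilterEvaluation:
    """Detection rate and FP proportion from matched event lists."""
    pairs = match_events(detections, annotations, min_overlap_fraction)
    return FilterEvaluation(
        n_manual=len(annotations),
        n_detected=len(detections),
        n_true_detected=len(pairs),
    )
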