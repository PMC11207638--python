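"""Event-level scoring of prediction streams (Ward-style categories).

An *event* is a maximal run of same-class frames with a start and stop time.
Each ground-truth event is categorized as Correct (C), Deletion (D),
Fragmented (F), Merged (M), or Fragmented-and-Merged (FM); each predicted
event as Correct (C), Insertion (I'), Fragmenting (F'), Merging (M'), or
Fragmenting-and-Merging (FM').  Overlap means at least one shared frame.

Event-level precision, recall, and F1 follow from the category tallies:

    P = (C + M' + FM' + F') / (C + M' + FM' + F' + I')
    R = (C + F + FM + M) / (C + F + FM + M + D)
    F1 = 2 P R / (P + R)

i.e. only insertions hurt precision and only deletions hurt recall;
fragmenting/merging returns still count as positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .prediction import PredictionStream
from .stream import ACTIVITY_LABELS, NULL


@dataclass(frozen=True)
class EventSegment:
    """Half-open frame-unit segment [start, end) of one class."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event must have end > start")

    def overlaps(self, other: "EventSegment") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class EventCategoryCounts:
    """Category tallies; the Correct count is shared by both sides."""

    C: int = 0
    D: int = 0
    F: int = 0
    M: int = 0
    FM: int = 0
    I_p: int = 0
    F_p: int = 0
    M_p: int = 0
    FM_p: int = 0

    @property
    def n_gt(self) -> int:
        return self.C + self.D + self.F + self.M + self.FM

    @property
    def n_pred(self) -> int:
        return self.C + self.I_p + self.F_p + self.M_p + self.FM_p

    def __add__(self, other: "EventCategoryCounts") -> "EventCategoryCounts":
        return EventCategoryCounts(
            *(getattr(self, f) + getattr(other, f) for f in
              ("C", "D", "F", "M", "FM", "I_p", "F_p", "M_p", "FM_p"))
        )


@dataclass
class EventMetrics:
    precision: float
    recall: float
    f1: float


def frames_to_events(labels, cls: str) -> list[EventSegment]:
    """Maximal runs of ``cls`` in a label stream, as half-open segments."""
    if isinstance(labels, PredictionStream):
        labels = labels.labels
    labels = np.asarray(labels, dtype=object)
    out = []
    start = None
    for i, lab in enumerate(labels):
        if lab == cls and start is None:
            start = i
        elif lab != cls and start is not None:
            out.append(EventSegment(cls, start, i))
            start = None
    if start is not None:
        out.append(EventSegment(cls, start, len(labels)))
    return out


def _check_disjoint_sorted(segs, name: str) -> None:
    for a, b in zip(segs, segs[1:]):
        if b.start < a.end:
            raise ValueError(f"{name} segments overlap or are unsorted")


def categorize_events(gt, pred, min_overlap_frac: float = 0.0) -> EventCategoryCounts:
    """Tally Ward categories for one class's ground-truth and predicted events.

    ``min_overlap_frac`` optionally requires a prediction to cover at least
    that fraction of a ground-truth event (and vice versa) before the pair
    counts as overlapping; by default any shared frame counts.
    """
    gt, pred = list(gt), list(pred)
    _check_disjoint_sorted(gt, "ground-truth")
    _check_disjoint_sorted(pred, "prediction")

    def _hit(a: EventSegment, b: EventSegment) -> bool:
        shared = min(a.end, b.end) - max(a.start, b.start)
        if shared <= 0:
            return False
        if min_overlap_frac > 0:
            need = min_overlap_frac * min(a.end - a.start, b.end - b.start)
            return shared >= need
        return True

    gt_hits = [[j for j, p in enumerate(pred) if _hit(g, p)] for g in gt]
    pred_hits = [[i for i, g in enumerate(gt) if _hit(g, p)] for p in pred]

    counts = EventCategoryCounts()
    for i, hits in enumerate(gt_hits):
        if not hits:
            counts.D += 1
            continue
        fragmented = len(hits) >= 2
        merged = any(len(pred_hits[j]) >= 2 for j in hits)
        if fragmented and merged:
            counts.FM += 1
        elif fragmented:
            counts.F += 1
        elif merged:
            counts.M += 1
        else:
            counts.C += 1
    n_correct_pred = 0
    for j, hits in enumerate(pred_hits):
        if not hits:
            counts.I_p += 1
            continue
        merging = len(hits) >= 2
        fragmenting = any(len(gt_hits[i]) >= 2 for i in hits)
        if merging and fragmenting:
            counts.FM_p += 1
        elif merging:
            counts.M_p += 1
        elif fragmenting:
            counts.F_p += 1
        else:
            n_correct_pred += 1
    assert n_correct_pred == counts.C, "correct tallies must agree by construction"
    return counts


def event_prf(counts: EventCategoryCounts) -> EventMetrics:
    """Event-level precision/recall/F1 from category tallies.

    Zero-denominator convention: a metric is 1 when both streams contain no
    events, and 0 when only the denominator side is empty.
    """
    for f in ("C", "D", "F", "M", "FM", "I_p", "F_p", "M_p", "FM_p"):
        if getattr(counts, f) < 0:
            raise ValueError("negative category count")
    p_num = counts.C + counts.M_p + counts.FM_p + counts.F_p
    p_den = p_num + counts.I_p
    r_num = counts.C + counts.F + counts.FM + counts.M
    r_den = r_num + counts.D

    if p_den == 0:
        precision = 1.0 if r_den == 0 else 0.0
    else:
        precision = p_num / p_den
    if r_den == 0:
        recall = 1.0 if p_den == 0 else 0.0
    else:
        recall = r_num / r_den
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return EventMetrics(precision, recall, f1)


def window_macro_prf(gt_labels, pred_labels) -> dict[str, float]:
    """Macro-averaged window-level precision/recall/F1 over all classes."""
    from sklearn.metrics import precision_recall_fscore_support

    labels = sorted(set(gt_labels) | set(pred_labels))
    p, r, f1, _ = precision_recall_fscore_support(
        gt_labels, pred_labels, labels=labels, average="macro", zero_division=0
    )
    return {"precision": float(p), "recall": float(r), "f1": float(f1)}


def score_streams(
    gt: PredictionStream,
    pred: PredictionStream,
    classes=None,
    min_overlap_frac: float = 0.0,
) -> dict:
    """Full event-level and window-level report for a stream pair.

    Per activity class (NULL is background, not an event class): events,
    categories, and event P/R/F1.  Pooled event metrics come from summing
    category counts across classes.  Window-level macro metrics are computed
    over all classes including NULL.
    """
    if len(gt) != len(pred):
        raise ValueError("ground-truth and prediction streams differ in length")
    if classes is None:
        present = set(gt.labels) | set(pred.labels)
        classes = [c for c in ACTIVITY_LABELS if c in present] or [
            c for c in sorted(present) if c != NULL
        ]
    per_class = {}
    pooled = EventCategoryCounts()
    for cls in classes:
        counts = categorize_events(
            frames_to_events(gt, cls), frames_to_events(pred, cls), min_overlap_frac
        )
        per_class[cls] = {"counts": counts, "metrics": event_prf(counts)}
        pooled = pooled + counts
    return {
        "per_class": per_class,
        "pooled_counts": pooled,
        "pooled": event_prf(pooled),
        "window_macro": window_macro_prf(gt.labels, pred.labels),
    }
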