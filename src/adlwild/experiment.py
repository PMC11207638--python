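"""Experiment orchestration: splits, dataset statistics, and model grids.

The protocol mirrors a user-independent evaluation on contiguous streams:
whole participant-sessions are assigned to train/validation/evaluation
splits (70/20/10 by ADL hours, greedy), window models are trained per
(preprocessing x family) cell, the postprocessing grid is swept on cached
validation predictions, and the selected configurations are scored once on
the held-out evaluation split.

Dataset imbalance is summarized by the average imbalance ratio across the
k activity classes,

    IR_avg = (1/k) * sum_a (n - |C_a|) / |C_a|,

where n counts every instance including NULL.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import imbalance as imb
from . import models as mdl
from .events import score_streams
from .postprocess import WEIGHT_FUNCTIONS, CorrectionConfig, correct_stream
from .prediction import PredictionStream
from .stream import ACTIVITY_LABELS, NULL


# ---------------------------------------------------------------------------
# dataset statistics


@dataclass
class DatasetStats:
    per_class_counts: dict[str, int]
    per_class_ir: dict[str, float]
    ir_avg: float
    per_class_hours: dict[str, float] | None = None


def imbalance_ratio(n_total: int, class_count: int) -> float:
    if class_count <= 0:
        raise ValueError("class count must be positive")
    return (n_total - class_count) / class_count


def mean_imbalance_ratio(per_class_irs) -> float:
    """Average IR across activity classes, given the per-class ratios."""
    irs = list(per_class_irs)
    if not irs:
        raise ValueError("no activity classes")
    return float(np.mean(irs))


def adl_share_percent(adl_hours: float, total_hours: float) -> float:
    """Share of recording time spent on ADLs, in percent."""
    if total_hours <= 0:
        raise ValueError("total hours must be positive")
    return 100.0 * adl_hours / total_hours


def imbalance_stats(labels, sample_rate_hz: float | None = None) -> DatasetStats:
    """Per-class and average imbalance ratios of a label sequence.

    NULL is excluded from the k activity classes but included in n.
    """
    counts = Counter(list(labels))
    n = sum(counts.values())
    activity = [lab for lab in counts if lab != NULL]
    if not activity:
        raise ValueError("no activity class present")
    order = [lab for lab in ACTIVITY_LABELS if lab in counts] + sorted(
        set(activity) - set(ACTIVITY_LABELS)
    )
    per_ir = {lab: imbalance_ratio(n, counts[lab]) for lab in order}
    hours = None
    if sample_rate_hz:
        hours = {lab: c / sample_rate_hz / 3600.0 for lab, c in counts.items()}
    return DatasetStats(
        per_class_counts=dict(counts),
        per_class_ir=per_ir,
        ir_avg=mean_imbalance_ratio(per_ir.values()),
        per_class_hours=hours,
    )


# ---------------------------------------------------------------------------
# participant-stratified split


SPLITS = ("train", "validation", "evaluation")


@dataclass
class SplitAssignment:
    assignment: dict[str, str]                 # session id -> split
    per_split_hours: dict[str, dict[str, float]]
    fractions: tuple

    def sessions(self, split: str) -> list[str]:
        return [s for s, sp in self.assignment.items() if sp == split]


def _session_class_hours(streams) -> dict[str, dict[str, float]]:
    out = {}
    for s in streams:
        c = Counter(s.labels.tolist())
        hours = {lab: n / s.sample_rate_hz / 3600.0 for lab, n in c.items()}
        out[s.participant_id] = hours
    return out


def split_objective(hours_by_session, assignment, fractions) -> float:
    """Summed absolute deviation of per-class ADL hours from the targets."""
    classes = sorted({lab for h in hours_by_session.values() for lab in h})
    totals = {
        lab: sum(h.get(lab, 0.0) for h in hours_by_session.values()) for lab in classes
    }
    obj = 0.0
    for split, frac in zip(SPLITS, fractions):
        for lab in classes:
            got = sum(
                hours_by_session[s].get(lab, 0.0)
                for s, sp in assignment.items()
                if sp == split
            )
            obj += abs(got - frac * totals[lab])
    return obj


def participant_split(
    streams_or_hours,
    fractions: tuple = (0.7, 0.2, 0.1),
    seed: int = 0,
    participant_of: dict[str, str] | None = None,
) -> SplitAssignment:
    """Greedy whole-session assignment to train/validation/evaluation.

    Sessions (contiguous streams) are never divided.  Sessions are visited
    in decreasing order of ADL hours and each is placed in the split that
    minimizes the summed absolute deviation of per-class ADL hours from the
    target fractions.  If ``participant_of`` groups several sessions under
    one participant, those sessions move as a unit (strict user
    independence).
    """
    if isinstance(streams_or_hours, dict):
        hours = {k: dict(v) for k, v in streams_or_hours.items()}
    else:
        hours = _session_class_hours(streams_or_hours)
    if len(hours) < len(SPLITS):
        raise ValueError("need at least as many sessions as splits")

    # group sessions into units (participants) that must stay together
    participant_of = participant_of or {s: s for s in hours}
    units: dict[str, list[str]] = {}
    for sess, part in participant_of.items():
        units.setdefault(part, []).append(sess)
    unit_hours = {
        part: {
            lab: sum(hours[s].get(lab, 0.0) for s in sessions)
            for lab in {lab for s in sessions for lab in hours[s]}
        }
        for part, sessions in units.items()
    }

    def adl_hours(h):
        return sum(v for lab, v in h.items() if lab != NULL)

    rng = np.random.default_rng(seed)
    order = sorted(unit_hours, key=lambda u: (-adl_hours(unit_hours[u]), u))
    # seeded tie-shuffle among equal-ADL units
    groups: dict[float, list[str]] = {}
    for u in order:
        groups.setdefault(round(adl_hours(unit_hours[u]), 9), []).append(u)
    order = []
    for key in sorted(groups, reverse=True):
        g = groups[key]
        rng.shuffle(g)
        order.extend(g)

    classes = sorted({lab for h in hours.values() for lab in h if lab != NULL})
    totals = {lab: sum(h.get(lab, 0.0) for h in hours.values()) for lab in classes}
    # fall back to total hours when the data carry no ADL labels at all
    use_total = all(v == 0 for v in totals.values())
    if use_total:
        classes = [NULL]
        totals = {NULL: sum(h.get(NULL, 0.0) for h in hours.values())}

    assigned = {split: dict.fromkeys(classes, 0.0) for split in SPLITS}
    assignment: dict[str, str] = {}
    for u in order:
        best_split, best_delta = None, None
        for split, frac in zip(SPLITS, fractions):
            delta = 0.0
            for lab in classes:
                cur = assigned[split][lab]
                new = cur + unit_hours[u].get(lab, 0.0)
                target = frac * totals[lab]
                delta += abs(new - target) - abs(cur - target)
            if best_delta is None or delta < best_delta - 1e-12:
                best_split, best_delta = split, delta
        for lab in classes:
            assigned[best_split][lab] += unit_hours[u].get(lab, 0.0)
        for sess in units[u]:
            assignment[sess] = best_split

    # every split must hold at least one session: with few coarse sessions the
    # greedy pass can starve the smallest split, so repair by moving the unit
    # whose relocation costs the least
    unit_split = {u: assignment[units[u][0]] for u in units}
    while set(unit_split.values()) != set(SPLITS) and len(units) >= len(SPLITS):
        empty = next(sp for sp in SPLITS if sp not in set(unit_split.values()))
        donors = [
            u for u in units
            if sum(1 for v in unit_split.values() if v == unit_split[u]) >= 2
        ]
        def cost(u):
            trial = dict(assignment)
            for sess in units[u]:
                trial[sess] = empty
            return split_objective(hours, trial, fractions)
        best_u = min(donors, key=lambda u: (cost(u), u))
        for sess in units[best_u]:
            assignment[sess] = empty
        unit_split[best_u] = empty

    per_split = {
        split: {
            lab: sum(
                hours[s].get(lab, 0.0) for s, sp in assignment.items() if sp == split
            )
            for lab in sorted({lab for h in hours.values() for lab in h})
        }
        for split in SPLITS
    }
    return SplitAssignment(assignment, per_split, tuple(fractions))


# ---------------------------------------------------------------------------
# grid runner


DEFAULT_WS_GRID_S = tuple(range(10, 250, 10))  # 24 sizes


@dataclass
class GridConfig:
    models: tuple = ("naive_bayes", "random_forest", "svm_rbf", "xgboost")
    preprocess: tuple = ("none", "rus", "ros", "csl")
    ws_grid_s: tuple = DEFAULT_WS_GRID_S
    weight_fns: tuple = WEIGHT_FUNCTIONS
    seed: int = 0
    sweep_top: int = 2              # best cells carried into the postprocess sweep
    model_overrides: dict = field(default_factory=dict)


def postprocess_grid(cfg: GridConfig) -> list[CorrectionConfig]:
    return [
        CorrectionConfig(weight_fn=fn, ws_seconds=float(ws))
        for ws, fn in itertools.product(cfg.ws_grid_s, cfg.weight_fns)
    ]


def _metrics_row(report) -> dict:
    return {
        "p_macro": report["window_macro"]["precision"],
        "r_macro": report["window_macro"]["recall"],
        "f1_macro": report["window_macro"]["f1"],
        "p_event": report["pooled"].precision,
        "r_event": report["pooled"].recall,
        "f1_event": report["pooled"].f1,
    }


def _train_cell(train_df, family, method, seed, overrides):
    weights = None
    rows = imb.resample(train_df, method, seed)
    if method == "csl":
        if family == "naive_bayes":
            return None
        weights = imb.balanced_class_weights(imb.class_counts(rows["label"]))
    cfg = mdl.ModelConfig(
        family=family, class_weights=weights, seed=seed, **overrides.get(family, {})
    )
    return mdl.train(rows, cfg)


def run_grid(
    train_df: pd.DataFrame,
    val_df: pd.DataFrame,
    val_gt: PredictionStream,
    cfg: GridConfig,
) -> dict:
    """Train the (preprocess x model) grid and sweep postprocessing on the best cells.

    Validation predictions are cached per cell; the postprocessing sweep is
    prediction-level, so each model trains exactly once.  Selection is by
    pooled event-level F1 (ties toward the smaller context window).
    """
    rows = []
    cache: dict[tuple, PredictionStream] = {}
    for method, family in itertools.product(cfg.preprocess, cfg.models):
        model = _train_cell(train_df, family, method, cfg.seed, cfg.model_overrides)
        if model is None:
            continue
        pred = mdl.predict_stream(model, val_df)
        cache[(method, family)] = pred
        report = score_streams(val_gt, pred)
        rows.append(
            {"trial": method, "model": family, "postprocess": "-", "seed": cfg.seed}
            | _metrics_row(report)
        )
    table = pd.DataFrame(rows)

    best_cells = (
        table.sort_values("f1_event", ascending=False)
        .head(cfg.sweep_top)[["trial", "model"]]
        .itertuples(index=False)
        if len(table)
        else []
    )
    post_rows = []
    for trial, family in best_cells:
        pred = cache[(trial, family)]
        for ccfg in postprocess_grid(cfg):
            corrected = correct_stream(pred, ccfg)
            report = score_streams(val_gt, corrected)
            post_rows.append(
                {
                    "trial": trial,
                    "model": family,
                    "postprocess": f"{ccfg.weight_fn}, {ccfg.ws_seconds:g} s",
                    "weight_fn": ccfg.weight_fn,
                    "ws_seconds": ccfg.ws_seconds,
                    "seed": cfg.seed,
                }
                | _metrics_row(report)
            )
    post_table = pd.DataFrame(post_rows)
    if len(post_table):
        best = post_table.sort_values(
            ["f1_event", "ws_seconds"], ascending=[False, True]
        ).iloc[0]
    else:
        best = None
    return {"cells": table, "postprocess": post_table, "best": best, "cache": cache}


def final_evaluate(
    model: mdl.TrainedModel,
    correction: CorrectionConfig | None,
    eval_df: pd.DataFrame,
    eval_gt: PredictionStream,
) -> dict:
    """Score one selected model on the held-out evaluation split.

    Reports pooled and per-class event metrics with and without
    postprocessing, plus the window-level confusion matrix.  Per-class rows
    cover all seven activity classes even when a class was never detected.
    """
    from sklearn.metrics import confusion_matrix

    pred = mdl.predict_stream(model, eval_df)
    reports = {"raw": score_streams(eval_gt, pred, classes=list(ACTIVITY_LABELS))}
    if correction is not None:
        corrected = correct_stream(pred, correction)
        reports["postprocessed"] = score_streams(
            eval_gt, corrected, classes=list(ACTIVITY_LABELS)
        )
    labels = list(ACTIVITY_LABELS) + [NULL]
    cm = confusion_matrix(eval_gt.labels, pred.labels, labels=labels)
    reports["confusion_matrix"] = pd.DataFrame(cm, index=labels, columns=labels)
    return reports
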