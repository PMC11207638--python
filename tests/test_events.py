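import itertools

import numpy as np
import pytest

import adlwild as a
from adlwild.events import EventCategoryCounts, EventSegment


def brute_categorize(gt_labels, pred_labels, cls):
    """Frame-set based Ward categorization, independent of the interval code."""
    def runs(labels):
        segs, cur = [], []
        for i, lab in enumerate(labels):
            if lab == cls:
                cur.append(i)
            elif cur:
                segs.append(set(cur))
                cur = []
        if cur:
            segs.append(set(cur))
        return segs

    gt, pred = runs(gt_labels), runs(pred_labels)
    counts = dict(C=0, D=0, F=0, M=0, FM=0, I_p=0, F_p=0, M_p=0, FM_p=0)
    for g in gt:
        hits = [p for p in pred if g & p]
        if not hits:
            counts["D"] += 1
            continue
        frag = len(hits) >= 2
        merged = any(sum(1 for g2 in gt if g2 & p) >= 2 for p in hits)
        key = "FM" if frag and merged else "F" if frag else "M" if merged else "C"
        counts[key] += 1
    for p in pred:
        hits = [g for g in gt if g & p]
        if not hits:
            counts["I_p"] += 1
            continue
        merging = len(hits) >= 2
        fragmenting = any(sum(1 for p2 in pred if g & p2) >= 2 for g in hits)
        if merging and fragmenting:
            counts["FM_p"] += 1
        elif merging:
            counts["M_p"] += 1
        elif fragmenting:
            counts["F_p"] += 1
    return counts


def seg(start, end, cls="A"):
    return EventSegment(cls, start, end)


class TestFramesToEvents:
    def test_run_length_reading(self):
        out = a.frames_to_events(np.array([0, 1, 1, 0, 1], dtype=object), 1)
        assert [(s.start, s.end) for s in out] == [(1, 3), (4, 5)]

    def test_all_class_stream_is_one_segment(self):
        out = a.frames_to_events(np.array(["A"] * 7, dtype=object), "A")
        assert [(s.start, s.end) for s in out] == [(0, 7)]

    def test_absent_class_gives_empty(self):
        assert a.frames_to_events(np.array(["B", "B"], dtype=object), "A") == []


class TestCategorizeEvents:
    def test_exact_match_is_correct(self):
        c = a.categorize_events([seg(0, 3)], [seg(0, 3)])
        assert (c.C, c.D, c.F, c.M, c.FM, c.I_p, c.F_p, c.M_p, c.FM_p) == (
            1, 0, 0, 0, 0, 0, 0, 0, 0)

    def test_fragmented_event(self):
        c = a.categorize_events([seg(2, 8)], [seg(3, 5), seg(6, 7)])
        assert (c.F, c.F_p, c.I_p, c.D, c.C) == (1, 2, 0, 0, 0)

    def test_correct_plus_insertion(self):
        c = a.categorize_events([seg(5, 8)], [seg(1, 2), seg(5, 8)])
        assert (c.C, c.I_p, c.D) == (1, 1, 0)

    def test_merged_events(self):
        c = a.categorize_events([seg(0, 2), seg(3, 5)], [seg(0, 5)])
        assert (c.M, c.M_p) == (2, 1)

    def test_overlapping_input_segments_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            a.categorize_events([seg(0, 3), seg(2, 5)], [])

    def test_exhaustive_oracle_equivalence(self):
        """All binary label streams up to length 5 match the frame-set oracle."""
        for n in range(1, 6):
            for gt_bits in itertools.product([a.NULL, "A"], repeat=n):
                gt_ev = a.frames_to_events(np.array(gt_bits, dtype=object), "A")
                for pred_bits in itertools.product([a.NULL, "A"], repeat=n):
                    pred_ev = a.frames_to_events(np.array(pred_bits, dtype=object), "A")
                    got = a.categorize_events(gt_ev, pred_ev)
                    want = brute_categorize(gt_bits, pred_bits, "A")
                    assert {
                        "C": got.C, "D": got.D, "F": got.F, "M": got.M, "FM": got.FM,
                        "I_p": got.I_p, "F_p": got.F_p, "M_p": got.M_p, "FM_p": got.FM_p,
                    } == want, (gt_bits, pred_bits)


class TestEventPRF:
    def test_correct_insertion_deletion_mix(self):
        m = a.event_prf(EventCategoryCounts(C=2, I_p=1, D=1))
        assert (m.precision, m.recall, m.f1) == (
            pytest.approx(2 / 3), pytest.approx(2 / 3), pytest.approx(2 / 3))

    def test_perfect_detection(self):
        m = a.event_prf(EventCategoryCounts(C=3))
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_fragmentation_counts_as_positive(self):
        m = a.event_prf(EventCategoryCounts(F=1, F_p=2))
        assert (m.precision, m.recall) == (1.0, 1.0)

    def test_zero_event_conventions(self):
        both_empty = a.event_prf(EventCategoryCounts())
        assert (both_empty.precision, both_empty.recall, both_empty.f1) == (1.0, 1.0, 1.0)
        only_gt = a.event_prf(EventCategoryCounts(D=2))
        assert (only_gt.precision, only_gt.recall) == (0.0, 0.0)
        only_pred = a.event_prf(EventCategoryCounts(I_p=2))
        assert (only_pred.precision, only_pred.recall) == (0.0, 0.0)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            a.event_prf(EventCategoryCounts(C=-1))

    def test_identities_on_random_streams(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            n = int(rng.integers(1, 60))
            gt = rng.choice(["A", a.NULL], size=n)
            pred = rng.choice(["A", a.NULL], size=n)
            c = a.categorize_events(
                a.frames_to_events(gt.astype(object), "A"),
                a.frames_to_events(pred.astype(object), "A"),
            )
            m = a.event_prf(c)
            if c.n_pred:
                assert m.precision == pytest.approx(1 - c.I_p / c.n_pred)
            if c.n_gt:
                assert m.recall == pytest.approx(1 - c.D / c.n_gt)
            # category conservation identities
            assert c.C + c.D + c.F + c.M + c.FM == c.n_gt
            assert c.C + c.I_p + c.F_p + c.M_p + c.FM_p == c.n_pred

    def test_time_reversal_symmetry(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(2, 50))
            gt = rng.choice(["A", a.NULL], size=n).astype(object)
            pred = rng.choice(["A", a.NULL], size=n).astype(object)
            fwd = a.categorize_events(
                a.frames_to_events(gt, "A"), a.frames_to_events(pred, "A"))
            rev = a.categorize_events(
                a.frames_to_events(gt[::-1], "A"), a.frames_to_events(pred[::-1], "A"))
            assert vars(fwd) == vars(rev)


class TestScoreStreams:
    def _stream(self, labels):
        return a.PredictionStream(np.array(labels, dtype=object))

    def test_perfect_prediction_scores_one(self):
        labels = ["Walking"] * 5 + [a.NULL] * 5 + ["Eating"] * 5
        rep = a.score_streams(self._stream(labels), self._stream(labels))
        assert rep["pooled"].f1 == 1.0
        assert rep["window_macro"]["f1"] == 1.0
        for cls in ("Walking", "Eating"):
            assert rep["per_class"][cls]["metrics"].f1 == 1.0

    def test_all_null_prediction_is_total_deletion(self):
        gt = [a.NULL] * 3 + ["Walking"] * 4 + [a.NULL] * 3 + ["Walking"] * 4
        rep = a.score_streams(self._stream(gt), self._stream([a.NULL] * len(gt)))
        c = rep["per_class"]["Walking"]["counts"]
        assert c.D == 2 and rep["per_class"]["Walking"]["metrics"].recall == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            a.score_streams(self._stream(["A"]), self._stream(["A", "B"]))

    def test_per_class_matches_independent_scorer(self):
        rng = np.random.default_rng(23)
        classes = ["Walking", "Eating", "Drinking"]
        gt = rng.choice(classes + [a.NULL] * 3, size=200).astype(object)
        pred = rng.choice(classes + [a.NULL] * 3, size=200).astype(object)
        rep = a.score_streams(self._stream(gt), self._stream(pred))
        pooled = dict(C=0, D=0, F=0, M=0, FM=0, I_p=0, F_p=0, M_p=0, FM_p=0)
        for cls in classes:
            want = brute_categorize(gt, pred, cls)
            got = vars(rep["per_class"][cls]["counts"])
            assert got == want
            for k in pooled:
                pooled[k] += want[k]
        assert vars(rep["pooled_counts"]) == pooled
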