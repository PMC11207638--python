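import itertools

import numpy as np
import pytest

import adlwild as a
from adlwild import experiment as ex
from adlwild import pipeline as pl

from conftest import make_stream


class TestImbalanceStats:
    def test_binary_example(self):
        labels = [a.NULL] * 100 + ["Walking"] * 10
        stats = ex.imbalance_stats(labels)
        assert stats.per_class_ir["Walking"] == pytest.approx(10.0)
        assert stats.ir_avg == pytest.approx(10.0)

    def test_balanced_binary_gives_unit_ratio(self):
        labels = [a.NULL] * 50 + ["Walking"] * 50
        assert ex.imbalance_stats(labels).ir_avg == pytest.approx(1.0)

    def test_average_matches_direct_summation(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(
            [a.NULL] * 10 + ["Walking", "Eating", "Drinking"], size=5000
        ).tolist()
        stats = ex.imbalance_stats(labels)
        n = len(labels)
        direct = []
        for cls in ("Walking", "Eating", "Drinking"):
            c = labels.count(cls)
            direct.append((n - c) / c)
        assert stats.ir_avg == pytest.approx(sum(direct) / 3)

    def test_no_activity_class_raises(self):
        with pytest.raises(ValueError):
            ex.imbalance_stats([a.NULL] * 5)

    def test_hours_reported_when_rate_given(self):
        stats = ex.imbalance_stats([a.NULL, "Walking"] * 1800, sample_rate_hz=1.0)
        assert stats.per_class_hours["Walking"] == pytest.approx(0.5)


class TestParticipantSplit:
    def _uniform_sessions(self, n=10):
        return {f"s{i}": {"Walking": 1.0, a.NULL: 9.0} for i in range(n)}

    def test_ten_equal_sessions_split_7_2_1(self):
        split = ex.participant_split(self._uniform_sessions(10), (0.7, 0.2, 0.1), seed=0)
        sizes = {sp: len(split.sessions(sp)) for sp in ex.SPLITS}
        assert sizes == {"train": 7, "validation": 2, "evaluation": 1}

    def test_every_session_in_exactly_one_split(self):
        split = ex.participant_split(self._uniform_sessions(8), seed=1)
        assert sorted(split.assignment) == sorted(self._uniform_sessions(8))
        assert set(split.assignment.values()) <= set(ex.SPLITS)

    def test_fewer_sessions_than_splits_raises(self):
        with pytest.raises(ValueError):
            ex.participant_split({"s0": {a.NULL: 1.0}, "s1": {a.NULL: 1.0}})

    def test_participant_grouping_keeps_sessions_together(self):
        hours = self._uniform_sessions(6)
        part_of = {f"s{i}": f"p{i // 2}" for i in range(6)}
        split = ex.participant_split(hours, seed=0, participant_of=part_of)
        for p in set(part_of.values()):
            splits = {split.assignment[s] for s, q in part_of.items() if q == p}
            assert len(splits) == 1

    def test_greedy_matches_exhaustive_optimum_on_toy(self):
        hours = {
            "s0": {"Walking": 3.5},
            "s1": {"Walking": 2.0},
            "s2": {"Walking": 1.5},
            "s3": {"Walking": 1.0},
            "s4": {"Walking": 1.0},
            "s5": {"Walking": 1.0},
        }
        fractions = (0.7, 0.2, 0.1)
        best = min(
            ex.split_objective(
                hours, dict(zip(hours, combo)), fractions
            )
            for combo in itertools.product(ex.SPLITS, repeat=len(hours))
        )
        split = ex.participant_split(hours, fractions, seed=0)
        got = ex.split_objective(hours, split.assignment, fractions)
        assert got == pytest.approx(best, abs=1e-9)

    def test_streams_accepted_directly(self):
        streams = [
            make_stream(participant=f"p{i}", duration_s=120.0, seed=i) for i in range(4)
        ]
        split = ex.participant_split(streams, seed=0)
        assert sorted(split.assignment) == [f"p{i}" for i in range(4)]


class TestGrid:
    def test_default_postprocess_grid_has_120_configs(self):
        cfgs = ex.postprocess_grid(ex.GridConfig())
        assert len(cfgs) == 24 * 5
        assert len({(c.weight_fn, c.ws_seconds) for c in cfgs}) == 120

    @pytest.fixture()
    def tiny_grid(self):
        events = (("Walking", 20.0, 60.0), ("Drinking", 90.0, 120.0),
                  ("BrushingTeeth", 150.0, 175.0))
        tr = make_stream(participant="tr", duration_s=200.0, events=events, seed=0)
        va = make_stream(participant="va", duration_s=200.0, events=events, seed=1)
        tr_df, _ = pl.features_for_stream(tr)
        va_df, va_gt = pl.features_for_stream(va)
        cfg = ex.GridConfig(
            models=("random_forest",),
            preprocess=("none", "ros"),
            ws_grid_s=(5, 10),
            weight_fns=("W1", "W4"),
            seed=0,
            sweep_top=1,
        )
        return ex.run_grid(tr_df, va_df, va_gt, cfg)

    def test_grid_trains_every_cell(self, tiny_grid):
        assert len(tiny_grid["cells"]) == 2
        assert set(tiny_grid["cells"]["trial"]) == {"none", "ros"}

    def test_best_row_is_argmax_of_its_column(self, tiny_grid):
        table = tiny_grid["postprocess"]
        assert len(table) == 4  # 2 ws x 2 fns for the single swept cell
        best = tiny_grid["best"]
        assert best["f1_event"] == table["f1_event"].max()

    def test_naive_bayes_skipped_in_csl_trial(self):
        tr = make_stream(participant="tr", duration_s=100.0,
                         events=(("Walking", 10.0, 40.0),), seed=0)
        va = make_stream(participant="va", duration_s=100.0,
                         events=(("Walking", 10.0, 40.0),), seed=1)
        tr_df, _ = pl.features_for_stream(tr)
        va_df, va_gt = pl.features_for_stream(va)
        cfg = ex.GridConfig(
            models=("naive_bayes",), preprocess=("csl",), ws_grid_s=(5,),
            weight_fns=("W1",), sweep_top=1,
        )
        out = ex.run_grid(tr_df, va_df, va_gt, cfg)
        assert len(out["cells"]) == 0


class TestFinalEvaluate:
    def test_per_class_table_and_confusion_conservation(self):
        tr = make_stream(participant="tr", duration_s=150.0,
                         events=(("Walking", 10.0, 50.0), ("Drinking", 80.0, 110.0)),
                         seed=0)
        ev = make_stream(participant="ev", duration_s=150.0,
                         events=(("Walking", 20.0, 60.0), ("Drinking", 90.0, 120.0)),
                         seed=3)
        tr_df, _ = pl.features_for_stream(tr)
        ev_df, ev_gt = pl.features_for_stream(ev)
        model = pl.train_with_preprocess(tr_df, "random_forest", "none", 0)
        rep = ex.final_evaluate(
            model, a.CorrectionConfig("W4", 10.0), ev_df, ev_gt
        )
        # all seven activity classes listed even when absent
        assert set(rep["raw"]["per_class"]) == set(a.ACTIVITY_LABELS)
        cm = rep["confusion_matrix"]
        from collections import Counter

        gt_counts = Counter(ev_gt.labels.tolist())
        for lab in cm.index:
            assert cm.loc[lab].sum() == gt_counts.get(lab, 0)

    def test_split_disjointness_guards_leakage(self):
        streams = [
            make_stream(participant=f"p{i}", duration_s=100.0, seed=i) for i in range(5)
        ]
        split = ex.participant_split(streams, seed=0)
        ids = [set(split.sessions(sp)) for sp in ex.SPLITS]
        for x, y in itertools.combinations(ids, 2):
            assert not (x & y)


class TestRunExperiment:
    def test_tiny_experiment_produces_results_and_artifacts(self, tmp_path):
        raw = {
            "seed": 0,
            "simulation": {
                "participants": 5,
                "hours_range": [0.25, 0.3],
                "sample_rate_hz": 10.0,
                "distractor_per_hour": 4.0,
                "signatures": [
                    {"label": "Walking", "freq_hz": 2.0, "amp": 2.5,
                     "events_per_hour": 10.0, "duration_median_s": 30.0},
                    {"label": "Drinking", "freq_hz": 1.2, "amp": 1.5,
                     "events_per_hour": 10.0, "duration_median_s": 20.0},
                ],
            },
            "models": ["random_forest"],
            "preprocess": ["none", "ros"],
            "ws_grid_s": [5],
            "weight_fns": ["W1"],
            "sweep_top": 1,
        }
        results = pl.run_experiment(raw, tmp_path)
        assert len(results["validation_cells"]) == 2
        assert "evaluation" in results
        assert (tmp_path / "results.json").exists()
        assert (tmp_path / "validation_cells.csv").exists()
        split = __import__("json").loads((tmp_path / "split.json").read_text())
        assert set(split.values()) == {"train", "validation", "evaluation"}


def test_split_repair_fills_every_split_with_coarse_sessions():
    hours = {f"s{i}": {"Walking": 1.0} for i in range(5)}
    split = ex.participant_split(hours, (0.7, 0.2, 0.1), seed=0)
    for sp in ex.SPLITS:
        assert split.sessions(sp), sp
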