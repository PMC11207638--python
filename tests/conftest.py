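import numpy as np
import pytest

import adlwild as a
from adlwild import pipeline as pl
from adlwild import simulate as sim


def make_stream(
    participant="p0",
    fs=20.0,
    duration_s=60.0,
    events=(("Walking", 10.0, 30.0),),
    noise=0.05,
    seed=0,
):
    """Small hand-built dual-wrist stream with oscillatory labeled events."""
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    labels = np.full(n, a.NULL, dtype=object)
    accel = {h: rng.normal(0, noise, size=(n, 3)) for h in ("left", "right")}
    freqs = {"Walking": 2.0, "Drinking": 1.4, "BrushingTeeth": 4.4}
    for lab, start, end in events:
        sl = slice(int(start * fs), int(end * fs))
        f = freqs.get(lab, 2.5)
        for h in ("left", "right"):
            for j in range(3):
                accel[h][sl, j] += 2.0 * np.sin(2 * np.pi * f * t[sl] + j)
        labels[sl] = lab
    return a.SensorStream(
        participant_id=participant, sample_rate_hz=fs, t=t, accel=accel, labels=labels
    )


@pytest.fixture
def tiny_stream():
    return make_stream()


@pytest.fixture(scope="session")
def demo_experiment():
    """One full reduced-scale experiment, shared across end-to-end tests.

    Generates the demo synthetic cohort (5 participants, ~2 h each, 20 Hz),
    trains baseline and ratio-preserving-oversampled XGBoost on the first
    three participants, and scores raw and context-corrected (W4, 160 s)
    prediction streams on the two held-out participants.
    """
    cfg = sim.SimulationConfig.demo(seed=1)
    streams = sim.generate_dataset(cfg)
    data = pl.prepare_dataset(streams)
    ids = [s.participant_id for s in streams]
    train_df, _ = pl.concat_split(data, ids[:3])
    eval_df, eval_gt = pl.concat_split(data, ids[3:])

    out = {"train_ids": ids[:3], "eval_ids": ids[3:], "eval_gt": eval_gt}
    correction = a.CorrectionConfig(weight_fn="W4", ws_seconds=160.0)
    for method in ("none", "ros"):
        model = pl.train_with_preprocess(train_df, "xgboost", method, seed=1)
        pred = a.predict_stream(model, eval_df)
        corrected = a.correct_stream(pred, correction)
        out[method] = {
            "pred": pred,
            "raw": a.score_streams(eval_gt, pred),
            "post": a.score_streams(eval_gt, corrected),
        }
    return out
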