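"""Synthetic dual-wrist streams with a NULL-dominated imbalance structure.

The generator emulates the statistical shape of an in-the-wild ADL
recording — a long NULL background with short, sparse activity events —
without attempting biomechanical realism.  Each activity class has an
idealized oscillatory signature (a distinct frequency band and amplitude,
rendered mainly on a dominant wrist); the NULL background is sensor noise
plus gravity plus random "distractor" motion bursts whose frequency and
amplitude ranges overlap the activity bands, which is what makes the
classification problem non-trivial and gives the NULL class its
characteristic confusability.

Event placement is a per-class Poisson process with a non-overlap
constraint; durations are log-normal.  Everything is deterministic given
the config seed.

:func:`corrupt_predictions` perturbs label streams directly (misses,
spurious insertions, fragmentation holes), emulating the error modes of a
window classifier so the postprocessor and event metrics can be exercised
without training a model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .prediction import PredictionStream
from .stream import ACTIVITY_LABELS, HANDS, NULL, SensorStream, write_stream_csv


@dataclass
class ActivitySignature:
    """Idealized oscillatory rendering of one activity class."""

    label: str
    freq_hz: float
    amp: float                      # m/s², dominant hand
    dominant_hand: str = "right"    # "left", "right", or "both"
    duration_median_s: float = 120.0
    duration_sigma: float = 0.35    # log-normal shape
    events_per_hour: float = 0.5
    freq_jitter_hz: float = 0.25
    amp_jitter: float = 0.3         # multiplicative, U(1-a, 1+a) per event
    axis_mix: tuple = (0.7, 0.9, 0.4)
    nondominant_atten: float = 0.3
    #: fraction of the event span occupied by the characteristic oscillatory
    #: gesture; 1.0 renders the whole span.  Consumption-style activities
    #: (drinking, taking medication) are mostly-idle spans punctuated by
    #: brief gestures, which is what makes them hard to recognize window by
    #: window.
    gesture_duty: float = 1.0
    gesture_len_s: float = 2.5
    #: rate of short NULL-labeled bursts rendered from this same signature —
    #: activity-like motions that are not the activity (a sip-like arm raise
    #: without drinking).  They make the class statistically confusable with
    #: the background, which is what suppresses rare-class recall under a
    #: NULL-dominated prior.
    confusers_per_hour: float = 0.0

    @property
    def mean_duration_s(self) -> float:
        return self.duration_median_s * math.exp(self.duration_sigma**2 / 2)

    def with_imbalance_target(self, ir: float) -> "ActivitySignature":
        """Set the event rate so the class's expected imbalance ratio is ``ir``.

        IR = (n - c) / c for class sample count c, so the target time
        fraction is 1 / (ir + 1).
        """
        rate = 3600.0 / ((ir + 1.0) * self.mean_duration_s)
        return replace(self, events_per_hour=rate)


def default_signatures() -> list[ActivitySignature]:
    """Study-scale signatures: per-class imbalance ratios in the 45-510 range."""
    base = [
        # label, freq, amp, hand, dur_median, axis_mix, confusers/h, IR target
        # label, freq, amp, hand, dur_median, axis_mix, confusers/h, duty, IR
        ("BrushingTeeth", 4.4, 2.0, "right", 120.0, (0.9, 0.5, 0.3), 0.0, 1.0, 500.0),
        ("CombingHair", 3.8, 2.0, "right", 90.0, (0.4, 0.9, 0.5), 0.0, 1.0, 457.0),
        ("Drinking", 1.4, 1.2, "right", 30.0, (0.7, 0.6, 0.7), 1.0, 0.2, 510.0),
        ("Eating", 1.0, 1.8, "right", 600.0, (0.8, 0.8, 0.3), 0.3, 1.0, 49.0),
        ("TakingMedication", 1.7, 1.0, "right", 45.0, (0.5, 0.7, 0.8), 0.8, 0.2, 364.0),
        ("Walking", 2.0, 2.5, "both", 300.0, (0.6, 0.4, 0.9), 0.0, 1.0, 45.0),
        ("WashingHands", 3.2, 2.2, "both", 40.0, (0.9, 0.8, 0.6), 0.0, 1.0, 239.0),
    ]
    return [
        ActivitySignature(
            lab, f, a, hand, dur, axis_mix=mix, confusers_per_hour=cf,
            gesture_duty=duty,
        ).with_imbalance_target(ir)
        for lab, f, a, hand, dur, mix, cf, duty, ir in base
    ]


def demo_signatures() -> list[ActivitySignature]:
    """Desk-scale signatures: same bands, compressed imbalance (~IR 15-60).

    Event rates are raised and durations kept at minutes-scale so that a few
    hours of simulated data contain enough events per class for event-level
    statistics to be meaningful.
    """
    base = [
        # label, freq, amp, hand, dur_median, axis_mix, events/h, confusers/h
        # label, freq, amp, hand, dur_median, axis_mix, events/h, confusers/h, duty
        ("BrushingTeeth", 4.4, 2.0, "right", 130.0, (0.9, 0.5, 0.3), 0.5, 0.0, 1.0),
        ("CombingHair", 3.8, 2.0, "right", 130.0, (0.4, 0.9, 0.5), 0.6, 0.0, 1.0),
        ("Drinking", 1.4, 1.2, "right", 110.0, (0.7, 0.6, 0.7), 0.5, 8.0, 0.12),
        ("Eating", 1.0, 1.8, "right", 180.0, (0.8, 0.8, 0.3), 0.9, 2.0, 1.0),
        ("TakingMedication", 1.7, 1.0, "right", 110.0, (0.5, 0.7, 0.8), 0.4, 7.0, 0.12),
        ("Walking", 2.0, 2.5, "both", 180.0, (0.6, 0.4, 0.9), 1.0, 0.0, 1.0),
        ("WashingHands", 3.2, 2.2, "both", 110.0, (0.9, 0.8, 0.6), 0.8, 0.0, 1.0),
    ]
    return [
        ActivitySignature(
            lab, f, a, hand, dur, axis_mix=mix, events_per_hour=rate,
            confusers_per_hour=cf, gesture_duty=duty,
        )
        for lab, f, a, hand, dur, mix, rate, cf, duty in base
    ]


@dataclass
class SimulationConfig:
    participants: int = 9
    hours_range: tuple = (3.0, 12.0)
    sample_rate_hz: float = 50.0
    signatures: list[ActivitySignature] = field(default_factory=default_signatures)
    noise_std: float = 0.15          # m/s², white accelerometer noise
    gravity: float = 9.81            # constant offset on the z axis
    distractor_per_hour: float = 12.0
    distractor_duration_s: float = 20.0
    distractor_freq_range: tuple = (0.3, 5.5)
    distractor_amp_range: tuple = (0.5, 2.0)
    # everyday arm motion is dominated by slow movements, so most distractor
    # bursts fall in a low-frequency band; this is what makes the consumption
    # activities (eating/drinking/medication) blend into the background
    distractor_low_band: tuple = (0.6, 2.2)
    distractor_low_frac: float = 0.6
    confuser_duration_s: float = 20.0   # log-normal median of confuser bursts
    seed: int = 0

    @classmethod
    def default(cls) -> "SimulationConfig":
        return cls()

    @classmethod
    def demo(cls, seed: int = 0) -> "SimulationConfig":
        """Reduced problem size for desk-scale end-to-end runs."""
        return cls(
            participants=5,
            hours_range=(1.6, 2.4),
            sample_rate_hz=20.0,
            signatures=demo_signatures(),
            distractor_per_hour=25.0,
            distractor_low_frac=0.7,
            seed=seed,
        )


def _place_events(rng, total_s, sigs, max_attempts=100):
    """Poisson placement of non-overlapping events; returns (start, end, sig)."""
    placed: list[tuple[float, float, ActivitySignature]] = []
    gap = 2.0
    for sig in sigs:
        n_ev = rng.poisson(sig.events_per_hour * total_s / 3600.0)
        for _ in range(n_ev):
            dur = float(
                rng.lognormal(math.log(sig.duration_median_s), sig.duration_sigma)
            )
            dur = min(dur, 0.25 * total_s)
            ok = False
            for _ in range(max_attempts):
                start = rng.uniform(0.0, total_s - dur)
                if all(
                    start >= e + gap or start + dur <= s - gap
                    for s, e, _ in placed
                ):
                    ok = True
                    break
            if ok:
                placed.append((start, start + dur, sig))
            # events that cannot be placed without overlap are dropped (cap)
    return sorted(placed, key=lambda x: x[0])


def _hand_gains(sig: ActivitySignature) -> dict[str, float]:
    if sig.dominant_hand == "both":
        return {h: 1.0 for h in HANDS}
    other = "left" if sig.dominant_hand == "right" else "right"
    return {sig.dominant_hand: 1.0, other: sig.nondominant_atten}


def _render_burst(accel, hand_arrays, t, sl, freq, amp, mix, hand_gains, rng):
    phases = rng.uniform(0, 2 * np.pi, size=3)
    tt = t[sl]
    for hand, gain in hand_gains.items():
        for j in range(3):
            hand_arrays[hand][sl, j] += (
                gain * amp * mix[j] * np.sin(2 * np.pi * freq * tt + phases[j])
            )


def generate_dataset(cfg: SimulationConfig) -> list[SensorStream]:
    """Generate one labeled stream per synthetic participant (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate_hz
    streams = []
    for p in range(cfg.participants):
        hours = rng.uniform(*cfg.hours_range)
        total_s = hours * 3600.0
        n = int(round(total_s * fs))
        t = np.arange(n) / fs
        labels = np.full(n, NULL, dtype=object)
        accel = {
            hand: rng.normal(0.0, cfg.noise_std, size=(n, 3)) for hand in HANDS
        }
        for hand in HANDS:
            accel[hand][:, 2] += cfg.gravity

        events = _place_events(rng, total_s, cfg.signatures)
        for start, end, sig in events:
            sl = slice(int(start * fs), min(int(end * fs), n))
            if sl.start >= sl.stop:
                continue
            freq = sig.freq_hz + rng.uniform(-sig.freq_jitter_hz, sig.freq_jitter_hz)
            amp = sig.amp * rng.uniform(1 - sig.amp_jitter, 1 + sig.amp_jitter)
            gains = _hand_gains(sig)
            if sig.gesture_duty >= 1.0:
                _render_burst(accel, accel, t, sl, freq, amp, sig.axis_mix, gains, rng)
            else:
                # mostly-idle span punctuated by brief characteristic gestures
                spacing = sig.gesture_len_s / sig.gesture_duty
                g0 = start
                while g0 < end - sig.gesture_len_s:
                    gs = g0 + rng.uniform(0.0, spacing - sig.gesture_len_s)
                    gsl = slice(
                        int(gs * fs), min(int((gs + sig.gesture_len_s) * fs), n)
                    )
                    if gsl.start < gsl.stop:
                        _render_burst(
                            accel, accel, t, gsl, freq, amp, sig.axis_mix, gains, rng
                        )
                    g0 += spacing
            labels[sl] = sig.label

        # distractor motions: oscillatory NULL-class bursts overlapping the
        # activity bands in frequency and amplitude
        n_dist = rng.poisson(cfg.distractor_per_hour * hours)
        for _ in range(n_dist):
            dur = float(rng.lognormal(math.log(cfg.distractor_duration_s), 0.4))
            for _ in range(50):
                start = rng.uniform(0.0, max(total_s - dur, 1.0))
                sl = slice(int(start * fs), min(int((start + dur) * fs), n))
                if sl.start < sl.stop and (labels[sl] == NULL).all():
                    if rng.random() < cfg.distractor_low_frac:
                        freq = rng.uniform(*cfg.distractor_low_band)
                    else:
                        freq = rng.uniform(*cfg.distractor_freq_range)
                    amp = rng.uniform(*cfg.distractor_amp_range)
                    mix = rng.uniform(0.3, 1.0, size=3)
                    hand = HANDS[rng.integers(2)]
                    other = "left" if hand == "right" else "right"
                    gains = {hand: 1.0, other: float(rng.uniform(0.0, 1.0))}
                    _render_burst(accel, accel, t, sl, freq, amp, mix, gains, rng)
                    break

        # confuser bursts: short activity-like motions that stay NULL-labeled,
        # rendered through the same signature path as real events
        for sig in cfg.signatures:
            if sig.confusers_per_hour <= 0:
                continue
            if sig.gesture_duty < 1.0:
                base_dur, sigma = sig.gesture_len_s, 0.25
            else:
                base_dur, sigma = cfg.confuser_duration_s, 0.4
            for _ in range(rng.poisson(sig.confusers_per_hour * hours)):
                dur = float(rng.lognormal(math.log(base_dur), sigma))
                for _ in range(50):
                    start = rng.uniform(0.0, max(total_s - dur, 1.0))
                    sl = slice(int(start * fs), min(int((start + dur) * fs), n))
                    if sl.start < sl.stop and (labels[sl] == NULL).all():
                        freq = sig.freq_hz + rng.uniform(
                            -sig.freq_jitter_hz, sig.freq_jitter_hz
                        )
                        amp = sig.amp * rng.uniform(
                            1 - sig.amp_jitter, 1 + sig.amp_jitter
                        )
                        _render_burst(
                            accel, accel, t, sl, freq, amp, sig.axis_mix,
                            _hand_gains(sig), rng,
                        )
                        break

        streams.append(
            SensorStream(
                participant_id=f"sim{p:02d}",
                sample_rate_hz=fs,
                t=t,
                accel=accel,
                labels=labels,
            )
        )
    return streams


def dataset_manifest(streams: list[SensorStream]) -> dict:
    """Achieved per-class hours and imbalance ratios of a generated dataset."""
    from collections import Counter

    counts: Counter = Counter()
    fs = streams[0].sample_rate_hz
    for s in streams:
        counts.update(s.labels.tolist())
    n = sum(counts.values())
    per_class = {}
    for lab in ACTIVITY_LABELS:
        c = counts.get(lab, 0)
        per_class[lab] = {
            "hours": c / fs / 3600.0,
            "ir": (n - c) / c if c else None,
        }
    per_class[NULL] = {"hours": counts.get(NULL, 0) / fs / 3600.0, "ir": None}
    return {"total_hours": n / fs / 3600.0, "classes": per_class}


def write_dataset(streams: list[SensorStream], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in streams:
        write_stream_csv(s, out_dir / f"{s.participant_id}.csv")
    (out_dir / "manifest.json").write_text(
        json.dumps(dataset_manifest(streams), indent=2)
    )


@dataclass
class CorruptionConfig:
    """Direct label-stream corruption emulating window-classifier errors."""

    miss_rate: float = 0.0            # per-step flip of activity -> NULL
    insertion_rate: float = 0.0       # expected fraction of NULL steps made spurious
    insertion_mean_len: float = 4.0   # geometric mean run length of insertions
    fragmentation_rate: float = 0.0   # per-step probability of punching a hole
    fragmentation_hole_len: int = 4   # hole length in steps
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.miss_rate, self.insertion_rate, self.fragmentation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("corruption rates must lie in [0, 1]")


def corrupt_predictions(gt: PredictionStream, cfg: CorruptionConfig) -> PredictionStream:
    """Apply misses, spurious insertions, and fragmentation holes (seeded).

    Length is conserved.  Insertions start at a NULL step with probability
    ``insertion_rate / insertion_mean_len`` and run for a geometric number of
    steps, so the expected number of inserted events over n NULL steps is
    about ``insertion_rate * n / insertion_mean_len``.
    """
    rng = np.random.default_rng(cfg.seed)
    labels = gt.labels.copy()
    n = len(labels)
    is_null = labels == NULL

    if cfg.fragmentation_rate > 0:
        starts = np.flatnonzero(
            (~is_null) & (rng.random(n) < cfg.fragmentation_rate)
        )
        for s in starts:
            labels[s : s + cfg.fragmentation_hole_len] = NULL

    if cfg.miss_rate > 0:
        flip = (~is_null) & (rng.random(n) < cfg.miss_rate)
        labels[flip] = NULL

    if cfg.insertion_rate > 0:
        p_start = cfg.insertion_rate / max(cfg.insertion_mean_len, 1.0)
        starts = np.flatnonzero(is_null & (rng.random(n) < p_start))
        for s in starts:
            run = int(rng.geometric(1.0 / cfg.insertion_mean_len))
            lab = ACTIVITY_LABELS[rng.integers(len(ACTIVITY_LABELS))]
            end = min(s + run, n)
            seg = slice(s, end)
            mask = gt.labels[seg] == NULL
            labels[seg] = np.where(mask, lab, labels[seg])

    return PredictionStream(labels, gt.stride_s)
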