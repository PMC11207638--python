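"""Labeled dual-wrist sensor streams: label vocabulary, relabeling, CSV ingestion.

A stream is a uniformly sampled, timestamped recording from two wrist-worn
inertial sensors with a per-sample activity label.  Raw annotations use an
open vocabulary (free-text "Other:<...>" labels, distractor labels such as
"Clapping"); a :class:`RelabelMap` collapses them onto the closed vocabulary
of seven activities of daily living plus the catch-all ``NULL`` class before
any downstream processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NULL = "NULL"

ACTIVITY_LABELS = (
    "BrushingTeeth",
    "CombingHair",
    "Drinking",
    "Eating",
    "TakingMedication",
    "Walking",
    "WashingHands",
)

LABELS = ACTIVITY_LABELS + (NULL,)

HANDS = ("left", "right")

#: Raw annotation -> canonical label.  Entries not present fall through to the
#: "Other:*" rule (stairs count as walking, anything else is NULL).
DEFAULT_RELABEL_RULES = {
    "Clapping": NULL,
    "Nothing": NULL,
    "nothing": NULL,
    "Taking Meds": "TakingMedication",
    "Washing Hands": "WashingHands",
    "Brushing Teeth": "BrushingTeeth",
    "Combing Hair": "CombingHair",
    # one participant used an electric toothbrush; those movements do not
    # resemble manual brushing and are treated as background
    "BrushingTeeth:electric": NULL,
}


@dataclass
class RelabelMap:
    """Total mapping from raw label text to the canonical closed vocabulary."""

    rules: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RELABEL_RULES))

    def __call__(self, raw: str) -> str:
        raw = str(raw).strip()
        if raw in self.rules:
            return self.rules[raw]
        if raw in LABELS:
            return raw
        if raw.startswith("Other:"):
            detail = raw[len("Other:") :].strip().lower()
            if "stairs" in detail or detail == "stairs":
                return "Walking"
            return NULL
        raise KeyError(f"unknown raw label {raw!r} with no relabel entry")

    def apply(self, labels) -> np.ndarray:
        return np.asarray([self(x) for x in labels], dtype=object)


@dataclass
class SensorStream:
    """Uniformly sampled dual-wrist recording with per-sample labels.

    ``accel[hand]`` is an ``(n, 3)`` array in m/s²; ``gyro`` is optional and
    unused by the classical feature set.  ``t`` is seconds from stream start.
    """

    participant_id: str
    sample_rate_hz: float
    t: np.ndarray
    accel: dict[str, np.ndarray]
    labels: np.ndarray
    gyro: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for hand, arr in self.accel.items():
            if hand not in HANDS:
                raise ValueError(f"unknown hand {hand!r}")
            if arr.shape != (n, 3):
                raise ValueError(
                    f"accel[{hand}] has shape {arr.shape}, expected ({n}, 3)"
                )
        if len(self.labels) != n:
            raise ValueError("labels and timestamps differ in length")
        bad = set(np.unique(self.labels)) - set(LABELS)
        if bad:
            raise ValueError(f"labels outside closed vocabulary: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def require_both_hands(self) -> None:
        for hand in HANDS:
            if hand not in self.accel:
                raise ValueError(f"missing accelerometer channel for hand {hand!r}")


REQUIRED_COLUMNS = ("t", "ax", "ay", "az", "label", "hand", "participant")


def _resample_hand(t: np.ndarray, xyz: np.ndarray, grid: np.ndarray) -> np.ndarray:
    out = np.empty((len(grid), 3))
    for j in range(3):
        out[:, j] = np.interp(grid, t, xyz[:, j])
    return out


def load_stream(
    path,
    relabel: RelabelMap | None = None,
    sample_rate_hz: float = 50.0,
    monotone_tolerance_s: float = 0.0,
) -> SensorStream:
    """Load a labeled CSV recording and return a canonical :class:`SensorStream`.

    The CSV is long-format with one row per sample and hand: columns
    ``t, ax, ay, az[, gx, gy, gz], label, hand, participant``.  Raw labels are
    mapped through ``relabel`` (default map if omitted); timestamps are
    resampled onto a uniform grid at ``sample_rate_hz`` by linear
    interpolation, and each grid tick takes the label of the nearest raw
    sample.
    """
    relabel = relabel or RelabelMap()
    # keep_default_na: the NULL class label must not be parsed as missing
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    if df.empty:
        raise ValueError("no samples")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    participants = df["participant"].unique()
    if len(participants) != 1:
        raise ValueError("one stream per participant-session; found " f"{participants}")

    hands = sorted(df["hand"].unique())
    t0 = df["t"].min()
    t_end = df["t"].max()
    n = int(np.floor((t_end - t0) * sample_rate_hz)) + 1
    grid = t0 + np.arange(n) / sample_rate_hz

    accel: dict[str, np.ndarray] = {}
    labels = None
    for hand in hands:
        sub = df[df["hand"] == hand]
        t = sub["t"].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(t) and (dt < -monotone_tolerance_s).any():
            raise ValueError(f"non-monotone timestamps for hand {hand!r}")
        order = np.argsort(t, kind="stable")
        t = t[order]
        xyz = sub[["ax", "ay", "az"]].to_numpy(dtype=float)[order]
        accel[hand] = _resample_hand(t, xyz, grid)
        if labels is None:
            raw = sub["label"].to_numpy()[order]
            canon = relabel.apply(raw)
            idx = np.clip(np.searchsorted(t, grid), 0, len(t) - 1)
            # nearest raw sample, not just the right neighbour
            left = np.clip(idx - 1, 0, len(t) - 1)
            use_left = np.abs(grid - t[left]) <= np.abs(t[idx] - grid)
            idx = np.where(use_left, left, idx)
            labels = canon[idx]

    return SensorStream(
        participant_id=str(participants[0]),
        sample_rate_hz=float(sample_rate_hz),
        t=grid - t0,
        accel=accel,
        labels=labels,
    )


def write_stream_csv(stream: SensorStream, path) -> None:
    """Inverse of :func:`load_stream` for canonical streams (long format)."""
    frames = []
    for hand in sorted(stream.accel):
        frames.append(
            pd.DataFrame(
                {
                    "t": stream.t,
                    "ax": stream.accel[hand][:, 0],
                    "ay": stream.accel[hand][:, 1],
                    "az": stream.accel[hand][:, 2],
                    "label": stream.labels,
                    "hand": hand,
                    "participant": stream.participant_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.5f")
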