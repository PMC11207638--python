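"""Sliding-window segmentation of labeled sensor streams.

The recognition pipeline operates on short fixed-length windows (default 1 s
with 75% overlap, i.e. a 0.25 s stride).  Each window carries one label
derived from its per-sample labels by a majority rule that favors the rare
activity classes over the NULL background.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .stream import NULL, SensorStream


@dataclass
class Window:
    """Half-open slice [start_s, end_s) of a stream with an assigned label."""

    start_s: float
    end_s: float
    accel: dict[str, np.ndarray]  # hand -> (n_samples, 3)
    label: str


def window_label(labels: np.ndarray) -> str:
    """Majority label of a window.

    Ties are resolved in favor of a non-NULL activity (rare classes are the
    signal of interest); among tied activities the label at the window's
    center sample wins, falling back to earliest first appearance.
    """
    labels = np.asarray(labels, dtype=object)
    counts = Counter(labels.tolist())
    top = max(counts.values())
    cands = [lab for lab, c in counts.items() if c == top]
    if len(cands) == 1:
        return cands[0]
    non_null = [lab for lab in cands if lab != NULL]
    if non_null:
        cands = non_null
    if len(cands) == 1:
        return cands[0]
    center = labels[len(labels) // 2]
    if center in cands:
        return center
    for lab in labels:  # earliest first appearance among the tied set
        if lab in cands:
            return lab
    return cands[0]


def window_starts(n_samples: int, sample_rate_hz: float, window_s: float, overlap: float):
    """Start indices of all full windows; stride = window_s * (1 - overlap)."""
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    stride_s = window_s * (1.0 - overlap)
    w = int(round(window_s * sample_rate_hz))
    duration = n_samples / sample_rate_hz
    n_windows = int(np.floor((duration - window_s) / stride_s + 1e-9)) + 1
    if n_windows < 1:
        return w, np.empty(0, dtype=int)
    starts = np.round(np.arange(n_windows) * stride_s * sample_rate_hz).astype(int)
    starts = starts[starts + w <= n_samples]
    return w, starts


def segment_windows(
    stream: SensorStream, window_s: float = 1.0, overlap: float = 0.75
) -> list[Window]:
    """Segment a stream into overlapping fixed-length windows.

    Window starts lie at multiples of the stride from stream start; a stream
    shorter than one window yields an empty list.
    """
    w, starts = window_starts(stream.n_samples, stream.sample_rate_hz, window_s, overlap)
    fs = stream.sample_rate_hz
    out = []
    for s in starts:
        sl = slice(s, s + w)
        out.append(
            Window(
                start_s=s / fs,
                end_s=(s + w) / fs,
                accel={hand: arr[sl] for hand, arr in stream.accel.items()},
                label=window_label(stream.labels[sl]),
            )
        )
    return out


def label_grid(stream: SensorStream, window_s: float = 1.0, overlap: float = 0.75) -> np.ndarray:
    """Per-window ground-truth labels on the prediction grid.

    Rasterizes per-sample labels to the window stride using the same majority
    rule as training, so that predicted and reference streams are directly
    comparable at the event level.
    """
    w, starts = window_starts(stream.n_samples, stream.sample_rate_hz, window_s, overlap)
    return np.asarray(
        [window_label(stream.labels[s : s + w]) for s in starts], dtype=object
    )
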