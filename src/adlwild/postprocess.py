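"""Context-based correction of window-level prediction streams.

Activity labels are strongly autocorrelated in time: a window's true class
almost always matches its neighbours'.  The postprocessor exploits this by
replacing each prediction with the weighted-majority label of the ``ws``
predictions around it, with weights that decay with distance ``d`` from the
window center:

====  ================  =============================
id    shape             weight(ws, d)
====  ================  =============================
W1    triangular        max(ceil(ws/2) - d, 0)
W2    inverse           1 / (d + 2)
W3    squared           max(ceil(ws/2) - d, 0) ** 2
W4    log               log(max(ceil(ws/2) - d, 0) + 1)
W5    inverse log       1 / log(d + 2)
====  ================  =============================

Natural log throughout; the corrected label is invariant to the log base
since all scores scale by the same positive constant.  Two stream modes are
offered: ``centered`` (default) aligns each corrected label with the window
it corrects, which is what scoring against ground truth requires;
``literal_streaming`` reproduces the online form of the algorithm, where the
first ``ws`` outputs pass through unchanged and each subsequent output is
the correction of the trailing context window (inherent lag included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil, log

import numpy as np

from .prediction import PredictionStream

WEIGHT_FUNCTIONS = ("W1", "W2", "W3", "W4", "W5")


def weight_value(fn: str, ws: int, d: int) -> float:
    """Evaluate weighting function ``fn`` at distance ``d`` from the center.

    ``d`` may be signed when the literal signed-offset convention is in use;
    the triangular/squared/log shapes clamp negative arguments to zero so
    evidence is never negative.
    """
    if fn == "W1":
        return float(max(ceil(ws / 2) - d, 0))
    if fn == "W2":
        return 1.0 / (d + 2)
    if fn == "W3":
        return float(max(ceil(ws / 2) - d, 0)) ** 2
    if fn == "W4":
        return log(max(ceil(ws / 2) - d, 0) + 1)
    if fn == "W5":
        return 1.0 / log(d + 2)
    raise ValueError(f"unknown weighting function {fn!r}")


def _weights(fn: str, ws: int, signed_distance: bool) -> np.ndarray:
    """Weight of each position i = 1..ws in a context window."""
    midpoint = ws // 2 + 1
    if signed_distance:
        ds = [i - midpoint + 1 for i in range(1, ws + 1)]
    else:
        ds = [abs(i - midpoint) for i in range(1, ws + 1)]
    return np.array([weight_value(fn, ws, d) for d in ds])


def correct_window(window, ws: int, fn: str, signed_distance: bool = False) -> str:
    """Weighted-majority label of one context window of length ``ws``.

    Each position contributes its weight to its label's score; the highest
    score wins.  Score ties break toward the higher raw count in the window,
    remaining ties toward the earliest first appearance.
    """
    labels = np.asarray(window, dtype=object)
    if len(labels) != ws or ws < 1:
        raise ValueError(f"context window must have exactly ws={ws} labels")
    uniq, codes = np.unique(labels, return_inverse=True)
    scores = np.bincount(codes, weights=_weights(fn, ws, signed_distance), minlength=len(uniq))
    counts = np.bincount(codes, minlength=len(uniq))
    return _argmax_label(labels, codes, uniq, scores, counts)


#: relative tolerance for score ties; mathematically equal scores (e.g. sums
#: of logs that factor identically) differ by rounding, and tie-breaking must
#: not depend on that — a relative tolerance is invariant to rescaling the
#: weight function, which keeps the corrected label independent of log base
TIE_RTOL = 1e-9


def _argmax_label(labels, codes, uniq, scores, counts) -> str:
    best = scores.max()
    cand = np.flatnonzero(best - scores <= TIE_RTOL * max(abs(best), 1.0))
    if len(cand) > 1:
        top_count = counts[cand].max()
        cand = cand[counts[cand] == top_count]
    if len(cand) > 1:
        first = np.full(len(uniq), len(codes))
        for pos in range(len(codes) - 1, -1, -1):
            first[codes[pos]] = pos
        cand = cand[np.argmin(first[cand])]
        return str(uniq[int(cand)])
    return str(uniq[int(cand[0])])


@dataclass
class CorrectionConfig:
    """Postprocessing configuration.

    ``ws_seconds`` is the context span in seconds of stream; the context
    length in steps is round(ws_seconds / stride), so e.g. 160 s at the
    default 0.25 s stride is 640 predictions.
    """

    weight_fn: str = "W4"
    ws_seconds: float = 160.0
    mode: str = "centered"
    signed_distance: bool = False

    def ws_count(self, stride_s: float) -> int:
        ws = int(round(self.ws_seconds / stride_s))
        if ws < 1:
            raise ValueError("context window shorter than one stride")
        return ws


def correct_stream(stream: PredictionStream, cfg: CorrectionConfig) -> PredictionStream:
    """Apply context-based correction to a whole prediction stream.

    Length is always conserved.  In centered mode, positions whose full
    context would extend past either end of the stream pass through
    unchanged; if the context window exceeds the stream length the entire
    stream passes through with a warning.
    """
    labels = stream.labels
    n = len(labels)
    if n == 0:
        return PredictionStream(labels.copy(), stream.stride_s)
    ws = cfg.ws_count(stream.stride_s)
    if ws == 1:  # a single-prediction context cannot change any label
        return PredictionStream(labels.copy(), stream.stride_s)
    if ws > n:
        warnings.warn(
            f"context window ({ws} steps) longer than stream ({n}); "
            "stream passed through uncorrected",
            stacklevel=2,
        )
        return PredictionStream(labels.copy(), stream.stride_s)
    if cfg.mode == "centered":
        out = labels.copy()
        midpoint = ws // 2 + 1
        before, after = midpoint - 1, ws - midpoint
        uniq, codes = np.unique(labels, return_inverse=True)
        w = _weights(cfg.weight_fn, ws, cfg.signed_distance)
        for t in range(before, n - after):
            sl = codes[t - before : t + after + 1]
            scores = np.bincount(sl, weights=w, minlength=len(uniq))
            counts = np.bincount(sl, minlength=len(uniq))
            out[t] = _argmax_label(labels[t - before : t + after + 1], sl, uniq, scores, counts)
        return PredictionStream(out, stream.stride_s)
    if cfg.mode == "literal_streaming":
        out = []
        window: list = []
        for i in range(n):
            if len(window) < ws:
                out.append(labels[i])
            else:
                out.append(correct_window(window, ws, cfg.weight_fn, cfg.signed_distance))
                window.pop(0)
            window.append(labels[i])
        return PredictionStream(np.asarray(out, dtype=object), stream.stride_s)
    raise ValueError(f"unknown mode {cfg.mode!r}")
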