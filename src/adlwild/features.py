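"""Window-level feature extraction for classical activity classifiers.

Seventeen features are computed per accelerometer axis per hand (time-domain
statistics, peak/valley structure, and spectral centroid/spread/rolloff and
entropy of the one-sided DFT magnitudes), plus two per-hand features (axis
overlap and a box-counting fractal dimension of the acceleration magnitude),
for a total of 17 x 3 axes x 2 hands + 2 x 2 hands = 106 features.

Conventions that the feature names rely on:

* spectra are one-sided DFT magnitudes with the DC bin excluded, indexed
  k = 1..N, and the spectral centroid/spread/rolloff are reported in bin
  units;
* peaks and valleys are local extrema with prominence >= 0.1 x the window's
  standard deviation; the "average / std of the number of peaks" features are
  taken over the window's four equal non-overlapping quarter segments;
* the fractal dimension is a box-counting slope on the curve rescaled to the
  unit square, clamped to [1, 2]; constant or too-short signals give 1.0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .windows import Window

AXES = ("x", "y", "z")
HANDS = ("left", "right")

PER_AXIS_FEATURES = (
    "jerk_mean",          # (A) mean |first difference| x sample rate
    "peak_height_mean",   # (B) mean signal value at detected peaks
    "peak_height_std",    # (C) std of signal value at detected peaks
    "energy",             # (D) mean squared mean-removed sample
    "entropy",            # (E) Shannon entropy of normalized DFT magnitudes
    "mean",               # (F)
    "std",                # (G)
    "rms",                # (H)
    "n_peaks",            # (I)
    "peaks_qmean",        # (J) mean peak count over quarter segments
    "peaks_qstd",         # (K) std of peak count over quarter segments
    "n_valleys",          # (L)
    "valleys_qmean",      # (M)
    "valleys_qstd",       # (N)
    "spectral_centroid",  # (O)
    "spectral_spread",    # (P)
    "spectral_rolloff",   # (Q) smallest bin accumulating 85% of magnitude
)

PER_HAND_FEATURES = (
    "axis_overlap",       # (R) pairwise axis-trace crossings per second
    "fractal_dim",        # (S) box-counting dimension of |accel|
)

META_COLUMNS = ("window_start_s", "window_end_s", "label")

N_FEATURES = len(PER_AXIS_FEATURES) * len(AXES) * len(HANDS) + len(
    PER_HAND_FEATURES
) * len(HANDS)  # 106


def feature_columns() -> list[str]:
    """Stable, documented order of the 106 feature column names."""
    cols = []
    for hand in HANDS:
        for axis in AXES:
            cols += [f"{hand}_{axis}_{name}" for name in PER_AXIS_FEATURES]
        cols += [f"{hand}_{name}" for name in PER_HAND_FEATURES]
    return cols


def spectral_summary(spectrum, rolloff_frac: float = 0.85):
    """Centroid, spread, and rolloff bin of a one-sided magnitude spectrum.

    ``spectrum[i]`` is the magnitude of bin k = i + 1 (DC excluded).  Centroid
    C = sum k X(k) / sum X(k); spread S = sqrt(sum (k - C)^2 X(k) / sum X(k));
    rolloff is the smallest k whose cumulative magnitude reaches
    ``rolloff_frac`` of the total.  An all-zero spectrum falls back to
    (0.0, 0.0, 1) rather than NaN.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("spectrum must be a non-empty 1-D magnitude array")
    if (x < 0).any():
        raise ValueError("magnitudes must be non-negative")
    tot = x.sum()
    if tot == 0:
        return 0.0, 0.0, 1
    k = np.arange(1, len(x) + 1, dtype=float)
    c = float((k * x).sum() / tot)
    s = float(np.sqrt(((k - c) ** 2 * x).sum() / tot))
    rolloff = int(np.searchsorted(np.cumsum(x), rolloff_frac * tot) + 1)
    return c, s, min(rolloff, len(x))


def _box_count_dims(mat: np.ndarray) -> np.ndarray:
    """Vectorized box-counting dimension per row, clamped to [1, 2]."""
    mat = np.asarray(mat, dtype=float)
    m, n = mat.shape
    out = np.ones(m)
    if n < 8:
        return out
    lo = mat.min(axis=1, keepdims=True)
    rng = mat.max(axis=1, keepdims=True) - lo
    ok = rng[:, 0] > 0
    if not ok.any():
        return out
    y = np.zeros_like(mat)
    y[ok] = (mat[ok] - lo[ok]) / rng[ok]

    # subdivide each segment x4 so the polyline, not just the samples,
    # determines box occupancy
    up = 4
    segs = [(1 - f) * y[:, :-1] + f * y[:, 1:] for f in np.arange(up) / up]
    y_up = np.concatenate(segs + [y[:, -1:]], axis=1)
    # column order matches segs: box counting is order-independent
    t_up = np.concatenate(
        [np.arange(n - 1) + f for f in np.arange(up) / up] + [[n - 1.0]]
    ) / (n - 1)
    n_up = y_up.shape[1]

    j_max = int(np.clip(np.floor(np.log2(n_up)) - 1, 2, 6))
    js = np.arange(1, j_max + 1)
    log_n = np.zeros((m, len(js)))
    for col, j in enumerate(js):
        g = 2**j
        ix = np.minimum((t_up * g).astype(int), g - 1)
        iy = np.minimum((y_up * g).astype(int), g - 1)
        code = np.sort(ix[None, :] * g + iy, axis=1)
        log_n[:, col] = np.log1p((np.diff(code, axis=1) != 0).sum(axis=1))
    # least-squares slope of log N(eps) against log(1/eps) = j log 2
    xj = js * np.log(2.0)
    xc = xj - xj.mean()
    slope = (log_n * xc).sum(axis=1) / (xc**2).sum()
    out[ok] = np.clip(slope[ok], 1.0, 2.0)
    return out


def fractal_dimension(signal) -> float:
    """Box-counting fractal dimension of a 1-D signal, clamped to [1, 2].

    Constant or shorter-than-8-sample signals return 1.0 by convention.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    return float(_box_count_dims(x[None, :])[0])


def _peak_stats(mat: np.ndarray, with_heights: bool):
    """Prominence-thresholded peak counts (and heights) per row.

    Returns (count, qmean, qstd[, height_mean, height_std]); quarter counts
    are over four equal non-overlapping segments of the window.
    """
    m, n = mat.shape
    prom = 0.1 * mat.std(axis=1)
    qedges = np.linspace(0, n, 5)
    count = np.zeros(m)
    qmean = np.zeros(m)
    qstd = np.zeros(m)
    hmean = np.zeros(m)
    hstd = np.zeros(m)
    for i in range(m):
        if prom[i] == 0:
            continue
        peaks, _ = find_peaks(mat[i], prominence=prom[i])
        count[i] = len(peaks)
        qc = np.histogram(peaks, bins=qedges)[0]
        qmean[i] = qc.mean()
        qstd[i] = qc.std()
        if with_heights and len(peaks):
            h = mat[i, peaks]
            hmean[i] = h.mean()
            hstd[i] = h.std()
    if with_heights:
        return count, qmean, qstd, hmean, hstd
    return count, qmean, qstd


def _axis_crossings(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Count sign changes of a - b per row, ignoring exact-equality samples."""
    d = np.sign(a - b)
    out = np.zeros(a.shape[0])
    for i in range(a.shape[0]):
        s = d[i][d[i] != 0]
        out[i] = int((np.diff(s) != 0).sum()) if len(s) else 0
    return out


def extract_features(windows: list[Window], sample_rate_hz: float | None = None) -> pd.DataFrame:
    """Compute the 106-feature matrix for a sequence of dual-wrist windows.

    Returns a DataFrame with ``window_start_s``, ``window_end_s``, ``label``
    and the 106 named feature columns, one row per window in time order.
    Deterministic given its input; raises if either hand's accelerometer is
    absent.
    """
    if not windows:
        return pd.DataFrame(columns=list(META_COLUMNS) + feature_columns())
    for hand in HANDS:
        if hand not in windows[0].accel:
            raise ValueError(f"missing accelerometer channel for hand {hand!r}")
    n = windows[0].accel[HANDS[0]].shape[0]
    dur = windows[0].end_s - windows[0].start_s
    fs = sample_rate_hz if sample_rate_hz is not None else n / dur

    out = {
        "window_start_s": np.array([w.start_s for w in windows]),
        "window_end_s": np.array([w.end_s for w in windows]),
        "label": np.array([w.label for w in windows], dtype=object),
    }

    for hand in HANDS:
        mats = {
            axis: np.stack([w.accel[hand][:, j] for w in windows])
            for j, axis in enumerate(AXES)
        }
        for axis, mat in mats.items():
            pre = f"{hand}_{axis}_"
            mean = mat.mean(axis=1)
            centered = mat - mean[:, None]
            std = mat.std(axis=1)
            out[pre + "jerk_mean"] = np.abs(np.diff(mat, axis=1)).mean(axis=1) * fs
            out[pre + "energy"] = (centered**2).mean(axis=1)
            out[pre + "mean"] = mean
            out[pre + "std"] = std
            out[pre + "rms"] = np.sqrt((mat**2).mean(axis=1))

            spec = np.abs(np.fft.rfft(mat, axis=1))[:, 1:]
            tot = spec.sum(axis=1)
            safe = np.where(tot > 0, tot, 1.0)
            p = spec / safe[:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                ent = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
            out[pre + "entropy"] = np.where(tot > 0, ent, 0.0)
            k = np.arange(1, spec.shape[1] + 1, dtype=float)
            cen = (spec * k).sum(axis=1) / safe
            spread = np.sqrt(((k[None, :] - cen[:, None]) ** 2 * p).sum(axis=1))
            cum = np.cumsum(spec, axis=1)
            roll = (cum < 0.85 * tot[:, None]).sum(axis=1) + 1
            out[pre + "spectral_centroid"] = np.where(tot > 0, cen, 0.0)
            out[pre + "spectral_spread"] = np.where(tot > 0, spread, 0.0)
            out[pre + "spectral_rolloff"] = np.where(
                tot > 0, np.minimum(roll, spec.shape[1]), 1
            ).astype(float)

            pc, pqm, pqs, phm, phs = _peak_stats(mat, with_heights=True)
            vc, vqm, vqs = _peak_stats(-mat, with_heights=False)
            out[pre + "n_peaks"] = pc
            out[pre + "peaks_qmean"] = pqm
            out[pre + "peaks_qstd"] = pqs
            out[pre + "n_valleys"] = vc
            out[pre + "valleys_qmean"] = vqm
            out[pre + "valleys_qstd"] = vqs
            out[pre + "peak_height_mean"] = phm
            out[pre + "peak_height_std"] = phs

        cross = (
            _axis_crossings(mats["x"], mats["y"])
            + _axis_crossings(mats["x"], mats["z"])
            + _axis_crossings(mats["y"], mats["z"])
        )
        out[f"{hand}_axis_overlap"] = cross / dur
        norm = np.sqrt(mats["x"] ** 2 + mats["y"] ** 2 + mats["z"] ** 2)
        out[f"{hand}_fractal_dim"] = _box_count_dims(norm)

    df = pd.DataFrame(out)
    return df[list(META_COLUMNS) + feature_columns()]
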