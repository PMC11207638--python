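"""Imbalance treatments for NULL-dominated training sets.

Three treatments are supported, all applied to the training split only:

* random undersampling (RUS) — the majority (NULL) class is resampled
  without replacement down to the total size of the non-majority classes;
* ratio-preserving random oversampling (ROS) — minority rows are duplicated
  with replacement so the total minority count equals the majority count
  while pairwise minority ratios are preserved (largest-remainder
  apportionment), avoiding the a-priori equal-frequency assumption of
  fully balanced oversampling;
* cost-sensitive class weights — weight_c = n_total / (n_classes * count_c),
  i.e. inversely proportional to class size.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .stream import NULL


def class_counts(labels) -> Counter:
    return Counter(list(labels))


def random_undersample(
    rows: pd.DataFrame, seed: int, majority: str = NULL, label_col: str = "label"
) -> pd.DataFrame:
    """Downsample the majority class to the total non-majority count.

    Sampling is without replacement and deterministic given ``seed``;
    minority rows pass through untouched.  Raises if the dataset is not
    majority-dominated.
    """
    counts = class_counts(rows[label_col])
    n_major = counts.get(majority, 0)
    n_minor = sum(c for lab, c in counts.items() if lab != majority)
    if n_major < n_minor:
        raise ValueError(
            f"majority class {majority!r} ({n_major}) smaller than the "
            f"non-majority total ({n_minor}); nothing to undersample"
        )
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero((rows[label_col] == majority).to_numpy())
    keep = np.sort(rng.choice(maj_idx, size=n_minor, replace=False))
    min_idx = np.flatnonzero((rows[label_col] != majority).to_numpy())
    sel = np.sort(np.concatenate([keep, min_idx]))
    return rows.iloc[sel].reset_index(drop=True)


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``shares``."""
    quota = shares / shares.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def ratio_preserving_oversample(
    rows: pd.DataFrame, seed: int, majority: str = NULL, label_col: str = "label"
) -> pd.DataFrame:
    """Oversample minority classes to match the majority total, preserving ratios.

    Each minority class keeps all its rows and gains duplicates sampled with
    replacement up to a largest-remainder apportionment of the majority
    count.  If the minority total already reaches the majority count the
    input is returned unchanged.
    """
    counts = class_counts(rows[label_col])
    minority = [lab for lab in counts if lab != majority]
    if not minority:
        raise ValueError("no minority class present")
    if any(counts[lab] == 0 for lab in minority):
        raise ValueError("minority class with zero instances")
    n_major = counts.get(majority, 0)
    n_minor = sum(counts[lab] for lab in minority)
    if n_minor >= n_major:
        return rows.reset_index(drop=True)

    minority = sorted(minority)  # deterministic apportionment order
    shares = np.array([counts[lab] for lab in minority], dtype=float)
    targets = _largest_remainder(shares, n_major)

    rng = np.random.default_rng(seed)
    labels = rows[label_col].to_numpy()
    parts = [rows]
    for lab, target in zip(minority, targets):
        idx = np.flatnonzero(labels == lab)
        extra = int(target) - len(idx)
        if extra > 0:
            dup = rng.choice(idx, size=extra, replace=True)
            parts.append(rows.iloc[dup])
    return pd.concat(parts, ignore_index=True)


def balanced_class_weights(counts: dict[str, int]) -> dict[str, float]:
    """Cost-sensitive weights: weight_c = n_total / (n_classes * count_c)."""
    if any(c <= 0 for c in counts.values()):
        raise ValueError("zero-count class in weight computation")
    n_total = sum(counts.values())
    k = len(counts)
    return {lab: n_total / (k * c) for lab, c in counts.items()}


def resample(rows: pd.DataFrame, method: str, seed: int) -> pd.DataFrame:
    """Dispatch helper: method in {"none", "rus", "ros"}."""
    if method == "none" or method == "csl":
        return rows.reset_index(drop=True)
    if method == "rus":
        return random_undersample(rows, seed)
    if method == "ros":
        return ratio_preserving_oversample(rows, seed)
    raise ValueError(f"unknown resampling method {method!r}")
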