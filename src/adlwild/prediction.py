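"""Ordered per-window label streams at a fixed stride."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PredictionStream:
    """Ordered class labels P = [P1..Pn] at a fixed stride in seconds.

    The default stride of 0.25 s corresponds to 1 s windows at 75% overlap.
    """

    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    stride_s: float = 0.25

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.stride_s <= 0:
            raise ValueError("stride must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PredictionStream)
            and self.stride_s == other.stride_s
            and len(self) == len(other)
            and bool((self.labels == other.labels).all())
        )
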