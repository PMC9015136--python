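"""Sliding-window profiles.

A :class:`Profile` is a per-position series produced by averaging a
per-residue value over an odd-width sliding window. Only positions with a
full window are reported, at the window's center (1-based): a window of
width ``w`` over a sequence of length ``L`` yields centers
``w//2 + 1 .. L - w//2``. No padded or truncated edge windows are ever
reported, so every value is a true window mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError


@dataclass(frozen=True)
class Profile:
    """Per-position windowed values.

    ``positions`` are 1-based window centers; ``values`` the window means.
    Positions covered by a masked residue (NaN input) are dropped.
    """

    positions: np.ndarray
    values: np.ndarray
    window: int
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.positions.shape != self.values.shape:
            raise ValidationError("positions and values must have equal length")

    def __len__(self) -> int:
        return len(self.positions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Profile):
            return NotImplemented
        return (
            self.window == other.window
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.values, other.values)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, self.name or "value": self.values})


def validate_window(window: int, length: int, *, allow_longer: bool = False) -> None:
    """Check window oddness/size against a sequence length."""
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be a positive odd integer, got {window}")
    if not allow_longer and window > length:
        raise ValidationError(
            f"window {window} exceeds sequence length {length}; "
            "use a whole-sequence statistic (e.g. net_charge or "
            "mean_scaled_hydropathy) instead"
        )


def sliding_mean(values: np.ndarray, window: int, name: str = "") -> Profile:
    """Mean of every full window, reported at the center position.

    NaN entries mark masked residues: any window covering one is dropped.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    validate_window(window, n)
    half = window // 2
    means = sliding_window_view(values, window).mean(axis=1)
    centers = np.arange(half + 1, n - half + 1)
    keep = ~np.isnan(means)
    return Profile(centers[keep], means[keep], window, name=name)
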