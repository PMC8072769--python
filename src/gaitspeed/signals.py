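"""Quasi-periodic gait signals and walking-speed patterns.

The frame-by-frame variation of each ratio feature over a walking
sequence traces a quasi-periodic signal (gait is cyclic).  This module
normalizes those signals to [0, 1], counts their local maxima as a
frequency proxy, computes amplitude / variation statistics, and stacks
the five normalized signals into the fixed-length multivariate pattern
the classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .silhouette import RATIO_NAMES, RatioFeatures

__all__ = [
    "SPEED_CLASSES",
    "RatioSignal",
    "WalkingSpeedPattern",
    "SignalStats",
    "DegenerateSignalError",
    "minmax_normalize",
    "count_peaks",
    "amplitude_percent",
    "variation_percent",
    "signal_stats",
    "build_pattern",
    "pattern_from_dataframe",
]

#: canonical class order; index = integer label used everywhere downstream
SPEED_CLASSES = ("slow", "normal", "fast")


class DegenerateSignalError(ValueError):
    """Raised for constant signals, which indicate extraction failure."""


@dataclass(frozen=True)
class RatioSignal:
    """One ratio feature's time series over the valid frames of a sequence."""

    name: str
    values: np.ndarray
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        if self.name not in RATIO_NAMES:
            raise ValueError(f"unknown signal name {self.name!r}; expected one of {RATIO_NAMES}")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("signal values must be one-dimensional")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class WalkingSpeedPattern:
    """A 5 x T matrix of normalized signals plus its speed-class label.

    Rows are ordered HW1, HW2, HW3, A1, A2; every row spans exactly
    [0, 1] after min-max normalization.  ``label`` is the integer class
    index into :data:`SPEED_CLASSES`.
    """

    signals: np.ndarray
    label: int
    source_id: str = ""

    def __post_init__(self) -> None:
        signals = np.asarray(self.signals, dtype=float)
        if signals.ndim != 2 or signals.shape[0] != len(RATIO_NAMES):
            raise ValueError(f"pattern must be {len(RATIO_NAMES)} x T")
        if not 0 <= self.label < len(SPEED_CLASSES):
            raise ValueError(f"label must index {SPEED_CLASSES}")
        object.__setattr__(self, "signals", signals)

    @property
    def T(self) -> int:
        return self.signals.shape[1]

    @property
    def label_name(self) -> str:
        return SPEED_CLASSES[self.label]


@dataclass(frozen=True)
class SignalStats:
    """Amplitude (%), peak count and variation (%) of one signal."""

    amplitude_percent: float
    peak_count: int
    variation_percent: float


def minmax_normalize(values: Sequence[float] | RatioSignal) -> np.ndarray:
    """Map a signal affinely onto [0, 1]: (x - min) / (max - min).

    Constant signals raise :class:`DegenerateSignalError` — a flat ratio
    trace means the extraction produced no gait information, and silently
    emitting zeros would poison the downstream pattern.
    """
    x = np.asarray(values.values if isinstance(values, RatioSignal) else values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to normalize")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSignalError("degenerate signal: constant values cannot be normalized")
    return (x - lo) / (hi - lo)


def count_peaks(values: Sequence[float] | RatioSignal) -> int:
    """Number of strict interior local maxima of a signal.

    A plateau of equal values flanked by strictly smaller neighbours
    counts once; endpoints never count.  The count over a fixed-length
    sequence is the frequency proxy used to compare walking speeds
    (width/area signals peak twice per gait cycle).
    """
    x = np.asarray(values.values if isinstance(values, RatioSignal) else values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples to count interior maxima")
    peaks, _ = find_peaks(x)
    return int(len(peaks))


def amplitude_percent(values: Sequence[float] | RatioSignal) -> float:
    """Relative range of a raw (pre-normalization) ratio signal, in %.

    Defined as 100 * (max - min) / max.  All values must be positive:
    the ratio features are strictly positive whenever extraction
    succeeded, so a non-positive sample indicates a bad input.
    """
    x = np.asarray(values.values if isinstance(values, RatioSignal) else values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples for an amplitude")
    if (x <= 0).any():
        raise ValueError("amplitude_percent requires strictly positive values")
    return float(100.0 * (x.max() - x.min()) / x.max())


def variation_percent(series: Sequence[float]) -> float:
    """Coefficient of variation of a raw measurement series, in %.

    100 * (sample SD / mean) over consecutive frames; quantifies how much
    a body measurement (e.g. full-body width) oscillates during walking.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples for a variation")
    mean = x.mean()
    if mean == 0:
        raise ValueError("variation_percent undefined for zero-mean series")
    return float(100.0 * x.std(ddof=1) / mean)


def signal_stats(values: Sequence[float] | RatioSignal) -> SignalStats:
    """Amplitude, peak count and variation of one raw signal in one go.

    The amplitude is reported as NaN when the signal touches zero or
    below (the relative range is undefined there, e.g. for A2 whenever
    the legs close).
    """
    x = np.asarray(values.values if isinstance(values, RatioSignal) else values, dtype=float)
    amp = amplitude_percent(x) if (x > 0).all() else float("nan")
    return SignalStats(
        amplitude_percent=amp,
        peak_count=count_peaks(x),
        variation_percent=variation_percent(x),
    )


def build_pattern(
    frames: Sequence[RatioFeatures],
    label: int | str,
    T: int,
    source_id: str = "",
) -> WalkingSpeedPattern:
    """Stack the first ``T`` frames' ratios into a normalized 5 x T pattern.

    Each of the five ratio series is truncated to its first ``T`` valid
    frames and min-max normalized independently, then stacked in the
    fixed row order HW1, HW2, HW3, A1, A2.
    """
    if isinstance(label, str):
        label = SPEED_CLASSES.index(label)
    if len(frames) < T:
        raise ValueError(
            f"sequence has {len(frames)} valid frames but the pattern length is {T} "
            f"({T - len(frames)} short)"
        )
    raw = np.array([f.as_tuple() for f in frames[:T]], dtype=float).T  # 5 x T
    rows = [minmax_normalize(raw[i]) for i in range(raw.shape[0])]
    return WalkingSpeedPattern(np.vstack(rows), label, source_id)


def pattern_from_dataframe(df, label: int | str, T: int, source_id: str = "") -> WalkingSpeedPattern:
    """Build a pattern from a :func:`gaitspeed.silhouette.measure_sequence` frame."""
    feats = [RatioFeatures(*row) for row in df.loc[:, list(RATIO_NAMES)].to_numpy()]
    return build_pattern(feats, label, T, source_id)
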