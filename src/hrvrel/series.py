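"""Core container for RR-interval recordings.

An RR interval (RRi) is the time in milliseconds between two successive
R-waves of the ECG QRS complex. A 10-minute supine recording at a typical
resting heart rate holds roughly 700-900 beats; every downstream index
(time-domain, spectral, entropy, fractal) is computed from a window of
these intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: Physiologically plausible RR range in ms; values outside are parsed but
#: flagged so that preprocessing, not I/O, decides their fate.
PLAUSIBLE_RR_MS = (200.0, 3000.0)


class BeatLabel(str, Enum):
    NORMAL = "normal"
    ECTOPIC = "ectopic"
    INTERPOLATED = "interpolated"


@dataclass
class RRiSeries:
    """An ordered sequence of RR intervals with per-beat annotations.

    Parameters
    ----------
    intervals : array-like of float
        RR intervals in milliseconds, all finite and strictly positive.
    beat_labels : array-like of str, optional
        Per-interval label (``normal``/``ectopic``/``interpolated``);
        defaults to all-normal.
    meta : dict, optional
        Free-form recording metadata (subject id, rater, occasion, ...).
    """

    intervals: np.ndarray
    beat_labels: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.intervals.size == 0:
            raise ValueError("no intervals")
        if not np.all(np.isfinite(self.intervals)):
            raise ValueError("intervals must be finite")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be strictly positive")
        if self.beat_labels is None:
            self.beat_labels = np.full(
                self.intervals.size, BeatLabel.NORMAL.value, dtype=object
            )
        else:
            self.beat_labels = np.asarray(self.beat_labels, dtype=object)
            self.beat_labels = np.array(
                [str(lbl) for lbl in self.beat_labels], dtype=object
            )
            valid = {lbl.value for lbl in BeatLabel}
            bad = set(self.beat_labels) - valid
            if bad:
                raise ValueError(f"unknown beat labels: {sorted(bad)}")
        if self.beat_labels.size != self.intervals.size:
            raise ValueError("intervals and beat_labels must have equal length")
        lo, hi = PLAUSIBLE_RR_MS
        n_implausible = int(np.sum((self.intervals < lo) | (self.intervals > hi)))
        if n_implausible:
            self.meta.setdefault("n_implausible", n_implausible)

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def beat_times_s(self) -> np.ndarray:
        """Cumulative beat times in seconds (time of each beat's end)."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum() / 1000.0)

    @property
    def is_normal(self) -> np.ndarray:
        return self.beat_labels == BeatLabel.NORMAL.value

    def with_labels(self, labels: np.ndarray) -> "RRiSeries":
        return RRiSeries(self.intervals.copy(), np.asarray(labels, dtype=object),
                         dict(self.meta))
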