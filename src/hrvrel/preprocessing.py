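"""Ectopic-beat handling and stationary-segment selection.

HRV indices assume a stationary window of sinus ("normal-to-normal")
intervals. Recordings are screened in three steps:

1. ectopic beats are flagged by deviation from a running median of the
   preceding normal beats (an automated surrogate for visual inspection);
2. recordings whose ectopic-to-sinus ratio exceeds 10% are discarded;
3. the best window of 256 consecutive normal beats is chosen by a
   composite score rewarding (a) absence of large outliers, (b) local
   stationarity, and (c) Gaussian-looking interval distribution.

The selection is a deterministic, reproducible stand-in for the manual
"best stationary stretch" choice that trained raters make by eye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .series import BeatLabel, RRiSeries

DEFAULT_SEGMENT_LENGTH = 256
DEFAULT_STRIDE = 16
DEFAULT_WEIGHTS = (0.4, 0.4, 0.2)


def detect_ectopic(
    series: RRiSeries,
    threshold_frac: float = 0.20,
    local_window: int = 11,
) -> RRiSeries:
    """Label beats deviating >``threshold_frac`` from the local median.

    A beat is ectopic iff it deviates from the median of the preceding
    ``local_window`` normal intervals by more than ``threshold_frac``
    (relative to that median). Beats already labeled ectopic keep their
    label and are excluded from the running history, which makes the
    operation idempotent.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    if len(series) < local_window + 1:
        raise ValueError(
            f"series has {len(series)} beats; need at least {local_window + 1}"
        )
    labels = series.beat_labels.copy()
    history: list[float] = []
    for i, rr in enumerate(series.intervals):
        if labels[i] == BeatLabel.ECTOPIC.value:
            continue
        if history:
            med = float(np.median(history[-local_window:]))
            if abs(rr - med) / med > threshold_frac:
                labels[i] = BeatLabel.ECTOPIC.value
                continue
        history.append(float(rr))
    return series.with_labels(labels)


def ectopic_fraction(series: RRiSeries) -> float:
    """Ectopic beats relative to the total of pure sinus beats."""
    n_ect = int(np.sum(series.beat_labels == BeatLabel.ECTOPIC.value))
    n_norm = int(np.sum(series.beat_labels == BeatLabel.NORMAL.value))
    if n_norm == 0:
        raise ValueError("no normal beats; ectopic fraction undefined")
    return n_ect / n_norm


@dataclass(frozen=True)
class DiscardDecision:
    accept: bool
    fraction: float
    reason: str


def apply_discard_rule(series: RRiSeries, max_frac: float = 0.10) -> DiscardDecision:
    """Reject the recording iff the ectopic fraction strictly exceeds ``max_frac``."""
    frac = ectopic_fraction(series)
    if frac > max_frac:
        return DiscardDecision(
            False, frac, f"ectopic fraction {frac:.3f} exceeds {max_frac:.2f}"
        )
    return DiscardDecision(True, frac, f"ectopic fraction {frac:.3f} acceptable")


@dataclass
class SegmentSelection:
    """A chosen window of consecutive RR intervals plus its quality scores."""

    start_index: int
    length: int
    window: np.ndarray
    quality: dict

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=float)
        if self.window.size != self.length:
            raise ValueError("window length mismatch")


def score_window(window: np.ndarray, weights: tuple = DEFAULT_WEIGHTS) -> dict:
    """Composite quality score for a candidate window.

    ``outlier_rate``: fraction of beats outside window mean +/- 3 SD.
    ``stationarity``: 1 - |split-half mean difference| / SD, floored at 0.
    ``normality``: Shapiro-Wilk p-value (1.0 for a constant window, where
    the test is undefined and there is no evidence against normality).
    """
    window = np.asarray(window, dtype=float)
    mu = window.mean()
    sd = window.std(ddof=1)
    if sd == 0:
        outlier_rate = 0.0
        half = window.size // 2
        stationarity = 1.0 if window[:half].mean() == window[half:].mean() else 0.0
        normality = 1.0
    else:
        outlier_rate = float(np.mean(np.abs(window - mu) > 3 * sd))
        half = window.size // 2
        stationarity = max(
            0.0, 1.0 - abs(window[:half].mean() - window[half:].mean()) / sd
        )
        normality = min(1.0, float(stats.shapiro(window).pvalue))
    w1, w2, w3 = weights
    composite = w1 * (1.0 - outlier_rate) + w2 * stationarity + w3 * normality
    return {
        "outlier_rate": outlier_rate,
        "stationarity_score": stationarity,
        "normality_score": normality,
        "composite": composite,
    }


def candidate_starts(
    series: RRiSeries, length: int, stride: int
) -> np.ndarray:
    """Starts of ectopic-free windows of ``length``, sampled every ``stride``.

    The final feasible start is always included so the tail of the
    recording is never unreachable.
    """
    n = len(series)
    if n < length:
        return np.empty(0, dtype=int)
    starts = list(range(0, n - length + 1, stride))
    if starts[-1] != n - length:
        starts.append(n - length)
    ok_normal = (series.beat_labels != BeatLabel.ECTOPIC.value).astype(int)
    csum = np.concatenate([[0], np.cumsum(ok_normal)])
    starts = np.asarray(starts, dtype=int)
    clean = (csum[starts + length] - csum[starts]) == length
    return starts[clean]


def select_best_segment(
    series: RRiSeries,
    length: int = DEFAULT_SEGMENT_LENGTH,
    stride: int = DEFAULT_STRIDE,
    weights: tuple = DEFAULT_WEIGHTS,
) -> SegmentSelection:
    """Pick the ectopic-free window maximizing the composite quality score.

    Deterministic: ties go to the earliest start. Raises if no
    ectopic-free window of the requested length exists (the recording
    should then be discarded).
    """
    starts = candidate_starts(series, length, stride)
    if starts.size == 0:
        raise ValueError(
            f"no ectopic-free window of {length} beats; consider discarding"
        )
    best = None
    for s in starts:
        q = score_window(series.intervals[s : s + length], weights)
        if best is None or q["composite"] > best[1]["composite"]:
            best = (int(s), q)
    start, quality = best
    return SegmentSelection(
        start_index=start,
        length=length,
        window=series.intervals[start : start + length].copy(),
        quality=quality,
    )
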