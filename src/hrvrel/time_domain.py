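"""Time-domain HRV indices on a selected beat window.

All functions take a 1-D sequence of RR intervals in milliseconds
(the extracted stationary window, assumed all-normal by construction).
"""

from __future__ import annotations

import numpy as np

#: Histogram bin width for the RR triangular index: 1/128 s, the sampling
#: convention of standard HRV analysis software.
RR_TRI_BIN_MS = 1000.0 / 128.0


def _as_window(window) -> np.ndarray:
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return w


def mean_rr(window) -> float:
    """Arithmetic mean of RR intervals, ms."""
    return float(_as_window(window).mean())


def sdnn(window) -> float:
    """Sample standard deviation (n-1 denominator) of the intervals, ms."""
    w = _as_window(window)
    if w.size < 2:
        raise ValueError("sdnn requires at least 2 intervals")
    return float(w.std(ddof=1))


def mean_hr(window) -> float:
    """Mean of instantaneous heart rates 60000/RRi, bpm.

    This is the beat-wise mean rate, not 60000 / mean RR; by Jensen's
    inequality it is >= the latter, strictly so unless the window is
    constant.
    """
    w = _as_window(window)
    if np.any(w <= 0):
        raise ValueError("intervals must be positive")
    return float(np.mean(60000.0 / w))


def rmssd(window) -> float:
    """Root mean square of successive RR differences, ms."""
    w = _as_window(window)
    if w.size < 2:
        raise ValueError("rmssd requires at least 2 intervals")
    d = np.diff(w)
    return float(np.sqrt(np.mean(d**2)))


def rr_tri(window, bin_width: float = RR_TRI_BIN_MS) -> float:
    """RR triangular index: total beat count / modal histogram bin count.

    The histogram uses fixed bins of width ``bin_width`` (default
    1/128 s = 7.8125 ms) anchored at 0 ms, so results do not depend on
    the window's own range.
    """
    w = _as_window(window)
    idx = np.floor(w / bin_width).astype(int)
    counts = np.bincount(idx - idx.min())
    return float(w.size / counts.max())
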