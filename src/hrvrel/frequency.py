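"""Frequency-domain HRV indices from a beat window.

The unevenly sampled tachogram RR(t) is cubic-spline resampled onto an
even 4 Hz grid, detrended with a smoothness-priors (regularized
second-difference) smoother, and its power spectral density estimated by
Welch's averaged periodogram with a Hann window. Band powers are the
trapezoidal integrals of the PSD over

    VLF [0.003, 0.04) Hz, LF [0.04, 0.15) Hz, HF [0.15, 0.4) Hz,

and normalized units express LF and HF as percentages of LF + HF.
These settings mirror standard short-term HRV analysis practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, sparse
from scipy.interpolate import CubicSpline
from scipy.sparse.linalg import spsolve

VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)

DEFAULT_RESAMPLE_HZ = 4.0
DEFAULT_DETREND_LAMBDA = 500.0
DEFAULT_WELCH_WINDOW_S = 128.0
DEFAULT_OVERLAP_FRAC = 0.5

#: Shortest span (s) for which a spectral estimate down to the LF band is
#: meaningful: ~30 s covers one full cycle at the lower LF edge region.
MIN_SPAN_S = 30.0


@dataclass
class SpectralEstimate:
    """PSD of the tachogram plus its band powers (ms^2)."""

    freqs: np.ndarray
    psd: np.ndarray
    band_powers: dict
    total_power: float
    settings: dict = field(default_factory=dict)


def resample_rri(window, rate: float = DEFAULT_RESAMPLE_HZ):
    """Cubic-spline resample RR(t) onto an even grid.

    ``window`` is the RR sequence in ms; beat times are its cumulative
    sums. Returns ``(times_s, rr_ms)`` with ``floor(span*rate)+1``
    samples over [t_first, t_last].
    """
    w = np.asarray(window, dtype=float)
    if w.size < 4:
        raise ValueError("need at least 4 beats for spline resampling")
    t = np.cumsum(w) / 1000.0
    span = t[-1] - t[0]
    if span < MIN_SPAN_S:
        raise ValueError("segment too short for spectral analysis")
    n_out = int(np.floor(span * rate)) + 1
    grid = t[0] + np.arange(n_out) / rate
    spline = CubicSpline(t, w)
    return grid, spline(grid)


def detrend_smoothness_priors(
    x, lam: float = DEFAULT_DETREND_LAMBDA
) -> np.ndarray:
    """Remove the slow trend via a second-difference-penalized smoother.

    The trend is ``H z`` with ``H = (I + lam^2 D2' D2)^-1`` where ``D2``
    is the second-difference operator; the detrended signal ``z - H z``
    is returned. Larger ``lam`` pushes the smoother's cutoff toward
    lower frequencies (lam=500 at 4 Hz cuts near 0.035 Hz); lam=0 makes
    H the identity, so the output is all zeros.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    z = np.asarray(x, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 samples to detrend")
    d2 = sparse.diags_array(
        [np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2],
        shape=(n - 2, n),
        format="csc",
    )
    a = sparse.eye_array(n, format="csc") + (lam**2) * (d2.T @ d2)
    trend = spsolve(a, z)
    return z - trend


def welch_band_powers(
    x,
    rate: float,
    window_s: float = DEFAULT_WELCH_WINDOW_S,
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
) -> SpectralEstimate:
    """Hann-windowed Welch PSD and trapezoidal band powers.

    If the signal is shorter than one Welch window, a single full-length
    window is used. Band edges are half-open ``[lo, hi)``.
    """
    if rate <= 2 * HF_BAND[1]:
        raise ValueError("sampling rate too low to resolve the HF band")
    z = np.asarray(x, dtype=float)
    nperseg = min(int(round(window_s * rate)), z.size)
    freqs, psd = signal.welch(
        z,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap_frac * nperseg)),
        detrend="constant",
    )
    bands = {}
    for name, (lo, hi) in {"vlf": VLF_BAND, "lf": LF_BAND, "hf": HF_BAND}.items():
        mask = (freqs >= lo) & (freqs < hi)
        bands[name] = float(np.trapezoid(psd[mask], freqs[mask])) if mask.sum() > 1 else 0.0
    total = float(np.trapezoid(psd, freqs))
    return SpectralEstimate(
        freqs=freqs,
        psd=psd,
        band_powers=bands,
        total_power=total,
        settings={
            "resample_hz": rate,
            "welch_window_s": window_s,
            "overlap_frac": overlap_frac,
        },
    )


def normalized_units(lf_ms2: float, hf_ms2: float) -> tuple[float, float]:
    """LF and HF as percentages of LF + HF; the pair sums to exactly 100."""
    tot = lf_ms2 + hf_ms2
    if tot <= 0:
        raise ValueError("LF + HF power must be positive")
    lf_nu = 100.0 * lf_ms2 / tot
    return lf_nu, 100.0 - lf_nu


def spectral_indices(
    window,
    rate: float = DEFAULT_RESAMPLE_HZ,
    lam: float = DEFAULT_DETREND_LAMBDA,
    window_s: float = DEFAULT_WELCH_WINDOW_S,
    overlap_frac: float = DEFAULT_OVERLAP_FRAC,
) -> dict:
    """Full spectral pipeline: resample, detrend, Welch, band powers, n.u."""
    _, rr = resample_rri(window, rate)
    detrended = detrend_smoothness_priors(rr, lam)
    est = welch_band_powers(detrended, rate, window_s, overlap_frac)
    lf, hf = est.band_powers["lf"], est.band_powers["hf"]
    lf_nu, hf_nu = normalized_units(lf, hf)
    return {
        "lf_ms2": lf,
        "hf_ms2": hf,
        "lf_nu": lf_nu,
        "hf_nu": hf_nu,
        "estimate": est,
    }
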