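"""Nonlinear HRV indices: entropies and detrended fluctuation analysis.

Approximate entropy (ApEn, Pincus convention: self-matches counted) and
sample entropy (SampEn, Richman-Moorman convention: self-matches
excluded, N - m templates at both lengths) quantify the regularity of
the beat series via template matching within a Chebyshev tolerance
``r`` at embedding dimension ``m``. Defaults m = 2 and r = 0.2 x SDNN of
the window, which makes both entropies invariant to shifting and
rescaling the data.

DFA integrates the mean-centered series, fits a least-squares line in
each non-overlapping box of n beats, and regresses log10 of the RMS
residual F(n) on log10 n. The short-range exponent alpha1 uses boxes of
4-16 beats, the long-range alpha2 16-64 beats. Uncorrelated noise gives
alpha ~ 0.5, Brownian-like integrated noise alpha ~ 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class EntropySettings:
    m: int = 2
    #: Tolerance as a fraction of the window's SDNN; the absolute
    #: tolerance in ms is r_frac * SD(window).
    r_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1 or int(self.m) != self.m:
            raise ValueError("m must be a positive integer")
        if self.r_frac <= 0:
            raise ValueError("tolerance fraction must be positive")


@dataclass(frozen=True)
class DFASettings:
    short_range: tuple = field(default=(4, 16))
    long_range: tuple = field(default=(16, 64))

    def __post_init__(self) -> None:
        for lo, hi in (self.short_range, self.long_range):
            if lo < 4 or hi <= lo:
                raise ValueError("box ranges must be non-empty with min >= 4")


def _tolerance(window: np.ndarray, settings: EntropySettings) -> float:
    r = settings.r_frac * window.std(ddof=1)
    if r <= 0:
        # constant window: any positive tolerance matches everything and
        # both entropies are exactly 0
        r = np.finfo(float).tiny
    return float(r)


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    n = x.size - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def _chebyshev_counts(templates: np.ndarray, r: float) -> np.ndarray:
    """Number of templates within Chebyshev distance r of each template
    (self included)."""
    d = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
    return (d <= r).sum(axis=1)


def apen(window, settings: EntropySettings = EntropySettings(), r: float | None = None) -> float:
    """Approximate entropy, Phi^m(r) - Phi^{m+1}(r), self-matches counted."""
    x = np.asarray(window, dtype=float)
    m = settings.m
    if x.size < m + 2:
        raise ValueError(f"need at least {m + 2} beats for ApEn")
    if r is None:
        r = _tolerance(x, settings)
    if r <= 0:
        raise ValueError("tolerance must be positive")

    def phi(p: int) -> float:
        t = _embed(x, p)
        c = _chebyshev_counts(t, r) / t.shape[0]
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sampen(window, settings: EntropySettings = EntropySettings(), r: float | None = None) -> float:
    """Sample entropy, -ln(A/B); self-matches excluded.

    A counts ordered pairs (i != j) of templates matching at length
    m + 1, B at length m, both over the N - m templates whose length-m
    prefix can be extended. Raises when no length-m pair matches (the
    tolerance is too small for the data).
    """
    x = np.asarray(window, dtype=float)
    m = settings.m
    if x.size < m + 2:
        raise ValueError(f"need at least {m + 2} beats for SampEn")
    if r is None:
        r = _tolerance(x, settings)
    if r <= 0:
        raise ValueError("tolerance must be positive")
    tm = _embed(x, m)[: x.size - m]
    tm1 = _embed(x, m + 1)
    b = int(_chebyshev_counts(tm, r).sum() - tm.shape[0])
    a = int(_chebyshev_counts(tm1, r).sum() - tm1.shape[0])
    if b == 0 or a == 0:
        raise ValueError("undefined entropy: no template matches at tolerance r")
    return float(-np.log(a / b))


def _fluctuation(y: np.ndarray, n: int) -> float:
    """RMS residual of per-box linear fits at box size n (tail dropped)."""
    nb = y.size // n
    segs = y[: nb * n].reshape(nb, n)
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    slopes = (segs @ tc) / denom
    resid = segs - segs.mean(axis=1, keepdims=True) - slopes[:, None] * tc
    return float(np.sqrt(np.mean(resid**2)))


def dfa(window, settings: DFASettings = DFASettings()) -> tuple[float, float]:
    """Detrended fluctuation analysis scaling exponents (alpha1, alpha2)."""
    x = np.asarray(window, dtype=float)
    max_box = max(settings.short_range[1], settings.long_range[1])
    if x.size < 2 * max_box:
        raise ValueError(f"need at least {2 * max_box} beats for DFA")
    y = np.cumsum(x - x.mean())

    def alpha(lo: int, hi: int) -> float:
        ns = np.arange(lo, hi + 1)
        f = np.array([_fluctuation(y, int(n)) for n in ns])
        if np.any(f == 0):
            raise ValueError("degenerate series: zero fluctuation")
        slope, _ = np.polyfit(np.log10(ns), np.log10(f), 1)
        return float(slope)

    return alpha(*settings.short_range), alpha(*settings.long_range)
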