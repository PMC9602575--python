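"""Synthetic RR-interval recordings and reliability datasets.

The beat model is a sinusoid-plus-noise tachogram: around a subject's
mean RR, a low-frequency oscillation (default 0.10 Hz, the
baroreflex/Mayer-wave band) and a high-frequency oscillation (default
0.25 Hz, respiratory sinus arrhythmia) are superposed with white
Gaussian beat-to-beat noise and an optional slow linear drift. Ectopic
events are inserted as premature/compensatory pairs (0.6x and 1.4x the
local RR), the classic ventricular-ectopic signature. The model is
deliberately simple enough that the expected spectral band powers
(a^2/2 per sinusoid) are known in closed form.

Reliability datasets follow the two-way random-effects model
X_ij = mu + b_i + r_j + e_ij that underlies ICC(2,1), with a fixed
rater offset to exercise the absolute-agreement penalty.

Rater behaviour is emulated by re-running segment selection with the
candidate grid restricted to a neighbourhood of the canonical best
segment and a seeded "subjective" perturbation added to the composite
score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import (
    DEFAULT_SEGMENT_LENGTH,
    DEFAULT_WEIGHTS,
    SegmentSelection,
    score_window,
    select_best_segment,
)
from .series import BeatLabel, RRiSeries


@dataclass(frozen=True)
class RRiGenParams:
    """Parameters of one synthetic 10-minute supine recording."""

    mean_rr: float = 800.0
    lf_amp: float = 30.0
    lf_freq: float = 0.10
    hf_amp: float = 25.0
    hf_freq: float = 0.25
    noise_sd: float = 10.0
    trend_slope: float = 0.0  # ms per minute
    ectopic_rate: float = 0.0  # per-beat probability of an ectopic pair
    duration_s: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean RR must be positive")
        for f in (self.lf_freq, self.hf_freq):
            if not 0 < f < 0.5:
                raise ValueError("modulation frequencies must lie in (0, 0.5) Hz")
        if min(self.lf_amp, self.hf_amp, self.noise_sd) < 0:
            raise ValueError("amplitudes and noise SD must be non-negative")
        if not 0 <= self.ectopic_rate < 0.5:
            raise ValueError("ectopic rate must lie in [0, 0.5)")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


def generate_rri(params: RRiGenParams) -> RRiSeries:
    """Generate a beat series from the oscillator model, seed-deterministic.

    Beat i occurring at cumulative time t has
    RR = mean_rr + lf_amp sin(2 pi f_lf t) + hf_amp sin(2 pi f_hf t + phi)
         + trend_slope t / 60 + N(0, noise_sd^2),
    with the HF phase phi drawn once per recording. Generation stops once
    cumulative time reaches ``duration_s``.
    """
    rng = np.random.default_rng(params.seed)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    intervals: list[float] = []
    labels: list[str] = []
    t = 0.0
    # a drift toward 0 makes RR decay geometrically (time advances by
    # RR/1000 per beat), so vanishing intervals must be caught explicitly
    max_beats = int(params.duration_s * 20)  # RR >= 50 ms throughout
    while t < params.duration_s - 1e-9:
        if len(intervals) >= max_beats:
            raise ValueError(
                "parameters yield implausibly small RR intervals"
            )
        rr = (
            params.mean_rr
            + params.lf_amp * np.sin(2 * np.pi * params.lf_freq * t)
            + params.hf_amp * np.sin(2 * np.pi * params.hf_freq * t + phi)
            + params.trend_slope * t / 60.0
        )
        if params.noise_sd > 0:
            rr += rng.normal(0.0, params.noise_sd)
        if rr < 1.0:
            raise ValueError("parameters yield a non-positive RR interval")
        if params.ectopic_rate > 0 and rng.uniform() < params.ectopic_rate:
            intervals.extend([0.6 * rr, 1.4 * rr])
            labels.extend([BeatLabel.ECTOPIC.value] * 2)
            t += 2.0 * rr / 1000.0
        else:
            intervals.append(float(rr))
            labels.append(BeatLabel.NORMAL.value)
            t += rr / 1000.0
    return RRiSeries(
        np.asarray(intervals),
        np.asarray(labels, dtype=object),
        {"generator": "oscillator", "seed": params.seed},
    )


def sample_subject_params(rng: np.random.Generator, **overrides) -> RRiGenParams:
    """Draw one subject's recording parameters from population distributions.

    Mean RR follows N(808, 107) ms (clipped to a plausible resting
    range); oscillation amplitudes and noise vary uniformly across
    subjects so the between-subject dispersion of the indices resembles
    a resting adult cohort.
    """
    params = dict(
        mean_rr=float(np.clip(rng.normal(808.0, 107.0), 550.0, 1200.0)),
        lf_amp=float(rng.uniform(20.0, 40.0)),
        hf_amp=float(rng.uniform(15.0, 35.0)),
        noise_sd=float(rng.uniform(5.0, 15.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    params.update(overrides)
    return RRiGenParams(**params)


@dataclass(frozen=True)
class ReliabilityGenParams:
    """Variance components of a two-way random-effects ratings model."""

    n_subjects: int = 69
    k: int = 2
    sigma_between: float = 3.0
    sigma_error: float = 1.0
    rater_offset: float = 0.0
    mu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.k < 2:
            raise ValueError("need n >= 2 subjects and k >= 2 measurements")
        if self.sigma_between < 0 or self.sigma_error < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def true_icc(self) -> float:
        """Population ICC(2,1) implied by the components.

        The fixed rater offsets enter as a rater variance
        sum(r_j^2)/(k-1), zero when the offset is zero.
        """
        offsets = np.linspace(-self.rater_offset / 2, self.rater_offset / 2, self.k)
        var_r = float(np.sum(offsets**2) / (self.k - 1))
        denom = self.sigma_between**2 + var_r + self.sigma_error**2
        return self.sigma_between**2 / denom if denom > 0 else float("nan")


def generate_reliability_study(params: ReliabilityGenParams):
    """Simulate a ratings matrix X_ij = mu + b_i + r_j + e_ij.

    Subject effects b ~ N(0, sigma_between^2); rater effects are fixed,
    evenly spread over +/- rater_offset/2; errors e ~ N(0,
    sigma_error^2). Returns a :class:`~hrvrel.reliability.RatingsMatrix`
    whose ``meta`` carries the population ICC implied by the components.
    """
    from .reliability import RatingsMatrix

    rng = np.random.default_rng(params.seed)
    n, k = params.n_subjects, params.k
    b = rng.normal(0.0, params.sigma_between, size=n)
    r = np.linspace(-params.rater_offset / 2, params.rater_offset / 2, k)
    e = rng.normal(0.0, params.sigma_error, size=(n, k))
    values = params.mu + b[:, None] + r[None, :] + e
    return RatingsMatrix(
        values,
        index_name="synthetic",
        comparison="interrater",
        meta={"true_icc": params.true_icc},
    )


def jittered_selection(
    series: RRiSeries,
    anchor_start: int,
    jitter_beats: int,
    noise: np.ndarray | None = None,
    length: int = DEFAULT_SEGMENT_LENGTH,
    weights: tuple = DEFAULT_WEIGHTS,
) -> SegmentSelection:
    """Best segment constrained to +/- ``jitter_beats`` of an anchor start.

    ``noise`` is an optional per-candidate perturbation (indexed by
    start - lo over the full candidate range) added to the composite
    score, emulating a rater's subjective weighting. With jitter 0 the
    anchor window itself is returned.
    """
    lo = max(0, anchor_start - jitter_beats)
    hi = min(len(series) - length, anchor_start + jitter_beats)
    if hi < lo:
        raise ValueError("series too short for the requested window")
    normal = series.beat_labels != BeatLabel.ECTOPIC.value
    csum = np.concatenate([[0], np.cumsum(normal.astype(int))])
    starts = [
        s for s in range(lo, hi + 1) if csum[s + length] - csum[s] == length
    ]
    if not starts:
        raise ValueError("no ectopic-free window within the jitter range")
    best = None
    for s in starts:
        q = score_window(series.intervals[s : s + length], weights)
        perturbed = q["composite"]
        if noise is not None:
            perturbed += float(noise[s - lo])
        if best is None or perturbed > best[2]:
            best = (s, q, perturbed)
    s, q, _ = best
    return SegmentSelection(
        start_index=s,
        length=length,
        window=series.intervals[s : s + length].copy(),
        quality=q,
    )


def simulate_rater_selection(
    series: RRiSeries,
    jitter_beats: int,
    seed: int = 0,
    length: int = DEFAULT_SEGMENT_LENGTH,
    noise_sd: float = 0.03,
) -> tuple[SegmentSelection, SegmentSelection]:
    """Two segment selections emulating intra-/interrater disagreement.

    The first is the canonical best segment; the second re-scores
    candidates within +/- ``jitter_beats`` of it with a seeded Gaussian
    perturbation of the composite score. Jitter 0 forces both selections
    to coincide.
    """
    first = select_best_segment(series, length=length)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=2 * jitter_beats + 1)
    second = jittered_selection(
        series, first.start_index, jitter_beats, noise=noise, length=length
    )
    return first, second
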