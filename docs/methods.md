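# Methods

This note documents the models, conventions and numerical choices behind
`hrvrel`, and what the synthetic-data tests do and do not establish.

## Signal model and preprocessing

The raw signal is a sequence of RR intervals in milliseconds. Beat times
are the cumulative sums of the intervals; the tachogram RR(t) assigns
each interval to its cumulative (end) time.

**Ectopic detection.** Visual artifact screening is replaced by a
running-median rule: a beat is ectopic when it deviates from the median
of the preceding 11 normal beats by more than 20% of that median.
Previously flagged beats are excluded from the history, so the rule is
idempotent and a premature/compensatory pair does not contaminate the
reference for subsequent beats. The 20%/11-beat defaults are the common
tachogram-artifact screening range; both are arguments.

**Discard rule.** A recording is rejected when the ratio of ectopic to
normal (sinus) beats strictly exceeds 0.10. The strict inequality keeps
exactly-10% recordings, the permissive reading of the usual clinical
rule.

**Segment selection.** Manual "best stationary stretch" selection is
replaced by a scored search over ectopic-free candidate windows of 256
beats (stride 16, final feasible start always included). Each window is
scored by

```
composite = 0.4·(1 − outlier_rate) + 0.4·stationarity + 0.2·normality
```

with `outlier_rate` the fraction of beats outside the window mean ± 3 SD,
`stationarity = max(0, 1 − |mean(first half) − mean(second half)|/SD)`
(a split-half reading of "equidistance", the only operationalization of
that criterion we found testable), and `normality` the Shapiro–Wilk
p-value (capped at 1; set to 1 for a constant window where the test is
undefined). Ties go to the earliest start, so selection is fully
deterministic; all three components are computed from window-local
statistics, making the chosen start invariant to adding a constant to
every interval. The weights favour the two artifact/stationarity
criteria over distribution shape and are configurable.

## Index conventions

* SDNN uses the n−1 (sample) denominator; at n = 256 the difference from
  the population form is < 0.2%.
* Mean HR is the mean of instantaneous rates 60000/RRi, not
  60000/mean RR; the two differ by a Jensen gap that is visible in
  published descriptive tables, which is why the beat-wise definition is
  used.
* The RR triangular index uses a fixed histogram bin width of
  1/128 s = 7.8125 ms anchored at 0 ms (the discrete-histogram
  convention of standard HRV software), so it is well defined without a
  free binning choice.
* Spectral chain: cubic-spline resampling of RR(t) at 4 Hz →
  smoothness-priors detrending (second-difference penalty weight
  λ = 500, the standard short-term setting; the smoother's cutoff at
  4 Hz is ≈ 0.035 Hz, so it removes VLF trend while attenuating a
  0.25 Hz oscillation by < 5% in amplitude) → Welch PSD with a 128-s
  Hann window and 50% overlap (a single full-length window when the
  segment is shorter) → trapezoidal band integrals over VLF
  [0.003, 0.04), LF [0.04, 0.15), HF [0.15, 0.4) Hz.
* Normalized units use the LF+HF denominator, so LF n.u. + HF n.u. = 100
  exactly. (The alternative total−VLF denominator differs only by
  residual VLF leakage after detrending; `cv`-style flags were judged
  not worth the surface and the ms² band powers are always reported
  alongside.)
* Entropies: m = 2, r = 0.2·SDNN of the analyzed window. ApEn follows
  the original self-match-counting definition; SampEn excludes
  self-matches and uses N−m templates at both lengths m and m+1, so
  every length-m template has an extension. Natural logarithms. A
  constant window yields 0 for both by convention (any positive
  tolerance matches everything). SampEn raises when no pair matches at
  length m or m+1 — the tolerance is too small for the data and the
  statistic is undefined rather than infinite.
* DFA: integrate the mean-centered series, non-overlapping boxes with
  the leftover tail dropped, per-box least-squares lines, α as the OLS
  slope of log10 F(n) on log10 n over the integer grids 4–16 (α1) and
  16–64 (α2). Note that canonical DFA on *white* noise over the 4–16
  grid is biased upward (≈ 0.585 rather than 0.5 at N = 10⁴) by the
  small-box line fit; the physics tests use the conventional ±0.1 band
  around 0.5, which this bias stays inside.

## Reliability statistics

ICC(2,1) is computed from the two-way ANOVA decomposition
`(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`, with the exact
F-based two-sided 95% interval for the absolute-agreement single-measures
form. When MSE = 0 (perfect agreement) the interval degenerates to the
point estimate. With n = 2 subjects only the point estimate is returned
(CI flagged as NaN). The implementation is cross-checked in the tests
against an independent hand-ANOVA oracle and against `pingouin`'s ICC2
row.

SEM = SD·√(1 − ICC) with SD pooled over all n·k measurements — the
reading of "standard deviation of the means" that reproduces the
SEM-to-percentage relations in published reliability tables.
MDC₉₅ = 1.96·√2·SEM. (Reliability literature sometimes prints the
formula as "1.96 × SEM × 2"; the √2 form is the one consistent with the
SEM→MDC ratios actually tabulated, and is adopted.) Percentages are
relative to the grand mean of all cells. CV is the mean across subjects
of within-subject SD/mean × 100 (RMS aggregation available via an
argument). Bland–Altman: bias = mean of first-minus-second differences,
limits bias ± 1.96 × sample SD of the differences.

Interpretation bands assign the boundary values 0.40 and 0.75 to the
upper band and 0.90 to "substantial" (i.e. "excellent" requires
ICC > 0.90).

**Sample size.** Walter–Eliasziw–Donner: θ = ρ/(1−ρ),
C0 = (1+kθ0)/(1+kθ1), n0 = 1 + 2k(z₁₋α/₂+z₁₋β)²/((k−1)(ln C0)²), rounded
up and then inflated by 1/(1−loss) and rounded up again. Two-sided α —
the sidedness that reproduces the canonical worked example
(0.40 vs 0.75, α = 0.05, power 0.80, k = 2, 15% loss → 33 subjects).

## Synthetic data

`generate_rri` builds beats as
`RR = mean + a_LF·sin(2π·0.10·t) + a_HF·sin(2π·0.25·t + φ) + drift·t/60 + ε`,
ε iid Gaussian, φ drawn once per recording, ectopic events inserted as
0.6×/1.4× premature–compensatory pairs. Defaults (mean 800 ms, a_LF 30,
a_HF 25 ms, noise SD 10 ms, 600 s) give index values in the range of
resting adult cohorts (SDNN ≈ 29 ms, RMSSD ≈ 28 ms, SampEn ≈ 1.75).
Population draws for multi-subject studies use mean RR ~ N(808, 107) ms
clipped to 550–1200 ms, and uniform amplitude/noise ranges (LF 20–40 ms,
HF 15–35 ms, noise 5–15 ms) chosen once to produce realistic
between-subject dispersion. The sinusoid-plus-noise construction was
preferred over integral-pulse-frequency-modulation because its band
powers are analytic (a²/2), which the spectral pipeline is tested
against; it does not emulate respiratory frequency wander, circadian
nonstationarity, or realistic ectopy morphology, so passing tests say
nothing about those features of real data. DFA α2 of the generator is
low (the model has no long-range fractal structure); it is still
reliably *measured*, which is what the reliability pipeline tests need.

**Rater simulation.** Each analysis cell (subject × rater × occasion)
re-selects its segment within ± jitter beats of the canonical best
start, adding to each candidate's composite score a seeded Gaussian
perturbation with a rater-persistent component (SD 0.03) plus an
occasion component (SD 0.015). Intrarater (test–retest) pairs share the
rater component, interrater pairs do not, so interrater differences are
structurally at least as variable — the design emulates stable
individual selection habits plus occasion-level wobble, not a tuned
outcome. Jitter 0 forces identical selections (ICC = 1 end to end),
which the pipeline tests assert.

## Problem sizes and determinism

Default study simulations use 40 subjects × 4 cells of ~750-beat
recordings with jitter 16 — sizes at which every estimator is in its
intended regime while the full pipeline runs in seconds. Oracle
equivalence for the entropy/ICC kernels is checked at N ≤ 100 and
matrices ≤ 6×3 where the O(N²)/hand computations are exact; estimator
physics (DFA ≈ 0.5/1.5, Parseval) at N = 10⁴ with fixed seeds; CI
coverage with 200 replicates at n = 69. All stochastic steps take
explicit integer seeds; identical seeds reproduce results bit for bit.

## Known limitations

* The selection score is one defensible operationalization of visual
  criteria; real raters may weight artifacts and stationarity
  differently, and the "equidistance" criterion has no standard
  definition.
* ICC confidence intervals assume the two-way normal random-effects
  model; heavy-tailed index distributions (LF/HF ms²) will reduce
  coverage somewhat.
* SampEn is undefined (raises) for very small tolerances; callers who
  need a total function should catch the error and report NaN.
* The generator's ectopy is a single ventricular-type signature; atrial
  ectopy and missed-beat artifacts are not modelled.
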