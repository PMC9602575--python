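import numpy as np
import pytest
from scipy import stats

from hrvrel.preprocessing import (
    apply_discard_rule,
    candidate_starts,
    detect_ectopic,
    ectopic_fraction,
    score_window,
    select_best_segment,
)
from hrvrel.series import BeatLabel, RRiSeries


def constant_series(n=100, value=800.0):
    return RRiSeries(np.full(n, value))


class TestDetectEctopic:
    def test_constant_series_has_no_ectopics(self):
        labeled = detect_ectopic(constant_series())
        assert not np.any(labeled.beat_labels == "ectopic")

    def test_single_premature_beat_is_flagged(self):
        rri = np.full(100, 800.0)
        rri[50] = 500.0  # |500-800|/800 = 0.375 > 0.20
        labeled = detect_ectopic(RRiSeries(rri))
        assert list(np.flatnonzero(labeled.beat_labels == "ectopic")) == [50]

    def test_modulated_series_within_threshold_untouched(self):
        t = np.arange(600) * 0.8
        rri = 800.0 + 40.0 * np.sin(2 * np.pi * 0.1 * t)  # max 5% deviation
        labeled = detect_ectopic(RRiSeries(rri))
        assert not np.any(labeled.beat_labels == "ectopic")

    def test_idempotent(self):
        rri = np.full(100, 800.0)
        rri[30] = 1100.0
        once = detect_ectopic(RRiSeries(rri))
        twice = detect_ectopic(once)
        assert np.array_equal(once.beat_labels, twice.beat_labels)

    def test_flagged_beat_excluded_from_running_median(self):
        # the beat after an ectopic is judged against the sinus history
        rri = np.full(100, 800.0)
        rri[50] = 500.0
        labeled = detect_ectopic(RRiSeries(rri))
        assert labeled.beat_labels[51] == "normal"

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            detect_ectopic(constant_series(n=5), local_window=11)


class TestDiscardRule:
    def _with_ectopics(self, n_ect, n_norm):
        labels = np.array(
            ["ectopic"] * n_ect + ["normal"] * n_norm, dtype=object
        )
        return RRiSeries(np.full(n_ect + n_norm, 800.0), labels)

    def test_fraction_is_ectopic_over_normal(self):
        assert ectopic_fraction(self._with_ectopics(0, 256)) == 0.0
        assert ectopic_fraction(self._with_ectopics(10, 90)) == pytest.approx(10 / 90)

    def test_all_ectopic_is_an_error(self):
        with pytest.raises(ValueError, match="no normal beats"):
            ectopic_fraction(self._with_ectopics(5, 0))

    def test_accept_reject_and_strict_boundary(self):
        assert apply_discard_rule(self._with_ectopics(5, 100)).accept  # 0.05
        assert not apply_discard_rule(self._with_ectopics(10, 90)).accept  # 0.111
        assert apply_discard_rule(self._with_ectopics(10, 100)).accept  # exactly 0.10

    def test_decision_carries_fraction(self):
        d = apply_discard_rule(self._with_ectopics(10, 90))
        assert d.fraction == pytest.approx(10 / 90)


def literal_composite(window, weights=(0.4, 0.4, 0.2)):
    """Independent re-statement of the three-criterion score."""
    window = np.asarray(window, float)
    mu, sd = window.mean(), window.std(ddof=1)
    outlier = np.mean(np.abs(window - mu) > 3 * sd) if sd > 0 else 0.0
    half = len(window) // 2
    if sd > 0:
        stat = max(0.0, 1 - abs(window[:half].mean() - window[half:].mean()) / sd)
        norm = min(1.0, stats.shapiro(window).pvalue)
    else:
        stat, norm = 1.0, 1.0
    return weights[0] * (1 - outlier) + weights[1] * stat + weights[2] * norm


class TestSelectBestSegment:
    def test_exact_length_series_is_forced_to_start_zero(self):
        sel = select_best_segment(constant_series(n=256))
        assert sel.start_index == 0
        assert np.array_equal(sel.window, np.full(256, 800.0))

    def test_window_matches_parent_slice(self, stationary_series):
        sel = select_best_segment(stationary_series)
        s = sel.start_index
        assert np.array_equal(
            sel.window, stationary_series.intervals[s : s + 256]
        )

    def test_outlier_window_scores_lower(self, rng):
        rri = rng.normal(800.0, 30.0, 600)
        rri[500] = 1500.0
        series = RRiSeries(rri)
        sel = select_best_segment(series)
        # selected composite beats every window containing the outlier
        for s in range(500 - 255, 501, 16):
            if 0 <= s <= 600 - 256:
                assert sel.quality["composite"] >= literal_composite(
                    rri[s : s + 256]
                )
        assert not (sel.start_index <= 500 < sel.start_index + 256)

    def test_drift_pushes_selection_to_flat_region(self, rng):
        drift = np.concatenate(
            [800 + np.linspace(0, 100, 300), np.full(300, 900.0)]
        ) + rng.normal(0, 5, 600)
        sel = select_best_segment(RRiSeries(drift), stride=16)
        assert sel.start_index >= 300 - 16

    def test_matches_exhaustive_oracle_at_stride_one(self, rng):
        rri = rng.normal(800.0, 25.0, 380)
        series = RRiSeries(rri)
        sel = select_best_segment(series, length=256, stride=1)
        scores = [
            literal_composite(rri[s : s + 256]) for s in range(380 - 256 + 1)
        ]
        assert sel.start_index == int(np.argmax(scores))
        assert sel.quality["composite"] == pytest.approx(max(scores), abs=1e-12)

    def test_translation_invariance(self, stationary_series):
        sel = select_best_segment(stationary_series)
        shifted = RRiSeries(stationary_series.intervals + 500.0)
        assert select_best_segment(shifted).start_index == sel.start_index

    def test_determinism(self, stationary_series):
        a = select_best_segment(stationary_series)
        b = select_best_segment(stationary_series)
        assert a.start_index == b.start_index and a.quality == b.quality

    def test_ectopic_windows_excluded(self):
        labels = np.full(600, "normal", dtype=object)
        labels[300] = "ectopic"
        series = RRiSeries(np.full(600, 800.0), labels)
        starts = candidate_starts(series, 256, 16)
        assert all(not (s <= 300 < s + 256) for s in starts)

    def test_no_clean_window_advises_discard(self):
        labels = np.full(300, "normal", dtype=object)
        labels[::20] = "ectopic"  # every 20th beat: no clean 256-run
        series = RRiSeries(np.full(300, 800.0), labels)
        with pytest.raises(ValueError, match="discard"):
            select_best_segment(series)

    def test_constant_window_scores_perfect(self):
        q = score_window(np.full(256, 800.0))
        assert q["composite"] == pytest.approx(1.0)
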