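import math

import numpy as np
import pandas as pd
import pytest

from hrvrel.reliability import (
    MDC_FACTOR,
    RatingsMatrix,
    bland_altman,
    classify_icc,
    cv_percent,
    icc_2_1,
    mdc,
    percent_of_mean,
    reliability_report,
    sample_size_icc,
    sem,
)
from hrvrel.synthetic import ReliabilityGenParams, generate_reliability_study


def icc_2_1_oracle(values):
    """Hand ANOVA: explicit sums of squares, then the ICC(2,1) formula."""
    values = np.asarray(values, float)
    n, k = values.shape
    grand = values.mean()
    ssr = sum(k * (values[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (values[:, j].mean() - grand) ** 2 for j in range(k))
    sst = sum((v - grand) ** 2 for v in values.ravel())
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_perfect_agreement(self):
        icc, ci = icc_2_1(RatingsMatrix([[1, 1], [2, 2], [3, 3]]))
        assert icc == 1.0

    def test_constant_offset_penalized(self):
        m = RatingsMatrix([[1, 2], [2, 3], [3, 4]])
        icc, _ = icc_2_1(m)
        assert icc == pytest.approx(icc_2_1_oracle(m.values), abs=1e-12)
        assert icc == pytest.approx(2 / 3)

    def test_matches_hand_anova_on_random_matrices(self, rng):
        for n, k in [(3, 2), (4, 2), (5, 3), (6, 3)]:
            for _ in range(10):
                v = rng.normal(10, 3, size=(n, k))
                icc, _ = icc_2_1(RatingsMatrix(v))
                assert icc == pytest.approx(icc_2_1_oracle(v), abs=1e-10)

    def test_matches_pingouin_point_and_interval(self, rng):
        pingouin = pytest.importorskip("pingouin")
        v = rng.normal(50, 10, size=(20, 2)) + rng.normal(0, 4, size=(20, 1))
        icc, ci = icc_2_1(RatingsMatrix(v))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 2),
                "rater": np.tile([0, 1], 20),
                "score": v.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        row = ref.loc["ICC(A,1)"] if "ICC(A,1)" in ref.index else ref.loc["ICC2"]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        lo, hi = row[ci_col]  # pingouin rounds the interval to 2 decimals
        assert ci[0] == pytest.approx(lo, abs=6e-3)
        assert ci[1] == pytest.approx(hi, abs=6e-3)

    def test_parameter_recovery_from_variance_components(self):
        ratings = generate_reliability_study(
            ReliabilityGenParams(
                n_subjects=1000, sigma_between=3.0, sigma_error=1.0, seed=11
            )
        )
        icc, ci = icc_2_1(ratings)
        assert ratings.meta["true_icc"] == pytest.approx(0.9)
        assert abs(icc - 0.9) < 0.02
        assert ci[0] <= icc <= ci[1]

    def test_degenerate_ratings_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc_2_1(RatingsMatrix([[5.0, 5.0], [5.0, 5.0]]))

    def test_two_subjects_point_estimate_only(self):
        icc, ci = icc_2_1(RatingsMatrix([[1.0, 1.1], [2.0, 2.2]]))
        assert np.isfinite(icc)
        assert np.isnan(ci[0]) and np.isnan(ci[1])


class TestClassification:
    @pytest.mark.parametrize(
        "icc,label",
        [
            (0.920, "excellent"),
            (0.39, "low"),
            (0.40, "moderate"),
            (0.75, "substantial"),
            (0.90, "substantial"),
            (0.901, "excellent"),
            (-0.2, "low"),
        ],
    )
    def test_bands(self, icc, label):
        assert classify_icc(icc) == label


class TestErrorStatistics:
    @pytest.mark.parametrize(
        "sd,icc,expected", [(10, 1, 0), (10, 0.75, 5.0), (10, 0, 10.0)]
    )
    def test_sem(self, sd, icc, expected):
        assert sem(sd, icc) == pytest.approx(expected)

    def test_sem_rejects_icc_above_one(self):
        with pytest.raises(ValueError):
            sem(10, 1.1)

    def test_mdc_factor_is_196_root_2(self):
        assert mdc(1.0) == pytest.approx(1.96 * math.sqrt(2))
        assert mdc(0.0) == 0.0

    def test_percent_of_mean(self):
        m = RatingsMatrix([[46.51, 47.44], [46.51, 47.44]])
        assert percent_of_mean(4.24, m) == pytest.approx(9.03, abs=0.005)
        assert percent_of_mean(0.0, m) == 0.0
        assert percent_of_mean(46.975, m) == pytest.approx(100.0)

    def test_cv_single_and_scale_invariance(self):
        one = RatingsMatrix([[100.0, 110.0], [100.0, 110.0]])
        assert cv_percent(one) == pytest.approx(6.734, abs=0.005)
        two = RatingsMatrix([[100.0, 110.0], [200.0, 220.0]])
        assert cv_percent(two) == pytest.approx(6.734, abs=0.005)
        assert cv_percent(one, aggregate="rms") == pytest.approx(
            cv_percent(one), abs=1e-9
        )

    def test_cv_identical_pairs_is_zero(self):
        assert cv_percent(RatingsMatrix([[5.0, 5.0], [7.0, 7.0]])) == 0.0

    def test_bland_altman_identical_pairs(self):
        bias, sd, loa = bland_altman(RatingsMatrix([[5.0, 5.0], [7.0, 7.0]]))
        assert bias == 0.0 and sd == 0.0 and loa == (0.0, 0.0)

    def test_bland_altman_requires_two_measurements(self):
        with pytest.raises(ValueError):
            bland_altman(RatingsMatrix(np.ones((4, 3)) + np.arange(4)[:, None]))


class TestReportInvariants:
    def test_report_chain_and_shift_invariance(self, rng):
        v = rng.normal(50, 10, size=(30, 2))
        rep = reliability_report(RatingsMatrix(v, index_name="x"))
        assert rep.mdc / rep.sem == pytest.approx(MDC_FACTOR)
        assert rep.loa[0] + rep.loa[1] == pytest.approx(2 * rep.bias)
        assert rep.ci95[0] <= rep.icc <= rep.ci95[1]
        shifted = reliability_report(RatingsMatrix(v + 100.0))
        assert shifted.icc == pytest.approx(rep.icc, abs=1e-12)
        assert shifted.sem == pytest.approx(rep.sem, abs=1e-9)
        assert shifted.sd_diff == pytest.approx(rep.sd_diff, abs=1e-9)
        assert shifted.bias == pytest.approx(rep.bias, abs=1e-9)


class TestSampleSize:
    def test_study_planning_values(self):
        assert sample_size_icc(0.40, 0.75, 0.05, 0.80, 2, 0.15) == 33
        assert sample_size_icc(0.40, 0.75, 0.05, 0.80, 2, 0.0) == 28

    def test_monotone_in_gap_and_power(self):
        wide = sample_size_icc(0.40, 0.75, 0.05, 0.80, 2)
        narrow = sample_size_icc(0.40, 0.60, 0.05, 0.80, 2)
        assert narrow > wide
        low_power = sample_size_icc(0.40, 0.75, 0.05, 0.60, 2)
        assert low_power <= wide

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="detectable"):
            sample_size_icc(0.75, 0.40)
        with pytest.raises(ValueError):
            sample_size_icc(0.4, 0.75, k=1)
        with pytest.raises(ValueError):
            sample_size_icc(0.4, 0.75, loss_frac=1.0)
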