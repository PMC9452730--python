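import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rtnf.stats import (
    ClinicalRecord,
    Eligibility,
    SeverityBand,
    TestResult,
    clinical_deltas,
    day_means,
    format_test_line,
    learning_deltas,
    learning_slope,
    screen_eligibility,
    severity_band,
    wilcoxon_signed_rank_exact,
    ztest_one_sample,
)


def brute_force_wilcoxon_two_tailed(diffs):
    """Independent oracle: enumerate all 2^n sign assignments of the
    observed absolute ranks and count tail probabilities of W+."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    w_all = np.asarray(w_all)
    p_le = np.mean(w_all <= w_obs + 1e-9)
    p_ge = np.mean(w_all >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestExactWilcoxon:
    def test_seven_all_positive_differences(self):
        # the clinician-rated improvement configuration: every patient
        # improved, exact two-tailed p = 2 / 2^7
        d = [2, 4, 6, 7, 9, 12, 15]
        res = wilcoxon_signed_rank_exact(d)
        assert res.p_value == pytest.approx(2 / 128)
        assert round(res.p_value, 3) == 0.016
        assert res.method == "wilcoxon-signed-rank-exact"
        assert res.statistic == 28.0

    def test_six_positive_one_smallest_negative(self):
        # the self-report configuration: one patient slightly worse
        d = [-1, 5, 7, 8, 9, 12, 15]
        res = wilcoxon_signed_rank_exact(d)
        assert res.p_value == pytest.approx(4 / 128)
        assert round(res.p_value, 3) == 0.031

    def test_single_nonzero_difference_saturates(self):
        assert wilcoxon_signed_rank_exact([3.0]).p_value == 1.0

    def test_all_zero_rejected_with_message(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank_exact([0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="differences"):
            wilcoxon_signed_rank_exact([])

    def test_zeros_dropped_before_ranking(self):
        with_zeros = wilcoxon_signed_rank_exact([0, 2, 4, 6, 0, 7, 9, 12, 15, 0])
        without = wilcoxon_signed_rank_exact([2, 4, 6, 7, 9, 12, 15])
        assert with_zeros.p_value == without.p_value
        assert with_zeros.n == 7

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        d = np.round(rng.normal(0.5, 2.0, n), 1)
        d = d[d != 0]
        if d.size == 0:
            return
        ours = wilcoxon_signed_rank_exact(d).p_value
        assert ours == pytest.approx(brute_force_wilcoxon_two_tailed(d), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_exact_on_untied_data(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.normal(0.3, 1.0, 10)
        # scipy's exact method assumes no ties; continuous draws are untied
        ours = wilcoxon_signed_rank_exact(d).p_value
        theirs = sps.wilcoxon(d, method="exact").pvalue
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_one_tailed_directions(self):
        d = [1, 2, 3, 4, 5]
        up = wilcoxon_signed_rank_exact(d, "one-tailed-greater")
        down = wilcoxon_signed_rank_exact(d, "one-tailed-less")
        assert up.p_value == pytest.approx(1 / 32)
        assert down.p_value == 1.0


class TestZTest:
    def test_reproduces_printed_day4_result(self):
        # group day-4 accuracy summary versus the 50% chance level
        res = ztest_one_sample(mean=56.19, sd=6.07, n=7, null_value=50.0)
        assert res.statistic == pytest.approx(2.698, abs=0.001)
        assert res.p_value == pytest.approx(0.0035, abs=0.0002)

    def test_mean_equal_to_null(self, rng):
        res = ztest_one_sample(mean=50.0, sd=1.0, n=10, null_value=50.0)
        assert res.statistic == 0.0
        assert res.p_value == 0.5

    def test_one_tailed_symmetry(self):
        up = ztest_one_sample(mean=53.0, sd=4.0, n=9, null_value=50.0)
        down = ztest_one_sample(mean=47.0, sd=4.0, n=9, null_value=50.0)
        assert down.statistic == pytest.approx(-up.statistic)
        assert down.p_value == pytest.approx(1.0 - up.p_value)

    def test_matches_normal_tail_closed_form(self, rng):
        values = rng.normal(55, 5, 12)
        res = ztest_one_sample(values, null_value=50.0)
        z = (values.mean() - 50.0) / (values.std(ddof=1) / np.sqrt(12))
        assert res.p_value == pytest.approx(sps.norm.sf(z), abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ztest_one_sample(mean=50.0, sd=0.0, n=5)
        with pytest.raises(ValueError):
            ztest_one_sample(np.array([1.0]))


def accuracy_row(values):
    return pd.DataFrame([dict((f"run{i+1}", v) for i, v in enumerate(values))],
                        index=["p1"])


class TestLearning:
    def test_constant_row_gives_zero_deltas(self):
        table = accuracy_row([55.0] * 16)
        d = learning_deltas(table)
        assert (d.loc["p1"] == 0).all()

    def test_linearly_rising_row(self):
        # +1%/run: run16-run1 = 15; day4 mean - day1 mean = 12
        table = accuracy_row([40.0 + i for i in range(16)])
        d = learning_deltas(table)
        assert d.loc["p1", "run16_minus_run1"] == 15.0
        assert d.loc["p1", "last2_minus_first2"] == pytest.approx(14.0)
        assert d.loc["p1", "day4_minus_day1"] == pytest.approx(12.0)

    def test_missing_runs_rejected(self):
        table = accuracy_row([50.0] * 16).drop(columns=["run7"])
        with pytest.raises(ValueError, match="run7"):
            learning_deltas(table)

    def test_day_means_recompute_from_runs(self, rng):
        vals = rng.uniform(30, 70, 16)
        table = accuracy_row(list(vals))
        days = day_means(table)
        for d in range(4):
            assert days.loc["p1", f"day{d+1}"] == pytest.approx(
                vals[4 * d: 4 * d + 4].mean())

    def test_slope_constant_series_is_zero(self):
        assert learning_slope([50.0] * 8) == pytest.approx(0.0)

    def test_slope_two_sessions(self):
        # day means 40 and 50 -> +10 per session
        acc = [40.0] * 4 + [50.0] * 4
        assert learning_slope(acc, unit="session") == pytest.approx(10.0)

    def test_slope_needs_two_points(self):
        with pytest.raises(ValueError):
            learning_slope([50.0], unit="run")
        with pytest.raises(ValueError, match="unknown unit"):
            learning_slope([1, 2], unit="week")

    def test_delta_antisymmetry(self, rng):
        vals = list(rng.uniform(30, 70, 16))
        fwd = learning_deltas(accuracy_row(vals))
        rev = learning_deltas(accuracy_row(vals[::-1]))
        assert fwd.loc["p1", "run16_minus_run1"] == pytest.approx(
            -rev.loc["p1", "run16_minus_run1"])
        assert fwd.loc["p1", "day4_minus_day1"] == pytest.approx(
            -rev.loc["p1", "day4_minus_day1"])


class TestClinical:
    def cohort(self):
        # 7 patients, all improving on the clinician scale from before
        # training (CE1) to after (CE2), stable at follow-up (CE3)
        records = []
        hdrs_improve = [2, 4, 6, 7, 9, 12, 15]
        for i, imp in enumerate(hdrs_improve):
            ce1 = 16 + (i % 3)
            records.append(ClinicalRecord(
                participant=f"p{i+1}",
                bdi=(18, 10, 10),
                hdrs=(ce1, ce1 - imp, ce1 - imp),
            ))
        return records

    def test_all_positive_hdrs_improvements(self):
        deltas, tests = clinical_deltas(self.cohort())
        assert (deltas["hdrs_ce2_ce1"] > 0).all()
        assert tests["hdrs_ce2_ce1"].p_value == pytest.approx(2 / 128)

    def test_identical_followup_yields_no_test(self):
        deltas, tests = clinical_deltas(self.cohort())
        assert (deltas["hdrs_ce3_ce2"] == 0).all()
        assert tests["hdrs_ce3_ce2"] is None

    def test_positive_delta_means_score_decrease(self):
        rec = ClinicalRecord("p", bdi=(20, 12, 11), hdrs=(15, 8, 9))
        deltas, _ = clinical_deltas([rec])
        assert deltas.loc["p", "bdi_ce2_ce1"] == 8
        assert deltas.loc["p", "bdi_ce3_ce1"] == 9
        assert deltas.loc["p", "hdrs_ce3_ce2"] == -1

    def test_single_record_skips_group_test(self):
        rec = ClinicalRecord("p", bdi=(20, 12, 11), hdrs=(15, 8, 9))
        deltas, tests = clinical_deltas([rec])
        assert tests["bdi_ce2_ce1"] is None

    def test_missing_timepoint_excluded_with_warning(self):
        records = self.cohort()
        records[0] = ClinicalRecord("p1", bdi=(18, None, 10), hdrs=(16, 9, 9))
        with pytest.warns(UserWarning, match="missing"):
            deltas, _ = clinical_deltas(records)
        assert np.isnan(deltas.loc["p1", "bdi_ce2_ce1"])
        assert deltas.loc["p1", "hdrs_ce2_ce1"] == 7

    def test_instrument_range_validation(self):
        with pytest.raises(ValueError, match="BDI-II"):
            ClinicalRecord("p", bdi=(70, 10, 10), hdrs=(10, 10, 10))


class TestScreening:
    @pytest.mark.parametrize(
        "bdi, suicide, okasha, expected",
        [
            (18, 0, 1, Eligibility.ELIGIBLE),
            (10, 0, 0, Eligibility.ELIGIBLE),
            (29, 1, 4, Eligibility.ELIGIBLE),
            (30, 0, 0, Eligibility.EXCLUDED_SEVERITY),
            (9, 0, 0, Eligibility.EXCLUDED_SEVERITY),
            (15, 2, 0, Eligibility.EXCLUDED_RISK),
            (15, 0, 5, Eligibility.EXCLUDED_RISK),
            (35, 3, 6, Eligibility.EXCLUDED_RISK),  # risk precedes severity
        ],
    )
    def test_screen_decisions(self, bdi, suicide, okasha, expected):
        assert screen_eligibility(bdi, suicide, okasha) == expected

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            screen_eligibility(64, 0, 0)
        with pytest.raises(ValueError):
            screen_eligibility(20, 4, 0)
        with pytest.raises(ValueError):
            screen_eligibility(20, 0, 13)

    @pytest.mark.parametrize(
        "score, band",
        [
            (0, SeverityBand.NONE),
            (9, SeverityBand.NONE),
            (10, SeverityBand.MILD),
            (19, SeverityBand.MILD),
            (20, SeverityBand.MODERATE),
            (29, SeverityBand.MODERATE),
            (30, SeverityBand.SEVERE),
            (63, SeverityBand.SEVERE),
        ],
    )
    def test_severity_bands(self, score, band):
        assert severity_band(score) == band


class TestReporting:
    def test_result_validates_p_range(self):
        with pytest.raises(ValueError):
            TestResult(1.0, 1.5, "two-tailed", 5, "x")

    def test_format_line_flags_unanimous_sign(self):
        d = np.array([2, 4, 6, 7, 9, 12, 15], float)
        res = wilcoxon_signed_rank_exact(d)
        line = format_test_line("HDRS CE2-CE1", d, res)
        assert "Median = 7" in line
        assert "0.0156" in line
        assert "share one sign" in line
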