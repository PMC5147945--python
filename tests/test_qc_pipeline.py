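"""QC decision rules: concentration choice, stability, attribution, verdicts."""

import numpy as np
import pytest

from conjuqc import (
    ChannelStats,
    ConfigurationError,
    QCConfig,
    SeriesError,
    attribute_decline,
    build_stability_series,
    compare_cv,
    compare_groups,
    optimize_concentration,
    rank_stability,
    stain_integrity_check,
)
from conjuqc.mesf import ABOVE_RANGE, IN_RANGE, DriftReport, MESFValue

import pandas as pd


def stats_of(gm, cv=20.0, n=3000):
    return ChannelStats(channel="FL2", n=n, geo_mean=gm, arith_mean=gm * 1.05,
                        sd=gm * cv / 100, cv_percent=cv, pct_positive=99.0)


def drift_report(months, flagged, tolerance=0.10):
    dev = pd.DataFrame(0.0, index=list(months), columns=["b1", "b2", "b3", "b4"])
    for m in flagged:
        dev.loc[m] = -0.2
    return DriftReport(deviations=dev, flagged=list(flagged), warnings={},
                       first_last_diff={}, tolerance=tolerance)


class TestCompareGroups:
    def test_identical_groups_t_test_p_one(self):
        res = compare_groups([[20, 21], [20, 21]], "t_test")
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_welch_t_hand_computed(self):
        # means 2 vs 12, each var 1, n 3: t = -10 / sqrt(2/3)
        res = compare_groups([[1, 2, 3], [11, 12, 13]], "t_test")
        assert res.statistic == pytest.approx(-12.247, abs=0.001)
        assert res.p_value < 0.001 and res.significant

    def test_anova_detects_separated_means(self):
        res = compare_groups([[1, 2, 3], [11, 12, 13], [21, 22, 23]], "anova")
        assert res.significant

    def test_zero_variance_identical_groups_undefined(self):
        res = compare_groups([[5, 5], [5, 5]], "t_test")
        assert "undefined_zero_variance" in res.flags
        assert not res.significant

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(2024)
        reject = 0
        reps = 1000
        for _ in range(reps):
            groups = [rng.normal(0, 1, 10) for _ in range(3)]
            if compare_groups(groups, "anova").significant:
                reject += 1
        assert 0.035 <= reject / reps <= 0.065

    def test_group_size_and_method_validation(self):
        with pytest.raises(ConfigurationError):
            compare_groups([[1, 2]], "t_test")
        with pytest.raises(ConfigurationError):
            compare_groups([[1], [2]], "t_test")
        with pytest.raises(ConfigurationError):
            compare_groups([[1, 2], [3, 4]], "median")


class TestOptimizeConcentration:
    def _panel(self, gms, cvs, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        return {
            lv: [stats_of(gm * (1 + jitter * rng.normal()),
                          cv * (1 + jitter * rng.normal()))
                 for _ in range(3)]
            for lv, gm, cv in zip([0.5, 1, 2.5, 5], gms, cvs)
        }

    def test_fi_up_cv_down_selects_highest(self):
        panel = self._panel([150, 300, 700, 1500], [60, 45, 30, 20], jitter=0.02)
        verdict = optimize_concentration(panel)
        assert verdict.verdict == "optimal"
        assert verdict.evidence["choice"] == 5
        assert verdict.p_values["anova_fi"] <= 0.05

    def test_identical_levels_no_preference_default_lowest(self):
        rng = np.random.default_rng(9)
        panel = {lv: [stats_of(500 * (1 + 0.02 * rng.normal()), 30) for _ in range(3)]
                 for lv in [0.5, 1, 2.5, 5]}
        verdict = optimize_concentration(panel)
        assert verdict.verdict == "no level preferred"
        assert verdict.evidence["choice"] == 0.5

    def test_fi_up_but_cv_up_flags_conflict(self):
        panel = self._panel([150, 300, 700, 1500], [20, 30, 45, 60], jitter=0.02)
        verdict = optimize_concentration(panel)
        assert verdict.verdict == "fi_cv_conflict"
        assert verdict.evidence["fi_choice"] == 5
        assert verdict.evidence["cv_choice"] == 0.5

    def test_dilution_series_with_flat_cv_decided_by_fi(self):
        # ordinal dilution levels; CVs similar across levels -> FI decides
        rng = np.random.default_rng(4)
        panel = {
            d: [stats_of(gm * (1 + 0.02 * rng.normal()),
                         30 * (1 + 0.02 * rng.normal())) for _ in range(3)]
            for d, gm in zip(["1:3000", "1:1000", "1:300"], [200, 600, 1800])
        }
        verdict = optimize_concentration(panel)
        assert verdict.verdict == "optimal"
        assert verdict.evidence["choice"] == "1:300"

    def test_single_level_rejected(self):
        with pytest.raises(ConfigurationError):
            optimize_concentration({5: [stats_of(100), stats_of(100)]})


class TestCompareCV:
    def test_clearly_lower_cv_at_high_concentration(self):
        verdict = compare_cv([30, 31, 32], [10, 11, 12])
        assert verdict.verdict == "more homogeneous at high concentration"
        assert verdict.p_values["t_test_cv"] <= 0.05

    def test_identical_groups_not_significant(self):
        verdict = compare_cv([20, 21], [20, 21])
        assert verdict.verdict == "not significantly different"

    def test_direction_reported_with_computed_p(self):
        verdict = compare_cv([25, 26, 27], [24, 25, 26])
        assert verdict.evidence["direction"] == "high_lower"
        assert 0 < verdict.p_values["t_test_cv"] <= 1

    def test_degenerate_zero_variance_indistinguishable(self):
        verdict = compare_cv([20, 20], [20, 20])
        assert verdict.verdict == "indistinguishable"


class TestBuildStabilitySeries:
    def test_printed_initial_final_pair(self):
        months = [0, 18]
        series = build_stability_series("A1", months,
                                        [stats_of(1633.3), stats_of(1143.3)])
        assert series.delta_fi == pytest.approx(490.0)
        assert series.pct_decrease == pytest.approx(30.0, abs=0.01)

    def test_identities_hold_exactly(self):
        months = [0, 6, 12]
        fis = [812.5, 700.0, 593.75]
        series = build_stability_series("X", months, [stats_of(f) for f in fis])
        assert series.delta_fi == fis[0] - fis[-1]
        assert series.pct_decrease == 100 * (fis[0] - fis[-1]) / fis[0]

    def test_constant_series_zero_delta(self):
        series = build_stability_series("X", [0, 9, 18], [stats_of(500)] * 3)
        assert series.delta_fi == 0.0
        assert series.pct_decrease == 0.0

    def test_drift_flagged_months_excluded_from_endpoints(self):
        months = list(range(8))
        fis = [1000, 990, 980, 970, 700, 690, 680, 670]  # dip from month 4 on
        report = drift_report(months, [4, 5, 6, 7])
        series = build_stability_series("X", months, [stats_of(f) for f in fis],
                                        drift_report=report)
        assert series.excluded_timepoints == [4, 5, 6, 7]
        # endpoints from non-flagged months only: 0 and 3
        assert series.delta_fi == pytest.approx(30.0)
        assert series.delta_fi_raw == pytest.approx(330.0)

    def test_raw_mode_keeps_full_span(self):
        months = [0, 1, 2]
        report = drift_report(months, [2])
        series = build_stability_series("X", months,
                                        [stats_of(f) for f in [100, 90, 60]],
                                        drift_report=report, exclude_drift=False)
        assert series.excluded_timepoints == []
        assert series.delta_fi == pytest.approx(40.0)

    def test_too_few_usable_timepoints_rejected(self):
        report = drift_report([0, 1], [1])
        with pytest.raises(SeriesError):
            build_stability_series("X", [0, 1], [stats_of(1), stats_of(2)],
                                   drift_report=report)


class TestRankStability:
    def _series(self, cid, delta, initial=1000.0, flag=IN_RANGE):
        mesf = [MESFValue(cid, 1e5, flag), MESFValue(cid, 9e4, flag)]
        return build_stability_series(
            cid, [0, 18], [stats_of(initial), stats_of(initial - delta)], mesf)

    def test_ascending_delta_fi_ordering(self):
        verdict = rank_stability([self._series("A1", 490.0),
                                  self._series("A2", 988.0),
                                  self._series("A3", 718.0)])
        assert verdict.evidence["stability_order"] == ["A1", "A3", "A2"]
        assert verdict.verdict == "most stable: A1"

    def test_brightness_and_stability_rank_independently(self):
        bright_unstable = self._series("B2", 900.0, initial=4564.0)
        dim_stable = self._series("A1", 100.0, initial=1656.0)
        verdict = rank_stability([bright_unstable, dim_stable])
        assert verdict.evidence["brightness_order"] == ["B2", "A1"]
        assert verdict.evidence["stability_order"] == ["A1", "B2"]

    def test_equal_deltas_reported_as_tie(self):
        verdict = rank_stability([self._series("X", 100.0), self._series("Y", 100.0)])
        assert verdict.verdict == "tie"

    def test_above_range_series_tagged_fi_only(self):
        verdict = rank_stability([self._series("B2", 300.0, flag=ABOVE_RANGE),
                                  self._series("A1", 100.0)])
        assert verdict.evidence["fi_only"] == ["B2"]

    def test_mismatched_spans_warn_but_rank(self):
        a = self._series("A", 100.0)
        b = build_stability_series("B", [4, 18],
                                   [stats_of(1000), stats_of(800)])
        verdict = rank_stability([a, b])
        assert verdict.evidence["warnings"]
        assert verdict.evidence["stability_order"] == ["A", "B"]


class TestAttributeDecline:
    def test_monotone_decline_with_flat_standards(self):
        months = list(range(5))
        fis = [1000, 900, 800, 700, 500]
        report = drift_report(months, [])
        series = build_stability_series("X", months, [stats_of(f) for f in fis],
                                        drift_report=report)
        verdict = attribute_decline(series, report)
        assert verdict.verdict == "true conjugate decrease"
        assert verdict.evidence["per_timepoint"][4] == "conjugate"

    def test_shared_dip_recovery_is_instrument_only(self):
        months = list(range(10))
        fis = [1000] * 4 + [800, 800, 800] + [1000] * 3
        report = drift_report(months, [4, 5, 6])
        series = build_stability_series("X", months, [stats_of(f) for f in fis],
                                        drift_report=report)
        verdict = attribute_decline(series, report)
        assert verdict.verdict == "no true decrease"
        assert all(verdict.evidence["per_timepoint"][m] == "instrument"
                   for m in (4, 5, 6))

    def test_decline_plus_midseries_dip_composite(self):
        months = list(range(8))
        fis = [1000, 980, 960, 940, 700, 690, 680, 500]
        report = drift_report(months, [4, 5, 6])
        series = build_stability_series("X", months, [stats_of(f) for f in fis],
                                        drift_report=report)
        verdict = attribute_decline(series, report)
        assert verdict.verdict == "true conjugate decrease"
        assert verdict.evidence["per_timepoint"][4] == "instrument"
        assert verdict.evidence["per_timepoint"][7] == "conjugate"

    def test_never_instrument_without_standards_flag(self):
        months = list(range(5))
        fis = [1000, 600, 500, 400, 300]
        report = drift_report(months, [])
        series = build_stability_series("X", months, [stats_of(f) for f in fis],
                                        drift_report=report)
        verdict = attribute_decline(series, report)
        assert "instrument" not in verdict.evidence["per_timepoint"].values()

    def test_no_overlapping_timepoints_rejected(self):
        report = drift_report([100, 101], [])
        series = build_stability_series("X", [0, 1],
                                        [stats_of(10), stats_of(9)])
        with pytest.raises(SeriesError):
            attribute_decline(series, report)


class TestStainIntegrity:
    @pytest.mark.parametrize("pe, fitc", [
        ((731, 56), (80, 71)),     # PE ret 7.7%, FITC ret 88.8%
        ((580, 45), (185, 166)),
        ((366, 35), (131, 118)),
        ((399, 37), (129, 101)),
    ])
    def test_pe_lost_fitc_retained_is_fading(self, pe, fitc):
        verdict = stain_integrity_check(pe, fitc)
        assert verdict.verdict == "fluorochrome fading"

    def test_both_lost_is_uncoupling(self):
        verdict = stain_integrity_check((400, 40), (100, 10))
        assert verdict.verdict == "uncoupling/degradation"

    def test_both_retained_is_stable(self):
        verdict = stain_integrity_check((400, 380), (100, 95))
        assert verdict.verdict == "stable"

    def test_retentions_reported_as_evidence(self):
        verdict = stain_integrity_check((731, 56), (80, 71))
        assert verdict.evidence["pe_retention"] == pytest.approx(56 / 731)
        assert verdict.evidence["fitc_retention"] == pytest.approx(71 / 80)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            stain_integrity_check((0, 1), (1, 1))


class TestQCConfig:
    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConfigurationError):
            QCConfig(alpha=1.5)

    def test_invalid_min_events_rejected(self):
        with pytest.raises(ConfigurationError):
            QCConfig(min_events=0)
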