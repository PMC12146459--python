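"""Censoring, discontinuation/switch/restart rules and period PDC."""

import datetime as dt

import pytest

from pdckit import (
    StudyWindow,
    analyze_participant_class,
    anniversary,
    categorize_pdc,
    detect_discontinuation,
    determine_censor_date,
    eligibility_for_pdc,
    exclude_restarts,
)

D = dt.date


def ords(*dates):
    return [D.fromisoformat(s).toordinal() for s in dates]


def days_from(start, step, count):
    t0 = D.fromisoformat(start).toordinal()
    return [t0 + step * k for k in range(count)]


class TestRestartExclusion:
    def test_records_after_first_long_gap_dropped(self):
        sup = ords("2013-01-01", "2013-02-01", "2013-03-01") + ords(
            "2014-09-01", "2014-10-01"
        )
        retained, dropped = exclude_restarts(sup)
        assert retained == sup[:3]
        assert dropped

    def test_no_long_gap_is_identity(self):
        sup = ords("2013-01-01", "2013-06-01", "2014-01-01")
        retained, dropped = exclude_restarts(sup)
        assert retained == sup and not dropped

    def test_gap_of_exactly_365_days_is_not_a_restart(self):
        sup = ords("2013-01-01", "2014-01-01")
        retained, dropped = exclude_restarts(sup)
        assert retained == sup and not dropped

    def test_restart_after_first_record_leaves_single_record(self):
        # months 0, 14, 15: only the first record survives
        sup = [0, 14 * 30 + 10, 15 * 30 + 10]
        retained, dropped = exclude_restarts(sup)
        assert retained == [0] and dropped


class TestEligibility:
    def test_single_record_is_flagged_and_ineligible(self):
        eligible, flag = eligibility_for_pdc([100])
        assert not eligible and flag

    def test_two_records_within_a_year_are_eligible(self):
        eligible, flag = eligibility_for_pdc([0, 180])
        assert eligible and not flag

    def test_second_record_beyond_a_year_is_a_restart_not_a_second_record(self):
        eligible, flag = eligibility_for_pdc([0, 396])
        assert not eligible and not flag


class TestDiscontinuationAndSwitch:
    def test_terminal_gap_without_other_class_is_discontinuation(self):
        events = detect_discontinuation([0, 100], [], horizon=100 + 400)
        assert events == [(100, "discontinued")]

    def test_gap_of_exactly_365_days_is_not_discontinuation(self):
        assert detect_discontinuation([0, 365], [], horizon=365 + 365) == []

    def test_other_class_record_after_last_supply_means_switch(self):
        events = detect_discontinuation([0, 100], [130], horizon=100 + 400)
        assert events == [(100, "switched")]

    def test_other_class_record_before_last_supply_is_not_a_switch(self):
        events = detect_discontinuation([0, 100], [50], horizon=100 + 400)
        assert events == [(100, "discontinued")]


class TestCensorDate:
    def test_persistent_user_censored_at_study_end(self):
        sup = days_from("2013-01-01", 37, 69)
        censor, event = determine_censor_date(sup, [], None, 37)
        assert (censor, event) == (D(2019, 12, 31), "study_end")

    def test_death_before_any_gap_censors_at_death(self):
        sup = days_from("2013-01-01", 37, 33)  # refills until shortly before death
        censor, event = determine_censor_date(sup, [], D(2016, 5, 1), 37)
        assert (censor, event) == (D(2016, 5, 1), "death")

    def test_switch_censors_at_last_supply_plus_scd(self):
        sup = ords("2014-06-01", "2014-12-01", "2015-03-01")
        other = ords("2015-04-01")
        censor, event = determine_censor_date(sup, other, None, 37)
        assert event == "switched"
        assert censor == D(2015, 3, 1) + dt.timedelta(days=37)

    def test_stop_shortly_before_death_is_death_not_discontinuation(self):
        # last supply 3 months before death: not alive over a >12-month gap
        sup = ords("2013-01-01", "2013-06-01")
        censor, event = determine_censor_date(sup, [], D(2013, 9, 1), 37)
        assert (censor, event) == (D(2013, 9, 1), "death")


class TestPeriods:
    def test_continuous_five_year_user_has_1826_analysis_days(self):
        sup = days_from("2013-01-05", 37, 69)
        res = analyze_participant_class("P", "metformin", sup, [], None, 37)
        assert [p["outcome"] for p in res.periods] == ["full"] * 5
        assert sum(p["analysis_days"] for p in res.periods) == 1826
        assert res.five_year is not None
        assert res.five_year["analysis_days"] == 1826
        assert res.five_year["pdc_5y"] == 1.0

    def test_death_mid_period_three_truncates_and_stops(self):
        sup = days_from("2013-01-20", 37, 25)
        res = analyze_participant_class(
            "P", "metformin", sup, [], D(2015, 6, 30), 37
        )
        outcomes = [p["outcome"] for p in res.periods]
        assert outcomes == ["full", "full", "died_or_study_end"]
        assert res.periods[2]["analysis_days"] == 162
        assert res.five_year is None

    def test_refills_at_twice_scd_give_half_pdc(self):
        sup = days_from("2013-01-01", 74, 35)
        res = analyze_participant_class("P", "metformin", sup, [], None, 37)
        for p in res.periods:
            assert p["pdc"] == pytest.approx(0.5, abs=0.02)
            assert not p["adherent"]

    def test_pdc_exactly_at_threshold_is_adherent(self):
        # 292 covered of 365 days = exactly 0.8; later supplies keep the
        # stream alive so period 1 is a full period
        t0 = D(2013, 1, 1).toordinal()
        sup = [t0 + k * 73 for k in range(4)] + [t0 + 430 + 73 * k for k in range(11)]
        res = analyze_participant_class("P", "metformin", sup, [], None, 73)
        p1 = res.periods[0]
        assert p1["covered_days"] == 292
        assert p1["pdc"] == pytest.approx(0.8)
        assert p1["adherent"]

    def test_period_after_censor_not_emitted(self):
        sup = ords("2013-01-10", "2013-02-16", "2013-03-25")
        res = analyze_participant_class("P", "metformin", sup, [], None, 37)
        assert len(res.periods) == 1
        assert res.periods[0]["outcome"] == "discontinued"

    def test_index_on_feb_29_anniversaries_map_to_mar_1(self):
        assert anniversary(D(2016, 2, 29), 1) == D(2017, 3, 1)
        assert anniversary(D(2016, 2, 29), 4) == D(2020, 2, 29)

    def test_all_pdc_within_unit_interval(self):
        sup = days_from("2013-01-01", 20, 60)  # early refills stockpile
        res = analyze_participant_class("P", "metformin", sup, [], None, 37)
        for p in res.periods:
            assert 0 <= p["pdc"] <= 1


class TestFiveYear:
    def test_censored_in_period_four_has_no_five_year_result(self):
        sup = days_from("2013-01-01", 37, 30)  # stops ~period 4
        res = analyze_participant_class("P", "metformin", sup, [], None, 37)
        assert res.five_year is None

    def test_alternating_good_and_poor_years(self):
        """Years at interval scd and 2*scd alternate; 5-year PDC is the
        covered-day weighted mean of the yearly PDCs."""
        t0 = D(2013, 1, 1).toordinal()
        sup = []
        for year in range(5):
            step = 37 if year % 2 == 0 else 74
            start = t0 + 365 * year
            sup.extend(range(start, t0 + 365 * (year + 1), step))
        sup.extend(range(t0 + 365 * 5, t0 + 365 * 5 + 200, 37))  # keep persistent
        res = analyze_participant_class("P", "metformin", sorted(sup), [], None, 37)
        assert res.five_year is not None
        per_period_covered = sum(p["covered_days"] for p in res.periods)
        assert res.five_year["covered_days"] == per_period_covered
        # design value: (3*365 + 2*5*37) / 1826 ~= 0.80
        assert res.five_year["pdc_5y"] == pytest.approx(1465 / 1826, abs=0.03)


@pytest.mark.parametrize(
    "pdc,expected",
    [
        (0.0, "strongly_nonadherent"),
        (0.49, "strongly_nonadherent"),
        (0.5, "nonadherent"),  # boundary closed on the left
        (0.79, "nonadherent"),
        (0.8, "adherent"),
        (1.0, "adherent"),
    ],
)
def test_adherence_categories_partition(pdc, expected):
    assert categorize_pdc(pdc) == expected
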