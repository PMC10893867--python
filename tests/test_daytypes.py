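"""Day typing, sleep-window detection and the validity rules."""

import datetime as dt

import numpy as np
import pytest

from vpabouts.daytypes import (
    DayRecord,
    DayType,
    SchoolCalendar,
    classify_day_type,
    detect_sleep_windows,
    validate_assessment,
    validate_awake,
    validate_day,
    validate_pe_class,
    validate_school_time,
    validate_segment,
)
from vpabouts.epochs import EPOCHS_PER_DAY, tod_epoch
from vpabouts.errors import ConfigError
from vpabouts.nonwear import detect_strict_nonwear
from vpabouts.simulate import generate_cohort

from .conftest import series_from_classes

MON = dt.date(2020, 1, 13)


def _calendar():
    dates = {MON + dt.timedelta(days=i) for i in range(8)}
    school = {d for d in dates if d.weekday() < 5}
    pe = {MON + dt.timedelta(days=1): (tod_epoch(9), tod_epoch(10))}
    return SchoolCalendar(dates=dates, school_days=school, pe_windows=pe)


def test_saturday_is_weekend():
    cal = _calendar()
    assert classify_day_type(MON + dt.timedelta(days=5), cal) is DayType.WEEKEND


def test_school_day_with_valid_pe():
    cal = _calendar()
    tue = MON + dt.timedelta(days=1)
    assert classify_day_type(tue, cal, pe_valid=True) is DayType.SCHOOL_WITH_PE


def test_invalid_pe_demotes_to_school_without_pe():
    cal = _calendar()
    tue = MON + dt.timedelta(days=1)
    assert classify_day_type(tue, cal, pe_valid=False) is DayType.SCHOOL_WITHOUT_PE


def test_absence_and_holiday_are_excluded_types():
    cal = _calendar()
    wed = MON + dt.timedelta(days=2)
    assert classify_day_type(wed, cal, absences={wed}) is DayType.ABSENCE
    cal.holidays.add(wed)
    assert classify_day_type(wed, cal) is DayType.HOLIDAY


def test_date_outside_calendar_is_a_config_error():
    with pytest.raises(ConfigError):
        classify_day_type(MON + dt.timedelta(days=30), _calendar())


def _day_series(wear=None):
    return series_from_classes(np.zeros(EPOCHS_PER_DAY, dtype=int), wear=wear)


def test_fully_worn_day_is_valid():
    assert validate_day(_day_series(), 0)


def test_under_20_recorded_hours_is_invalid():
    wear = np.ones(EPOCHS_PER_DAY, dtype=bool)
    wear[: int(4.1 * 720)] = False  # 19.9 h worn, non-wear before 8 AM mostly
    assert not validate_day(_day_series(wear=wear), 0)


def test_over_two_hours_nonwear_in_window_is_invalid():
    wear = np.ones(EPOCHS_PER_DAY, dtype=bool)
    wear[tod_epoch(10) : tod_epoch(12, 30)] = False  # 2.5 h inside 8-22, 21.5 h worn
    assert not validate_day(_day_series(wear=wear), 0)


def test_awake_and_segment_validity():
    wake, bed = tod_epoch(7, 30), tod_epoch(22)
    assert validate_awake(_day_series(), 0, wake, bed)
    assert validate_segment(_day_series(), 0, wake, bed, "before")
    wear = np.ones(EPOCHS_PER_DAY, dtype=bool)
    wear[tod_epoch(10) : tod_epoch(11, 1)] = False  # 61 min, all Before 2 PM
    s = _day_series(wear=wear)
    assert not validate_segment(s, 0, wake, bed, "before")
    assert validate_segment(s, 0, wake, bed, "after")
    wear2 = np.ones(EPOCHS_PER_DAY, dtype=bool)
    wear2[tod_epoch(9) : tod_epoch(11, 1)] = False  # 2 h 1 min awake non-wear
    assert not validate_awake(_day_series(wear=wear2), 0, wake, bed)


def test_school_time_requires_four_recorded_hours():
    wear = np.ones(EPOCHS_PER_DAY, dtype=bool)
    wear[tod_epoch(9) : tod_epoch(10, 30)] = False  # 3.5 h recorded in 9-14
    assert not validate_school_time(_day_series(wear=wear), 0)
    wear2 = np.ones(EPOCHS_PER_DAY, dtype=bool)
    wear2[tod_epoch(9) : tod_epoch(10, 10)] = False  # 70 min non-wear
    assert not validate_school_time(_day_series(wear=wear2), 0)
    assert validate_school_time(_day_series(), 0)


def test_pe_class_validity_branches():
    window = (tod_epoch(9), tod_epoch(10))
    cls = np.zeros(EPOCHS_PER_DAY, dtype=int)
    cls[tod_epoch(9) : tod_epoch(9, 10)] = 2  # 10 MVPA minutes
    assert validate_pe_class(series_from_classes(cls), 0, window)

    wear = np.ones(EPOCHS_PER_DAY, dtype=bool)
    wear[tod_epoch(9) : tod_epoch(9, 2)] = False  # 2 min non-wear
    assert not validate_pe_class(series_from_classes(cls, wear=wear), 0, window)

    # 45-min class: 2 MVPA min (< 3) but only 25 sedentary min -> valid
    window45 = (tod_epoch(9), tod_epoch(9, 45))
    cls45 = np.ones(EPOCHS_PER_DAY, dtype=int)  # LPA everywhere
    cls45[tod_epoch(9) : tod_epoch(9, 25)] = 0
    cls45[tod_epoch(9, 30) : tod_epoch(9, 32)] = 2
    assert validate_pe_class(series_from_classes(cls45), 0, window45)

    # 45-min class: 2 MVPA min and 31 sedentary min -> invalid
    cls45[tod_epoch(9) : tod_epoch(9, 31)] = 0
    assert not validate_pe_class(series_from_classes(cls45), 0, window45)


def _rec(day, day_type, valid=True, before=True, after=True):
    return DayRecord(
        day=day,
        date=MON + dt.timedelta(days=day),
        day_type=day_type,
        valid_day=valid,
        valid_before=before,
        valid_after=after,
    )


def test_assessment_valid_with_all_required_types():
    records = [
        _rec(0, DayType.SCHOOL_WITH_PE),
        _rec(1, DayType.SCHOOL_WITH_PE),
        _rec(2, DayType.SCHOOL_WITHOUT_PE),
        _rec(3, DayType.SCHOOL_WITHOUT_PE),
        _rec(5, DayType.WEEKEND),
    ]
    assert validate_assessment(records).valid


def test_assessment_requires_a_weekend_day():
    records = [
        _rec(0, DayType.SCHOOL_WITH_PE),
        _rec(1, DayType.SCHOOL_WITH_PE),
        _rec(2, DayType.SCHOOL_WITHOUT_PE),
        _rec(3, DayType.SCHOOL_WITHOUT_PE),
    ]
    out = validate_assessment(records)
    assert not out.valid
    assert "no valid weekend day" in out.reasons


def test_assessment_requires_segments_per_type():
    records = [
        _rec(0, DayType.SCHOOL_WITH_PE),
        _rec(1, DayType.SCHOOL_WITH_PE),
        _rec(2, DayType.SCHOOL_WITHOUT_PE),
        _rec(3, DayType.SCHOOL_WITHOUT_PE),
        _rec(5, DayType.WEEKEND, before=False),
    ]
    out = validate_assessment(records)
    assert not out.valid
    assert any("Before segment on weekend" in r for r in out.reasons)


def test_sleep_windows_recovered_within_ten_minutes():
    """On synthetic days the angle-SD heuristic finds wake/bed to +-10 min."""
    subjects = generate_cohort(8, seed=5)
    total = within = 0
    for s in subjects:
        series = s.series
        series.ensure_classes()
        series.wear, _ = detect_strict_nonwear(series)
        detected = detect_sleep_windows(series)
        for d, day in enumerate(s.plan.days):
            wake, bed, _ = detected[d]
            total += 2
            within += abs(wake - day.wake) <= 120  # 120 epochs = 10 min
            within += abs(bed - day.bed) <= 120
    assert within / total >= 0.95


def test_sleep_log_overrides_detection():
    cls = np.zeros(2 * EPOCHS_PER_DAY, dtype=int)
    series = series_from_classes(cls)
    log = {series.date_of_day(0): (tod_epoch(7), tod_epoch(21, 30))}
    with pytest.warns(UserWarning):
        windows = detect_sleep_windows(series, sleep_log=log)
    assert windows[0] == (tod_epoch(7), tod_epoch(21, 30), False)


def test_sleep_fallback_when_no_quiet_run():
    # constantly moving, never sedentary-quiet: detection must fall back
    cls = np.full(EPOCHS_PER_DAY, 2, dtype=int)
    series = series_from_classes(cls)
    with pytest.warns(UserWarning, match="fallback"):
        windows = detect_sleep_windows(series)
    assert windows[0][2] is True
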