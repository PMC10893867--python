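"""Weekday-slot averaging, weighting, compliance and group statistics."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpabouts.daytypes import DayRecord, DayType
from vpabouts.summarize import (
    WeekdaySlot,
    average_duplicate_weekdays,
    compare_groups,
    compliance_flag,
    compliance_table,
    osa_group,
    osa_minutes_per_day,
    percent_days_with_bout,
    weekly_weighted_mean,
)

MON = dt.date(2020, 1, 13)


def _rec(day, weekday, day_type, has_bout=False, vpa=0.0, valid=True):
    r = DayRecord(
        day=day,
        date=MON + dt.timedelta(days=(weekday - MON.weekday()) % 7 + 7 * (day // 7)),
        day_type=day_type,
        valid_day=valid,
        valid_before=valid,
        valid_after=valid,
    )
    r.has_bout = has_bout
    r.before_bout = has_bout
    r.after_bout = False
    r.minutes = {k: vpa for k in ("SEDENTARY", "LPA", "MPA", "VPA", "MVPA", "LMVPA")}
    return r


def _slot(weekday, day_type, prop):
    return WeekdaySlot(
        weekday=weekday,
        day_type=day_type,
        n_days=1,
        bout_prop=prop,
        before_prop=prop,
        after_prop=prop,
        minutes={},
        bout_min=0.0,
        out_of_school_bout_min=0.0,
        vpa_in_bouts_min=0.0,
    )


def test_single_day_slot_passes_through():
    recs = [_rec(0, 0, DayType.SCHOOL_WITHOUT_PE, has_bout=True, vpa=10.0)]
    slots = average_duplicate_weekdays(recs)
    assert len(slots) == 1
    assert slots[0].bout_prop == 1.0
    assert slots[0].minutes["VPA"] == 10.0


def test_duplicate_weekdays_average_to_fractions():
    recs = [
        _rec(0, 0, DayType.SCHOOL_WITHOUT_PE, has_bout=True, vpa=10.0),
        _rec(7, 0, DayType.SCHOOL_WITHOUT_PE, has_bout=False, vpa=20.0),
    ]
    slots = average_duplicate_weekdays(recs)
    assert len(slots) == 1
    assert slots[0].bout_prop == 0.5
    assert slots[0].minutes["VPA"] == 15.0


def test_invalid_days_never_enter_slots():
    recs = [
        _rec(0, 0, DayType.SCHOOL_WITHOUT_PE, has_bout=True, valid=False),
        _rec(1, 1, DayType.SCHOOL_WITHOUT_PE),
    ]
    slots = average_duplicate_weekdays(recs)
    assert [s.weekday for s in slots] == [1]


@pytest.mark.parametrize(
    "school, weekend, expected",
    [
        (28.0, 13.4, 23.8),   # printed all-participants weekly mean
        (34.5, 18.2, 29.9),   # boys
        (21.9, 8.9, 18.2),    # girls
        (10.0, 10.0, 10.0),   # identity when both equal
    ],
)
def test_weekly_weighted_mean_five_sevenths_two_sevenths(school, weekend, expected):
    assert weekly_weighted_mean(school, weekend) == pytest.approx(expected, abs=0.1)


def test_weekly_weighted_mean_propagates_undefined():
    assert weekly_weighted_mean(None, 5.0) is None


@given(
    st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)
)
@settings(deadline=None, max_examples=100)
def test_weekly_mean_lies_between_school_and_weekend(school, weekend):
    w = weekly_weighted_mean(school, weekend)
    assert min(school, weekend) - 1e-9 <= w <= max(school, weekend) + 1e-9


def test_percent_days_with_bout_examples():
    pe = [_slot(1, DayType.SCHOOL_WITH_PE, 1.0), _slot(3, DayType.SCHOOL_WITH_PE, 1.0)]
    assert percent_days_with_bout(pe, (DayType.SCHOOL_WITH_PE,)) == 100.0
    mixed = [
        _slot(0, DayType.SCHOOL_WITHOUT_PE, 1.0),
        _slot(2, DayType.SCHOOL_WITHOUT_PE, 0.0),
        _slot(4, DayType.SCHOOL_WITHOUT_PE, 0.0),
    ]
    assert percent_days_with_bout(mixed, (DayType.SCHOOL_WITHOUT_PE,)) == pytest.approx(
        33.3, abs=0.05
    )
    frac = [
        _slot(0, DayType.WEEKEND, 1.0),
        _slot(6, DayType.WEEKEND, 0.5),
    ]
    assert percent_days_with_bout(frac, (DayType.WEEKEND,)) == 75.0
    assert percent_days_with_bout([], (DayType.WEEKEND,)) is None


def test_compliance_boundary_three_of_seven():
    slots = [
        _slot(w, DayType.SCHOOL_WITHOUT_PE if w < 5 else DayType.WEEKEND, 1.0 if w < 3 else 0.0)
        for w in range(7)
    ]
    assert compliance_flag(slots)  # 3/7 >= 3/7


def test_compliance_below_and_above_threshold_with_four_slots():
    def slots(k):
        return [
            _slot(w, DayType.SCHOOL_WITHOUT_PE, 1.0 if w < k else 0.0) for w in range(4)
        ]

    assert not compliance_flag(slots(1))  # 0.25 < 3/7
    assert compliance_flag(slots(2))      # 0.50 >= 3/7


def test_compliance_requires_valid_slots():
    with pytest.raises(ValueError, match="excluded"):
        compliance_flag([])


def test_adding_a_bout_day_never_flips_compliance_off():
    rng = np.random.default_rng(2)
    for _ in range(50):
        props = rng.random(7).round(1)
        slots = [_slot(w, DayType.SCHOOL_WITHOUT_PE, p) for w, p in enumerate(props)]
        if compliance_flag(slots):
            j = int(rng.integers(0, 7))
            raised = props.copy()
            raised[j] = 1.0
            assert compliance_flag(
                [_slot(w, DayType.SCHOOL_WITHOUT_PE, p) for w, p in enumerate(raised)]
            )


@pytest.mark.parametrize(
    "hours, expected",
    [(0, ("0", "<3")), (2, ("1-2", "<3")), (3, (">=3", ">=3")), (11, (">=3", ">=3"))],
)
def test_osa_grouping(hours, expected):
    assert osa_group(hours) == expected


def test_osa_grouping_rejects_out_of_range_and_skips_missing():
    with pytest.raises(ValueError):
        osa_group(12)
    assert osa_group(None) is None
    assert osa_group(float("nan")) is None


@pytest.mark.parametrize("hours, minutes", [(7, 60.0), (0, 0.0), (3.5, 30.0)])
def test_osa_minutes_per_day(hours, minutes):
    assert osa_minutes_per_day(hours) == pytest.approx(minutes)


def _compliance_df(counts):
    """counts: {group: (n, n_compliant)} -> subject-level frame."""
    rows = []
    for grp, (n, k) in counts.items():
        for i in range(n):
            rows.append({"group": grp, "compliant": i < k})
    return pd.DataFrame(rows)


def test_compliance_table_percentages():
    df = _compliance_df({"all": (353, 84)})
    out = compliance_table(df)
    assert out.loc[0, "pct_compliant"] == pytest.approx(23.8, abs=0.05)


def test_compliance_table_chi_square_on_sex_counts():
    df = _compliance_df({"boy": (170, 56), "girl": (183, 28)})
    out = compliance_table(df, "group")
    assert out["pct_compliant"].tolist() == pytest.approx([32.9, 15.3], abs=0.05)
    assert out["p"].iloc[0] < 0.001


def test_compliance_table_degenerate_groups_omit_p():
    df = _compliance_df({"a": (5, 5), "b": (5, 5)})
    out = compliance_table(df, "group")
    assert np.isnan(out["p"].iloc[0])


def test_compare_groups_identical_distributions_do_not_reject():
    rng = np.random.default_rng(4)
    x = rng.normal(10, 2, 40)
    values = np.concatenate([x, x])
    groups = np.array(["a"] * 40 + ["b"] * 40)
    _, _, p = compare_groups(values, groups)
    assert p > 0.9


def test_compare_groups_gates_on_normality():
    rng = np.random.default_rng(5)
    normal = np.concatenate([rng.normal(10, 2, 40), rng.normal(12, 2, 40)])
    skewed = np.concatenate([rng.exponential(1, 40), rng.exponential(3, 40)])
    groups = np.array(["a"] * 40 + ["b"] * 40)
    name_n, _, _ = compare_groups(normal, groups)
    name_s, _, _ = compare_groups(skewed, groups)
    assert name_n == "t-test"
    assert name_s == "mann-whitney"


def test_paired_shift_is_detected():
    rng = np.random.default_rng(6)
    before = rng.normal(28, 10, 50)
    after = before - rng.normal(26, 5, 50)
    name, _, p = compare_groups((before, after), paired=True)
    assert name == "wilcoxon"
    assert p < 0.05


def test_all_tied_paired_differences_omit_p():
    x = np.ones(10)
    name, _, p = compare_groups((x, x), paired=True)
    assert p is None


def test_chi_square_on_printed_style_2x2_counts():
    # 56/114 vs 28/155 compliant/non-compliant
    from scipy import stats

    p = stats.chi2_contingency([[56, 114], [28, 155]], correction=False).pvalue
    df = _compliance_df({"boy": (170, 56), "girl": (183, 28)})
    out = compliance_table(df, "group")
    assert out["p"].iloc[0] == pytest.approx(float(p))
    assert p < 0.001
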