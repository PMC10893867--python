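"""Day typing, sleep-window detection and validity rules.

Five day types are distinguished (school day with a valid PE class, school
day without, weekend, holiday, school absence) and two daily segments
(Before 2:00 PM = out of bed until 14:00; After 2:00 PM = 14:00 until bed).
Validity rules gate every downstream statistic:

* day: worn-and-recording >= 20 h in 00:00-24:00 AND non-wear accumulated
  between 8:00 AM and 10:00 PM <= 2 h;
* awake time: non-wear within wake-bed <= 2 h;
* each segment: non-wear <= 1 h;
* school time (9:00-14:00): recorded >= 4 h AND non-wear <= 1 h;
* PE class: non-wear < 1 min AND (MVPA >= 3 min OR sedentary <= 30 min);
* assessment: >= 4 valid weekly days including >= 1 school day with PE,
  >= 1 without, >= 1 weekend day, and >= 1 valid Before and After segment
  on every analyzed day type.

A scheduled PE class that fails its validity rule demotes the day to
"school day without PE"; the day itself can still be valid.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .epochs import (
    EPOCHS_PER_DAY,
    EPOCHS_PER_HOUR,
    EPOCHS_PER_MINUTE,
    EpochSeries,
    IntensityClass,
    tod_epoch,
)
from .errors import ConfigError
from .nonwear import nonwear_minutes

SCHOOL_START = tod_epoch(9)
SCHOOL_END = tod_epoch(14)
SEGMENT_SPLIT = tod_epoch(14)


class DayType(Enum):
    SCHOOL_WITH_PE = "school_with_PE"
    SCHOOL_WITHOUT_PE = "school_without_PE"
    WEEKEND = "weekend"
    HOLIDAY = "holiday"
    ABSENCE = "absence"


ANALYZED_TYPES = (DayType.SCHOOL_WITH_PE, DayType.SCHOOL_WITHOUT_PE, DayType.WEEKEND)


@dataclass
class SchoolCalendar:
    """Per-date school schedule: school flag, optional PE window, holiday flag.

    ``pe_windows`` maps date -> (start, end) epoch-of-day of the scheduled PE
    class. Dates not listed in ``dates`` are outside the calendar's coverage.
    """

    dates: set[dt.date]
    school_days: set[dt.date]
    pe_windows: dict[dt.date, tuple[int, int]]
    holidays: set[dt.date] = field(default_factory=set)

    @classmethod
    def from_csv(cls, path) -> "SchoolCalendar":
        df = pd.read_csv(path)
        dates, school, pe, hol = set(), set(), {}, set()
        for _, row in df.iterrows():
            d = pd.Timestamp(row["date"]).date()
            dates.add(d)
            if bool(row.get("is_holiday", False)):
                hol.add(d)
            if bool(row["is_school_day"]):
                school.add(d)
            if isinstance(row.get("pe_start"), str) and row["pe_start"]:
                s = _parse_clock(row["pe_start"])
                e = _parse_clock(row["pe_end"])
                pe[d] = (s, e)
        return cls(dates=dates, school_days=school, pe_windows=pe, holidays=hol)

    def to_csv(self, path) -> None:
        rows = []
        for d in sorted(self.dates):
            s, e = self.pe_windows.get(d, (None, None))
            rows.append(
                {
                    "date": d.isoformat(),
                    "is_school_day": int(d in self.school_days),
                    "pe_start": _format_clock(s) if s is not None else "",
                    "pe_end": _format_clock(e) if e is not None else "",
                    "is_holiday": int(d in self.holidays),
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)


def _parse_clock(text: str) -> int:
    h, m = str(text).split(":")[:2]
    return tod_epoch(int(h), int(m))


def _format_clock(epoch_of_day: int) -> str:
    seconds = epoch_of_day * 5
    return f"{seconds // 3600:02d}:{(seconds % 3600) // 60:02d}"


@dataclass
class DayRecord:
    """One calendar day of one subject, with validity flags and results."""

    day: int
    date: dt.date
    day_type: DayType
    wake: int | None = None      # epoch-of-day
    bed: int | None = None
    sleep_fallback: bool = False
    pe_window: tuple[int, int] | None = None
    pe_valid: bool | None = None
    valid_day: bool = False
    valid_awake: bool = False
    valid_before: bool = False
    valid_after: bool = False
    valid_school_time: bool | None = None
    minutes: dict[str, float] = field(default_factory=dict)
    bouts: list = field(default_factory=list)
    has_bout: bool = False
    before_bout: bool = False
    after_bout: bool = False
    bout_min: float = 0.0
    out_of_school_bout_min: float = 0.0

    @property
    def analyzable(self) -> bool:
        return self.day_type in ANALYZED_TYPES

    @property
    def is_school(self) -> bool:
        return self.day_type in (DayType.SCHOOL_WITH_PE, DayType.SCHOOL_WITHOUT_PE)


def classify_day_type(
    date: dt.date,
    calendar: SchoolCalendar,
    absences: set[dt.date] | None = None,
    pe_valid: bool = False,
) -> DayType:
    """Assign the day type; PE presence requires a *valid* PE class."""
    if date not in calendar.dates:
        raise ConfigError(f"date {date} outside the school calendar coverage")
    if date.weekday() >= 5:
        return DayType.WEEKEND
    if date in calendar.holidays or date not in calendar.school_days:
        return DayType.HOLIDAY
    if absences and date in absences:
        return DayType.ABSENCE
    if date in calendar.pe_windows and pe_valid:
        return DayType.SCHOOL_WITH_PE
    return DayType.SCHOOL_WITHOUT_PE


# --- sleep-window detection -------------------------------------------------

SLEEP_SD_WINDOW = 5 * EPOCHS_PER_MINUTE   # rolling 5-min window
SLEEP_SD_THRESHOLD = 5.0                  # degrees
SLEEP_SEARCH_START = tod_epoch(19)        # bed candidates start after 19:00
SLEEP_SEARCH_END = tod_epoch(2) + EPOCHS_PER_DAY   # ... until 02:00 next day
WAKE_CAP = tod_epoch(12)                  # wake must occur before noon
FALLBACK_BED = tod_epoch(23)
FALLBACK_WAKE = tod_epoch(7, 30)
MIN_SLEEP_RUN = 60 * EPOCHS_PER_MINUTE    # candidate runs must last >= 1 h


def _quiet_mask(series: EpochSeries) -> np.ndarray:
    """Epochs that look like sleep: calm tilt angle and sedentary intensity."""
    cls = series.ensure_classes()
    sd = (
        pd.Series(series.angle_z)
        .rolling(SLEEP_SD_WINDOW, min_periods=SLEEP_SD_WINDOW, center=True)
        .std()
        .to_numpy()
    )
    quiet = np.zeros(series.n, dtype=bool)
    ok = ~np.isnan(sd)
    quiet[ok] = sd[ok] < SLEEP_SD_THRESHOLD
    return quiet & (cls == IntensityClass.SEDENTARY)


def detect_sleep_windows(
    series: EpochSeries, sleep_log: dict[dt.date, tuple[int, int]] | None = None
) -> list[tuple[int, int, bool]]:
    """Per day: (wake, bed, fallback_used), all epoch-of-day indices.

    Bed is the start (clipped to >= 19:00) of the longest quiet sedentary run
    beginning in the evening; wake is where that run ends the next morning
    (capped at noon). A sleep-log entry for a date overrides detection. When
    no qualifying run exists the configured defaults are used with a warning.
    """
    quiet = _quiet_mask(series)
    runs = _mask_runs(quiet)
    n_days = series.n_days
    bed = [None] * n_days
    wake = [None] * n_days
    # wake on day 0: the run overlapping the start of the record
    for lo, hi in runs:
        if lo <= tod_epoch(4) and hi - lo >= MIN_SLEEP_RUN:
            wake[0] = min(hi, WAKE_CAP)
            break
    for d in range(n_days):
        base = d * EPOCHS_PER_DAY
        s0, s1 = base + SLEEP_SEARCH_START, base + SLEEP_SEARCH_END
        best, best_len = None, 0
        for lo, hi in runs:
            start = max(lo, base + SLEEP_SEARCH_START)
            if start < s0 or start >= s1:
                continue
            if hi - start < MIN_SLEEP_RUN:
                continue
            if hi - start > best_len:
                best, best_len = (start, hi), hi - start
        if best is not None:
            bed[d] = min(best[0] - base, EPOCHS_PER_DAY)
            if d + 1 < n_days:
                wake[d + 1] = min(max(best[1] - (d + 1) * EPOCHS_PER_DAY, 0), WAKE_CAP)
    out = []
    for d in range(n_days):
        w, b, fb = wake[d], bed[d], False
        date = series.date_of_day(d)
        if sleep_log and date in sleep_log:
            w, b = sleep_log[date]
        else:
            if w is None or b is None:
                warnings.warn(
                    f"day {d}: no qualifying sleep run, using fallback wake/bed",
                    stacklevel=2,
                )
                w = FALLBACK_WAKE if w is None else w
                b = FALLBACK_BED if b is None else b
                fb = True
        out.append((int(w), int(b), fb))
    return out


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    diff = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    return list(
        zip(np.flatnonzero(diff == 1).tolist(), np.flatnonzero(diff == -1).tolist())
    )


# --- validity rules ---------------------------------------------------------

DAY_MIN_RECORDED_H = 20.0
DAY_MAX_NONWEAR_H = 2.0
AWAKE_MAX_NONWEAR_H = 2.0
SEGMENT_MAX_NONWEAR_H = 1.0
SCHOOL_MIN_RECORDED_H = 4.0
SCHOOL_MAX_NONWEAR_H = 1.0
NONWEAR_WINDOW = (tod_epoch(8), tod_epoch(22))


def validate_day(series: EpochSeries, day: int) -> bool:
    lo, hi = series.day_bounds(day)
    worn_h = float(np.sum(series.wear[lo:hi])) / EPOCHS_PER_HOUR
    nw = nonwear_minutes(series, lo + NONWEAR_WINDOW[0], lo + NONWEAR_WINDOW[1]) / 60.0
    return worn_h >= DAY_MIN_RECORDED_H and nw <= DAY_MAX_NONWEAR_H


def validate_awake(series: EpochSeries, day: int, wake: int, bed: int) -> bool:
    base = day * EPOCHS_PER_DAY
    nw_h = nonwear_minutes(series, base + wake, base + bed) / 60.0
    return nw_h <= AWAKE_MAX_NONWEAR_H


def validate_segment(
    series: EpochSeries, day: int, wake: int, bed: int, which: str
) -> bool:
    base = day * EPOCHS_PER_DAY
    if which == "before":
        lo, hi = base + wake, base + min(SEGMENT_SPLIT, bed)
    elif which == "after":
        lo, hi = base + max(SEGMENT_SPLIT, wake), base + bed
    else:
        raise ValueError("which must be 'before' or 'after'")
    if hi <= lo:
        return False
    return nonwear_minutes(series, lo, hi) / 60.0 <= SEGMENT_MAX_NONWEAR_H


def validate_school_time(series: EpochSeries, day: int) -> bool:
    base = day * EPOCHS_PER_DAY
    lo, hi = base + SCHOOL_START, base + SCHOOL_END
    worn_h = float(np.sum(series.wear[lo:hi])) / EPOCHS_PER_HOUR
    nw_h = nonwear_minutes(series, lo, hi) / 60.0
    return worn_h >= SCHOOL_MIN_RECORDED_H and nw_h <= SCHOOL_MAX_NONWEAR_H


PE_MAX_NONWEAR_MIN = 1.0
PE_MIN_MVPA_MIN = 3.0
PE_MAX_SEDENTARY_MIN = 30.0


def validate_pe_class(
    series: EpochSeries, day: int, pe_window: tuple[int, int]
) -> bool:
    """PE class validity: data quality AND activity evidence.

    Non-wear < 1 min is a hard condition; the class then counts when it
    shows >= 3 MVPA minutes or stays within 30 sedentary minutes.
    """
    base = day * EPOCHS_PER_DAY
    lo, hi = base + pe_window[0], base + pe_window[1]
    if nonwear_minutes(series, lo, hi) >= PE_MAX_NONWEAR_MIN:
        return False
    cls = series.ensure_classes()[lo:hi]
    worn = series.wear[lo:hi]
    mvpa_min = float(np.sum(worn & (cls >= IntensityClass.MPA))) / EPOCHS_PER_MINUTE
    sed_min = float(np.sum(worn & (cls == IntensityClass.SEDENTARY))) / EPOCHS_PER_MINUTE
    return mvpa_min >= PE_MIN_MVPA_MIN or sed_min <= PE_MAX_SEDENTARY_MIN


@dataclass
class AssessmentValidity:
    valid: bool
    n_valid_days: int
    counts_by_type: dict[str, int]
    reasons: list[str]


def validate_assessment(records: list[DayRecord]) -> AssessmentValidity:
    """Subject-level gate: enough valid days of every analyzed type."""
    valid_days = [r for r in records if r.analyzable and r.valid_day]
    counts = {t.name: 0 for t in ANALYZED_TYPES}
    for r in valid_days:
        counts[r.day_type.name] += 1
    reasons = []
    if len(valid_days) < 4:
        reasons.append(f"only {len(valid_days)} valid weekly days (need 4)")
    labels = {
        DayType.SCHOOL_WITH_PE: "no valid school day with PE",
        DayType.SCHOOL_WITHOUT_PE: "no valid school day without PE",
        DayType.WEEKEND: "no valid weekend day",
    }
    for t, label in labels.items():
        if counts[t.name] == 0:
            reasons.append(label)
            continue
        of_type = [r for r in valid_days if r.day_type is t]
        if not any(r.valid_before for r in of_type):
            reasons.append(f"no valid Before segment on {t.value}")
        if not any(r.valid_after for r in of_type):
            reasons.append(f"no valid After segment on {t.value}")
    return AssessmentValidity(
        valid=not reasons,
        n_valid_days=len(valid_days),
        counts_by_type=counts,
        reasons=reasons,
    )
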