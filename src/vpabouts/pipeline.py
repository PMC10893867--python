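"""Per-subject orchestration: epochs -> day records -> bouts.

Fixed stage order: device non-wear flags, strict sustained-inactivity rule,
sleep windows, day typing and validity, imputation of residual non-wear
inside valid days, then bout detection and per-day statistics. Bouts and
minutes are only ever computed for valid, analyzable days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .bouts import (
    bout_day_flags,
    bout_minutes,
    bout_threshold,
    detect_vpa_bouts,
    out_of_school_bout_minutes,
)
from .daytypes import (
    AssessmentValidity,
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
from .epochs import EPOCHS_PER_DAY, EpochSeries, minutes_by_intensity
from .nonwear import ImputationRecord, detect_strict_nonwear, impute_nonwear


@dataclass
class SubjectResult:
    subject_id: str
    sex: str
    records: list[DayRecord]
    assessment: AssessmentValidity
    imputation: list[ImputationRecord] = field(default_factory=list)
    strict_nonwear_min: float = 0.0


def process_subject(
    series: EpochSeries,
    sex: str,
    calendar: SchoolCalendar,
    absences: set[dt.date] | None = None,
    sleep_log: dict[dt.date, tuple[int, int]] | None = None,
) -> SubjectResult:
    """Run the full epoch-to-bout pipeline for one subject."""
    series.ensure_classes()
    wear, strict = detect_strict_nonwear(series)
    series.wear = wear
    sleep = detect_sleep_windows(series, sleep_log=sleep_log)
    threshold = bout_threshold(sex)

    records: list[DayRecord] = []
    for day in range(series.n_days):
        date = series.date_of_day(day)
        wake, bed, fallback = sleep[day]
        pe_window = calendar.pe_windows.get(date)
        pe_valid = None
        if pe_window is not None and date.weekday() < 5:
            pe_valid = validate_pe_class(series, day, pe_window)
        day_type = classify_day_type(
            date, calendar, absences=absences, pe_valid=bool(pe_valid)
        )
        rec = DayRecord(
            day=day,
            date=date,
            day_type=day_type,
            wake=wake,
            bed=bed,
            sleep_fallback=fallback,
            pe_window=pe_window,
            pe_valid=pe_valid,
        )
        rec.valid_day = validate_day(series, day)
        rec.valid_awake = validate_awake(series, day, wake, bed)
        rec.valid_before = rec.valid_day and validate_segment(series, day, wake, bed, "before")
        rec.valid_after = rec.valid_day and validate_segment(series, day, wake, bed, "after")
        if rec.is_school:
            rec.valid_school_time = validate_school_time(series, day)
            if not rec.valid_school_time:
                rec.valid_day = False  # a valid school day implies valid school time
        records.append(rec)

    imputation = impute_nonwear(series, records)

    for rec in records:
        if not (rec.valid_day and rec.analyzable):
            continue
        base = rec.day * EPOCHS_PER_DAY
        rec.minutes = minutes_by_intensity(series, base + rec.wake, base + rec.bed)
        day_cls = series.classes[base : base + EPOCHS_PER_DAY]
        countable = series.countable()[base : base + EPOCHS_PER_DAY]
        rec.bouts = detect_vpa_bouts(
            day_cls, rec.wake, rec.bed, threshold, day=rec.day, countable=countable
        )
        rec.has_bout, rec.before_bout, rec.after_bout = bout_day_flags(rec.bouts)
        rec.bout_min = bout_minutes(rec.bouts)
        rec.out_of_school_bout_min = out_of_school_bout_minutes(rec.bouts, rec.is_school)

    assessment = validate_assessment(records)
    return SubjectResult(
        subject_id=series.subject_id,
        sex=sex,
        records=records,
        assessment=assessment,
        imputation=imputation,
        strict_nonwear_min=sum(i.duration_min for i in strict),
    )
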