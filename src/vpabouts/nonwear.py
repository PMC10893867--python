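"""Strict non-wear detection and non-wear imputation.

Device non-wear algorithms tuned for long removals miss short ones, so the
device flags are supplemented with a strict sustained-inactivity rule: any
maximal run of at least 30 minutes during which every successive 5-s change
in the z-axis tilt angle stays below 2 degrees is treated as non-wear, with
the flag credited only between 8:00 AM and 10:00 PM (overnight stillness is
sleep, not removal). Run length is evaluated on the full record and the
resulting flag clipped to the crediting window.

Residual non-wear inside days that survived the validity rules is imputed at
the epoch level: each missing clock slot takes the majority intensity class
observed at that slot across the subject's other valid days of the same day
type (ties resolved toward the lower intensity; fallback to all valid days
when the type has no donors). Imputed epochs are marked and participate in
all downstream minutes and bout statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .epochs import (
    EPOCHS_PER_DAY,
    EPOCHS_PER_MINUTE,
    EpochSeries,
    IntensityClass,
    tod_epoch,
)


@dataclass(frozen=True)
class NonwearInterval:
    """Flagged non-wear stretch, in absolute epoch indices [start, end)."""

    start: int
    end: int
    source: str  # device_flag | strict_rule | reported

    @property
    def duration_min(self) -> float:
        return (self.end - self.start) / EPOCHS_PER_MINUTE


@dataclass
class ImputationRecord:
    day: int
    start: int          # epoch-of-day
    end: int
    day_type: str
    donor_days: int
    fallback: bool
    unfilled: bool = False


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    if mask.size == 0:
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_strict_nonwear(
    series: EpochSeries,
    angle_threshold_deg: float = 2.0,
    min_duration_min: int = 30,
    window_start_hour: int = 8,
    window_end_hour: int = 22,
) -> tuple[np.ndarray, list[NonwearInterval]]:
    """Flag sustained stillness as non-wear.

    Returns the updated wear flags (union with existing device non-wear;
    never un-flags anything) and the list of newly flagged intervals, one
    per (run x crediting window) intersection.
    """
    n = series.n
    wear = series.wear.copy()
    if n < 2:
        return wear, []
    calm = np.abs(np.diff(series.angle_z)) < angle_threshold_deg
    min_epochs = min_duration_min * EPOCHS_PER_MINUTE
    # connected epochs: epoch i and i+1 belong to one run when calm[i]
    member = np.zeros(n, dtype=bool)
    member[:-1] |= calm
    member[1:] |= calm
    intervals: list[NonwearInterval] = []
    w0, w1 = tod_epoch(window_start_hour), tod_epoch(window_end_hour)
    for lo, hi in _runs(member):
        if hi - lo < min_epochs:
            continue
        first_day = lo // EPOCHS_PER_DAY
        last_day = (hi - 1) // EPOCHS_PER_DAY
        for day in range(first_day, last_day + 1):
            base = day * EPOCHS_PER_DAY
            s = max(lo, base + w0)
            e = min(hi, base + w1, n)
            if e > s:
                newly = s, e
                wear[newly[0]:newly[1]] = False
                intervals.append(NonwearInterval(s, e, "strict_rule"))
    return wear, intervals


def nonwear_minutes(series: EpochSeries, start: int, end: int) -> float:
    """Minutes of non-wear within epochs [start, end)."""
    start, end = max(0, int(start)), min(series.n, int(end))
    if end <= start:
        return 0.0
    return float(np.sum(~series.wear[start:end]) / EPOCHS_PER_MINUTE)


def impute_nonwear(series: EpochSeries, day_records) -> list[ImputationRecord]:
    """Fill residual non-wear on valid days from same-type donor days.

    ``day_records`` are calendar_validity DayRecord objects with final
    validity flags, day types and wake/bed epochs. Mutates ``series.classes``
    and ``series.imputed`` in place and returns one record per contiguous
    imputed (or unfillable) gap. Idempotent: imputed epochs are never
    treated as gaps or used as donors.
    """
    series.ensure_classes()
    cls = series.classes
    imputed = series.imputed
    valid = [r for r in day_records if r.valid_day and r.analyzable]
    by_type: dict[str, list] = {}
    for r in valid:
        by_type.setdefault(r.day_type.name, []).append(r)
    records: list[ImputationRecord] = []
    for r in valid:
        base = r.day * EPOCHS_PER_DAY
        lo, hi = base + r.wake, base + min(r.bed, EPOCHS_PER_DAY)
        gap = ~series.wear[lo:hi] & ~imputed[lo:hi]
        if not gap.any():
            continue
        donors = [d for d in by_type[r.day_type.name] if d.day != r.day]
        fallback_donors = [d for d in valid if d.day != r.day]
        for g0, g1 in _runs(gap):
            slots = np.arange(lo + g0, lo + g1)       # absolute epochs
            tod = slots - base                        # epoch-of-day
            maj, covered = _majority_class(series, donors, tod)
            used_fallback = False
            if not covered.all():
                maj_fb, cov_fb = _majority_class(series, fallback_donors, tod)
                fill = ~covered & cov_fb
                maj[fill] = maj_fb[fill]
                covered |= cov_fb
                used_fallback = bool(fill.any())
            rec = ImputationRecord(
                day=r.day,
                start=int(tod[0]),
                end=int(tod[-1]) + 1,
                day_type=r.day_type.name,
                donor_days=len(donors),
                fallback=used_fallback,
            )
            if not covered.all():
                rec.unfilled = True
                warnings.warn(
                    f"day {r.day}: {np.sum(~covered)} epoch(s) left unfilled "
                    "(no donor coverage)",
                    stacklevel=2,
                )
            sel = slots[covered]
            cls[sel] = maj[covered]
            imputed[sel] = True
            records.append(rec)
    return records


def _majority_class(series: EpochSeries, donors, tod: np.ndarray):
    """Majority worn class per clock slot across donor days.

    Ties resolve toward the lower-intensity class (argmax scans classes in
    ascending order). Returns (classes, covered) with covered False where no
    donor wore the device at that slot.
    """
    counts = np.zeros((len(IntensityClass), tod.size), dtype=np.int32)
    for d in donors:
        idx = d.day * EPOCHS_PER_DAY + tod
        ok = (idx < series.n) & series.wear[idx.clip(max=series.n - 1)]
        if not ok.any():
            continue
        dcls = series.classes[idx[ok]]
        for c in IntensityClass:
            counts[c, ok] += dcls == c
    covered = counts.sum(axis=0) > 0
    maj = counts.argmax(axis=0).astype(np.int8)
    return maj, covered


def substitute_reported_sport(
    series: EpochSeries,
    day: int,
    start: int,
    end: int,
    template_classes: np.ndarray,
) -> ImputationRecord:
    """Replace a reported sport session that coincides with non-wear.

    ``start``/``end`` are epoch-of-day indices; ``template_classes`` is the
    per-epoch intensity sequence of a similar observed activity (config
    hook). Refuses unless the whole interval is flagged non-wear.
    """
    series.ensure_classes()
    lo = day * EPOCHS_PER_DAY + int(start)
    hi = day * EPOCHS_PER_DAY + int(end)
    if hi <= lo or hi > series.n:
        raise ValueError("reported interval outside the record")
    if series.wear[lo:hi].any():
        raise ValueError(
            "reported sport interval is not fully non-wear; refusing to substitute"
        )
    template = np.asarray(template_classes, dtype=np.int8)
    if template.size != hi - lo:
        raise ValueError("template length does not match the interval")
    series.classes[lo:hi] = template
    series.imputed[lo:hi] = True
    return ImputationRecord(
        day=day, start=int(start), end=int(end), day_type="reported",
        donor_days=0, fallback=False,
    )
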