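"""Sex-specific VPA-bout detection.

A vigorous-intensity activity session (VIA) is operationalized as a VPA-Bout:
an interval of at least 60 minutes whose covering 60-minute windows each
contain enough vigorous epochs. The density threshold is one sixth for boys
and one eighth for girls, i.e. 120 and 90 VPA epochs per 720-epoch window,
or 10.0 and 7.5 VPA minutes per hour. The canonical form is the epoch count
(the rounded percentages 16.7%/12.5% are presentation only).

Construction: every 720-epoch window fully inside the day's awake interval
qualifies when its VPA count reaches the threshold; an epoch is in a bout
when at least one qualifying window covers it; bouts are the maximal runs of
in-bout epochs. Windows never cross midnight nor extend outside wake-bed.
The bout itself is not required to satisfy the density over its full extent;
only every covering window is. ``brute_force_bouts`` re-derives the same
contract by explicit per-window scanning and serves as the testing oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .epochs import EPOCHS_PER_HOUR, EPOCHS_PER_MINUTE, IntensityClass, tod_epoch

WINDOW_EPOCHS = EPOCHS_PER_HOUR  # 60-minute window = 720 five-second epochs
SEGMENT_SPLIT = tod_epoch(14)    # Before / After 2:00 PM boundary


@dataclass(frozen=True)
class BoutThreshold:
    """Minimum VPA density for a window to qualify, by sex."""

    sex: str
    proportion: Fraction

    @property
    def epochs_per_window(self) -> int:
        return int(self.proportion * WINDOW_EPOCHS)

    @property
    def minutes_per_hour(self) -> float:
        return self.epochs_per_window / EPOCHS_PER_MINUTE


_THRESHOLDS = {
    "boy": Fraction(1, 6),   # 120 epochs -> 10.0 min/h
    "girl": Fraction(1, 8),  # 90 epochs  -> 7.5 min/h
}


def bout_threshold(sex: str) -> BoutThreshold:
    """Sex-specific VPA density threshold; no default exists for other values."""
    key = sex.strip().lower()
    if key not in _THRESHOLDS:
        raise ValueError(f"unknown sex {sex!r}: thresholds are defined for boy/girl")
    return BoutThreshold(sex=key, proportion=_THRESHOLDS[key])


@dataclass(frozen=True)
class VPABout:
    """Detected bout, in epoch-of-day indices [start, end)."""

    day: int
    start: int
    end: int
    vpa_epochs: int

    @property
    def duration_min(self) -> float:
        return (self.end - self.start) / EPOCHS_PER_MINUTE

    @property
    def vpa_min(self) -> float:
        return self.vpa_epochs / EPOCHS_PER_MINUTE

    @property
    def touches_before(self) -> bool:
        return self.start < SEGMENT_SPLIT

    @property
    def touches_after(self) -> bool:
        return self.end > SEGMENT_SPLIT


def _vpa_mask(day_classes: np.ndarray, countable: np.ndarray | None) -> np.ndarray:
    v = day_classes == IntensityClass.VPA
    if countable is not None:
        v &= countable
    return v


def detect_vpa_bouts(
    day_classes: np.ndarray,
    wake: int,
    bed: int,
    threshold: BoutThreshold,
    day: int = 0,
    countable: np.ndarray | None = None,
) -> list[VPABout]:
    """Detect VPA-Bouts within one day's awake interval [wake, bed).

    ``day_classes`` is the epoch-of-day intensity array (single calendar
    day); ``countable`` optionally restricts which epochs may count as VPA
    (worn or imputed). Returns [] with a warning when the awake interval is
    shorter than one window.
    """
    n = day_classes.shape[0]
    wake, bed = max(0, int(wake)), min(n, int(bed))
    if bed - wake < WINDOW_EPOCHS:
        warnings.warn("awake interval shorter than 60 minutes: no bouts", stacklevel=2)
        return []
    v = _vpa_mask(day_classes, countable)
    counts = np.cumsum(np.concatenate(([0], v[wake:bed].view(np.int8))))
    window_counts = counts[WINDOW_EPOCHS:] - counts[:-WINDOW_EPOCHS]
    qualifying = window_counts >= threshold.epochs_per_window  # start offsets
    if not qualifying.any():
        return []
    # union of qualifying windows via a coverage difference array
    span = bed - wake
    delta = np.zeros(span + 1, dtype=np.int32)
    starts = np.flatnonzero(qualifying)
    np.add.at(delta, starts, 1)
    np.add.at(delta, starts + WINDOW_EPOCHS, -1)
    in_bout = np.cumsum(delta[:-1]) > 0
    bouts = []
    for lo, hi in _bool_runs(in_bout):
        s, e = wake + lo, wake + hi
        bouts.append(VPABout(day=day, start=s, end=e, vpa_epochs=int(v[s:e].sum())))
    return bouts


def brute_force_bouts(
    day_classes: np.ndarray,
    wake: int,
    bed: int,
    threshold: BoutThreshold,
    day: int = 0,
    countable: np.ndarray | None = None,
) -> list[VPABout]:
    """Exhaustive reference implementation with the same output contract."""
    n = day_classes.shape[0]
    wake, bed = max(0, int(wake)), min(n, int(bed))
    if bed - wake < WINDOW_EPOCHS:
        return []
    v = _vpa_mask(day_classes, countable)
    in_bout = np.zeros(n, dtype=bool)
    need = threshold.epochs_per_window
    for s in range(wake, bed - WINDOW_EPOCHS + 1):
        if v[s : s + WINDOW_EPOCHS].sum() >= need:
            in_bout[s : s + WINDOW_EPOCHS] = True
    bouts = []
    for lo, hi in _bool_runs(in_bout):
        bouts.append(
            VPABout(day=day, start=lo, end=hi, vpa_epochs=int(v[lo:hi].sum()))
        )
    return bouts


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    diff = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    return list(zip(np.flatnonzero(diff == 1).tolist(), np.flatnonzero(diff == -1).tolist()))


def bout_day_flags(bouts: list[VPABout]) -> tuple[bool, bool, bool]:
    """(day has bout, Before-2PM has bout, After-2PM has bout).

    A bout straddling 2:00 PM credits both segments.
    """
    has = len(bouts) > 0
    before = any(b.touches_before for b in bouts)
    after = any(b.touches_after for b in bouts)
    return has, before, after


def bout_minutes(
    bouts: list[VPABout], start: int | None = None, end: int | None = None
) -> float:
    """Total bout minutes intersected with epoch-of-day interval [start, end)."""
    lo = 0 if start is None else int(start)
    hi = 10**9 if end is None else int(end)
    total = 0
    for b in bouts:
        total += max(0, min(b.end, hi) - max(b.start, lo))
    return total / EPOCHS_PER_MINUTE


def out_of_school_bout_minutes(bouts: list[VPABout], is_school_day: bool) -> float:
    """Out-of-school scope: After 2:00 PM on school days, whole day on weekends."""
    if is_school_day:
        return bout_minutes(bouts, start=SEGMENT_SPLIT)
    return bout_minutes(bouts)
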