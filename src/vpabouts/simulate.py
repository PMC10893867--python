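"""Synthetic week-long cohorts with exact ground truth.

The generator emulates the schedule structure the analysis assumes: school
days 9:00-14:00 with a 30-minute recess starting between 11:00 and 12:00,
PE classes on a configurable subset of school weekdays, extracurricular
sport sessions of parameterized duration and vigorous density, weekends,
nightly sleep, and injected non-wear episodes. Contexts are piecewise-
constant blocks; inside a block the intensity class of each 5-s epoch is an
i.i.d. draw from the context's class-probability vector, and the ENMO value
is drawn uniformly within the class's cut-point interval (the downstream
classification is threshold-based, so the within-class shape is
irrelevant). Because the class probabilities are known per block, the
expected VPA density of every 60-minute window — and hence which intervals
a correct bout detector must find — is known exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bouts import WINDOW_EPOCHS, bout_threshold
from .daytypes import SchoolCalendar, _format_clock
from .epochs import (
    EPOCHS_PER_DAY,
    EPOCHS_PER_MINUTE,
    DEFAULT_CUTPOINTS,
    EpochSeries,
    tod_epoch,
)
from .errors import ConfigError

CONTEXTS = (
    "sleep",
    "sedentary",
    "free_play",
    "recess",
    "pe_class",
    "sport_session",
    "transit",
)

#: per-class ENMO sampling intervals (mg), strictly inside the cut-point bands
_DEFAULT_ENMO_RANGES = ((0.0, 50.0), (60.0, 185.0), (200.0, 650.0), (700.0, 2000.0))

_DEFAULT_PROBS = {
    "sleep":         (1.00, 0.00, 0.00, 0.00),
    "sedentary":     (0.75, 0.22, 0.03, 0.00),
    "free_play":     (0.35, 0.40, 0.22, 0.03),
    "recess":        (0.20, 0.40, 0.32, 0.08),
    "pe_class":      (0.10, 0.25, 0.35, 0.30),
    "sport_session": (0.05, 0.20, 0.40, 0.35),
    "transit":       (0.15, 0.60, 0.24, 0.01),
}


@dataclass(frozen=True)
class ActivityProfile:
    """Per-context intensity mixtures and per-class ENMO sampling intervals."""

    probs: dict = None
    enmo_ranges: tuple = _DEFAULT_ENMO_RANGES

    def __post_init__(self):
        object.__setattr__(
            self,
            "probs",
            {k: np.asarray(v, dtype=float) for k, v in (self.probs or _DEFAULT_PROBS).items()},
        )
        for ctx in CONTEXTS:
            if ctx not in self.probs:
                raise ConfigError(f"profile missing context {ctx!r}")
            p = self.probs[ctx]
            if p.shape != (4,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ConfigError(f"class probabilities for {ctx!r} must sum to 1")
        edges = [0.0, *DEFAULT_CUTPOINTS.edges, 2000.0]
        for c, (lo, hi) in enumerate(self.enmo_ranges):
            if not (edges[c] <= lo < hi <= edges[c + 1]):
                raise ConfigError(
                    f"ENMO range {lo}-{hi} escapes the class-{c} cut-point band"
                )

    def vpa_prob(self, ctx: str) -> float:
        return float(self.probs[ctx][3])


DEFAULT_PROFILE = ActivityProfile()


@dataclass
class Block:
    context: str
    start: int  # epoch-of-day
    end: int


@dataclass
class DayPlan:
    date: dt.date
    weekday: int
    is_school: bool
    wake: int
    bed: int
    blocks: list[Block]
    pe_window: tuple[int, int] | None = None
    pe_vigorous: bool = False
    holiday: bool = False
    absence: bool = False


@dataclass
class NonwearSpec:
    day: int
    start: int  # epoch-of-day
    end: int
    device_flagged: bool


@dataclass
class WeekPlan:
    subject_id: str
    sex: str
    days: list[DayPlan]
    nonwear: list[NonwearSpec]
    osa_hours: int
    pe_weekdays: tuple[int, ...]
    session_weekdays: tuple[int, ...]
    session_context: str
    weight_status: str | None = None

    @property
    def n_days(self) -> int:
        return len(self.days)

    def calendar(self) -> SchoolCalendar:
        dates = {d.date for d in self.days}
        school = {d.date for d in self.days if d.is_school and not d.holiday}
        pe = {d.date: d.pe_window for d in self.days if d.pe_window is not None}
        hol = {d.date for d in self.days if d.holiday}
        return SchoolCalendar(dates=dates, school_days=school, pe_windows=pe, holidays=hol)

    def absences(self) -> set[dt.date]:
        return {d.date for d in self.days if d.absence}


@dataclass
class SubjectParams:
    subject_id: str = "S001"
    sex: str = "girl"
    osa_hours: int = 0
    pe_days: int = 2
    n_sessions: int | None = None
    session_weekdays: tuple[int, ...] | None = None
    session_context: str = "sport_session"
    pe_vigorous_prob: float = 0.5
    start_date: dt.date = dt.date(2020, 1, 13)  # a Monday in the study's school year
    n_days: int = 8
    nonwear_daily_prob: float = 0.15
    weight_status: str | None = None
    holidays: tuple[dt.date, ...] = ()
    absences: tuple[dt.date, ...] = ()


def _snap(epoch: float, grid: int = EPOCHS_PER_MINUTE) -> int:
    return int(round(epoch / grid) * grid)


def _draw_clock(rng, h0, m0, h1, m1) -> int:
    lo, hi = tod_epoch(h0, m0), tod_epoch(h1, m1)
    return _snap(rng.uniform(lo, hi))


def _default_sessions(osa_hours: int) -> int:
    if osa_hours <= 0:
        return 0
    return max(1, min(osa_hours, round(osa_hours / 1.5)))


def _session_durations(osa_hours: int, n_sessions: int) -> list[int]:
    """Per-session durations in epochs; total equals osa_hours exactly."""
    total_min = osa_hours * 60
    base = max(60, int(round(total_min / n_sessions / 5)) * 5)  # 5-min grid
    durs = [base] * (n_sessions - 1)
    durs.append(total_min - base * (n_sessions - 1))
    if durs[-1] < 60:  # rebalance so every session lasts >= 60 min
        durs = [60] * (n_sessions - 1)
        durs.append(total_min - 60 * (n_sessions - 1))
    return [d * EPOCHS_PER_MINUTE for d in durs]


def build_week_plan(params: SubjectParams, seed) -> WeekPlan:
    """Schedule one subject's assessment week (>= 8 consecutive days)."""
    rng = np.random.default_rng(seed)
    if not 0 <= params.osa_hours <= 11:
        raise ConfigError("OSA hours must lie in [0, 11]")
    if params.n_days < 8:
        raise ConfigError("an assessment covers at least 8 consecutive days")
    dates = [params.start_date + dt.timedelta(days=i) for i in range(params.n_days)]
    school_weekdays = sorted({d.weekday() for d in dates if d.weekday() < 5})
    if params.pe_days > len(school_weekdays):
        raise ConfigError("more PE days than school weekdays")
    pe_weekdays = tuple(
        sorted(rng.choice(school_weekdays, size=params.pe_days, replace=False).tolist())
    )
    n_sessions = (
        _default_sessions(params.osa_hours)
        if params.n_sessions is None
        else params.n_sessions
    )
    if n_sessions > 0 and params.osa_hours == 0:
        raise ConfigError("sessions requested but zero OSA hours")
    if n_sessions > 7:
        raise ConfigError("at most one organized sport session per weekday")
    if params.session_weekdays is not None:
        session_weekdays = tuple(params.session_weekdays)
        if len(session_weekdays) != n_sessions:
            raise ConfigError("session_weekdays must match n_sessions")
    else:
        session_weekdays = tuple(
            sorted(rng.choice(7, size=n_sessions, replace=False).tolist())
        )
    durations = _session_durations(params.osa_hours, n_sessions) if n_sessions else []
    dur_by_weekday = dict(zip(session_weekdays, durations))

    days: list[DayPlan] = []
    nonwear: list[NonwearSpec] = []
    for i, date in enumerate(dates):
        wd = date.weekday()
        is_school = wd < 5 and date not in params.holidays
        wake = (
            _draw_clock(rng, 7, 0, 8, 30) if is_school else _draw_clock(rng, 8, 0, 9, 30)
        )
        bed = _draw_clock(rng, 21, 0, 23, 0)
        pe_window = None
        pe_vig = False
        if is_school and wd in pe_weekdays:
            pe_window = (
                (tod_epoch(9), tod_epoch(10))
                if rng.random() < 0.5
                else (tod_epoch(13), tod_epoch(14))
            )
            pe_vig = bool(rng.random() < params.pe_vigorous_prob)
        session = None
        if wd in dur_by_weekday:
            dur = dur_by_weekday[wd]
            if is_school:
                start = tod_epoch(16, 30) + int(rng.integers(0, 3)) * 15 * EPOCHS_PER_MINUTE
            else:
                start = tod_epoch(10, 30) if rng.random() < 0.5 else tod_epoch(16, 0)
            session = (start, start + dur)
        blocks = _day_blocks(rng, is_school, wake, bed, pe_window, pe_vig, session,
                             params.session_context)
        days.append(
            DayPlan(
                date=date,
                weekday=wd,
                is_school=is_school,
                wake=wake,
                bed=bed,
                blocks=blocks,
                pe_window=pe_window,
                pe_vigorous=pe_vig,
                holiday=date in params.holidays,
                absence=date in params.absences,
            )
        )
        if rng.random() < params.nonwear_daily_prob:
            start = _snap(rng.uniform(tod_epoch(19), tod_epoch(19, 45)))
            dur = int(rng.integers(6, 13)) * 5 * EPOCHS_PER_MINUTE  # 30-60 min
            end = min(start + dur, bed)
            if end - start >= 30 * EPOCHS_PER_MINUTE:
                nonwear.append(
                    NonwearSpec(
                        day=i,
                        start=start,
                        end=end,
                        device_flagged=(end - start) >= 45 * EPOCHS_PER_MINUTE,
                    )
                )
    return WeekPlan(
        subject_id=params.subject_id,
        sex=params.sex,
        days=days,
        nonwear=nonwear,
        osa_hours=params.osa_hours,
        pe_weekdays=pe_weekdays,
        session_weekdays=session_weekdays,
        session_context=params.session_context,
        weight_status=params.weight_status,
    )


def _day_blocks(rng, is_school, wake, bed, pe_window, pe_vig, session, session_ctx):
    """Non-overlapping context blocks covering wake to bed."""
    fixed: list[Block] = []
    if is_school:
        recess_start = _snap(rng.uniform(tod_epoch(11), tod_epoch(12)))
        recess = Block("recess", recess_start, recess_start + 30 * EPOCHS_PER_MINUTE)
        fixed.append(Block("transit", tod_epoch(8, 40), tod_epoch(9)))
        school_fill = [(tod_epoch(9), tod_epoch(14))]
        if pe_window:
            ctx = "pe_class" if pe_vig else "free_play"
            fixed.append(Block(ctx, *pe_window))
            school_fill = _subtract(school_fill, pe_window)
        fixed.append(recess)
        school_fill = _subtract(school_fill, (recess.start, recess.end))
        for lo, hi in school_fill:
            fixed.append(Block("sedentary", lo, hi))
        fixed.append(Block("transit", tod_epoch(14), tod_epoch(14, 15)))
    if session:
        fixed.append(Block(session_ctx, *session))
    fixed.sort(key=lambda b: b.start)
    blocks: list[Block] = []
    cursor = wake
    for b in fixed:
        if b.start > cursor:
            blocks.extend(_fill(rng, cursor, b.start))
        blocks.append(b)
        cursor = max(cursor, b.end)
    if cursor < bed:
        blocks.extend(_fill(rng, cursor, bed))
    return blocks


def _subtract(spans, cut):
    out = []
    for lo, hi in spans:
        if cut[1] <= lo or cut[0] >= hi:
            out.append((lo, hi))
            continue
        if lo < cut[0]:
            out.append((lo, cut[0]))
        if cut[1] < hi:
            out.append((cut[1], hi))
    return out


def _fill(rng, start, end, contexts=("sedentary", "free_play")):
    """Fill a free span with alternating leisure blocks of 30-90 minutes."""
    blocks = []
    cursor = start
    ctx = contexts[int(rng.integers(0, len(contexts)))]
    while cursor < end:
        dur = int(rng.integers(6, 19)) * 5 * EPOCHS_PER_MINUTE
        hi = min(cursor + dur, end)
        if end - hi < 6 * 5 * EPOCHS_PER_MINUTE // 5:  # avoid a tiny tail block
            hi = end
        blocks.append(Block(ctx, cursor, hi))
        cursor = hi
        ctx = contexts[1] if ctx == contexts[0] else contexts[0]
    return blocks


_CTX_CODE = {c: i for i, c in enumerate(CONTEXTS)}


def simulate_epochs(
    plan: WeekPlan, profile: ActivityProfile = DEFAULT_PROFILE, seed=0
) -> EpochSeries:
    """Draw the epoch stream implied by a week plan.

    One epoch per 5 s from 00:00 of day 1 to 24:00 of the last day. Epochs
    outside wake-bed are sleep; injected non-wear episodes get near-zero
    acceleration and a nearly constant tilt angle (successive changes
    < 2 degrees by construction); device-flagged episodes additionally have
    wear=False in the output.
    """
    rng = np.random.default_rng(seed)
    n = plan.n_days * EPOCHS_PER_DAY
    codes = np.zeros(n, dtype=np.int8)  # sleep
    for i, day in enumerate(plan.days):
        base = i * EPOCHS_PER_DAY
        for b in day.blocks:
            codes[base + b.start : base + b.end] = _CTX_CODE[b.context]
    classes = np.zeros(n, dtype=np.int8)
    for ctx in CONTEXTS:  # fixed iteration order keeps draws reproducible
        idx = np.flatnonzero(codes == _CTX_CODE[ctx])
        if idx.size:
            classes[idx] = rng.choice(4, size=idx.size, p=profile.probs[ctx])
    enmo = np.empty(n)
    for c, (lo, hi) in enumerate(profile.enmo_ranges):
        sel = classes == c
        enmo[sel] = rng.uniform(lo, hi, size=int(sel.sum()))
    angle = rng.uniform(-60.0, 60.0, size=n)
    sleep_mask = codes == _CTX_CODE["sleep"]
    for lo, hi in _mask_runs(sleep_mask):
        angle[lo:hi] = rng.uniform(-60, 60) + rng.uniform(-0.4, 0.4, size=hi - lo)
    wear = np.ones(n, dtype=bool)
    for spec in plan.nonwear:
        lo = spec.day * EPOCHS_PER_DAY + spec.start
        hi = spec.day * EPOCHS_PER_DAY + spec.end
        enmo[lo:hi] = rng.uniform(0.0, 5.0, size=hi - lo)
        angle[lo:hi] = rng.uniform(-60, 60) + rng.uniform(-0.4, 0.4, size=hi - lo)
        if spec.device_flagged:
            wear[lo:hi] = False
    start = pd.Timestamp(dt.datetime.combine(plan.days[0].date, dt.time()))
    return EpochSeries(
        subject_id=plan.subject_id, start=start, enmo=enmo, angle_z=angle, wear=wear
    )


@dataclass
class GroundTruth:
    """Intervals a correct detector must find, plus expected compliance."""

    must_detect: dict[int, list[tuple[int, int]]]  # day -> [(start, end)] epoch-of-day
    must_weekdays: set[int]
    expected_compliant: bool
    margin: float


def expected_bouts(
    plan: WeekPlan,
    profile: ActivityProfile = DEFAULT_PROFILE,
    margin: float = 0.05,
) -> GroundTruth:
    """Ground truth from expected VPA densities.

    A 60-minute window is must-detect when its expected VPA density (from
    the context class probabilities; zero inside injected non-wear) is at
    least the sex threshold plus the margin. Windows within the margin of
    the threshold are may-detect and excluded from the ground truth, which
    keeps tests away from the decision boundary. A subject expecting
    must-detect intervals on at least 3 of the 7 weekly day-slots is
    expected-compliant.
    """
    thr = float(bout_threshold(plan.sex).proportion) + margin
    must: dict[int, list[tuple[int, int]]] = {}
    weekdays: set[int] = set()
    nonwear_by_day: dict[int, list[NonwearSpec]] = {}
    for spec in plan.nonwear:
        nonwear_by_day.setdefault(spec.day, []).append(spec)
    for i, day in enumerate(plan.days):
        p = np.zeros(EPOCHS_PER_DAY)
        for b in day.blocks:
            p[b.start : b.end] = profile.vpa_prob(b.context)
        for spec in nonwear_by_day.get(i, []):
            p[spec.start : spec.end] = 0.0
        wake, bed = day.wake, day.bed
        if bed - wake < WINDOW_EPOCHS:
            continue
        c = np.concatenate(([0.0], np.cumsum(p[wake:bed])))
        dens = (c[WINDOW_EPOCHS:] - c[:-WINDOW_EPOCHS]) / WINDOW_EPOCHS
        qualifying = np.flatnonzero(dens >= thr - 1e-12)
        if qualifying.size == 0:
            continue
        cover = np.zeros(bed - wake + 1, dtype=np.int32)
        np.add.at(cover, qualifying, 1)
        np.add.at(cover, qualifying + WINDOW_EPOCHS, -1)
        in_bout = np.cumsum(cover[:-1]) > 0
        intervals = [
            (wake + lo, wake + hi) for lo, hi in _mask_runs(in_bout)
        ]
        if intervals:
            must[i] = intervals
            weekdays.add(day.weekday)
    return GroundTruth(
        must_detect=must,
        must_weekdays=weekdays,
        expected_compliant=len(weekdays) >= 3,
        margin=margin,
    )


def _mask_runs(mask):
    diff = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    return list(
        zip(np.flatnonzero(diff == 1).tolist(), np.flatnonzero(diff == -1).tolist())
    )


@dataclass
class CohortMix:
    """Parameter distributions for a generated cohort.

    Defaults emulate the study population: about half boys, a quarter of
    subjects designed to comply with the vigorous-session recommendation
    (three weekly vigorous sessions on distinct weekdays), two PE weekdays,
    half of PE classes vigorous, and reported organized sport that for
    non-compliant subjects either is absent or does not reach vigorous
    intensity (emitted as free play).
    """

    frac_boys: float = 0.5
    compliance_prevalence: float = 0.25
    pe_days: int = 2
    pe_vigorous_prob: float = 0.5
    compliant_osa: tuple = ((3, 4, 5, 6), (0.40, 0.25, 0.20, 0.15))
    noncompliant_osa: tuple = ((0, 1, 2, 3, 4, 5), (0.45, 0.15, 0.15, 0.15, 0.05, 0.05))
    nonwear_daily_prob: float = 0.15
    start_date: dt.date = dt.date(2020, 1, 13)
    n_days: int = 8


@dataclass
class CohortSubject:
    params: SubjectParams
    plan: WeekPlan
    series: EpochSeries
    truth: GroundTruth
    designed_compliant: bool


def generate_cohort(
    n: int,
    mix: CohortMix | None = None,
    seed: int = 0,
    profile: ActivityProfile = DEFAULT_PROFILE,
) -> list[CohortSubject]:
    """Generate ``n`` subjects with deterministic per-subject sub-seeds."""
    if n < 1:
        raise ConfigError("cohort size must be >= 1")
    mix = mix or CohortMix()
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    children = ss.spawn(n + 1)[1:]
    n_boys = int(round(mix.frac_boys * n))
    sexes = np.array(["boy"] * n_boys + ["girl"] * (n - n_boys))
    master.shuffle(sexes)
    n_compliant = int(round(mix.compliance_prevalence * n))
    compliant = np.array([True] * n_compliant + [False] * (n - n_compliant))
    master.shuffle(compliant)
    subjects: list[CohortSubject] = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        plan_seed, epoch_seed = children[i].spawn(2)
        if compliant[i]:
            osa = int(rng.choice(mix.compliant_osa[0], p=mix.compliant_osa[1]))
            params = SubjectParams(
                subject_id=f"S{i + 1:03d}",
                sex=str(sexes[i]),
                osa_hours=osa,
                pe_days=mix.pe_days,
                n_sessions=3,
                session_context="sport_session",
                pe_vigorous_prob=mix.pe_vigorous_prob,
                start_date=mix.start_date,
                n_days=mix.n_days,
                nonwear_daily_prob=mix.nonwear_daily_prob,
            )
        else:
            osa = int(rng.choice(mix.noncompliant_osa[0], p=mix.noncompliant_osa[1]))
            params = SubjectParams(
                subject_id=f"S{i + 1:03d}",
                sex=str(sexes[i]),
                osa_hours=osa,
                pe_days=mix.pe_days,
                session_context="free_play",  # reported sport below vigorous intensity
                pe_vigorous_prob=mix.pe_vigorous_prob,
                start_date=mix.start_date,
                n_days=mix.n_days,
                nonwear_daily_prob=mix.nonwear_daily_prob,
            )
        plan = build_week_plan(params, plan_seed)
        series = simulate_epochs(plan, profile, epoch_seed)
        truth = expected_bouts(plan, profile)
        subjects.append(
            CohortSubject(
                params=params,
                plan=plan,
                series=series,
                truth=truth,
                designed_compliant=bool(compliant[i]),
            )
        )
    return subjects


# --- cohort file output -----------------------------------------------------

def write_cohort(subjects: list[CohortSubject], outdir) -> None:
    """Write epoch, schedule, ground-truth and subject CSVs for a cohort."""
    from .epochs import write_epochs  # local import to avoid cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sched_rows, truth_rows, subj_rows = [], [], []
    for s in subjects:
        write_epochs(s.series, outdir / f"{s.plan.subject_id}_epochs.csv")
        s.plan.calendar().to_csv(outdir / f"{s.plan.subject_id}_calendar.csv")
        for i, day in enumerate(s.plan.days):
            for b in day.blocks:
                sched_rows.append(
                    {
                        "subject_id": s.plan.subject_id,
                        "date": day.date.isoformat(),
                        "context": b.context,
                        "start": _format_clock(b.start),
                        "end": _format_clock(b.end),
                    }
                )
        for day, intervals in s.truth.must_detect.items():
            for lo, hi in intervals:
                truth_rows.append(
                    {
                        "subject_id": s.plan.subject_id,
                        "date": s.plan.days[day].date.isoformat(),
                        "start": _format_clock(lo),
                        "end": _format_clock(hi),
                    }
                )
        subj_rows.append(
            {
                "subject_id": s.plan.subject_id,
                "sex": s.plan.sex,
                "osa_hours": s.plan.osa_hours,
                "weight_status": s.plan.weight_status or "",
                "expected_compliant": int(s.truth.expected_compliant),
            }
        )
    pd.DataFrame(sched_rows).to_csv(outdir / "schedule.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)
    pd.DataFrame(subj_rows).to_csv(outdir / "subjects.csv", index=False)
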