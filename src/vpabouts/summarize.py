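"""Person- and cohort-level aggregation, compliance and comparison tables.

Aggregation path: valid days -> one record per weekday slot (duplicates of
the same weekday and day type averaged; bout flags become fractional
proportions) -> per-day-type means -> weekly values weighted 5/7 school,
2/7 weekend -> compliance (at least one bout on >= 3/7 of valid weekly
slots) -> cohort tables with the field's standard tests (Shapiro-gated
t / Mann-Whitney for independent groups, Wilcoxon signed-rank for paired
contrasts, Pearson chi-square for proportions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .daytypes import DayRecord, DayType

SCHOOL_WEIGHT = Fraction(5, 7)
WEEKEND_WEIGHT = Fraction(2, 7)
COMPLIANCE_FRACTION = Fraction(3, 7)

_MINUTE_KEYS = ("SEDENTARY", "LPA", "MPA", "VPA", "MVPA", "LMVPA")


@dataclass
class WeekdaySlot:
    """One weekday slot after duplicate-day averaging."""

    weekday: int
    day_type: DayType
    n_days: int
    bout_prop: float          # fraction of duplicate days with >= 1 bout
    before_prop: float | None  # None when no duplicate had a valid segment
    after_prop: float | None
    minutes: dict[str, float]
    bout_min: float
    out_of_school_bout_min: float
    vpa_in_bouts_min: float


def average_duplicate_weekdays(records: list[DayRecord]) -> list[WeekdaySlot]:
    """Collapse valid analyzable days to one record per (weekday, day type).

    Numeric fields are averaged; binary bout flags average to proportions so
    a weekday slot whose duplicates disagree contributes a fractional "day
    with bout" downstream.
    """
    groups: dict[tuple[int, str], list[DayRecord]] = {}
    for r in records:
        if r.valid_day and r.analyzable:
            groups.setdefault((r.date.weekday(), r.day_type.name), []).append(r)
    slots = []
    for (weekday, type_name), recs in sorted(groups.items()):
        minutes = {
            k: float(np.mean([r.minutes.get(k, 0.0) for r in recs]))
            for k in _MINUTE_KEYS
        }
        before = [float(r.before_bout) for r in recs if r.valid_before]
        after = [float(r.after_bout) for r in recs if r.valid_after]
        vpa_in_bouts = float(
            np.mean([sum(b.vpa_min for b in r.bouts) for r in recs])
        )
        slots.append(
            WeekdaySlot(
                weekday=weekday,
                day_type=DayType[type_name],
                n_days=len(recs),
                bout_prop=float(np.mean([float(r.has_bout) for r in recs])),
                before_prop=float(np.mean(before)) if before else None,
                after_prop=float(np.mean(after)) if after else None,
                minutes=minutes,
                bout_min=float(np.mean([r.bout_min for r in recs])),
                out_of_school_bout_min=float(
                    np.mean([r.out_of_school_bout_min for r in recs])
                ),
                vpa_in_bouts_min=vpa_in_bouts,
            )
        )
    return slots


def weekly_weighted_mean(school_value, weekend_value):
    """(5 * school + 2 * weekend) / 7; None propagates as undefined."""
    if school_value is None or weekend_value is None:
        return None
    return (
        float(SCHOOL_WEIGHT) * school_value + float(WEEKEND_WEIGHT) * weekend_value
    )


_SCHOOL_TYPES = (DayType.SCHOOL_WITH_PE, DayType.SCHOOL_WITHOUT_PE)


def _select(slots, day_types) -> list[WeekdaySlot]:
    return [s for s in slots if s.day_type in day_types]


def percent_days_with_bout(slots: list[WeekdaySlot], day_types, segment=None):
    """100 * mean slot bout proportion over the selected valid slots.

    ``segment`` may be 'before' or 'after' to use the segment-level flags
    (slots without a valid segment of that kind are excluded). Undefined
    (None) when no valid slot matches.
    """
    sel = _select(slots, day_types)
    if segment == "before":
        props = [s.before_prop for s in sel if s.before_prop is not None]
    elif segment == "after":
        props = [s.after_prop for s in sel if s.after_prop is not None]
    else:
        props = [s.bout_prop for s in sel]
    if not props:
        return None
    return 100.0 * float(np.mean(props))


def compliance_flag(slots: list[WeekdaySlot]) -> bool:
    """WHO vigorous-session compliance: bouts on >= 3/7 of valid weekly slots."""
    valid = _select(slots, (*_SCHOOL_TYPES, DayType.WEEKEND))
    if not valid:
        raise ValueError("no valid weekly slots: subject should have been excluded")
    total = sum(s.bout_prop for s in valid)
    return total / len(valid) >= float(COMPLIANCE_FRACTION) - 1e-12


def osa_group(hours) -> tuple[str, str] | None:
    """Weekly organized-sport hours -> ('0'|'1-2'|'>=3', '<3'|'>=3').

    None (missing questionnaire) -> None: excluded from OSA analyses but
    kept in accelerometer analyses.
    """
    if hours is None or (isinstance(hours, float) and np.isnan(hours)):
        return None
    if not 0 <= hours <= 11:
        raise ValueError("OSA hours must lie in [0, 11]")
    if hours >= 3:
        return (">=3", ">=3")
    return ("0" if hours == 0 else "1-2", "<3")


def osa_minutes_per_day(hours) -> float:
    """Reported weekly hours spread over 7 days, in minutes."""
    return hours * 60.0 / 7.0


@dataclass
class SubjectSummary:
    subject_id: str
    sex: str
    osa_hours: int | None
    compliant: bool
    values: dict[str, float | None] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "sex": self.sex,
            "osa_hours": self.osa_hours,
            "compliant": self.compliant,
        }
        grp = osa_group(self.osa_hours)
        row["osa_group"] = grp[0] if grp else None
        row["osa_binary"] = grp[1] if grp else None
        row.update(self.values)
        return row


def summarize_subject(result, osa_hours=None) -> SubjectSummary:
    """Weekly weighted person-level summary from a pipeline SubjectResult."""
    slots = average_duplicate_weekdays(result.records)
    school = _select(slots, _SCHOOL_TYPES)
    weekend = _select(slots, (DayType.WEEKEND,))

    def mean_or_none(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    values: dict[str, float | None] = {}
    for key in _MINUTE_KEYS:
        values[f"weekly_{key}_min"] = weekly_weighted_mean(
            mean_or_none([s.minutes[key] for s in school]),
            mean_or_none([s.minutes[key] for s in weekend]),
        )
    values["weekly_bout_min"] = weekly_weighted_mean(
        mean_or_none([s.bout_min for s in school]),
        mean_or_none([s.bout_min for s in weekend]),
    )
    # out-of-school scope: After 2 PM on school days (5/7), whole weekend day (2/7)
    values["out_of_school_bout_min"] = weekly_weighted_mean(
        mean_or_none([s.out_of_school_bout_min for s in school]),
        mean_or_none([s.bout_min for s in weekend]),
    )
    values["weekly_vpa_in_bouts_min"] = weekly_weighted_mean(
        mean_or_none([s.vpa_in_bouts_min for s in school]),
        mean_or_none([s.vpa_in_bouts_min for s in weekend]),
    )
    selections = {
        "weekly": (*_SCHOOL_TYPES, DayType.WEEKEND),
        "school": _SCHOOL_TYPES,
        "school_pe": (DayType.SCHOOL_WITH_PE,),
        "school_nope": (DayType.SCHOOL_WITHOUT_PE,),
        "weekend": (DayType.WEEKEND,),
    }
    for name, types in selections.items():
        if name == "weekly":
            pct = weekly_weighted_mean(
                percent_days_with_bout(slots, _SCHOOL_TYPES),
                percent_days_with_bout(slots, (DayType.WEEKEND,)),
            )
            values["pct_days_bout_weekly"] = pct
            for seg in ("before", "after"):
                values[f"pct_days_bout_weekly_{seg}"] = weekly_weighted_mean(
                    percent_days_with_bout(slots, _SCHOOL_TYPES, segment=seg),
                    percent_days_with_bout(slots, (DayType.WEEKEND,), segment=seg),
                )
            continue
        values[f"pct_days_bout_{name}"] = percent_days_with_bout(slots, types)
        for seg in ("before", "after"):
            values[f"pct_days_bout_{name}_{seg}"] = percent_days_with_bout(
                slots, types, segment=seg
            )
    if osa_hours is not None:
        values["osa_min_per_day"] = osa_minutes_per_day(osa_hours)
    return SubjectSummary(
        subject_id=result.subject_id,
        sex=result.sex,
        osa_hours=osa_hours,
        compliant=compliance_flag(slots),
        values=values,
    )


def cohort_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])


# --- statistical comparisons ------------------------------------------------

SHAPIRO_ALPHA = 0.05


def compare_groups(values, groups=None, paired=False):
    """Two-group comparison with a normality-gated test choice.

    Independent: Shapiro-Wilk on each group at alpha = 0.05; Student's
    t-test when both look normal, Mann-Whitney U otherwise. Paired
    (``values`` = (x, y)): Wilcoxon signed-rank. Returns (test_name,
    statistic, p); p is None with a note for degenerate input (all paired
    differences tied at zero).
    """
    if paired:
        x, y = np.asarray(values[0], float), np.asarray(values[1], float)
        if x.shape != y.shape:
            raise ValueError("paired vectors must have equal length")
        diff = x - y
        if np.allclose(diff, 0):
            return ("wilcoxon", np.nan, None)
        res = stats.wilcoxon(x, y)
        return ("wilcoxon", float(res.statistic), float(res.pvalue))
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("compare_groups expects exactly two groups")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    normal = all(
        stats.shapiro(g).pvalue >= SHAPIRO_ALPHA if len(set(g)) > 1 else False
        for g in (a, b)
    )
    if normal:
        res = stats.ttest_ind(a, b)
        return ("t-test", float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ("mann-whitney", float(res.statistic), float(res.pvalue))


def compliance_table(df: pd.DataFrame, grouping: str | None = None) -> pd.DataFrame:
    """Compliance counts and percentages, with a chi-square test across groups.

    ``df`` needs a boolean ``compliant`` column and, when ``grouping`` is
    given, the grouping column; rows with a missing group value are dropped
    from that grouped table. Percentages are reported at full precision
    (rounding is presentation-side).
    """
    def row(label, sub):
        n = len(sub)
        k = int(sub["compliant"].sum())
        return {
            "group": label,
            "n": n,
            "n_compliant": k,
            "pct_compliant": 100.0 * k / n if n else np.nan,
        }

    if grouping is None:
        out = pd.DataFrame([row("all", df)])
        out["p"] = np.nan
        return out
    sub = df[df[grouping].notna()]
    rows, counts = [], []
    for label, g in sub.groupby(grouping, sort=True):
        if len(g) == 0:
            warnings.warn(f"empty group {label!r} omitted", stacklevel=2)
            continue
        rows.append(row(label, g))
        counts.append([int(g["compliant"].sum()), int((~g["compliant"]).sum())])
    out = pd.DataFrame(rows)
    p = np.nan
    table = np.asarray(counts)
    if len(counts) >= 2 and (table.sum(axis=0) > 0).all():
        try:
            p = float(stats.chi2_contingency(table, correction=False).pvalue)
        except ValueError:  # degenerate table (e.g. everyone compliant)
            p = np.nan
    out["p"] = p
    return out


# --- report tables ----------------------------------------------------------

def build_tables(
    df: pd.DataFrame, records_by_subject=None, outdir=None, decimals: int = 1
) -> dict[str, pd.DataFrame]:
    """Cohort report tables (valid-day descriptives, weekly activity by sex,
    percent of days/segments with a bout, OSA contrasts, compliance).

    Returns the tables keyed by name and optionally writes one CSV each.
    """
    tables: dict[str, pd.DataFrame] = {}
    if records_by_subject is not None:
        tables["day_counts"] = _day_count_table(records_by_subject)

    def group_stats(col, by=None):
        rows = []
        scopes = [("all", df)]
        if by is not None:
            scopes += [(str(label), g) for label, g in df.groupby(by, sort=True)]
        for label, g in scopes:
            vals = g[col].dropna()
            rows.append(
                {
                    "group": label,
                    "n": len(vals),
                    "mean": round(float(vals.mean()), decimals) if len(vals) else np.nan,
                    "sd": round(float(vals.std(ddof=1)), decimals) if len(vals) > 1 else np.nan,
                }
            )
        return rows

    pa_rows = []
    for col in (
        "weekly_vpa_in_bouts_min",
        "weekly_VPA_min",
        "weekly_MPA_min",
        "weekly_LPA_min",
        "weekly_MVPA_min",
        "weekly_LMVPA_min",
        "weekly_bout_min",
        "out_of_school_bout_min",
        "osa_min_per_day",
    ):
        if col not in df.columns:
            continue
        for r in group_stats(col, by="sex"):
            pa_rows.append({"variable": col, **r})
    tables["weekly_activity"] = pd.DataFrame(pa_rows)

    pct_rows = []
    for col in [c for c in df.columns if c.startswith("pct_days_bout")]:
        for r in group_stats(col, by="sex"):
            pct_rows.append({"variable": col, **r})
    tables["pct_days_with_bout"] = pd.DataFrame(pct_rows)

    osa_rows = []
    if "osa_binary" in df.columns:
        for col in [c for c in df.columns if c.startswith("pct_days_bout")]:
            for r in group_stats(col, by="osa_binary"):
                osa_rows.append({"variable": col, **r})
    tables["pct_days_with_bout_by_osa"] = pd.DataFrame(osa_rows)

    comp = [compliance_table(df)]
    for grouping in ("sex", "osa_binary"):
        if grouping in df.columns:
            t = compliance_table(df, grouping)
            t.insert(0, "grouping", grouping)
            comp.append(t)
    tables["compliance"] = pd.concat(comp, ignore_index=True)
    tables["compliance"]["pct_compliant"] = tables["compliance"]["pct_compliant"].round(
        decimals
    )

    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(outdir / f"table_{name}.csv", index=False)
    return tables


def _day_count_table(records_by_subject: dict[str, list[DayRecord]]) -> pd.DataFrame:
    rows = []
    specs = {
        "weekly": lambda r: r.analyzable,
        "school": lambda r: r.is_school,
        "school_with_PE": lambda r: r.day_type is DayType.SCHOOL_WITH_PE,
        "school_without_PE": lambda r: r.day_type is DayType.SCHOOL_WITHOUT_PE,
        "weekend": lambda r: r.day_type is DayType.WEEKEND,
    }
    for name, pred in specs.items():
        counts = [
            sum(1 for r in recs if r.valid_day and pred(r))
            for recs in records_by_subject.values()
        ]
        counts = [c for c in counts if c > 0]
        if not counts:
            continue
        arr = np.asarray(counts)
        rows.append(
            {
                "day_type": name,
                "participants": len(arr),
                "min": int(arr.min()),
                "max": int(arr.max()),
                "total_days": int(arr.sum()),
                "mean": round(float(arr.mean()), 1),
                "sd": round(float(arr.std(ddof=1)), 1) if len(arr) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
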