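"""Shared fixtures: class-array builders and a small processed cohort."""

import numpy as np
import pandas as pd
import pytest

from vpabouts.epochs import EPOCHS_PER_DAY, EpochSeries, IntensityClass
from vpabouts.pipeline import process_subject
from vpabouts.simulate import generate_cohort
from vpabouts.summarize import summarize_subject

#: representative ENMO (mg) per intensity class, inside each cut-point band
CLASS_ENMO = {
    IntensityClass.SEDENTARY: 10.0,
    IntensityClass.LPA: 100.0,
    IntensityClass.MPA: 400.0,
    IntensityClass.VPA: 900.0,
}


def series_from_classes(
    classes,
    wear=None,
    start="2020-01-13",
    subject_id="T001",
    seed=0,
) -> EpochSeries:
    """Build an EpochSeries whose ENMO encodes the given class sequence.

    The tilt angle jitters enough that the strict non-wear rule never fires
    unless a test constructs stillness explicitly.
    """
    classes = np.asarray(classes, dtype=np.int8)
    rng = np.random.default_rng(seed)
    enmo = np.array([CLASS_ENMO[IntensityClass(c)] for c in classes], dtype=float)
    angle = rng.uniform(-60, 60, size=classes.size)
    if wear is None:
        wear = np.ones(classes.size, dtype=bool)
    return EpochSeries(
        subject_id=subject_id,
        start=pd.Timestamp(start),
        enmo=enmo,
        angle_z=angle,
        wear=np.asarray(wear, dtype=bool),
    )


def day_of(classes_by_day):
    """Concatenate per-day class arrays (each padded to a full day)."""
    out = []
    for day in classes_by_day:
        arr = np.zeros(EPOCHS_PER_DAY, dtype=np.int8)
        arr[: len(day)] = day
        out.append(arr)
    return np.concatenate(out)


@pytest.fixture(scope="session")
def small_cohort():
    """Six synthetic subjects processed end to end (fixed seed)."""
    subjects = generate_cohort(6, seed=1)
    processed = []
    for s in subjects:
        res = process_subject(
            s.series, s.plan.sex, s.plan.calendar(), absences=s.plan.absences()
        )
        summ = (
            summarize_subject(res, osa_hours=s.plan.osa_hours)
            if res.assessment.valid
            else None
        )
        processed.append((s, res, summ))
    return processed
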