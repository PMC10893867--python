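"""Epoch data model, raw-to-epoch conversion and intensity classification.

The pipeline works on 5-second epochs of ENMO (Euclidean norm minus one,
negative values truncated to zero, expressed in milligravitational units, mg)
plus a z-axis tilt angle, as produced by wrist-worn triaxial accelerometers.
Intensity classes follow the wrist cut-points for children (non-dominant
wrist, ENMO): sedentary < 56.3 mg <= LPA < 191.6 mg <= MPA < 695.8 mg <= VPA.
Class intervals are half-open and lower-inclusive; the boundary convention is
a documented choice since prose definitions ("over 695.8 mg") are ambiguous
on measure-zero sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .errors import FormatError

EPOCH_SECONDS = 5
EPOCHS_PER_MINUTE = 60 // EPOCH_SECONDS          # 12
EPOCHS_PER_HOUR = 3600 // EPOCH_SECONDS          # 720
EPOCHS_PER_DAY = 24 * EPOCHS_PER_HOUR            # 17280


def tod_epoch(hour: int, minute: int = 0, second: int = 0) -> int:
    """Epoch-of-day index of a wall-clock time (local clock, no DST)."""
    return (hour * 3600 + minute * 60 + second) // EPOCH_SECONDS


class IntensityClass(IntEnum):
    SEDENTARY = 0
    LPA = 1
    MPA = 2
    VPA = 3


@dataclass(frozen=True)
class IntensityCutpoints:
    """ENMO cut-points (mg) separating the four intensity classes."""

    light_lo: float = 56.3
    mod_lo: float = 191.6
    vig_lo: float = 695.8

    def __post_init__(self) -> None:
        if not (0.0 < self.light_lo < self.mod_lo < self.vig_lo):
            raise ValueError(
                "cut-points must satisfy 0 < light_lo < mod_lo < vig_lo, got "
                f"{self.light_lo}, {self.mod_lo}, {self.vig_lo}"
            )

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.light_lo, self.mod_lo, self.vig_lo])


DEFAULT_CUTPOINTS = IntensityCutpoints()


@dataclass
class EpochSeries:
    """One subject's gap-free 5-second epoch stream.

    ``start`` is the timestamp of the first epoch; epoch ``i`` covers
    ``start + 5i`` seconds. Non-wear is flagged (``wear``), never deleted,
    so the grid has no gaps. ``classes`` (intensity per epoch) and
    ``imputed`` (epoch filled by the imputation step) are populated by the
    downstream stages and default to None.
    """

    subject_id: str
    start: pd.Timestamp
    enmo: np.ndarray
    angle_z: np.ndarray
    wear: np.ndarray
    classes: np.ndarray | None = None
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.enmo = np.asarray(self.enmo, dtype=float)
        self.angle_z = np.asarray(self.angle_z, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        n = self.enmo.shape[0]
        if self.angle_z.shape[0] != n or self.wear.shape[0] != n:
            raise ValueError("enmo, angle_z and wear must have equal length")
        if np.any(self.enmo < 0):
            raise ValueError("ENMO must be non-negative")
        if np.any(np.abs(self.angle_z) > 90 + 1e-9):
            raise ValueError("angle_z must lie in [-90, 90] degrees")
        if (self.start.value // 10**9) % EPOCH_SECONDS != 0:
            raise ValueError("series must start on the 5-second grid")
        if self.classes is not None:
            self.classes = np.asarray(self.classes, dtype=np.int8)
        if self.imputed is not None:
            self.imputed = np.asarray(self.imputed, dtype=bool)

    @property
    def n(self) -> int:
        return self.enmo.shape[0]

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n, freq=f"{EPOCH_SECONDS}s")

    @property
    def n_days(self) -> int:
        if (self.start - self.start.normalize()).value != 0:
            raise ValueError("day arithmetic requires a midnight-aligned series")
        return int(np.ceil(self.n / EPOCHS_PER_DAY))

    def day_bounds(self, day: int) -> tuple[int, int]:
        """Epoch index range [lo, hi) of calendar day ``day`` (0-based)."""
        lo = day * EPOCHS_PER_DAY
        return lo, min(lo + EPOCHS_PER_DAY, self.n)

    def date_of_day(self, day: int):
        return (self.start.normalize() + pd.Timedelta(days=day)).date()

    def countable(self) -> np.ndarray:
        """Epochs that contribute to minutes and bouts: worn or imputed."""
        mask = self.wear.copy()
        if self.imputed is not None:
            mask |= self.imputed
        return mask

    def ensure_classes(
        self, cutpoints: IntensityCutpoints = DEFAULT_CUTPOINTS
    ) -> np.ndarray:
        if self.classes is None:
            self.classes = classify_intensity(self.enmo, cutpoints)
            self.imputed = np.zeros(self.n, dtype=bool)
        return self.classes


def classify_intensity(enmo, cutpoints: IntensityCutpoints = DEFAULT_CUTPOINTS):
    """Map ENMO (mg) to intensity classes.

    Half-open, lower-inclusive intervals: a value equal to a cut-point
    belongs to the class above it (695.8 mg -> VPA). Scalars return an
    IntensityClass, arrays an int8 array.
    """
    arr = np.asarray(enmo, dtype=float)
    if np.any(arr < 0):
        raise ValueError("ENMO must be non-negative")
    codes = np.searchsorted(cutpoints.edges, arr, side="right").astype(np.int8)
    if np.isscalar(enmo) or arr.ndim == 0:
        return IntensityClass(int(codes))
    return codes


#: aggregate classes reported alongside the four base classes
_AGGREGATES = {
    "MVPA": (IntensityClass.MPA, IntensityClass.VPA),
    "LMVPA": (IntensityClass.LPA, IntensityClass.MPA, IntensityClass.VPA),
}


def minutes_by_intensity(
    series: EpochSeries,
    start: int | None = None,
    end: int | None = None,
    cutpoints: IntensityCutpoints = DEFAULT_CUTPOINTS,
) -> dict[str, float]:
    """Minutes per intensity class over epochs [start, end).

    Counts worn epochs plus imputed epochs (epochs = minutes * 12). Reports
    the four base classes plus MVPA and LMVPA; the base classes partition
    the countable time exactly.
    """
    start = 0 if start is None else int(start)
    end = series.n if end is None else int(end)
    if end <= start:
        warnings.warn("empty interval: zero minutes", stacklevel=2)
        keys = [c.name for c in IntensityClass] + list(_AGGREGATES)
        return {k: 0.0 for k in keys}
    cls = series.ensure_classes(cutpoints)[start:end]
    mask = series.countable()[start:end]
    out: dict[str, float] = {}
    for c in IntensityClass:
        out[c.name] = float(np.sum(mask & (cls == c)) / EPOCHS_PER_MINUTE)
    for name, members in _AGGREGATES.items():
        out[name] = float(sum(out[m.name] for m in members))
    return out


def raw_to_epochs(
    raw: pd.DataFrame,
    fs: float,
    epoch_len: int = EPOCH_SECONDS,
    subject_id: str = "unknown",
) -> EpochSeries:
    """Summarize raw triaxial acceleration (g) into ENMO/angle epochs.

    Per sample: ENMO = max(sqrt(x^2+y^2+z^2) - 1, 0), in mg. Per epoch:
    ENMO = mean of sample ENMO (truncation happens before averaging);
    angle_z = atan(mean_z / sqrt(mean_x^2 + mean_y^2)) in degrees, from the
    per-epoch axis means. A trailing partial epoch is dropped.
    """
    required = {"timestamp", "x_g", "y_g", "z_g"}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"raw input missing column(s): {sorted(missing)}")
    ts = pd.to_datetime(raw["timestamp"])
    if len(ts) > 1:
        steps = np.diff(ts.values.astype("datetime64[ns]").astype(np.int64))
        expected = round(1e9 / fs)
        if np.any(np.abs(steps - expected) > 1e6):  # 1 ms jitter allowance
            bad = int(np.argmax(np.abs(steps - expected) > 1e6))
            raise FormatError(
                f"non-uniform sampling at row {bad + 1}: expected {1/fs:.6f} s steps"
            )
    spe = fs * epoch_len
    if abs(spe - round(spe)) > 1e-9:
        raise FormatError("fs * epoch_len must be an integer number of samples")
    spe = int(round(spe))
    n_epochs = len(raw) // spe
    if n_epochs == 0:
        raise FormatError("raw record shorter than one epoch")
    x = raw["x_g"].to_numpy(float)[: n_epochs * spe].reshape(n_epochs, spe)
    y = raw["y_g"].to_numpy(float)[: n_epochs * spe].reshape(n_epochs, spe)
    z = raw["z_g"].to_numpy(float)[: n_epochs * spe].reshape(n_epochs, spe)
    enmo_samples = np.maximum(np.sqrt(x**2 + y**2 + z**2) - 1.0, 0.0) * 1000.0
    enmo = enmo_samples.mean(axis=1)
    xb, yb, zb = x.mean(axis=1), y.mean(axis=1), z.mean(axis=1)
    angle = np.degrees(np.arctan2(zb, np.sqrt(xb**2 + yb**2)))
    return EpochSeries(
        subject_id=subject_id,
        start=ts.iloc[0],
        enmo=enmo,
        angle_z=angle,
        wear=np.ones(n_epochs, dtype=bool),
    )


_EPOCH_COLUMNS = ["subject_id", "timestamp", "enmo_mg", "angle_z_deg", "wear"]


def write_epochs(series: EpochSeries, path, decimals: int = 4) -> None:
    """Write the epoch CSV dialect (one subject per file)."""
    df = pd.DataFrame(
        {
            "subject_id": series.subject_id,
            "timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "enmo_mg": np.round(series.enmo, decimals),
            "angle_z_deg": np.round(series.angle_z, decimals),
            "wear": series.wear.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_epochs(path) -> EpochSeries:
    """Read and validate the epoch CSV dialect.

    Raises FormatError (with the offending row, 1-based data rows) for
    missing columns, non-numeric cells, or timestamps off the 5-s grid.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in _EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df["subject_id"].nunique() > 1:
        raise FormatError(f"{path}: expected a single subject per file")
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    if ts.isna().any():
        row = int(ts.isna().idxmax()) + 1
        raise FormatError(f"{path}: unparseable timestamp at row {row}")
    steps = np.diff(ts.values.astype("datetime64[s]").astype(np.int64))
    bad = np.flatnonzero(steps != EPOCH_SECONDS)
    if bad.size:
        raise FormatError(
            f"{path}: broken 5-s epoch grid between rows {bad[0] + 1} and {bad[0] + 2}"
        )
    for col in ("enmo_mg", "angle_z_deg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 1
            raise FormatError(f"{path}: non-numeric value in '{col}' at row {row}")
        df[col] = vals
    return EpochSeries(
        subject_id=str(df["subject_id"].iloc[0]),
        start=ts.iloc[0],
        enmo=df["enmo_mg"].to_numpy(float),
        angle_z=df["angle_z_deg"].to_numpy(float),
        wear=df["wear"].astype(bool).to_numpy(),
    )
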