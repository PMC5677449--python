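"""Data model, validation and serialization for event-sampled spiral-drawing traces.

A *trial* is one drawn spiral: an ordered sequence of touch samples
``(x px, y px, t ms)`` emitted whenever the pen position changed
(event-based sampling, so inter-sample intervals are irregular).  Trials
are grouped three to a *test occasion*, occasions belong to a *subject*,
and subjects carry the study design variables (group, age, gender,
minutes-from-dose schedule, optional mean clinical ratings).

The on-disk format is a flat delimited trace table, one row per sample,
with subject/occasion metadata repeated per row.  It round-trips exactly
and diffs cleanly; see :func:`read_cohort` / :func:`write_cohort`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, TrialValidationError

#: The seven mean clinical rating scales an occasion may carry: six
#: UPDRS part-III motor items (finger tapping, alternating hand
#: movements, leg agility, arising from chair, gait, bradykinesia) and a
#: 0-4 dyskinesia severity scale.
RATING_SCALES: tuple[str, ...] = (
    "updrs23",
    "updrs25",
    "updrs26",
    "updrs27",
    "updrs29",
    "updrs31",
    "dys",
)

GROUPS: tuple[str, ...] = ("healthy", "early", "intermediate", "advanced")
PATIENT_GROUPS: tuple[str, ...] = ("early", "intermediate", "advanced")

#: Trace-table columns, in canonical order (rating columns are optional).
TRACE_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "group",
    "age",
    "gender",
    "occasion_minutes",
    "trial_index",
    "x_px",
    "y_px",
    "t_ms",
)


class SpiralSample(NamedTuple):
    """One touch event: screen position in pixels, time in ms from trial start."""

    x: float
    y: float
    t: float


@dataclass(frozen=True)
class DeviceSpec:
    """Touch-screen geometry.  Origin is top-left (touch-event convention)."""

    width_px: int = 480
    height_px: int = 800
    ppi: float = 233.0


@dataclass
class SpiralTrial:
    """One spiral drawing: parallel coordinate/time arrays plus a trial index (1-3)."""

    x: np.ndarray
    y: np.ndarray
    t_ms: np.ndarray
    trial_index: int = 1
    device: DeviceSpec = field(default_factory=DeviceSpec)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        if not (self.x.shape == self.y.shape == self.t_ms.shape):
            raise TrialValidationError("x, y and t_ms must have equal length")

    def __len__(self) -> int:
        return self.x.size

    @property
    def samples(self) -> Iterator[SpiralSample]:
        for xi, yi, ti in zip(self.x, self.y, self.t_ms):
            yield SpiralSample(float(xi), float(yi), float(ti))

    @property
    def duration_s(self) -> float:
        """Elapsed time between first and last sample, in seconds."""
        if len(self) < 2:
            return 0.0
        return float(self.t_ms[-1] - self.t_ms[0]) / 1000.0


@dataclass
class TestOccasion:
    """Up to three trials drawn at one scheduled time point.

    ``minutes_from_dose`` is signed minutes relative to levodopa intake
    for patients (baseline is -20); for healthy subjects it is minutes
    from their first test, stored in the same field.
    ``ratings`` maps a scale name from :data:`RATING_SCALES` to the mean
    score (over three raters) on that 0-4 scale, or is ``None``.
    """

    minutes_from_dose: float
    trials: list[SpiralTrial]
    ratings: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.trials) <= 3:
            raise TrialValidationError(
                f"occasion at {self.minutes_from_dose} min has {len(self.trials)} "
                "trials; expected 1-3"
            )
        if self.ratings is not None:
            for key, value in self.ratings.items():
                if key not in RATING_SCALES:
                    raise TrialValidationError(f"unknown rating scale {key!r}")
                if not 0.0 <= value <= 4.0:
                    raise TrialValidationError(
                        f"rating {key}={value} outside [0, 4]"
                    )


@dataclass
class SubjectRecord:
    """One participant with their ordered test occasions."""

    subject_id: str
    group: str
    age: float
    gender: str
    occasions: list[TestOccasion]
    years_on_levodopa: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise TrialValidationError(
                f"group {self.group!r} not one of {GROUPS}"
            )
        if self.group == "healthy":
            if any(o.ratings for o in self.occasions):
                raise TrialValidationError(
                    f"healthy subject {self.subject_id} must not carry ratings"
                )
            if self.years_on_levodopa is not None:
                raise TrialValidationError(
                    f"healthy subject {self.subject_id} must not carry levodopa years"
                )

    @property
    def is_patient(self) -> bool:
        return self.group in PATIENT_GROUPS


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_trial`."""

    invariant: str
    index: int
    message: str


def validate_trial(trial: SpiralTrial) -> list[Violation]:
    """Check a trial against the data-model invariants.

    Returns an empty list iff the trial is valid; violations are
    returned, never raised.  Checked invariants: at least 3 samples,
    strictly increasing timestamps, non-negative times, and coordinates
    within the device screen bounds.
    """
    violations: list[Violation] = []
    n = len(trial)
    if n < 3:
        violations.append(
            Violation("min_samples", n, f"trial has {n} samples; at least 3 required")
        )
    if n and trial.t_ms[0] < 0:
        violations.append(
            Violation("nonnegative_time", 0, f"t={trial.t_ms[0]} ms is negative")
        )
    if n >= 2:
        bad = np.nonzero(np.diff(trial.t_ms) <= 0)[0]
        for i in bad:
            violations.append(
                Violation(
                    "strictly_increasing_time",
                    int(i) + 1,
                    f"t[{i + 1}]={trial.t_ms[i + 1]} ms does not exceed "
                    f"t[{i}]={trial.t_ms[i]} ms",
                )
            )
    dev = trial.device
    out_x = np.nonzero((trial.x < 0) | (trial.x > dev.width_px))[0]
    out_y = np.nonzero((trial.y < 0) | (trial.y > dev.height_px))[0]
    for i in out_x:
        violations.append(
            Violation("x_in_bounds", int(i), f"x[{i}]={trial.x[i]} outside [0, {dev.width_px}]")
        )
    for i in out_y:
        violations.append(
            Violation("y_in_bounds", int(i), f"y[{i}]={trial.y[i]} outside [0, {dev.height_px}]")
        )
    return violations


def require_valid(trial: SpiralTrial, context: str = "") -> None:
    """Raise :class:`TrialValidationError` if the trial fails validation."""
    violations = validate_trial(trial)
    if violations:
        where = f" ({context})" if context else ""
        detail = "; ".join(v.message for v in violations[:5])
        raise TrialValidationError(f"invalid trial{where}: {detail}")


def downsample_every_second(trial: SpiralTrial) -> SpiralTrial:
    """Keep every second sample, starting with the first.

    Event-based touch sampling on the study device ran faster than the
    reference device the score was developed on; halving the rate keeps
    the effective sampling comparable.  Samples at original even indices
    0, 2, 4, ... are kept, so the trial-start sample always survives and
    the output length is ``ceil(n / 2)``.
    """
    if len(trial) < 2:
        raise DegenerateInputError(
            f"cannot downsample a trial with {len(trial)} sample(s)"
        )
    return SpiralTrial(
        x=trial.x[::2].copy(),
        y=trial.y[::2].copy(),
        t_ms=trial.t_ms[::2].copy(),
        trial_index=trial.trial_index,
        device=trial.device,
    )


def _trial_frame(subject: SubjectRecord, occ: TestOccasion, trial: SpiralTrial,
                 rating_cols: Sequence[str]) -> pd.DataFrame:
    n = len(trial)
    data: dict[str, object] = {
        "subject_id": np.repeat(subject.subject_id, n),
        "group": np.repeat(subject.group, n),
        "age": np.repeat(float(subject.age), n),
        "gender": np.repeat(subject.gender, n),
        "occasion_minutes": np.repeat(float(occ.minutes_from_dose), n),
        "trial_index": np.repeat(int(trial.trial_index), n),
        "x_px": trial.x,
        "y_px": trial.y,
        "t_ms": trial.t_ms,
    }
    for col in rating_cols:
        val = math.nan if occ.ratings is None else occ.ratings.get(col, math.nan)
        data[col] = np.repeat(float(val), n)
    return pd.DataFrame(data)


def _with_levodopa(frame: pd.DataFrame, subject: SubjectRecord) -> pd.DataFrame:
    value = subject.years_on_levodopa
    frame["years_on_levodopa"] = math.nan if value is None else float(value)
    return frame


def write_cohort(records: Iterable[SubjectRecord], path: str, sep: str = ",") -> str:
    """Write a cohort to a flat trace table (one row per touch sample).

    Rows are sorted by subject, occasion minutes, trial index, then
    time, and the column order is canonical, so output is deterministic
    and ``read_cohort(write_cohort(x)) == x``.  Rating columns are
    emitted only if some occasion carries ratings.
    """
    records = list(records)
    has_ratings = any(
        occ.ratings for rec in records for occ in rec.occasions
    )
    has_levodopa = any(rec.years_on_levodopa is not None for rec in records)
    rating_cols = list(RATING_SCALES) if has_ratings else []
    frames = [
        _with_levodopa(_trial_frame(rec, occ, trial, rating_cols), rec)
        if has_levodopa
        else _trial_frame(rec, occ, trial, rating_cols)
        for rec in sorted(records, key=lambda r: r.subject_id)
        for occ in sorted(rec.occasions, key=lambda o: o.minutes_from_dose)
        for trial in sorted(occ.trials, key=lambda t: t.trial_index)
    ]
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        extra = ["years_on_levodopa"] if has_levodopa else []
        table = pd.DataFrame(columns=list(TRACE_COLUMNS) + rating_cols + extra)
    table.to_csv(path, sep=sep, index=False)
    return path


def read_cohort(path: str, sep: str = ",", device: DeviceSpec | None = None,
                validate: bool = True) -> list[SubjectRecord]:
    """Read a trace table written by :func:`write_cohort` (or equivalent).

    Required columns: ``subject_id, group, age, gender, occasion_minutes,
    trial_index, x_px, y_px, t_ms``; the seven rating columns are
    optional.  Samples are sorted by time within each trial; with
    ``validate=True`` (default) every trial must pass
    :func:`validate_trial`.

    Raises
    ------
    FormatError
        If a required column is missing (the message names it).
    TrialValidationError
        If a trial violates an invariant (the message identifies
        subject, occasion and trial).
    """
    device = device or DeviceSpec()
    table = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in TRACE_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"trace table {path!r} is missing column {col!r}")
    rating_cols = [c for c in RATING_SCALES if c in table.columns]

    records: list[SubjectRecord] = []
    for subject_id, sub in table.groupby("subject_id", sort=True):
        group = str(sub["group"].iloc[0])
        age = float(sub["age"].iloc[0])
        gender = str(sub["gender"].iloc[0])
        occasions: list[TestOccasion] = []
        for minutes, occ_rows in sub.groupby("occasion_minutes", sort=True):
            trials: list[SpiralTrial] = []
            for trial_index, trial_rows in occ_rows.groupby("trial_index", sort=True):
                trial_rows = trial_rows.sort_values("t_ms", kind="stable")
                trial = SpiralTrial(
                    x=trial_rows["x_px"].to_numpy(dtype=float),
                    y=trial_rows["y_px"].to_numpy(dtype=float),
                    t_ms=trial_rows["t_ms"].to_numpy(dtype=float),
                    trial_index=int(trial_index),
                    device=device,
                )
                if validate:
                    require_valid(
                        trial,
                        context=f"subject {subject_id}, occasion {minutes} min, "
                        f"trial {trial_index}",
                    )
                trials.append(trial)
            ratings: dict[str, float] | None = None
            if rating_cols:
                vals = {c: float(occ_rows[c].iloc[0]) for c in rating_cols}
                vals = {k: v for k, v in vals.items() if not math.isnan(v)}
                ratings = vals or None
            occasions.append(
                TestOccasion(
                    minutes_from_dose=float(minutes),
                    trials=trials,
                    ratings=ratings,
                )
            )
        years = None
        if "years_on_levodopa" in sub.columns:
            raw = float(sub["years_on_levodopa"].iloc[0])
            years = None if math.isnan(raw) else raw
        records.append(
            SubjectRecord(
                subject_id=str(subject_id),
                group=group,
                age=age,
                gender=gender,
                occasions=occasions,
                years_on_levodopa=years,
            )
        )
    return records
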