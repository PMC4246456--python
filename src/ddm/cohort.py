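"""Duration-event cohorts and their CSV representation.

A cohort is the basic unit of analysis: one observed duration per subject
(months from treatment start) together with an event indicator — ``True``
when the subject recovered at that time, ``False`` when the episode
outlasted follow-up and the duration is right-censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import CsvFormatError, ValidationError

CSV_COLUMNS = ("time_months", "event")


@dataclass(frozen=True)
class StudyDesign:
    """Follow-up design of a prospective duration study.

    Parameters
    ----------
    n_subjects
        Cohort size.
    censor_horizon
        Administrative censoring time in months: subjects still in episode
        at this time contribute a right-censored duration.
    duration_floor
        Shortest recordable duration in months. Recoveries within days of
        treatment start are conventionally recorded at this floor.
    seed
        Seed for the generator that simulates the cohort.
    """

    n_subjects: int
    censor_horizon: float = 24.0
    duration_floor: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not self.censor_horizon > 0:
            raise ValidationError("censor_horizon must be positive")
        if not self.duration_floor > 0:
            raise ValidationError("duration_floor must be positive")
        if not self.duration_floor < self.censor_horizon:
            raise ValidationError("duration_floor must be below censor_horizon")


@dataclass(frozen=True)
class DurationRecord:
    """One subject's observed duration (months) and event status."""

    time: float
    event: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValidationError(f"duration must be positive, got {self.time}")


class Cohort:
    """A set of duration records, optionally tied to a study design.

    Data are held as parallel numpy arrays for efficiency; ``records``
    materialises ``DurationRecord`` objects on demand.
    """

    def __init__(
        self,
        times: Sequence[float] | np.ndarray,
        events: Sequence[bool] | np.ndarray,
        design: StudyDesign | None = None,
    ):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=bool)
        if times.ndim != 1 or times.shape != events.shape:
            raise ValidationError("times and events must be 1-d arrays of equal length")
        if times.size == 0:
            raise ValidationError("cohort must contain at least one record")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise ValidationError("all durations must be positive and finite")
        if design is not None:
            if times.size != design.n_subjects:
                raise ValidationError(
                    f"cohort has {times.size} records but design expects "
                    f"{design.n_subjects}"
                )
            if np.any(times < design.duration_floor - 1e-12):
                raise ValidationError("durations below the design duration_floor")
            censored = ~events
            if np.any(np.abs(times[censored] - design.censor_horizon) > 1e-12):
                raise ValidationError(
                    "censored durations must equal the censor horizon "
                    "(administrative censoring only)"
                )
        self.times = times
        self.events = events
        self.design = design

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.times.size

    def __iter__(self) -> Iterator[DurationRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.events, other.events)
        )

    def __repr__(self) -> str:
        return (
            f"Cohort(n={len(self)}, events={self.n_events}, "
            f"censored={self.n_censored})"
        )

    # -- derived views -----------------------------------------------------
    @property
    def records(self) -> list[DurationRecord]:
        return [DurationRecord(t, bool(e)) for t, e in zip(self.times, self.events)]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def n_censored(self) -> int:
        return int((~self.events).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {CSV_COLUMNS[0]: self.times, CSV_COLUMNS[1]: self.events.astype(int)}
        )


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV with header ``time_months,event``."""
    cohort.to_frame().to_csv(path, index=False)


def read_cohort(path, design: StudyDesign | None = None) -> Cohort:
    """Read a duration-event CSV.

    The file must carry the header ``time_months,event`` with positive
    durations and event values in {0, 1}.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CsvFormatError(f"{path}: empty file") from exc
    except (pd.errors.ParserError, OSError) as exc:
        raise CsvFormatError(f"{path}: {exc}") from exc

    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CsvFormatError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{','.join(CSV_COLUMNS)}"
        )

    times = pd.to_numeric(frame[CSV_COLUMNS[0]], errors="coerce")
    events = pd.to_numeric(frame[CSV_COLUMNS[1]], errors="coerce")
    # +2: header line plus 1-based numbering
    bad_time = times.isna() | ~np.isfinite(times) | (times <= 0)
    if bad_time.any():
        line = int(np.flatnonzero(bad_time.to_numpy())[0]) + 2
        raise ValidationError(
            f"{path}: line {line}: time_months must be a positive number"
        )
    bad_event = events.isna() | ~events.isin([0, 1])
    if bad_event.any():
        line = int(np.flatnonzero(bad_event.to_numpy())[0]) + 2
        raise ValidationError(f"{path}: line {line}: event must be 0 or 1")

    return Cohort(times.to_numpy(float), events.to_numpy(int).astype(bool), design)
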