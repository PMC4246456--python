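"""Product-limit (Kaplan–Meier) estimation of episode survival.

``S(t)`` is the probability of still being in the index episode at time
``t``; it is estimated as the product over event times up to ``t`` of
``(1 - d_i / n_i)`` with ``d_i`` recoveries among ``n_i`` subjects still
at risk. Subjects censored at an event time are counted in that time's
risk set (censoring resolves after events at ties). The curve is a
right-continuous step function, so "fraction recovered by t" includes
recoveries at exactly ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .cohort import Cohort
from .errors import InsufficientDataError, MedianUndefinedError

_TOL = 1e-12


@dataclass(frozen=True)
class SurvivalCurve:
    """Step-function survival estimate over the distinct event times.

    ``survival[i]`` is S just after ``times[i]``; ``n_censored_between[i]``
    counts censorings in ``[times[i-1], times[i])`` (index 0: before the
    first event time; a trailing entry counts censorings at or after the
    last event time).
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored_between: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > _TOL):
            raise ValueError("survival estimates must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t) evaluated as a right-continuous step function (1 before
        the first event time)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def fraction_recovered_by(self, t: float) -> float:
        return 1.0 - self.survival_at(t)

    def median(self) -> float:
        below = np.flatnonzero(self.survival <= 0.5 + _TOL)
        if below.size == 0:
            raise MedianUndefinedError(
                "survival never drops to 0.5 within the observed range"
            )
        return float(self.times[below[0]])


def kaplan_meier(cohort: Cohort) -> SurvivalCurve:
    """Fit the product-limit estimator to a right-censored cohort."""
    if cohort.n_events == 0:
        raise InsufficientDataError(
            "all records are censored; the survival curve is undefined below 1"
        )
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.times, event_observed=cohort.events)

    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    survival = kmf.survival_function_["KM_estimate"].reindex(event_rows.index)
    survival = survival.to_numpy(dtype=float)
    n_at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    n_events = event_rows["observed"].to_numpy(dtype=int)

    # censorings binned between successive event times; ties go with the
    # interval that starts at the event time (risk-set convention above)
    censor_times = np.repeat(
        table.index.to_numpy(dtype=float), table["censored"].to_numpy(dtype=int)
    )
    bins = np.searchsorted(times, censor_times, side="right")
    n_censored_between = np.bincount(bins, minlength=times.size + 1)

    return SurvivalCurve(times, survival, n_at_risk, n_events, n_censored_between)


def median_time(curve: SurvivalCurve) -> float:
    """Smallest event time at which S(t) has dropped to 0.5 or below."""
    return curve.median()


def fraction_recovered_by(curve: SurvivalCurve, t: float) -> float:
    """1 - S(t): the estimated fraction recovered by time ``t``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return curve.fraction_recovered_by(t)
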