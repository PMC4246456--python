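"""Censored maximum-likelihood fits of parametric duration models.

Three families are supported, with fixed parameterisations (months):

- exponential: S(t) = exp(-t/theta), theta the mean/scale;
- Weibull: S(t) = exp(-(t/alpha)^beta), alpha scale, beta shape;
- log-normal: S(t) = 1 - Phi((ln t - mu)/sigma), natural logarithm.

The likelihood is the standard right-censored one,
ell = sum_events ln f(t_i) + sum_censored ln S(t_i).
The exponential MLE is closed form (total observed time over event
count); Weibull and log-normal are maximised numerically via lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from lifelines import LogNormalFitter, WeibullFitter
from lifelines.exceptions import ConvergenceError

from .cohort import Cohort
from .datagen import GeneratorSpec
from .errors import ComparisonError, DomainError, FitError

FAMILY_PARAM_NAMES = {
    "exponential": ("theta",),
    "weibull": ("alpha", "beta"),
    "lognormal": ("mu", "sigma"),
}


@dataclass(frozen=True)
class ParametricFit:
    family: str
    params: Mapping[str, float]
    loglik: float
    converged: bool
    n_events: int
    n_censored: int
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(FAMILY_PARAM_NAMES[self.family])

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    def survival(self, t) -> float | np.ndarray:
        return survival_function(self, t)


def censored_loglik(family: str, params: Mapping[str, float],
                    cohort: Cohort) -> float:
    """Right-censored log-likelihood of ``params`` on ``cohort``."""
    dist = GeneratorSpec(family, params).distribution()
    ev = cohort.events
    return float(dist.logpdf(cohort.times[ev]).sum()
                 + dist.logsf(cohort.times[~ev]).sum())


def _require_events(cohort: Cohort, minimum_distinct: int, family: str) -> None:
    if cohort.n_events == 0:
        raise FitError(f"{family}: no events to fit")
    if minimum_distinct > 1:
        distinct = np.unique(cohort.times[cohort.events]).size
        if distinct < minimum_distinct:
            raise FitError(
                f"{family}: needs >= {minimum_distinct} distinct event times, "
                f"got {distinct}"
            )


def fit_exponential(cohort: Cohort) -> ParametricFit:
    """Closed-form censored MLE: theta = total observed time / event count."""
    _require_events(cohort, 1, "exponential")
    theta = float(cohort.times.sum()) / cohort.n_events
    params = {"theta": theta}
    return ParametricFit(
        "exponential", params, censored_loglik("exponential", params, cohort),
        converged=True, n_events=cohort.n_events, n_censored=cohort.n_censored,
    )


def _fit_lifelines(cohort: Cohort, family: str, fitter_cls,
                   param_map: Mapping[str, str]) -> ParametricFit:
    _require_events(cohort, 2, family)
    fitter = fitter_cls()
    try:
        fitter.fit(cohort.times, event_observed=cohort.events)
        params = {ours: float(getattr(fitter, theirs))
                  for ours, theirs in param_map.items()}
        converged, message = True, ""
        loglik = censored_loglik(family, params, cohort)
    except (ConvergenceError, ValueError, RuntimeError,
            np.linalg.LinAlgError) as exc:
        params = {ours: float("nan") for ours in param_map}
        converged, message, loglik = False, str(exc), float("-inf")
    return ParametricFit(family, params, loglik, converged,
                         cohort.n_events, cohort.n_censored, message)


def fit_weibull(cohort: Cohort) -> ParametricFit:
    """Numeric censored MLE of the Weibull scale and shape."""
    return _fit_lifelines(cohort, "weibull", WeibullFitter,
                          {"alpha": "lambda_", "beta": "rho_"})


def fit_lognormal(cohort: Cohort) -> ParametricFit:
    """Numeric censored MLE of the log-normal log-mean and log-sd."""
    return _fit_lifelines(cohort, "lognormal", LogNormalFitter,
                          {"mu": "mu_", "sigma": "sigma_"})


FITTERS = {
    "exponential": fit_exponential,
    "weibull": fit_weibull,
    "lognormal": fit_lognormal,
}


def fit_all(cohort: Cohort) -> list[ParametricFit]:
    return [fit(cohort) for fit in FITTERS.values()]


def survival_function(fit: ParametricFit, t) -> float | np.ndarray:
    """Fitted S(t) under the fit's family; t must be positive."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise DomainError("survival_function requires t > 0")
    out = GeneratorSpec(fit.family, fit.params).distribution().sf(t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def compare_models(fits: list[ParametricFit]) -> list[ParametricFit]:
    """Rank fits by AIC (2k - 2 ell), ties broken by fewer parameters.

    All fits must come from the same cohort, checked via matching event
    and censoring counts.
    """
    if len(fits) <= 1:
        return list(fits)
    counts = {(f.n_events, f.n_censored) for f in fits}
    if len(counts) > 1:
        raise ComparisonError(
            f"fits disagree on cohort composition: {sorted(counts)}"
        )
    return sorted(fits, key=lambda f: (f.aic, f.n_params))
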