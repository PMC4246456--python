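"""Power-law trend on double-logarithmic axes and the hazard ∝ 1/t model.

A survival curve S(t) = A·t^(-k) is a straight line in log10–log10
coordinates, with slope -k and intercept log10 A. ``fit_loglog_trend``
estimates that line by ordinary least squares on the KM event-time
points. The same survival law is the closed-form solution of the
differential equation dN/dt = -k·N/t — a cohort whose instantaneous
recovery rate (hazard) decays as k/t — which ``verify_ode_solution``
checks numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError, ParameterError
from .km import SurvivalCurve


@dataclass(frozen=True)
class PowerLawTrend:
    """OLS line log10 S = intercept + slope · log10 t."""

    intercept: float
    slope: float
    r_squared: float
    n_points: int

    @property
    def k(self) -> float:
        """Power-law exponent (positive when survival decays)."""
        return -self.slope

    @property
    def A(self) -> float:
        """Survival-scale prefactor: S(1 month) on the fitted line."""
        return 10.0 ** self.intercept


@dataclass(frozen=True)
class OdeModel:
    """Survival N(t) = A·t^(-k) on [t_min, ∞), hazard k/t."""

    k: float
    A: float
    t_min: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 0 or self.A <= 0 or self.t_min <= 0:
            raise ParameterError("OdeModel requires k >= 0, A > 0, t_min > 0")


@dataclass(frozen=True)
class ResidualReport:
    """Finite-difference check that A·t^(-k) solves dN/dt = -kN/t."""

    max_abs_residual: float
    step: float
    n_grid: int


def fit_loglog_trend(curve: SurvivalCurve) -> PowerLawTrend:
    """OLS of log10 S on log10 t over KM event-time points (S = 0 dropped)."""
    usable = curve.survival > 0.0
    if usable.sum() < 3:
        raise InsufficientDataError(
            f"log-log trend needs >= 3 points with S > 0, got {int(usable.sum())}"
        )
    x = np.log10(curve.times[usable])
    y = np.log10(curve.survival[usable])
    if np.ptp(y) == 0:  # constant survival: horizontal line, exact fit
        return PowerLawTrend(float(y[0]), 0.0, 1.0, int(usable.sum()))
    result = stats.linregress(x, y)
    return PowerLawTrend(float(result.intercept), float(result.slope),
                         float(result.rvalue**2), int(usable.sum()))


def _check_domain(model: OdeModel, t: np.ndarray) -> None:
    if np.any(t < model.t_min - 1e-12):
        raise DomainError(f"t below the model support t_min = {model.t_min}")


def ode_survival(model: OdeModel, t) -> float | np.ndarray:
    """A·t^(-k), clipped at 1 (the prefactor can exceed 1 for small t)."""
    t_arr = np.asarray(t, dtype=float)
    _check_domain(model, t_arr)
    out = np.minimum(model.A * t_arr ** (-model.k), 1.0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def ode_hazard(model: OdeModel, t) -> float | np.ndarray:
    """Instantaneous recovery rate k/t — decreasing in episode duration."""
    t_arr = np.asarray(t, dtype=float)
    _check_domain(model, t_arr)
    out = model.k / t_arr
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def verify_ode_solution(model: OdeModel, grid, step: float = 1e-4) -> ResidualReport:
    """Max |dN/dt + k·N/t| over ``grid``, dN/dt by central differences.

    A small residual confirms the power-law survival solves the
    hazard ∝ 1/t differential equation. Grid points must sit at least
    ``step`` above ``t_min`` so both stencil points are in the support.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid - step < model.t_min):
        raise DomainError("grid must satisfy t - step >= t_min")
    n_plus = ode_survival(model, grid + step)
    n_minus = ode_survival(model, grid - step)
    dn_dt = (n_plus - n_minus) / (2.0 * step)
    residual = np.abs(dn_dt + model.k * ode_survival(model, grid) / grid)
    return ResidualReport(float(residual.max()), step, grid.size)
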