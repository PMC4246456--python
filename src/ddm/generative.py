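"""Generative mechanisms for long-tailed duration distributions.

Two stochastic processes connect the empirical findings to theory:

- A *multiplicative process* — a quantity multiplied by many independent
  positive factors — has normally distributed logs, hence a log-normal
  distribution. Here the per-step factors are themselves log-normal, so
  the product is exactly log-normal at every step count, not only in the
  central-limit regime.
- The same process with a *lower reflecting barrier* (the state cannot
  fall below a bounded minimum) and downward drift instead develops a
  power-law upper tail: straight, rather than curved, on a log-log
  complementary-CDF plot.

``tail_linearity`` quantifies that distinction by OLS straightness of
the log-log CCDF above an upper quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ParameterError


@dataclass(frozen=True)
class ProcessConfig:
    """Configuration of a multiplicative chain.

    Each of ``n_samples`` independent chains starts at ``initial_value``
    and is multiplied by ``n_steps`` i.i.d. factors F with
    ln F ~ Normal(factor_log_mean, factor_log_sd). With ``barrier`` set,
    the state is reflected: x <- max(barrier, x·F).
    """

    n_steps: int
    factor_log_mean: float
    factor_log_sd: float
    n_samples: int
    initial_value: float = 1.0
    barrier: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ParameterError("n_steps must be >= 1")
        if not self.factor_log_sd > 0:
            raise ParameterError("factor_log_sd must be strictly positive")
        if not self.initial_value > 0:
            raise ParameterError("initial_value must be strictly positive")
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        if self.barrier is not None:
            if not self.barrier > 0:
                raise ParameterError("barrier must be strictly positive")
            if not self.barrier < self.initial_value:
                raise ParameterError("barrier must lie below initial_value")


def multiplicative_process(cfg: ProcessConfig) -> np.ndarray:
    """Barrier-free product of i.i.d. log-normal factors.

    The returned samples are exactly log-normal with log-mean
    ``ln(initial) + n_steps·m`` and log-sd ``sqrt(n_steps)·s``.
    """
    if cfg.barrier is not None:
        raise ParameterError(
            "multiplicative_process is barrier-free; use reflected_process"
        )
    rng = np.random.default_rng(cfg.seed)
    log_x = np.full(cfg.n_samples, np.log(cfg.initial_value))
    for _ in range(cfg.n_steps):
        log_x += rng.normal(cfg.factor_log_mean, cfg.factor_log_sd, cfg.n_samples)
    return np.exp(log_x)


def reflected_process(cfg: ProcessConfig) -> np.ndarray:
    """Multiplicative chain reflected at a lower barrier.

    With negative log-drift the chain keeps revisiting the barrier and
    the stationary distribution acquires a power-law upper tail; with
    non-negative drift no stationary power law is guaranteed, and a
    warning is issued.
    """
    if cfg.barrier is None:
        raise ParameterError("reflected_process requires a barrier")
    if cfg.factor_log_mean >= 0:
        warnings.warn(
            "factor_log_mean >= 0 with a barrier: the chain drifts away from "
            "the barrier and no stationary power-law tail is guaranteed",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    x = np.full(cfg.n_samples, float(cfg.initial_value))
    for _ in range(cfg.n_steps):
        factors = np.exp(rng.normal(cfg.factor_log_mean, cfg.factor_log_sd,
                                    cfg.n_samples))
        x = np.maximum(cfg.barrier, x * factors)
    return x


def tail_linearity(samples: np.ndarray, upper_quantile: float = 0.9) -> float:
    """Straightness (r²) of the log-log empirical CCDF above a quantile.

    A power-law tail is linear on these axes; a log-normal tail curves
    downward. Requires at least 50 samples above the quantile.
    """
    samples = np.asarray(samples, dtype=float)
    if not 0.0 < upper_quantile < 1.0:
        raise ParameterError("upper_quantile must be in (0, 1)")
    if np.any(samples <= 0):
        raise ParameterError("samples must be strictly positive")
    n = samples.size
    xs = np.sort(samples)
    threshold = np.quantile(xs, upper_quantile)
    idx = np.flatnonzero(xs > threshold)
    if idx.size < 50:
        raise InsufficientDataError(
            f"needs >= 50 samples above the {upper_quantile:.0%} quantile, "
            f"got {idx.size}"
        )
    tail = xs[idx]
    if np.ptp(tail) == 0:
        raise InsufficientDataError("no spread in the tail samples")
    ccdf = (n - idx.astype(float)) / n  # P(X >= x) at each sorted tail point
    r = stats.pearsonr(np.log10(tail), np.log10(ccdf))[0]
    return float(r**2)
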