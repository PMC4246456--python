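"""Figure helpers for the CLI (never needed by the numeric pipeline)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .km import SurvivalCurve
from .probability_paper import transform_points

_PAPER_LABELS = {
    "exponential": ("t (months)", "-ln S"),
    "weibull": ("ln t", "ln(-ln S)"),
    "lognormal": ("ln t", "Phi^-1(1 - S)"),
    "powerlaw": ("log10 t (months)", "log10 S"),
}


def _step_xy(curve: SurvivalCurve) -> tuple[np.ndarray, np.ndarray]:
    x = np.concatenate([[0.0], np.repeat(curve.times, 2)])
    y = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1]])
    return x, y


def plot_survival(curve: SurvivalCurve, path) -> None:
    """Two panels: the KM step curve and the same points on log-log axes."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(*_step_xy(curve), drawstyle="default")
    ax1.set_xlabel("months in episode")
    ax1.set_ylabel("P(still in episode)")
    ax1.set_ylim(0, 1.02)
    positive = curve.survival > 0
    ax2.plot(np.log10(curve.times[positive]),
             np.log10(curve.survival[positive]), "o")
    ax2.set_xlabel("log10 months")
    ax2.set_ylabel("log10 S")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_probability_papers(curve: SurvivalCurve, path,
                            families=("exponential", "weibull", "lognormal",
                                      "powerlaw")) -> None:
    """One panel per family: transformed KM points with their OLS line."""
    fig, axes = plt.subplots(1, len(families), figsize=(4 * len(families), 4))
    if len(families) == 1:
        axes = [axes]
    for ax, family in zip(axes, families):
        plot = transform_points(curve, family)
        ax.plot(plot.x, plot.y, "o")
        slope, intercept = np.polyfit(plot.x, plot.y, 1)
        xs = np.array([plot.x.min(), plot.x.max()])
        ax.plot(xs, intercept + slope * xs, "-", lw=1)
        xlabel, ylabel = _PAPER_LABELS[family]
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        ax.set_title(f"{family} (r² = {plot.r_squared:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
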