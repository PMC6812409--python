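"""Optional figures: regression scatter, residual plot, DIT time course.

Matplotlib is imported lazily so the core pipeline has no plotting
dependency; these figures are documentation aids, not analysis surfaces.
"""

from __future__ import annotations

import numpy as np

from .dit import DITSeries
from .fasting_model import FastingModel, transform_activity
from .preprocess import BinnedTrace


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_fasting_fit(
    model: FastingModel,
    fasting: BinnedTrace,
    fed: BinnedTrace | None = None,
    path: str | None = None,
):
    """Scatter of EE vs transformed activity with the fasting regression line."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4))
    x_fast = transform_activity(fasting.activity, model.transform)
    ax.plot(x_fast, fasting.ee, "ko", ms=4, label="fasted")
    if fed is not None:
        ax.plot(
            transform_activity(fed.activity, model.transform),
            fed.ee, "o", mfc="none", mec="tab:blue", ms=4, label="fed",
        )
    grid = np.linspace(0, max(x_fast.max(), 1e-9), 50)
    ax.plot(grid, model.intercept + model.slope * grid, "k-", lw=1,
            label=f"fit (R²={model.r2:.3f})")
    ax.set_xlabel(f"{model.transform}(activity count)")
    ax.set_ylabel("EE (kcal/min)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_residuals(model: FastingModel, path: str | None = None):
    """Residual-vs-fitted plot for the fasting regression."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(model.fitted, model.residuals, "ko", ms=4)
    ax.axhline(0.0, color="grey", lw=1)
    ax.set_xlabel("fitted EE (kcal/min)")
    ax.set_ylabel("residual (kcal/min)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_dit_time_course(series: DITSeries, path: str | None = None):
    """DIT and EE rates against time with dark-phase shading."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(7, 4))
    hours = series.time_mid / 60.0
    ax.plot(hours, series.dit, "-", color="tab:red", label="DIT")
    ax.plot(hours, series.ee_observed, "--", color="tab:grey", label="EE")
    dark = series.photoperiod == "dark"
    if dark.any():
        ax.fill_between(
            hours, ax.get_ylim()[0], ax.get_ylim()[1],
            where=dark, color="k", alpha=0.08, linewidth=0,
        )
    ax.set_xlabel("time since start (h)")
    ax.set_ylabel("rate (kcal/min)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
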