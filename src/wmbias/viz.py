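"""Bias-curve figures: moving average of the raw points with the fitted
DoG overlay."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .circular import dog_value
from .inference import DoGFit, moving_average_curve

__all__ = ["plot_bias_curve"]


def plot_bias_curve(points, fit: DoGFit | None = None, fraction: float = 0.04,
                    path=None, title: str | None = None):
    """Plot the delta-sorted moving average of errors and, optionally, the
    fitted DoG curve.  Saves to ``path`` when given, else returns the axes."""
    delta, smoothed = moving_average_curve(points, fraction)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(delta, smoothed, lw=1, color="steelblue", label="moving average")
    if fit is not None:
        grid = np.linspace(-90, 90, 361)
        ax.plot(grid, dog_value(grid, fit.params), lw=2, color="crimson",
                label=f"DoG fit (a={fit.params.a:+.2f}, w={fit.params.w:.3f})")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("target–reference difference Δ (deg)")
    ax.set_ylabel("response error (deg)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return ax
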