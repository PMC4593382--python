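"""Static plots of saturation curves and moment stability."""

from __future__ import annotations

from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from desire.moments import MomentSummary, MOMENT_NAMES
from desire.saturation import GompertzFit, SaturationCurve


def plot_saturation(
    curves: Iterable[SaturationCurve],
    fits: dict | None = None,
    ax: plt.Axes | None = None,
    out: str | None = None,
) -> plt.Axes:
    """Expressed-gene counts vs depth fraction, one panel, one color per
    (sample, method); Gompertz fits drawn through their curves when given."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        x, y = curve.xy()
        label = f"{curve.sample_id} θ={curve.theta} ({curve.method})"
        pts = ax.plot(x, y, "o", ms=3, alpha=0.6, label=label)
        fit: GompertzFit | None = None
        if fits is not None:
            fit = fits.get((curve.sample_id, curve.theta))
        if fit is not None and fit.converged:
            xs = np.linspace(min(x), max(x), 200)
            ax.plot(xs, fit.predict(xs), "-", color=pts[0].get_color())
    ax.set_xlabel("depth fraction f")
    ax.set_ylabel("expressed genes")
    ax.legend(fontsize=7)
    if out:
        ax.figure.savefig(out, dpi=150, bbox_inches="tight")
    return ax


def plot_moments_by_depth(
    summaries: Sequence[MomentSummary],
    out: str | None = None,
) -> plt.Figure:
    """Four panels (mean, variance, skewness, kurtosis) against depth —
    the normalization-stability picture."""
    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharex=True)
    for ax, name in zip(axes.ravel(), MOMENT_NAMES):
        xs = [s.fraction for s in summaries if s.moment(name) is not None]
        ys = [s.moment(name) for s in summaries if s.moment(name) is not None]
        ax.plot(xs, ys, "o", ms=3, alpha=0.6)
        ax.set_title(name)
    for ax in axes[1]:
        ax.set_xlabel("depth fraction f")
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=150, bbox_inches="tight")
    return fig
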