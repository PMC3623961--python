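"""Diagnostic plots for fitted models.

Thin matplotlib helpers; every function takes the data object and the fit
result and returns the Axes (creating a figure when none is supplied).
"""

from __future__ import annotations

import numpy as np

from .decay import DecayCurve, MultiExpFit, convolve_model

__all__ = ["plot_decay_fit", "plot_titration_fit"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_decay_fit(curve: DecayCurve, fit: MultiExpFit, ax=None):
    """Semilog decay, IRF and reconvolved model."""
    ax = _axes(ax)
    model = convolve_model(
        [c.tau for c in fit.components],
        [c.alpha for c in fit.components],
        curve.irf_counts,
        curve.channel_width,
        background=fit.background,
        shift=fit.shift,
    )
    ax.semilogy(curve.time, np.maximum(curve.counts, 0.5), ".", ms=2, label="data")
    ax.semilogy(curve.time, np.maximum(curve.irf_counts, 0.5), "-", lw=0.8, label="IRF")
    ax.semilogy(curve.time, np.maximum(model, 0.5), "-", label="fit")
    ax.set_xlabel("time (ns)")
    ax.set_ylabel("counts")
    ax.legend()
    return ax


def plot_titration_fit(series, fit, ax=None):
    """Observable vs protein concentration with the fitted 1:1 hyperbola."""
    ax = _axes(ax)
    P = series.protein_conc_uM
    ax.plot(P, series.observable, "o", label="data")
    grid = np.linspace(0, P.max(), 200)
    K = fit.k_assoc
    curve = fit.f0 + (fit.f_inf - fit.f0) * K * grid * 1e-6 / (1 + K * grid * 1e-6)
    ax.plot(grid, curve, "-", label=f"K = {K:.3g} M$^{{-1}}$")
    ax.set_xlabel("protein (µM)")
    ax.set_ylabel(series.observable_kind)
    ax.legend()
    return ax
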