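"""Static diagnostic plots: chain traces, the optimization path in signature
space, and a corner plot of the posterior. All functions return the figure
and optionally save it; nothing is interactive."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .sampler import MarkovChain

__all__ = ["trace_plot", "optimization_path", "corner_plot"]


def trace_plot(chain: MarkovChain, path=None):
    """Per-variable time series of the recorded chain entries."""
    variables = chain.variables()
    fig, axes = plt.subplots(len(variables), 1, sharex=True,
                             figsize=(7, 1.6 * len(variables)), squeeze=False)
    for ax, (name, vals) in zip(axes[:, 0], variables.items()):
        ax.plot(vals, lw=0.4)
        ax.set_ylabel(name)
    axes[-1, 0].set_xlabel("entry")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def optimization_path(chain: MarkovChain, measurement=None, model=None, path=None):
    """Chain of predicted signatures in (I1, I2) space with the measurement
    and source boxes overlaid (first two signatures when n = 3)."""
    if chain.mu.shape[1] < 2:
        raise ValueError("optimization path needs at least two signatures")
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.plot(chain.mu[:, 0], chain.mu[:, 1], ".-", ms=2, lw=0.2, alpha=0.4,
            label="chain predictions")
    if measurement is not None:
        ax.errorbar(measurement.x[0], measurement.x[1],
                    xerr=measurement.sigma_x[0], yerr=measurement.sigma_x[1],
                    fmt="ko", label="measurement")
    if model is not None:
        means = model.source_means()
        spans = model.source_half_ranges() + model.source_sigmas()
        for j, src in enumerate(model.sources):
            ax.add_patch(plt.Rectangle(
                (means[j, 0] - spans[j, 0], means[j, 1] - spans[j, 1]),
                2 * spans[j, 0], 2 * spans[j, 1],
                alpha=0.25, color="grey"))
            ax.annotate(src.name, means[j, :2], ha="center")
    ax.set_xlabel(chain.signature_labels[0])
    ax.set_ylabel(chain.signature_labels[1])
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def corner_plot(chain: MarkovChain, path=None, bins=40):
    """Histograms on the diagonal, scatter above, Pearson r below."""
    variables = chain.variables()
    names = list(variables)
    k = len(names)
    fig, axes = plt.subplots(k, k, figsize=(2.2 * k, 2.2 * k), squeeze=False)
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            ax = axes[i, j]
            if i == j:
                ax.hist(variables[ni], bins=bins, color="steelblue")
            elif i < j:
                ax.plot(variables[nj], variables[ni], ",", alpha=0.3)
            else:
                a, b = variables[ni], variables[nj]
                sa, sb = np.std(a), np.std(b)
                r = np.corrcoef(a, b)[0, 1] if sa > 0 and sb > 0 else np.nan
                ax.text(0.5, 0.5, f"r = {r:.2f}" if np.isfinite(r) else "r undefined",
                        ha="center", va="center", transform=ax.transAxes)
                ax.set_axis_off()
            if i == k - 1 and i >= j:
                ax.set_xlabel(nj, fontsize=8)
            if j == 0 and i != j:
                ax.set_ylabel(ni, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
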