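"""Matplotlib renderings: dot plots, spiral panels, walks, coefficient clusters.

Everything takes an ``Axes`` (or makes its own figure) and returns the
``Axes``/``Figure``, so the functions compose with user figures; the CLI
wraps them with savefig.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; harmless if a GUI backend is active

import matplotlib.pyplot as plt
import numpy as np

from .representation import IndicatorMatrix, SpiralLayout, WalkSeries
from .wavelet import CoefficientClusters

__all__ = ["plot_dot", "plot_spiral", "plot_walk", "plot_clusters"]


def plot_dot(mat: IndicatorMatrix, ax: plt.Axes | None = None) -> plt.Axes:
    """Dot plot of an indicator matrix: black where u = 1, white where 0."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(mat.values, cmap="binary", origin="lower", interpolation="nearest")
    ax.set_xlabel("position k")
    ax.set_ylabel("position h")
    if mat.sequence_ref:
        ax.set_title(mat.sequence_ref)
    return ax


def plot_spiral(
    layout: SpiralLayout, symbols: tuple[str, ...] | None = None
) -> plt.Figure:
    """One panel per symbol showing that symbol's spiral point set."""
    syms = symbols if symbols is not None else tuple(sorted(layout.by_symbol))
    fig, axes = plt.subplots(1, len(syms), figsize=(3.2 * len(syms), 3.2), squeeze=False)
    for ax, s in zip(axes[0], syms):
        pts = np.asarray(layout.by_symbol.get(s, ()), dtype=float)
        if len(pts):
            ax.plot(pts[:, 0], pts[:, 1], ".", markersize=2)
        ax.set_title(s)
        ax.set_aspect("equal")
    fig.suptitle(layout.identifier)
    fig.tight_layout()
    return fig


def plot_walk(series: WalkSeries, ax: plt.Axes | None = None) -> plt.Axes:
    """Trajectory of the walk in the complex plane."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(series.terms.real, series.terms.imag, linewidth=0.8)
    ax.set_xlabel("Re z")
    ax.set_ylabel("Im z")
    ax.set_aspect("equal")
    if series.identifier:
        ax.set_title(series.identifier)
    return ax


def plot_clusters(clusters: CoefficientClusters, labels: list[str] | None = None) -> plt.Figure:
    """Scatter panels of (real-channel, imag-channel) coefficient pairs.

    Marker area scales with multiplicity, so discrete clusters of a
    root-encoded signal show up as a few fat points per panel.
    """
    labels = labels if labels is not None else list(clusters.points)
    fig, axes = plt.subplots(1, len(labels), figsize=(3.2 * len(labels), 3.2), squeeze=False)
    for ax, label in zip(axes[0], labels):
        tally = clusters.points[label]
        pts = np.array(list(tally), dtype=float).reshape(-1, 2)
        mult = np.array(list(tally.values()), dtype=float)
        ax.scatter(pts[:, 0], pts[:, 1], s=4 + 40 * mult / mult.max())
        ax.set_title(label)
        ax.set_xlabel("real channel")
        ax.set_ylabel("imag channel")
    fig.tight_layout()
    return fig
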