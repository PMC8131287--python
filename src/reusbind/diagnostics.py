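"""Visual diagnostics: window-histogram overlap, replica traces, PMF shape.

Matplotlib (Agg-safe) figures mirroring the standard health checks of a
replica-exchange umbrella run: (a) stacked per-window histograms of the
reaction coordinate -- neighboring windows must overlap for WHAM to connect
them; (b) window-label time series of selected replicas -- a mixing replica
random-walks across the ladder; (c) the PMF with its bootstrap band and, for
bidirectional runs, the symmetry of the two flanks about the bound pose.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .reus import REUSResult, replica_trace
from .wham import HistogramSet, PMFProfile

__all__ = ["plot_window_histograms", "plot_replica_traces", "plot_pmf"]


def plot_window_histograms(hist: HistogramSet, ax=None):
    """Per-window reaction-coordinate histograms (normalized), one color per
    umbrella; visual check for sufficient neighbor overlap."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    centers = hist.centers
    for m in range(hist.n_windows):
        n = hist.sample_totals[m]
        if n > 0:
            ax.plot(centers, hist.counts[m] / n, lw=0.8)
    ax.set_xlabel(r"$\zeta$ ($\mathrm{\AA}$)")
    ax.set_ylabel("probability / bin")
    return ax


def plot_replica_traces(result: REUSResult, replicas: Sequence[int], ax=None):
    """Window label vs exchange attempt for selected replicas."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for i in replicas:
        ax.plot(replica_trace(result, i), lw=0.8, label=f"replica {i}")
    ax.set_xlabel("exchange sweep")
    ax.set_ylabel("window label")
    ax.legend(fontsize=8)
    return ax


def plot_pmf(pmf: PMFProfile, ax=None, mirror_center: float | None = None):
    """PMF along zeta; optionally overlay the profile mirrored about
    ``mirror_center`` to expose bidirectional asymmetry."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    z = pmf.centers[pmf.mask]
    F = pmf.free_energy[pmf.mask]
    if pmf.stderr is not None:
        err = pmf.stderr[pmf.mask]
        ax.fill_between(z, F - err, F + err, alpha=0.3)
    ax.plot(z, F, lw=1.2)
    if mirror_center is not None:
        ax.plot(2 * mirror_center - z, F, lw=0.8, ls="--", alpha=0.7)
    ax.set_xlabel(r"$\zeta$ ($\mathrm{\AA}$)")
    ax.set_ylabel(r"$F(\zeta)$ (kcal/mol)")
    return ax
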