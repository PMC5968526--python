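"""Minimal plotting helpers (MDS scatter, Ne trajectories, Q bar plot)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .admixture import AdmixtureFit
from .ne import NeTrajectory
from .structure import MDSResult


def mds_scatter(result: MDSResult, population_ids: list[str], ax=None):
    """C1/C2 scatter colored by population."""
    ax = ax or plt.gca()
    pops = sorted(set(population_ids))
    for pop in pops:
        idx = [i for i, p in enumerate(population_ids) if p == pop]
        ax.scatter(result.coordinates[idx, 0], result.coordinates[idx, 1], s=12, label=pop)
    f = result.variance_fraction
    ax.set_xlabel(f"C1 ({100 * f[0]:.1f}%)")
    if len(f) > 1:
        ax.set_ylabel(f"C2 ({100 * f[1]:.1f}%)")
    ax.legend(fontsize=7)
    return ax


def ne_plot(trajectories: list[NeTrajectory], ax=None):
    ax = ax or plt.gca()
    for traj in trajectories:
        ts, nes = zip(*traj.points)
        ax.plot(ts, nes, marker="o", ms=3, label=traj.label or None)
    ax.set_xlabel("generations ago")
    ax.set_ylabel("Ne")
    ax.set_xscale("log")
    ax.set_yscale("log")
    if any(t.label for t in trajectories):
        ax.legend(fontsize=7)
    return ax


def admixture_bars(fit: AdmixtureFit, ax=None):
    """Stacked ancestry-proportion bars, samples grouped by population."""
    ax = ax or plt.gca()
    order = np.argsort(fit.population_ids) if fit.population_ids else np.arange(len(fit.Q))
    Q = fit.Q[order]
    bottom = np.zeros(len(Q))
    for k in range(fit.K):
        ax.bar(np.arange(len(Q)), Q[:, k], bottom=bottom, width=1.0)
        bottom += Q[:, k]
    ax.set_xlim(-0.5, len(Q) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry proportion")
    return ax
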