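"""Minimal plotting helpers (matplotlib)."""

from __future__ import annotations

import numpy as np

from .repertoire import DiversityProfile
from .scqpcr import ClusterResult, Log2ExMatrix


def plot_renyi_profiles(profiles, ax=None):
    """Rényi diversity profiles on a symlog-style alpha axis.

    ``profiles`` is an iterable of :class:`DiversityProfile`; infinite
    alpha is drawn at twice the largest finite grid point.
    """
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for prof in profiles:
        finite = np.isfinite(prof.alphas)
        x = prof.alphas.copy()
        if (~finite).any():
            x[~finite] = 2 * prof.alphas[finite].max()
        ax.plot(x, prof.values, marker="o", label=prof.label)
    ax.set_xscale("symlog", linthresh=1.0)
    ax.set_xlabel(r"$\alpha$")
    ax.set_ylabel(r"$H_\alpha$ (nats)")
    ax.legend()
    return ax


def plot_binary_heatmap(log2ex: Log2ExMatrix, clusters: ClusterResult, ax=None):
    """Binary expressed/non-expressed heatmap in dendrogram order."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    mat = log2ex.expressed.loc[clusters.cell_order, clusters.gene_order]
    ax.imshow(mat.to_numpy().T, aspect="auto", cmap="Greys",
              interpolation="nearest")
    ax.set_yticks(range(len(clusters.gene_order)))
    ax.set_yticklabels(clusters.gene_order, fontsize=6)
    ax.set_xlabel("cells (dendrogram order)")
    return ax


def plot_trajectory_curves(result, ax=None):
    """Relative median curves along pseudotime (one line per channel)."""
    import matplotlib.pyplot as plt
    if result.curves is None:
        raise ValueError("run binned_curves first")
    if ax is None:
        _, ax = plt.subplots()
    for ch in result.curves.columns:
        ax.plot(result.curves.index, result.curves[ch], label=ch)
    ax.set_xlabel("pseudotime bin")
    ax.set_ylabel("relative median expression")
    ax.legend(fontsize=7)
    return ax
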