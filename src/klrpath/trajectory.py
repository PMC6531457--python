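"""Cytometry pseudotime: density-dependent downsampling and a
waypoint-ensemble graph trajectory anchored at naive (CD45RA+CCR7+) cells.

Events are first thinned to a fixed budget with retention probabilities
inversely proportional to local k-NN density, which flattens density
differences so rare late-stage populations are not swamped.  Pseudotime
is then computed on a k-nearest-neighbour graph over the trajectory
channels: shortest-path distances from an initiator cell give an initial
ordering, which an ensemble of randomly sampled waypoints iteratively
refines (each waypoint "triangulates" every event's position as its own
pseudotime plus/minus the graph distance to the event); repeats over
random initiators/waypoints are averaged and min–max scaled to [0, 1].

Binned relative median curves along pseudotime summarise each channel's
expression and yield the marker acquisition order (first 0.5-crossing of
the normalized curve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components, dijkstra
from sklearn.neighbors import NearestNeighbors, kneighbors_graph

from .cytogate import EventTable

__all__ = [
    "TRAJECTORY_CHANNELS", "PseudotimeResult",
    "density_downsample", "pseudotime", "binned_curves",
]

#: Channels driving downsampling, graph construction and the curves.
TRAJECTORY_CHANNELS = ("CCR7", "CD45RA", "KLRB1", "KLRG1", "KLRF1",
                       "GPR56", "TNF", "IFNG")

_MARKER_CHANNELS = ("KLRB1", "KLRG1", "GPR56", "KLRF1")


@dataclass
class PseudotimeResult:
    """Per-event pseudotime plus the binned summary once computed."""

    pseudotime: pd.Series  # in [0, 1], indexed like the event table
    channels: tuple[str, ...]
    curves: pd.DataFrame | None = None          # bins × channels, in [0, 1]
    acquisition_order: list[str] = field(default_factory=list)


def _scaled(events: EventTable, channels: Sequence[str]) -> np.ndarray:
    """Per-channel robust z-score (median/MAD) of log intensities."""
    events.require(channels)
    X = np.log(events.data[list(channels)].to_numpy(dtype=float).clip(min=1e-9))
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    mad = np.where(mad < 1e-9, 1.0, mad)
    return (X - med) / mad


def _knn_densities(X: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dists, _ = nn.kneighbors(X)
    mean_dist = dists[:, 1:].mean(axis=1)  # exclude self
    return 1.0 / (mean_dist + 1e-12)


def density_downsample(events: EventTable, target_total: int = 50000,
                       k_density: int = 15, seed: int | None = None,
                       channels: Sequence[str] = TRAJECTORY_CHANNELS
                       ) -> EventTable:
    """Thin events to ``target_total`` with density-dependent retention.

    Local density is the inverse mean distance to the ``k_density``
    nearest neighbours on the scaled trajectory channels.  Events are
    kept with probability ``min(1, c / density)`` where ``c`` is found by
    bisection so the expected kept count equals the budget; a final
    uniform trim or top-up makes the output size exactly
    ``min(target_total, len(events))``.  Inputs smaller than the budget
    are returned whole with a warning.
    """
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    n = len(events)
    if n <= target_total:
        if n < target_total:
            warnings.warn(f"only {n} events available for a budget of "
                          f"{target_total}; keeping all")
        return EventTable(events.data.copy(), dict(events.thresholds))
    rng = np.random.default_rng(seed)
    density = _knn_densities(_scaled(events, channels), k_density)

    def expected_kept(c: float) -> float:
        return float(np.minimum(1.0, c / density).sum())

    lo, hi = 0.0, float(density.max())
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if expected_kept(mid) < target_total:
            lo = mid
        else:
            hi = mid
    keep_prob = np.minimum(1.0, hi / density)
    kept = rng.random(n) < keep_prob
    idx = np.flatnonzero(kept)
    if len(idx) > target_total:
        idx = rng.choice(idx, size=target_total, replace=False)
    elif len(idx) < target_total:
        pool = np.flatnonzero(~kept)
        extra = rng.choice(pool, size=target_total - len(idx), replace=False)
        idx = np.concatenate([idx, extra])
    idx = np.sort(idx)
    return EventTable(events.data.iloc[idx].reset_index(drop=True),
                      dict(events.thresholds))


def _connected_knn_graph(X: np.ndarray, k: int):
    """Symmetric k-NN distance graph; disconnected components are joined
    by their nearest inter-component pair (with a warning)."""
    g = kneighbors_graph(X, n_neighbors=k, mode="distance")
    g = g.maximum(g.T).tolil()
    n_comp, labels = connected_components(g, directed=False)
    if n_comp > 1:
        warnings.warn(f"k-NN graph has {n_comp} components; connecting "
                      "via nearest inter-component edges")
    while n_comp > 1:
        a = np.flatnonzero(labels == labels[0])
        b = np.flatnonzero(labels != labels[0])
        nn = NearestNeighbors(n_neighbors=1).fit(X[b])
        d, j = nn.kneighbors(X[a])
        i_best = int(np.argmin(d.ravel()))
        u, v = a[i_best], b[j.ravel()[i_best]]
        g[u, v] = g[v, u] = float(d.ravel()[i_best])
        n_comp, labels = connected_components(g, directed=False)
    return g.tocsr()


def _initiator_mask(events: EventTable, channels: Sequence[str],
                    fraction: float = 0.05) -> np.ndarray:
    """Naive-phenotype initiators: CD45RA+CCR7+ events negative for every
    KLR marker present (naive cells express none of them); falls back to
    the top ``fraction`` of events by scaled CD45RA × CCR7 when no
    thresholds are available."""
    try:
        mask = (events.marker_state("CD45RA")
                & events.marker_state("CCR7"))
        for m in _MARKER_CHANNELS:
            if m in events.data.columns and m in events.thresholds:
                mask &= ~events.marker_state(m)
        mask = mask.to_numpy()
        if mask.any():
            return mask
    except ValueError:
        pass
    S = _scaled(events, ["CD45RA", "CCR7"])
    score = S.sum(axis=1)
    cut = np.quantile(score, 1.0 - fraction)
    return score >= cut


def pseudotime(events: EventTable, initiator_mask: np.ndarray | None = None,
               k_graph: int = 15, n_waypoints: int = 200, n_repeats: int = 5,
               n_refine: int = 2, n_sources: int = 50,
               seed: int | None = None,
               channels: Sequence[str] = TRAJECTORY_CHANNELS
               ) -> PseudotimeResult:
    """Waypoint-ensemble graph pseudotime anchored at naive initiators.

    Per repeat: ``n_sources`` initiator events and ``n_waypoints``
    waypoints are sampled; the mean graph shortest-path distance from
    the sampled initiators gives the initial trajectory (averaging over
    initiators removes the dependence on any single start cell), which
    ``n_refine`` refinement sweeps update — each event's position
    becomes the distance-weighted average of every waypoint's
    perspective ``t(w) ± d(w, event)``, with the sign chosen by whether
    the event currently lies beyond the waypoint.  Each repeat is
    robustly scaled to [0, 1] (1st–99th percentile, clipped) before the
    ensemble average, then the mean is min–max scaled.  Deterministic
    under a fixed seed.
    """
    if initiator_mask is None:
        initiator_mask = _initiator_mask(events, channels)
    initiator_mask = np.asarray(initiator_mask, dtype=bool)
    if not initiator_mask.any():
        raise ValueError("initiator mask selects no events")
    X = _scaled(events, channels)
    n = len(X)
    graph = _connected_knn_graph(X, k_graph)
    rng = np.random.default_rng(seed)
    initiators = np.flatnonzero(initiator_mask)
    trajs = np.zeros((n_repeats, n))
    for r in range(n_repeats):
        srcs = rng.choice(initiators, size=min(n_sources, len(initiators)),
                          replace=False)
        wp = rng.choice(n, size=min(n_waypoints, n), replace=False)
        D = dijkstra(graph, directed=False,
                     indices=np.concatenate([srcs, wp]))
        t = D[:len(srcs)].mean(axis=0)
        w_dist = D[len(srcs):]  # waypoints × events
        weights = 1.0 / (w_dist + 1e-9)
        for _ in range(n_refine):
            t_w = t[wp]
            # perspective of waypoint w on event i: t(w) + sign * d(w, i)
            sign = np.where(t[None, :] >= t_w[:, None], 1.0, -1.0)
            persp = t_w[:, None] + sign * w_dist
            t = (weights * persp).sum(axis=0) / weights.sum(axis=0)
        lo, hi = np.quantile(t, [0.01, 0.99])
        trajs[r] = np.clip((t - lo) / (hi - lo if hi > lo else 1.0), 0, 1)
    pt = trajs.mean(axis=0)
    span = pt.max() - pt.min()
    pt = (pt - pt.min()) / (span if span > 0 else 1.0)
    return PseudotimeResult(pd.Series(pt, index=events.data.index,
                                      name="pseudotime"),
                            tuple(channels))


def binned_curves(result: PseudotimeResult, events: EventTable,
                  n_bins: int = 20,
                  acquisition_channels: Sequence[str] = _MARKER_CHANNELS,
                  threshold: float = 0.5) -> PseudotimeResult:
    """Relative median expression per pseudotime bin, plus acquisition order.

    Events are split into ``n_bins`` pseudotime-quantile bins (near-empty
    bins from ties are merged by ``qcut``); the per-bin median intensity
    of every trajectory channel is min–max normalized to [0, 1].  The
    acquisition order ranks ``acquisition_channels`` by the (interpolated)
    bin position where the normalized curve first rises through
    ``threshold``; flat channels are excluded.
    """
    if n_bins < 5:
        raise ValueError("need at least 5 bins")
    pt = result.pseudotime
    bins = pd.qcut(pt.rank(method="first"), q=n_bins, labels=False,
                   duplicates="drop")
    med = events.data[list(result.channels)].groupby(bins).median()
    lo, hi = med.min(axis=0), med.max(axis=0)
    flat = (hi - lo) < 1e-12
    curves = (med - lo) / (hi - lo).where(~flat, 1.0)
    crossings: dict[str, float] = {}
    for ch in acquisition_channels:
        if ch not in curves.columns or flat.get(ch, False):
            continue
        c = curves[ch].to_numpy()
        above = np.flatnonzero(c >= threshold)
        if len(above) == 0:
            continue
        i = int(above[0])
        if i == 0:
            crossings[ch] = 0.0
        else:
            frac = (threshold - c[i - 1]) / (c[i] - c[i - 1])
            crossings[ch] = (i - 1) + float(frac)
    order = sorted(crossings, key=lambda ch: crossings[ch])
    result.curves = curves
    result.acquisition_order = order
    return result
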