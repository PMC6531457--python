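"""Single-cell qRT-PCR preprocessing: Ct matrices, LoD binarization, clustering.

Expression of a gene in a cell is quantified as ``Log2Ex = LoD − Ct``,
the distance of the observed cycle threshold from the gene's limit of
detection (default Ct 24).  A cell expresses a gene iff its Ct lies below
the LoD; missing or at/above-LoD measurements clamp to ``Log2Ex = 0``.
Per-gene LoDs can be tightened from the default by locating the valley
between the expressing mode and the noise mode of the Ct distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelmax, argrelmin

__all__ = [
    "CtMatrix", "Log2ExMatrix", "ClusterResult", "DEFAULT_LOD",
    "compute_log2ex", "adjust_lod", "filter_matrix", "cluster_binary",
    "expressing_fraction",
]

DEFAULT_LOD: float = 24.0

#: Sentinels that instrument exports use for "no amplification".
_MISSING_SENTINELS = {"", "na", "nan", "999", "999.0"}


@dataclass
class CtMatrix:
    """Cells × genes cycle-threshold matrix with per-gene limits of detection.

    ``values`` holds Ct in cycles (NaN = no amplification).  ``lod`` maps
    every gene to its LoD Ct; genes absent from an explicit override keep
    ``DEFAULT_LOD``.  ``cell_subsets`` optionally labels each cell with its
    sorted subset of origin.
    """

    values: pd.DataFrame
    control_genes: tuple[str, str] = ("B2M", "Spike1")
    lod: pd.Series | None = None
    cell_subsets: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.lod is None:
            self.lod = pd.Series(DEFAULT_LOD, index=self.values.columns,
                                 dtype=float)
        else:
            self.lod = pd.Series(self.lod, dtype=float).reindex(
                self.values.columns, fill_value=DEFAULT_LOD)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "CtMatrix":
        """Read a TSV of cells (rows) × genes (columns); blank/NA/999
        sentinels are normalized to missing."""
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        norm = df.map(lambda v: np.nan if v is None or
                      str(v).strip().lower() in _MISSING_SENTINELS
                      else float(v))
        return cls(norm.astype(float), **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class Log2ExMatrix:
    """Cells × genes expression levels (Log2Ex) with the boolean call matrix.

    The invariant ``expressed == (values > 0)`` holds by construction.
    """

    values: pd.DataFrame
    expressed: pd.DataFrame
    control_genes: tuple[str, str] = ("B2M", "Spike1")
    cell_subsets: pd.Series | None = None
    filter_report: dict = field(default_factory=dict)


def compute_log2ex(ct: CtMatrix) -> Log2ExMatrix:
    """Convert Ct to expression levels: ``Log2Ex = LoD − Ct``.

    Missing Ct or Ct at/above the gene's LoD yield a non-expressed call
    with Log2Ex clamped to 0.

    Raises
    ------
    ValueError
        If any present Ct value is zero or negative (names the cell and
        gene).
    """
    vals = ct.values
    bad = (vals <= 0)
    if bad.any().any():
        cell = bad.any(axis=1).idxmax()
        gene = bad.loc[cell].idxmax()
        raise ValueError(
            f"non-positive Ct for cell {cell!r}, gene {gene!r}: "
            f"{vals.loc[cell, gene]}")
    log2ex = (ct.lod - vals).clip(lower=0.0).fillna(0.0)
    expressed = vals.lt(ct.lod) & vals.notna()
    return Log2ExMatrix(log2ex, expressed, control_genes=ct.control_genes,
                        cell_subsets=ct.cell_subsets)


def adjust_lod(ct: CtMatrix, default_lod: float = DEFAULT_LOD,
               min_cells: int = 20, bandwidth: float = 1.0,
               overrides: Mapping[str, float] | None = None) -> pd.Series:
    """Tighten per-gene LoDs to exclude late-cycle noise.

    For every gene with at least ``min_cells`` amplifying cells, a
    histogram of its Ct values (0.5-cycle bins) is smoothed with a
    Gaussian kernel of ``bandwidth`` cycles.  If the smoothed density is
    bimodal — an early expressing mode and a late noise mode — the LoD is
    set to the valley (local minimum) between the two most populated
    modes, capped at ``default_lod``.  Unimodal genes and genes with too
    few observations keep the default.  ``overrides`` wins over the
    heuristic for the listed genes.
    """
    out = pd.Series(float(default_lod), index=ct.values.columns)
    for gene in ct.values.columns:
        cts = ct.values[gene].dropna().to_numpy()
        if len(cts) < min_cells:
            continue
        edges = np.arange(np.floor(cts.min()), np.ceil(cts.max()) + 0.5, 0.5)
        if len(edges) < 4:
            continue
        counts, edges = np.histogram(cts, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        smooth = gaussian_filter1d(counts.astype(float), bandwidth / 0.5)
        peaks = argrelmax(smooth)[0]
        if len(peaks) < 2:
            continue
        # the two most populated modes bracket the search window
        top2 = np.sort(peaks[np.argsort(smooth[peaks])[-2:]])
        lo, hi = top2
        valleys = argrelmin(smooth)[0]
        inner = valleys[(valleys > lo) & (valleys < hi)]
        if len(inner) == 0:
            inner = np.array([lo + np.argmin(smooth[lo:hi + 1])])
        valley_ct = centers[inner[np.argmin(smooth[inner])]]
        out[gene] = min(float(valley_ct), float(default_lod))
    if overrides:
        for gene, v in overrides.items():
            out[gene] = float(v)
    return out


def filter_matrix(log2ex: Log2ExMatrix, min_cells: int = 10) -> Log2ExMatrix:
    """Apply the control-gene and low-prevalence filters.

    Cells with undetectable expression of either control gene (B2M or
    Spike1) are removed first; then genes expressed in fewer than
    ``min_cells`` of the remaining cells are dropped.  The control columns
    themselves are excluded from the returned analysis matrix.  The
    returned object carries a ``filter_report`` with the removed cells and
    genes.  Idempotent: re-filtering a filtered matrix changes nothing.

    Raises
    ------
    ValueError
        If every cell fails the control-gene filter.
    """
    controls = [g for g in log2ex.control_genes if g in log2ex.values.columns]
    if controls:
        ok = log2ex.expressed[controls].all(axis=1)
    else:  # controls already stripped by a previous pass
        ok = pd.Series(True, index=log2ex.values.index)
    removed_cells = list(log2ex.values.index[~ok])
    if not ok.any():
        raise ValueError("all cells removed: no cell has detectable "
                         f"{' and '.join(log2ex.control_genes)}")
    expressed = log2ex.expressed.loc[ok]
    keep_genes = expressed.sum(axis=0) >= min_cells
    genes = [g for g in log2ex.values.columns
             if keep_genes[g] and g not in controls]
    removed_genes = [g for g in log2ex.values.columns
                     if g not in genes and g not in controls]
    report = {"cells_removed": removed_cells, "genes_removed": removed_genes,
              "n_cells_kept": int(ok.sum()), "n_genes_kept": len(genes)}
    subsets = (log2ex.cell_subsets[ok] if log2ex.cell_subsets is not None
               else None)
    return Log2ExMatrix(log2ex.values.loc[ok, genes],
                        expressed[genes],
                        control_genes=log2ex.control_genes,
                        cell_subsets=subsets,
                        filter_report=report)


@dataclass
class ClusterResult:
    """Ward/Euclidean agglomerative clustering of cells and genes."""

    cell_order: list
    gene_order: list
    cell_linkage: np.ndarray
    gene_linkage: np.ndarray

    def cut_cells(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.cell_linkage, t=n_clusters,
                                    criterion="maxclust")
        return pd.Series(labels, index=self._cell_index)

    _cell_index: pd.Index | None = None


def cluster_binary(log2ex: Log2ExMatrix) -> ClusterResult:
    """Hierarchically cluster cells and genes (Euclidean distance, Ward
    linkage) on the continuous Log2Ex values.

    The binarized ``expressed`` matrix is the intended rendering of the
    resulting heatmap; the linkage itself uses the continuous values.
    Input rows are pre-sorted lexicographically by cell identifier so the
    dendrogram does not depend on record order.
    """
    vals = log2ex.values.sort_index(axis=0).sort_index(axis=1)
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("clustering needs at least 2 cells and 2 genes")
    cell_link = hierarchy.linkage(vals.to_numpy(), method="ward",
                                  metric="euclidean")
    gene_link = hierarchy.linkage(vals.to_numpy().T, method="ward",
                                  metric="euclidean")
    cell_order = [vals.index[i] for i in hierarchy.leaves_list(cell_link)]
    gene_order = [vals.columns[i] for i in hierarchy.leaves_list(gene_link)]
    res = ClusterResult(cell_order, gene_order, cell_link, gene_link)
    res._cell_index = vals.index
    return res


def expressing_fraction(log2ex: Log2ExMatrix,
                        labels: pd.Series | None = None) -> pd.DataFrame:
    """Per-subset fraction of cells expressing each gene.

    ``labels`` assigns a subset to every cell (defaults to the matrix's
    own ``cell_subsets``).  Unlabeled cells are an error.
    """
    if labels is None:
        labels = log2ex.cell_subsets
    if labels is None:
        raise ValueError("no cell subset labels supplied")
    labels = labels.reindex(log2ex.expressed.index)
    unlabeled = list(labels.index[labels.isna()])
    if unlabeled:
        raise ValueError(f"unlabeled cells: {unlabeled}")
    return log2ex.expressed.groupby(labels).mean()
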