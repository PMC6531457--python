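"""Bulk expression intersection analysis for memory T-cell subsets.

Sorted CD4+ subsets (T_N, T_CM, T_EM, T_EMRA) are quantile-normalized,
compared gene-by-gene with two-sample t-tests, and candidate surface
markers are selected by intersecting "at least twofold up, p < 0.05"
calls across all required pairwise comparisons:

* T_EMRA-specific: up in T_EMRA vs each of T_N, T_CM, T_EM;
* shared effector-memory: up in both T_EMRA and T_EM vs each of T_N, T_CM.

Candidates are optionally restricted to a surfaceome gene list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BulkMatrix", "DEResult", "SUBSETS",
    "quantile_normalize", "pairwise_tests",
    "intersect_temra", "intersect_tem_temra", "surfaceome_filter",
    "run_intersection_analysis", "read_gene_list",
]

SUBSETS = ("T_N", "T_CM", "T_EM", "T_EMRA")


@dataclass
class BulkMatrix:
    """Samples × genes log2 expression with a subset label per sample."""

    values: pd.DataFrame
    sample_labels: pd.Series

    def __post_init__(self) -> None:
        self.sample_labels = pd.Series(self.sample_labels).reindex(
            self.values.index)
        if self.sample_labels.isna().any():
            missing = list(self.values.index[self.sample_labels.isna()])
            raise ValueError(f"samples without subset label: {missing}")

    @classmethod
    def from_tsv(cls, path: str | Path, label_column: str = "subset"
                 ) -> "BulkMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = df.pop(label_column)
        return cls(df.astype(float), labels)

    def to_tsv(self, path: str | Path, label_column: str = "subset") -> None:
        out = self.values.copy()
        out.insert(0, label_column, self.sample_labels)
        out.to_csv(path, sep="\t")

    def group(self, subset: str) -> pd.DataFrame:
        sub = self.values[self.sample_labels == subset]
        if len(sub) < 2:
            raise ValueError(f"subset {subset!r} has {len(sub)} samples; "
                             "need at least 2 replicates")
        return sub


def quantile_normalize(matrix: BulkMatrix) -> BulkMatrix:
    """Force every sample onto the common distribution of mean order
    statistics.

    After normalization each sample's sorted value vector equals the
    across-sample mean of order statistics; genes tied within a sample
    receive the mean of the reference values their positions span.
    """
    X = matrix.values.to_numpy(dtype=float)
    ref = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        order = np.argsort(X[i], kind="mergesort")
        row = np.empty_like(ref)
        row[order] = ref
        # ties: average the reference values assigned to equal inputs
        s = pd.Series(row).groupby(pd.Series(X[i])).transform("mean")
        out[i] = s.to_numpy()
    return BulkMatrix(pd.DataFrame(out, index=matrix.values.index,
                                   columns=matrix.values.columns),
                      matrix.sample_labels)


def pairwise_tests(matrix: BulkMatrix, comparison: tuple[str, str],
                   welch: bool = True) -> pd.DataFrame:
    """Per-gene two-sample t-test and fold change for one subset pair.

    ``comparison = (a, b)`` tests a vs b per gene; the fold change is on
    the linear scale, ``2 ** (mean_a − mean_b)`` for log2 data, so fold >
    1 means up in ``a``.  Welch's unequal-variance test is the default;
    set ``welch=False`` for Student's.  Genes with zero variance in both
    groups get p = 1 when means are equal, p = 0 otherwise.
    """
    a, b = comparison
    A, B = matrix.group(a).to_numpy(), matrix.group(b).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, B, axis=0, equal_var=not welch)
    mean_diff = A.mean(axis=0) - B.mean(axis=0)
    degenerate = np.isnan(p)
    p = np.where(degenerate & np.isclose(mean_diff, 0.0), 1.0,
                 np.where(degenerate, 0.0, p))
    return pd.DataFrame({"fold": 2.0 ** mean_diff, "p": p,
                         "t": np.where(np.isnan(t), 0.0, t)},
                        index=matrix.values.columns)


def _intersect(results: Mapping[tuple[str, str], pd.DataFrame],
               required: Sequence[tuple[str, str]],
               fold_threshold: float, alpha: float,
               adjust: str | None) -> set[str]:
    for comp in required:
        if comp not in results:
            raise ValueError(f"missing comparison {comp[0]} vs {comp[1]}")
    keep: set[str] | None = None
    for comp in required:
        res = results[comp]
        p = res["p"]
        if adjust:
            from statsmodels.stats.multitest import multipletests
            p = pd.Series(multipletests(p, method=adjust)[1], index=p.index)
        hits = set(res.index[(res["fold"] >= fold_threshold) & (p < alpha)])
        keep = hits if keep is None else keep & hits
    return keep or set()


def intersect_temra(results: Mapping[tuple[str, str], pd.DataFrame],
                    fold_threshold: float = 2.0, alpha: float = 0.05,
                    adjust: str | None = None) -> set[str]:
    """Genes at least ``fold_threshold``-fold up (p < ``alpha``) in T_EMRA
    vs every one of T_N, T_CM and T_EM.

    ``results`` maps comparison pairs to :func:`pairwise_tests` output.
    ``adjust`` optionally applies a multiple-testing correction (e.g.
    ``"fdr_bh"``) within each comparison; the default uses raw p-values.
    """
    req = [("T_EMRA", "T_N"), ("T_EMRA", "T_CM"), ("T_EMRA", "T_EM")]
    return _intersect(results, req, fold_threshold, alpha, adjust)


def intersect_tem_temra(results: Mapping[tuple[str, str], pd.DataFrame],
                        fold_threshold: float = 2.0, alpha: float = 0.05,
                        adjust: str | None = None) -> set[str]:
    """Genes at least ``fold_threshold``-fold up (p < ``alpha``) in each of
    T_EMRA vs T_N, T_EMRA vs T_CM, T_EM vs T_N and T_EM vs T_CM."""
    req = [("T_EMRA", "T_N"), ("T_EMRA", "T_CM"),
           ("T_EM", "T_N"), ("T_EM", "T_CM")]
    return _intersect(results, req, fold_threshold, alpha, adjust)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def surfaceome_filter(genes: Sequence[str], surfaceome: Sequence[str]
                      ) -> tuple[set[str], list[str]]:
    """Restrict a gene set to surfaceome members (case-insensitive).

    Returns the matched genes (original casing) and the list of input
    genes that found no surfaceome match.  An empty surfaceome list
    produces a warning and an empty result.
    """
    if not surfaceome:
        warnings.warn("empty surfaceome list: no genes can match")
        return set(), list(genes)
    surf = {g.upper() for g in surfaceome}
    matched = {g for g in genes if g.upper() in surf}
    unmatched = [g for g in genes if g.upper() not in surf]
    return matched, unmatched


@dataclass
class DEResult:
    """Bundled output of the full intersection analysis."""

    tests: dict
    temra_specific: set[str] = field(default_factory=set)
    tem_temra_shared: set[str] = field(default_factory=set)
    surfaceome_temra: set[str] | None = None
    surfaceome_shared: set[str] | None = None
    unmatched_symbols: list[str] = field(default_factory=list)


def run_intersection_analysis(matrix: BulkMatrix,
                              surfaceome: Sequence[str] | None = None,
                              fold_threshold: float = 2.0,
                              alpha: float = 0.05,
                              welch: bool = True,
                              normalize: bool = True) -> DEResult:
    """Quantile-normalize, test all required subset pairs, and intersect."""
    norm = quantile_normalize(matrix) if normalize else matrix
    comps = [("T_EMRA", "T_N"), ("T_EMRA", "T_CM"), ("T_EMRA", "T_EM"),
             ("T_EM", "T_N"), ("T_EM", "T_CM")]
    tests = {c: pairwise_tests(norm, c, welch=welch) for c in comps}
    res = DEResult(tests=tests,
                   temra_specific=intersect_temra(
                       tests, fold_threshold, alpha),
                   tem_temra_shared=intersect_tem_temra(
                       tests, fold_threshold, alpha))
    if surfaceome is not None:
        res.surfaceome_temra, un1 = surfaceome_filter(
            sorted(res.temra_specific), surfaceome)
        res.surfaceome_shared, un2 = surfaceome_filter(
            sorted(res.tem_temra_shared), surfaceome)
        res.unmatched_symbols = sorted(set(un1) | set(un2))
    return res
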