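"""TCRβ clonotype tables and repertoire diversity/similarity statistics.

A clonotype is identified by the triple (V gene, J gene, CDR3 amino-acid
sequence).  Repertoires are compared with the Morisita–Horn similarity
index (abundance-weighted, 0 = disjoint, 1 = identical composition) and
characterised by Rényi diversity profiles ``H_alpha``, which unify
richness (alpha = 0), Shannon entropy (alpha = 1), log reciprocal Simpson
concentration (alpha = 2) and the Berger–Parker readout (alpha = inf) in a
single curve.  All entropies are in natural-log units (nats).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ClonotypeTable",
    "DiversityProfile",
    "DEFAULT_ALPHAS",
    "filter_reads",
    "clonotypes_from_reads",
    "top_clones",
    "morisita_horn",
    "renyi_profile",
    "compare_profiles",
    "rank_profiles",
    "shared_dominant_clones",
    "clonal_space",
]

#: Default alpha grid for diversity profiles (inf handled analytically).
DEFAULT_ALPHAS: tuple[float, ...] = (
    0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, math.inf,
)

_AIRR_COLUMNS = {"v_call": "v_gene", "j_call": "j_gene",
                 "junction_aa": "cdr3_aa", "duplicate_count": "count"}


@dataclass
class ClonotypeTable:
    """A repertoire of TCRβ clonotypes with read counts.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``v_gene``, ``j_gene``, ``cdr3_aa``, ``count``.  Duplicate
        identities are aggregated on construction.
    label : str, optional
        Population label (e.g. ``"P1"``).
    """

    records: pd.DataFrame
    label: str | None = None

    def __post_init__(self) -> None:
        required = ["v_gene", "j_gene", "cdr3_aa", "count"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValueError(f"clonotype table missing columns: {missing}")
        df = self.records[required].copy()
        counts = df["count"].to_numpy()
        if len(df) and (not np.issubdtype(df["count"].dtype, np.number)
                        or np.any(counts <= 0)
                        or np.any(counts != np.floor(counts))):
            raise ValueError("clonotype counts must be positive integers")
        df["count"] = df["count"].astype(np.int64)
        # clonotype identity is the (V, J, CDR3aa) triple: aggregate duplicates
        df = (df.groupby(["v_gene", "j_gene", "cdr3_aa"], as_index=False,
                         sort=False)["count"].sum())
        self.records = df.reset_index(drop=True)

    # -- derived quantities -------------------------------------------------

    @property
    def total(self) -> int:
        """Total read count (the repertoire size P or Q)."""
        return int(self.records["count"].sum())

    @property
    def richness(self) -> int:
        """Number of unique clonotypes."""
        return len(self.records)

    @property
    def identities(self) -> pd.Index:
        return pd.MultiIndex.from_frame(
            self.records[["v_gene", "j_gene", "cdr3_aa"]])

    def proportions(self) -> pd.Series:
        """Clonal proportions p_i = count_i / total, indexed by identity."""
        if self.total == 0:
            raise ValueError("empty clonotype table has no proportions")
        return pd.Series(self.records["count"].to_numpy() / self.total,
                         index=self.identities)

    # -- IO (AIRR-style TSV) ------------------------------------------------

    @classmethod
    def from_airr(cls, path: str | Path, label: str | None = None
                  ) -> "ClonotypeTable":
        """Read an AIRR-style rearrangement TSV
        (``v_call``, ``j_call``, ``junction_aa``, ``duplicate_count``)."""
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _AIRR_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing AIRR columns {missing}")
        return cls(df.rename(columns=_AIRR_COLUMNS), label=label)

    def to_airr(self, path: str | Path) -> None:
        inv = {v: k for k, v in _AIRR_COLUMNS.items()}
        self.records.rename(columns=inv).to_csv(path, sep="\t", index=False)


@dataclass
class DiversityProfile:
    """Rényi diversity profile: alpha grid mapped to entropies H_alpha (nats)."""

    alphas: np.ndarray
    values: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.alphas.shape != self.values.shape:
            raise ValueError("alpha grid and entropy values differ in length")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.alphas, name=self.label)


# ---------------------------------------------------------------------------
# read-level preprocessing


def filter_reads(reads: str | Path | Iterable, min_avg_quality: float = 30.0):
    """Quality-filter sequencing reads by mean Phred score.

    Reads with an average quality strictly below ``min_avg_quality`` are
    discarded; a read exactly at the cutoff is retained.

    Parameters
    ----------
    reads : path or iterable of Bio.SeqRecord
        A FASTQ file (Phred+33) or pre-parsed records with
        ``letter_annotations["phred_quality"]``.

    Returns
    -------
    (retained, report) : (list of SeqRecord, dict)
        ``report`` holds ``n_input``, ``n_retained``, ``n_excluded``.
    """
    if isinstance(reads, (str, Path)):
        records = SeqIO.parse(str(reads), "fastq")
    else:
        records = reads
    retained: list = []
    n_input = 0
    for idx, rec in enumerate(records):
        n_input += 1
        quals = rec.letter_annotations.get("phred_quality")
        if not quals:
            raise ValueError(f"read record {idx} ({rec.id}): no quality scores")
        if float(np.mean(quals)) >= min_avg_quality:
            retained.append(rec)
    report = {"n_input": n_input, "n_retained": len(retained),
              "n_excluded": n_input - len(retained),
              "min_avg_quality": min_avg_quality}
    return retained, report


def clonotypes_from_reads(records: Iterable, label: str | None = None
                          ) -> ClonotypeTable:
    """Aggregate clonotype-annotated reads into a :class:`ClonotypeTable`.

    Each read id must carry its clonotype annotation as
    ``...|<v_gene>|<j_gene>|<cdr3_aa>`` (the format written by
    :func:`klrpath.synth.reads_to_fastq`).
    """
    rows: dict[tuple, int] = {}
    for rec in records:
        parts = rec.id.split("|")
        if len(parts) < 3:
            raise ValueError(f"read id {rec.id!r} lacks clonotype annotation")
        key = tuple(parts[-3:])
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame([(*k, v) for k, v in rows.items()],
                      columns=["v_gene", "j_gene", "cdr3_aa", "count"])
    return ClonotypeTable(df, label=label)


# ---------------------------------------------------------------------------
# clone selection


def top_clones(table: ClonotypeTable, n: int = 100) -> ClonotypeTable:
    """Select the ``n`` most expanded clonotypes.

    Ties at the selection boundary are broken deterministically by
    (count descending, v_gene, j_gene, cdr3_aa), so the result does not
    depend on input record order.  Returns all clonotypes when fewer than
    ``n`` exist.
    """
    ordered = table.records.sort_values(
        by=["count", "v_gene", "j_gene", "cdr3_aa"],
        ascending=[False, True, True, True],
        kind="mergesort").head(n)
    return ClonotypeTable(ordered.reset_index(drop=True), label=table.label)


# ---------------------------------------------------------------------------
# similarity


def _aligned_counts(P: ClonotypeTable, Q: ClonotypeTable):
    if P.total == 0 or Q.total == 0:
        raise ValueError("Morisita-Horn is undefined for an empty repertoire")
    union = P.identities.union(Q.identities)
    x = pd.Series(P.records["count"].to_numpy(), index=P.identities
                  ).reindex(union, fill_value=0).to_numpy(dtype=float)
    y = pd.Series(Q.records["count"].to_numpy(), index=Q.identities
                  ).reindex(union, fill_value=0).to_numpy(dtype=float)
    return x, y


def morisita_horn(P: ClonotypeTable, Q: ClonotypeTable) -> float:
    """Morisita–Horn similarity of two repertoires, in [0, 1].

    Computed over the union of clonotype identities in two algebraically
    equivalent forms — on raw counts ``x_i, y_i`` with totals ``X, Y``::

        S = 2 Σ x_i y_i / ((Σ x_i²/X² + Σ y_i²/Y²) · X · Y)

    and on proportions ``p_i = x_i/X, q_i = y_i/Y``::

        S = 2 Σ p_i q_i / (Σ p_i² + Σ q_i²)

    Both are evaluated and asserted equal; 1 means identical clonal
    composition, 0 means disjoint clonotype sets.
    """
    x, y = _aligned_counts(P, Q)
    X, Y = x.sum(), y.sum()
    counts_form = 2.0 * np.dot(x, y) / (
        ((x ** 2).sum() / X ** 2 + (y ** 2).sum() / Y ** 2) * X * Y)
    p, q = x / X, y / Y
    props_form = 2.0 * np.dot(p, q) / ((p ** 2).sum() + (q ** 2).sum())
    if not math.isclose(counts_form, props_form, rel_tol=1e-12, abs_tol=1e-12):
        raise AssertionError(
            f"count and proportion forms disagree: {counts_form} vs {props_form}")
    return float(props_form)


# ---------------------------------------------------------------------------
# diversity


def renyi_profile(table: ClonotypeTable,
                  alphas: Sequence[float] = DEFAULT_ALPHAS) -> DiversityProfile:
    """Rényi diversity profile H_alpha = ln(Σ p_i^alpha) / (1 − alpha).

    Limit cases are evaluated analytically: H_0 = ln(richness),
    H_1 = Shannon entropy −Σ p_i ln p_i, H_inf = −ln(max p_i).
    """
    p = table.proportions().to_numpy()
    out = np.empty(len(alphas))
    for k, a in enumerate(alphas):
        if a < 0:
            raise ValueError(f"alpha must be non-negative, got {a}")
        if a == 0:
            out[k] = math.log(len(p))
        elif a == 1:
            out[k] = float(-(p * np.log(p)).sum())
        elif math.isinf(a):
            out[k] = float(-math.log(p.max()))
        else:
            out[k] = float(math.log((p ** a).sum()) / (1.0 - a))
    return DiversityProfile(np.asarray(alphas, dtype=float), out,
                            label=table.label)


def compare_profiles(a: DiversityProfile, b: DiversityProfile,
                     tol: float = 0.0) -> str:
    """Rank two diversity profiles on a common alpha grid.

    Returns ``"more_diverse"`` if ``a`` dominates ``b`` (H_alpha(a) ≥
    H_alpha(b) everywhere, strictly somewhere), ``"less_diverse"`` for the
    reverse, ``"tied"`` for identical profiles and ``"not_rankable"`` when
    the profiles cross: then no diversity ordering exists.
    """
    if a.alphas.shape != b.alphas.shape or not np.allclose(a.alphas, b.alphas):
        raise ValueError("profiles are on different alpha grids")
    diff = a.values - b.values
    above = bool(np.any(diff > tol))
    below = bool(np.any(diff < -tol))
    if above and below:
        return "not_rankable"
    if above:
        return "more_diverse"
    if below:
        return "less_diverse"
    return "tied"


def rank_profiles(profiles: Mapping[str, DiversityProfile]) -> pd.DataFrame:
    """Pairwise diversity ranking of several profiles (rows vs columns)."""
    labels = list(profiles)
    out = pd.DataFrame(index=labels, columns=labels, dtype=object)
    for i in labels:
        for j in labels:
            out.loc[i, j] = ("tied" if i == j
                             else compare_profiles(profiles[i], profiles[j]))
    return out


# ---------------------------------------------------------------------------
# clonal sharing and clonal space


def shared_dominant_clones(source: ClonotypeTable,
                           targets: Mapping[str, ClonotypeTable],
                           top_k: int = 100) -> pd.Series:
    """Count how many of the source's dominant clonotypes occur in each target.

    The source's ``top_k`` clonotypes by count (all, if fewer exist) are
    looked up by identity in each target repertoire.
    """
    dom = top_clones(source, n=top_k).identities
    counts = {name: int(dom.isin(t.identities).sum())
              for name, t in targets.items()}
    return pd.Series(counts, name=source.label)


def clonal_space(table: ClonotypeTable,
                 bins: Sequence[tuple[int, int | None]] = ((1, 10), (11, 100),
                                                           (101, None)),
                 ) -> pd.Series:
    """Fraction of the repertoire occupied by clone-rank bins.

    Clones are ranked by descending count (ties broken as in
    :func:`top_clones`); each ``(lo, hi)`` bin (1-based, inclusive, ``hi
    None`` = open-ended) receives the summed proportion of reads of the
    clones ranked inside it.
    """
    prev_hi = 0
    for lo, hi in bins:
        if lo <= prev_hi:
            raise ValueError("rank bins must be non-overlapping and ordered")
        prev_hi = lo if hi is None else hi
    ordered = top_clones(table, n=table.richness).records
    props = ordered["count"].to_numpy() / table.total
    out = {}
    for lo, hi in bins:
        hi_eff = len(props) if hi is None else min(hi, len(props))
        name = f"{lo}-{hi}" if hi is not None else f"{lo}+"
        out[name] = float(props[lo - 1:hi_eff].sum()) if lo <= len(props) else 0.0
    return pd.Series(out, name=table.label)
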