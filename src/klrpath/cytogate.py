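"""Cytometry-style gating of CD4+ T-cell events and group comparisons.

Events carry per-channel intensities.  Two label maps are derived from
boolean marker states (intensity strictly above a per-channel threshold):

* the classical CD45RA × CCR7 quadrants — T_N (RA+R7+), T_CM (RA−R7+),
  T_EM (RA−R7−), T_EMRA (RA+R7−) — after excluding CD25-high CD127-low
  regulatory T cells, and
* the progressive KLR/GPR56 scheme P1..P5 over the 4-bit
  (KLRB1, KLRG1, GPR56, KLRF1) pattern, from all-negative (P1) through
  sequential marker acquisition to all-positive (P5); the 11 non-canonical
  patterns are reported as ``off_path(...)`` with their pattern retained.

Donor-matched group comparisons use Friedman's test with Dunn's post-hoc
z tests on mean ranks; unmatched comparisons use Kruskal–Wallis + Dunn.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EventTable", "KLR_MARKERS", "CLASSIC_CHANNELS", "CANONICAL_PATTERNS",
    "estimate_thresholds", "gate_classic", "gate_klr",
    "coproducer_frequency", "subset_composition", "compare_groups",
    "GroupComparison", "stage_recovery_accuracy",
]

KLR_MARKERS = ("KLRB1", "KLRG1", "GPR56", "KLRF1")
CLASSIC_CHANNELS = ("CD45RA", "CCR7", "CD25", "CD127")
CYTOKINES = ("TNF", "IFNG", "IL4", "IL17A")

#: Canonical progressive 4-bit patterns (KLRB1, KLRG1, GPR56, KLRF1).
CANONICAL_PATTERNS: dict[tuple[bool, bool, bool, bool], str] = {
    (False, False, False, False): "P1",
    (True, False, False, False): "P2",
    (True, True, False, False): "P3",
    (True, True, True, False): "P4",
    (True, True, True, True): "P5",
}

#: KLRB1-negative analogues of the later stages (8-way composition maps).
_B1NEG_VARIANTS: dict[tuple[bool, bool, bool, bool], str] = {
    (False, True, False, False): "P3_B1neg",
    (False, True, True, False): "P4_B1neg",
    (False, True, True, True): "P5_B1neg",
}

_SHORT = {"KLRB1": "B1", "KLRG1": "G1", "GPR56": "56", "KLRF1": "F1"}


@dataclass
class EventTable:
    """Events × channels intensity table with per-channel thresholds.

    Columns prefixed ``truth_`` are hidden ground-truth annotations from
    the synthetic generator and are never consulted by any gating
    operation.  Positivity is strict: an event exactly at a threshold
    counts as negative.
    """

    data: pd.DataFrame
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def channels(self) -> list[str]:
        return [c for c in self.data.columns if not c.startswith("truth_")]

    def __len__(self) -> int:
        return len(self.data)

    def require(self, channels: Sequence[str]) -> None:
        missing = [c for c in channels if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing channels: {missing}")

    def marker_state(self, channel: str) -> pd.Series:
        """Boolean positivity of one channel (intensity > threshold)."""
        self.require([channel])
        if channel not in self.thresholds:
            raise ValueError(f"no threshold set for channel {channel!r}")
        return self.data[channel] > self.thresholds[channel]

    @classmethod
    def from_tsv(cls, path: str | Path,
                 thresholds: dict[str, float] | None = None) -> "EventTable":
        return cls(pd.read_csv(path, sep="\t"), thresholds or {})

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def estimate_thresholds(events: EventTable,
                        channels: Sequence[str] | None = None,
                        random_state: int = 0) -> dict[str, float]:
    """Per-channel positivity thresholds from a two-component fit.

    A two-component Gaussian mixture is fitted to log intensities; the
    threshold is the valley of the mixture density between the component
    means (the point where an event is equally likely under either
    component, weighted by mixing proportions).
    """
    channels = list(channels or events.channels)
    out: dict[str, float] = {}
    for ch in channels:
        x = np.log(events.data[ch].to_numpy(dtype=float).clip(min=1e-9))
        gm = GaussianMixture(n_components=2, random_state=random_state,
                             n_init=2).fit(x.reshape(-1, 1))
        means = gm.means_.ravel()
        lo, hi = np.sort(means)
        if hi - lo < 1e-6:  # effectively unimodal: midpoint fallback
            out[ch] = float(np.exp(lo))
            continue
        grid = np.linspace(lo, hi, 512)
        dens = np.exp(gm.score_samples(grid.reshape(-1, 1)))
        out[ch] = float(np.exp(grid[np.argmin(dens)]))
    return out


def _states(events: EventTable, markers: Sequence[str]) -> pd.DataFrame:
    events.require(markers)
    return pd.concat({m: events.marker_state(m) for m in markers}, axis=1)


def gate_classic(events: EventTable) -> pd.Series:
    """Label events as Treg or one of the CD45RA × CCR7 quadrants.

    Regulatory T cells (CD25 above its high threshold AND CD127 at/below
    its low threshold) are labeled ``"Treg"`` regardless of CD45RA/CCR7
    and are excluded from the conventional subsets, which partition the
    remaining events: T_N (RA+R7+), T_CM (RA−R7+), T_EM (RA−R7−),
    T_EMRA (RA+R7−).
    """
    events.require(CLASSIC_CHANNELS)
    treg = events.marker_state("CD25") & ~events.marker_state("CD127")
    ra = events.marker_state("CD45RA")
    r7 = events.marker_state("CCR7")
    labels = pd.Series("T_EMRA", index=events.data.index,
                       name="classic_subset")
    labels[~ra & ~r7] = "T_EM"
    labels[~ra & r7] = "T_CM"
    labels[ra & r7] = "T_N"
    labels[treg] = "Treg"
    return labels


def gate_klr(events: EventTable, extended: bool = False) -> pd.Series:
    """Map the 4-bit (KLRB1, KLRG1, GPR56, KLRF1) pattern to P1..P5.

    The five canonical progressive patterns map to P1..P5; any other
    pattern is labeled ``off_path(<pattern>)`` with the pattern rendered
    as e.g. ``B1-G1+56-F1-``.  With ``extended=True`` the KLRB1-negative
    analogues of P3/P4/P5 receive their own labels (the 8-way composition
    map) instead of off_path.
    """
    st = _states(events, KLR_MARKERS)
    table = dict(CANONICAL_PATTERNS)
    if extended:
        table.update(_B1NEG_VARIANTS)
    def render(bits: tuple[bool, ...]) -> str:
        patt = "".join(_SHORT[m] + ("+" if b else "-")
                       for m, b in zip(KLR_MARKERS, bits))
        return f"off_path({patt})"
    labels = [table.get(bits) or render(bits)
              for bits in map(tuple, st.to_numpy())]
    return pd.Series(labels, index=events.data.index, name="klr_population")


def coproducer_frequency(events: EventTable, grouping: pd.Series,
                         cytokines: tuple[str, str] = ("TNF", "IFNG")
                         ) -> pd.DataFrame:
    """Percent cytokine producers per group.

    Returns, per group, the percentage of events positive for each single
    cytokine and for both (co-producers).  Empty groups yield NaN rather
    than an error.
    """
    a, b = cytokines
    st_a, st_b = events.marker_state(a), events.marker_state(b)
    df = pd.DataFrame({f"{a}+": st_a, f"{b}+": st_b,
                       f"{a}+{b}+": st_a & st_b})
    grouping = grouping.reindex(events.data.index)
    return df.groupby(grouping, observed=True).mean() * 100.0


def subset_composition(events: EventTable,
                       classic_labels: pd.Series | None = None,
                       klr_labels: pd.Series | None = None,
                       within: Sequence[str] = ("T_EM", "T_EMRA"),
                       pool_off_path: bool = True) -> pd.DataFrame:
    """KLR/GPR56 population composition within classical subsets.

    For each classical subset in ``within``, the fraction of its events
    in each KLR population (off_path patterns pooled into one bucket by
    default).  Fractions sum to 1 per subset; empty subsets are omitted.
    """
    classic = classic_labels if classic_labels is not None else gate_classic(events)
    klr = klr_labels if klr_labels is not None else gate_klr(events)
    if pool_off_path:
        klr = klr.where(~klr.str.startswith("off_path"), "off_path")
    rows = {}
    for subset in within:
        sel = klr[classic == subset]
        if len(sel) == 0:
            continue
        rows[subset] = sel.value_counts(normalize=True)
    return pd.DataFrame(rows).T.fillna(0.0)


def stage_recovery_accuracy(events: EventTable) -> float:
    """Fraction of events whose gated KLR pattern matches the planted truth.

    The generator records each event's true marker states in
    ``truth_<marker>_on`` columns; gating recovers those states from the
    continuous intensities.  The accuracy is the fraction of events whose
    full 4-bit gated pattern equals the true pattern — equivalently,
    whose gated population label (P1..P5 or off_path) matches the label
    the true states imply.  It measures threshold separation only: an
    event whose true phenotype deviates from its generative stage is
    *correctly* gated as its actual pattern.
    """
    truth_cols = [f"truth_{m}_on" for m in KLR_MARKERS]
    missing = [c for c in truth_cols if c not in events.data.columns]
    if missing:
        raise ValueError(f"no planted truth columns: {missing}")
    pred = _states(events, KLR_MARKERS).to_numpy()
    truth = events.data[truth_cols].to_numpy(dtype=bool)
    return float(np.all(pred == truth, axis=1).mean())


# ---------------------------------------------------------------------------
# group comparisons (Friedman / Kruskal-Wallis with Dunn's post hoc)


@dataclass
class GroupComparison:
    """Omnibus statistic plus Dunn pairwise results."""

    test: str
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame  # columns: group1, group2, z, p, p_adj


def _dunn_pairs(mean_ranks: Mapping[str, float], se_fn, adjust: str
                ) -> pd.DataFrame:
    rows = []
    for g1, g2 in itertools.combinations(mean_ranks, 2):
        se = se_fn(g1, g2)
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((g1, g2, z, p))
    df = pd.DataFrame(rows, columns=["group1", "group2", "z", "p"])
    df["p_adj"] = multipletests(df["p"], method=adjust)[1].clip(0, 1)
    return df


def compare_groups(values, matched: bool = True,
                   adjust: str = "bonferroni") -> GroupComparison:
    """Compare ≥ 3 groups non-parametrically, with Dunn's post hoc.

    Matched design (``matched=True``): ``values`` is a complete-block
    DataFrame (rows = donors, columns = groups); Friedman's chi-square is
    the omnibus test and Dunn's z statistics use within-block mean ranks
    with SE = sqrt(k(k+1)/(6n)).  Unmatched: ``values`` is a mapping of
    group name to 1-d samples; Kruskal–Wallis is the omnibus test and
    Dunn's z uses pooled ranks with tie correction.  ``adjust`` is any
    statsmodels multiple-testing method applied over all tested pairs.

    Raises
    ------
    ValueError
        For incomplete blocks in the matched design (listing the missing
        donor/group cells) or fewer than 3 groups/donors.
    """
    if matched:
        df = pd.DataFrame(values)
        if df.shape[1] < 3:
            raise ValueError("matched comparison needs >= 3 groups")
        if df.shape[0] < 3:
            raise ValueError("matched comparison needs >= 3 donors")
        if df.isna().any().any():
            cells = [(i, c) for i, c in zip(*np.where(df.isna().to_numpy()))]
            missing = [(df.index[i], df.columns[c]) for i, c in cells]
            raise ValueError(f"incomplete blocks; missing cells: {missing}")
        n, k = df.shape
        ranks = df.rank(axis=1)
        if float(ranks.to_numpy().var()) == 0:  # every block fully tied
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.friedmanchisquare(*[df[c] for c in df.columns])
        mean_ranks = ranks.mean(axis=0).to_dict()
        se = np.sqrt(k * (k + 1) / (6.0 * n))
        posthoc = _dunn_pairs(mean_ranks, lambda a, b: se, adjust)
        return GroupComparison("friedman", float(stat), float(p), posthoc)

    groups = {k: np.asarray(v, dtype=float) for k, v in dict(values).items()}
    if len(groups) < 3:
        raise ValueError("unmatched comparison needs >= 3 groups")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*groups.values())
    N = len(pooled)
    all_ranks = stats.rankdata(pooled)
    sizes, mean_ranks, start = {}, {}, 0
    for g, v in groups.items():
        sizes[g] = len(v)
        mean_ranks[g] = all_ranks[start:start + len(v)].mean()
        start += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (N - 1))
    def se_fn(a: str, b: str) -> float:
        return np.sqrt((N * (N + 1) / 12.0 - tie_term)
                       * (1.0 / sizes[a] + 1.0 / sizes[b]))
    posthoc = _dunn_pairs(mean_ranks, se_fn, adjust)
    return GroupComparison("kruskal", float(stat), float(p), posthoc)
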