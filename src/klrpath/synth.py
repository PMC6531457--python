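"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators emulate the pipeline's input kinds without any external
data:

* :func:`gen_events` — cytometry-style event tables over a five-stage
  progressive differentiation model (P1..P5: sequential acquisition of
  KLRB1, KLRG1, GPR56, KLRF1) with naive-like CD45RA/CCR7 structure, a
  Treg background, and unimodal TNF/IFN-γ co-production peaking at the
  intermediate stages;
* :func:`gen_ct_matrix` — single-cell qRT-PCR Ct matrices with bimodal
  Ct distributions around a limit of detection and B2M/Spike1 controls;
* :func:`gen_repertoires` — clonally expanded TCRβ repertoires whose
  rank-frequency decay steepens along the stages (diversity falls
  P1→P5) and whose late-stage dominant clones seed earlier stages;
* :func:`gen_bulk` — bulk log2 expression matrices with planted subset
  signatures.

Every generator is deterministic under a fixed seed, and every event
table carries hidden ``truth_`` columns so downstream modules can be
scored against the planted ground truth while running blinded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bulkde import BulkMatrix
from .cytogate import CANONICAL_PATTERNS, EventTable, KLR_MARKERS
from .repertoire import ClonotypeTable
from .scqpcr import DEFAULT_LOD, CtMatrix

__all__ = [
    "StageModel", "RepertoireModel",
    "gen_events", "gen_ct_matrix", "gen_repertoires", "gen_bulk",
    "gen_reads", "reads_to_fastq",
]

STAGES = ("P1", "P2", "P3", "P4", "P5")

#: Default two-component log-normal intensity parameters, shared across
#: channels: negative events around 100 a.u., positive around 3000 a.u.
_NEG = (math.log(100.0), 0.45)
_POS = (math.log(3000.0), 0.45)

_ALL_CHANNELS = ("CCR7", "CD45RA", "CD25", "CD127",
                 "KLRB1", "KLRG1", "GPR56", "KLRF1",
                 "TNF", "IFNG", "IL4", "IL17A")


def _default_marker_on_prob() -> pd.DataFrame:
    # rows: stages (+ Treg); columns: boolean-state channels.
    # KLR markers acquire progressively; CCR7 is lost and CD45RA follows
    # the naive-high / memory-low / late re-expression pattern.
    rows = {
        #          KLRB1  KLRG1  GPR56  KLRF1  CCR7  CD45RA  IL4   IL17A
        "P1":    (0.02,  0.02,  0.02,  0.01,  0.85, 0.75,  0.02, 0.01),
        "P2":    (0.98,  0.05,  0.03,  0.02,  0.55, 0.15,  0.03, 0.10),
        "P3":    (0.98,  0.98,  0.05,  0.03,  0.15, 0.10,  0.03, 0.03),
        "P4":    (0.98,  0.98,  0.98,  0.05,  0.05, 0.30,  0.02, 0.01),
        "P5":    (0.98,  0.98,  0.98,  0.98,  0.02, 0.80,  0.01, 0.01),
        "Treg":  (0.10,  0.05,  0.02,  0.01,  0.60, 0.20,  0.02, 0.02),
    }
    cols = ("KLRB1", "KLRG1", "GPR56", "KLRF1", "CCR7", "CD45RA",
            "IL4", "IL17A")
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _default_cytokine_prob() -> pd.DataFrame:
    # joint TNF/IFN-γ production per stage: co-producers rise to a
    # maximum at P3/P4 and collapse at P5 (the exhausted phenotype).
    rows = {
        #          co    tnf_only  ifng_only
        "P1":    (0.04,  0.06,     0.02),
        "P2":    (0.28,  0.30,     0.05),
        "P3":    (0.55,  0.20,     0.08),
        "P4":    (0.52,  0.18,     0.10),
        "P5":    (0.12,  0.10,     0.06),
        "Treg":  (0.02,  0.04,     0.02),
    }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["co", "tnf_only", "ifng_only"])


@dataclass
class StageModel:
    """Generative model of the five-stage progressive marker acquisition.

    Attributes
    ----------
    stages : ordered stage labels P1..P5 (Treg is a background class).
    marker_on_prob : per stage × channel probability of positivity; the
        four KLR markers are monotonically acquired along P1→P5.
    cytokine_prob : per stage probabilities of TNF+IFN-γ+ co-production
        and single production; co-production is unimodal with its peak at
        P3/P4.
    intensity_params : per channel ``{"neg": (meanlog, sdlog), "pos": ...}``
        of the two log-normal intensity components.
    stage_mix : stage proportions per sample (including the Treg
        background), summing to 1.
    """

    stages: tuple[str, ...] = STAGES
    marker_on_prob: pd.DataFrame = field(default_factory=_default_marker_on_prob)
    cytokine_prob: pd.DataFrame = field(default_factory=_default_cytokine_prob)
    intensity_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {ch: {"neg": _NEG, "pos": _POS}
                                 for ch in _ALL_CHANNELS})
    stage_mix: dict[str, float] = field(default_factory=lambda: {
        "Treg": 0.05, "P1": 0.40, "P2": 0.20, "P3": 0.15,
        "P4": 0.12, "P5": 0.08})

    def __post_init__(self) -> None:
        probs = pd.concat([self.marker_on_prob, self.cytokine_prob], axis=1)
        if ((probs < 0) | (probs > 1)).any().any():
            raise ValueError("probabilities must lie in [0, 1]")
        if not math.isclose(sum(self.stage_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("stage_mix must sum to 1")
        on = self.marker_on_prob.loc[list(self.stages), list(KLR_MARKERS)]
        if (on.diff().dropna() < -1e-12).any().any():
            raise ValueError("KLR marker acquisition must be monotone P1->P5")
        co = self.cytokine_prob.loc[list(self.stages), "co"].to_numpy()
        peak = int(np.argmax(co))
        rising = np.all(np.diff(co[:peak + 1]) >= 0)
        falling = np.all(np.diff(co[peak:]) <= 0)
        if peak not in (2, 3) or not (rising and falling):
            raise ValueError("co-production must be unimodal with its "
                             "maximum at P3 or P4")

    def default_thresholds(self) -> dict[str, float]:
        """Geometric midpoint between the two intensity components."""
        return {ch: math.exp(0.5 * (p["neg"][0] + p["pos"][0]))
                for ch, p in self.intensity_params.items()}


def gen_events(model: StageModel, n_cells: int, seed: int) -> EventTable:
    """Draw an event table of ``n_cells`` from a :class:`StageModel`.

    Each event gets a hidden stage (``truth_stage``), boolean marker
    states drawn from the stage's probabilities, and intensities from the
    matching log-normal component.  Treg events are CD25-positive and
    CD127-negative; all other events the reverse.  Identical
    ``(model, n_cells, seed)`` produce byte-identical tables.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    degenerate = model.marker_on_prob.loc[
        list(model.stage_mix)].eq(0).all(axis=1)
    if degenerate.any():
        warnings.warn("stage(s) with all-zero marker probabilities: "
                      f"{list(degenerate.index[degenerate])}")
    rng = np.random.default_rng(seed)
    names = list(model.stage_mix)
    stage = rng.choice(names, size=n_cells, p=list(model.stage_mix.values()))
    cols: dict[str, np.ndarray] = {}
    state: dict[str, np.ndarray] = {}
    for ch in model.marker_on_prob.columns:
        p_on = model.marker_on_prob[ch].reindex(stage).to_numpy()
        state[ch] = rng.random(n_cells) < p_on
    # joint TNF / IFN-γ states
    cy = model.cytokine_prob.reindex(stage)
    u = rng.random(n_cells)
    co = cy["co"].to_numpy()
    tnf_only = cy["tnf_only"].to_numpy()
    ifng_only = cy["ifng_only"].to_numpy()
    state["TNF"] = (u < co) | ((u >= co) & (u < co + tnf_only))
    state["IFNG"] = (u < co) | ((u >= co + tnf_only)
                                & (u < co + tnf_only + ifng_only))
    is_treg = stage == "Treg"
    state["CD25"] = is_treg.copy()
    state["CD127"] = ~is_treg
    for ch in _ALL_CHANNELS:
        pneg = model.intensity_params[ch]["neg"]
        ppos = model.intensity_params[ch]["pos"]
        meanlog = np.where(state[ch], ppos[0], pneg[0])
        sdlog = np.where(state[ch], ppos[1], pneg[1])
        cols[ch] = np.exp(rng.normal(meanlog, sdlog))
    df = pd.DataFrame(cols)
    df["truth_stage"] = stage
    for ch in ("KLRB1", "KLRG1", "GPR56", "KLRF1", "TNF", "IFNG"):
        df[f"truth_{ch}_on"] = state[ch]
    return EventTable(df, thresholds=model.default_thresholds())


def gen_ct_matrix(subset_profiles: pd.DataFrame | Mapping[str, Mapping[str, float]],
                  n_cells: int, seed: int,
                  lod: Mapping[str, float] | None = None,
                  failed_control_frac: float = 0.05,
                  missing_frac: float = 0.7) -> CtMatrix:
    """Simulate a single-cell qRT-PCR chip run.

    ``subset_profiles`` gives, per subset (rows) and gene (columns), the
    fraction of cells expressing the gene; ``n_cells`` cells are drawn
    per subset.  Expressing cells draw Ct from a normal centred 8 cycles
    below the gene's LoD (truncated below the LoD); non-expressing cells
    are missing with probability ``missing_frac``, otherwise at/above the
    LoD.  A ``failed_control_frac`` fraction of cells loses both control
    genes (failed wells).  B2M and Spike1 are appended automatically as
    fully expressing controls.
    """
    profiles = pd.DataFrame(subset_profiles)
    if ((profiles < 0) | (profiles > 1)).any().any():
        raise ValueError("expressing fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(profiles.columns) + ["B2M", "Spike1"]
    lod_s = pd.Series({g: (lod or {}).get(g, DEFAULT_LOD) for g in genes})
    rows, labels, index = [], [], []
    for subset in profiles.index:
        for i in range(n_cells):
            cell = {}
            for gene in genes:
                frac = 1.0 if gene in ("B2M", "Spike1") \
                    else float(profiles.loc[subset, gene])
                g_lod = lod_s[gene]
                if rng.random() < frac:  # expressing: Ct strictly below LoD
                    ct = rng.normal(g_lod - 8.0, 2.0)
                    ct = float(np.clip(ct, 5.0, g_lod - 0.1))
                else:
                    if rng.random() < missing_frac:
                        ct = np.nan
                    else:
                        ct = float(g_lod + abs(rng.normal(1.5, 1.0)))
                cell[gene] = ct
            rows.append(cell)
            labels.append(subset)
            index.append(f"{subset}_c{i:04d}")
    values = pd.DataFrame(rows, index=index, columns=genes)
    failed = rng.random(len(values)) < failed_control_frac
    values.loc[failed, ["B2M", "Spike1"]] = np.nan
    return CtMatrix(values, lod=lod_s,
                    cell_subsets=pd.Series(labels, index=index))


@dataclass
class RepertoireModel:
    """Generative model of stage-wise clonally expanded TCRβ repertoires.

    ``expansion_law`` holds the rank-frequency power-law exponent per
    stage (clone rank r has expected frequency ∝ r^−a); the exponent
    grows along P1→P5, so expected Rényi diversity decreases along the
    path.  ``sharing_matrix`` maps (source, target) stage index pairs to
    the probability that a clone dominant in the (late) source stage also
    occurs in the (earlier) target stage; adjacent late stages share more
    than distal pairs.
    """

    n_clones: dict[str, int] = field(default_factory=lambda: {
        "P1": 2500, "P2": 2000, "P3": 1500, "P4": 1200, "P5": 1000})
    expansion_law: dict[str, float] = field(default_factory=lambda: {
        "P1": 0.30, "P2": 0.60, "P3": 0.90, "P4": 1.20, "P5": 1.50})
    sharing_matrix: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("P4", "P5"): 0.50, ("P5", "P4"): 0.50,
            ("P4", "P3"): 0.30, ("P4", "P2"): 0.15, ("P4", "P1"): 0.05,
            ("P5", "P3"): 0.25, ("P5", "P2"): 0.12, ("P5", "P1"): 0.04})
    read_depth: int = 30000
    n_dominant: int = 100
    quality_mean: float = 36.0
    quality_sd: float = 3.0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_clones.values()):
            raise ValueError("need at least one clone per stage")
        exps = [self.expansion_law[s] for s in STAGES if s in self.expansion_law]
        if any(np.diff(exps) <= 0):
            raise ValueError("expansion exponent must increase along P1->P5")


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_clonotype(rng: np.random.Generator) -> tuple[str, str, str]:
    v = f"TRBV{rng.integers(1, 31)}"
    j = f"TRBJ{rng.integers(1, 3)}-{rng.integers(1, 8)}"
    core = "".join(rng.choice(_AA, size=int(rng.integers(6, 13))))
    return v, j, f"CASS{core}F"


def gen_repertoires(model: RepertoireModel, seed: int
                    ) -> dict[str, ClonotypeTable]:
    """Generate one clonotype table per stage.

    Each stage draws ``read_depth`` reads multinomially from a power-law
    rank-frequency distribution over its own clone identities; afterwards
    the dominant (top ``n_dominant``) clones of stages P4/P5 replace
    mid-rank clones of other stages with the probabilities in
    ``sharing_matrix``, modelling clonal continuity along the path.
    """
    rng = np.random.default_rng(seed)
    identities: dict[str, list[tuple[str, str, str]]] = {}
    seen: set[tuple[str, str, str]] = set()
    for stage, n in model.n_clones.items():
        ids = []
        while len(ids) < n:
            c = _random_clonotype(rng)
            if c not in seen:
                seen.add(c)
                ids.append(c)
        identities[stage] = ids
    # cross-stage sharing: dominant late-stage clones seed other stages
    for (src, tgt), prob in model.sharing_matrix.items():
        if src not in identities or tgt not in identities:
            continue
        top = identities[src][:model.n_dominant]
        n_tgt = len(identities[tgt])
        late_pair = src in ("P4", "P5") and tgt in ("P4", "P5")
        for k, clone in enumerate(top):
            if rng.random() < prob and clone not in identities[tgt]:
                # a clone shared between the adjacent late stages stays
                # dominant in both; clones seeded back into earlier
                # stages sit at low ranks there
                if late_pair:
                    # approximately rank-preserving: the clone is about as
                    # expanded in the neighbouring late stage
                    pos = int(np.clip(k + rng.integers(-5, 6), 0,
                                      min(model.n_dominant, n_tgt) - 1))
                else:
                    pos = int(rng.integers(n_tgt // 4, n_tgt))
                identities[tgt][pos] = clone
    tables = {}
    for stage, ids in identities.items():
        a = model.expansion_law[stage]
        ranks = np.arange(1, len(ids) + 1, dtype=float)
        p = ranks ** (-a)
        p /= p.sum()
        counts = rng.multinomial(model.read_depth, p)
        keep = counts > 0
        df = pd.DataFrame(
            [(v, j, c, int(n)) for (v, j, c), n, k in
             zip(ids, counts, keep) if k],
            columns=["v_gene", "j_gene", "cdr3_aa", "count"])
        tables[stage] = ClonotypeTable(df, label=stage)
    return tables


_CODON = {a: c for a, c in zip(
    "ACDEFGHIKLMNPQRSTVWY",
    ["GCT", "TGT", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT", "AAA", "CTT",
     "ATG", "AAT", "CCT", "CAA", "CGT", "TCT", "ACT", "GTT", "TGG", "TAT"])}


def gen_reads(table: ClonotypeTable, seed: int,
              quality_mean: float = 36.0, quality_sd: float = 3.0):
    """Expand a clonotype table into per-read records with quality scores.

    Each clonotype contributes ``count`` reads; the read sequence is a
    deterministic codon expansion of the CDR3 and the per-read mean
    quality is drawn from a clipped normal.  Read ids carry the clonotype
    annotation ``read<k>|<v>|<j>|<cdr3>`` consumed by
    :func:`klrpath.repertoire.clonotypes_from_reads`.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    rng = np.random.default_rng(seed)
    records = []
    k = 0
    for _, row in table.records.iterrows():
        nt = "".join(_CODON[a] for a in row["cdr3_aa"])
        for _ in range(int(row["count"])):
            q = int(np.clip(round(rng.normal(quality_mean, quality_sd)), 2, 40))
            rec = SeqRecord(
                Seq(nt),
                id=f"read{k}|{row['v_gene']}|{row['j_gene']}|{row['cdr3_aa']}",
                description="")
            rec.letter_annotations["phred_quality"] = [q] * len(nt)
            records.append(rec)
            k += 1
    return records


def reads_to_fastq(records, path: str | Path) -> None:
    """Write read records as Phred+33 FASTQ."""
    from Bio import SeqIO
    SeqIO.write(records, str(path), "fastq")


def gen_bulk(signature: Mapping[str, tuple[Sequence[str], float]] | None,
             n_replicates: int = 6, noise_sd: float = 0.25, seed: int = 0,
             n_background_genes: int = 200,
             subsets: Sequence[str] = ("T_N", "T_CM", "T_EM", "T_EMRA")
             ) -> BulkMatrix:
    """Simulate a bulk log2 expression matrix with planted signatures.

    ``signature`` maps gene symbols to ``(subsets_up, linear_fold)``: the
    gene's mean is shifted by ``log2(fold)`` in the listed subsets.  All
    folds must be positive.  Background genes have no subset effect.
    """
    signature = dict(signature or {})
    for gene, (_, fold) in signature.items():
        if fold <= 0:
            raise ValueError(f"fold for {gene!r} must be positive")
    rng = np.random.default_rng(seed)
    genes = list(signature) + [f"BG{i:04d}" for i in range(n_background_genes)]
    baseline = pd.Series(rng.normal(7.0, 1.0, size=len(genes)), index=genes)
    rows, labels, index = [], [], []
    for subset in subsets:
        for r in range(n_replicates):
            shift = pd.Series(0.0, index=genes)
            for gene, (ups, fold) in signature.items():
                if subset in ups:
                    shift[gene] = math.log2(fold)
            vals = baseline + shift + rng.normal(0.0, noise_sd, size=len(genes))
            rows.append(vals)
            labels.append(subset)
            index.append(f"{subset}_r{r}")
    values = pd.DataFrame(rows, index=index)
    return BulkMatrix(values, pd.Series(labels, index=index))
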