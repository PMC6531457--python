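# Methods

This note documents the models implemented in `klrpath`, the defaults
and why they were chosen, and what the synthetic benchmark does and does
not establish about real data.

## The progressive-marker model

The pipeline is organised around a five-population classification of
CD4⁺ memory T cells by combinational surface expression of KLRB1
(CD161), KLRG1, GPR56 (ADGRG1) and KLRF1 (NKp80). The canonical
patterns are acquired sequentially:

| population | KLRB1 | KLRG1 | GPR56 | KLRF1 |
|---|---|---|---|---|
| P1 | − | − | − | − |
| P2 | + | − | − | − |
| P3 | + | + | − | − |
| P4 | + | + | + | − |
| P5 | + | + | + | + |

The remaining 11 boolean patterns are reported as `off_path` with their
pattern preserved; an extended 8-way map additionally names the
KLRB1-negative analogues of P3–P5, which occur at low frequency in real
samples. Functionally, TNF/IFN-γ co-production follows a
low → high → exhausted arc along P1→P5 with its maximum at P3/P4.

## Synthetic-data generator (`synth`)

The generator defines the conditions under which the pipeline is
exercised and validated. Its defaults were fixed once, before any
downstream tuning, to values a cytometrist would call realistic for
peripheral-blood CD4⁺ T cells:

- **Stage mixture** — Treg 5%, P1 40%, P2 20%, P3 15%, P4 12%, P5 8%.
  Early populations dominate; the all-positive population is rare.
- **Marker states** — per stage, each marker is positive with
  probability 0.98 when the canonical pattern says "on" and 0.01–0.05
  when "off". The 1–5% flip rates produce the off-path patterns seen in
  real data; they are biological noise, not measurement noise. The
  model validates that each KLR marker's on-probability is monotone
  non-decreasing along P1→P5.
- **Cytokines** — joint TNF/IFN-γ states per stage; co-production
  probabilities 0.04, 0.28, 0.55, 0.52, 0.12 along P1→P5 (validated
  unimodal with peak at P3/P4). CCR7 is lost monotonically; CD45RA is
  high in P1 (naive-like), low in the middle and re-expressed in P5
  (the T_EMRA phenotype).
- **Intensities** — every channel draws from a two-component log-normal:
  negative events exp(N(ln 100, 0.45)), positive exp(N(ln 3000, 0.45)),
  in arbitrary fluorescence units. The ~3.4 log-unit separation at
  σ = 0.45 makes component overlap negligible (<10⁻⁴ per channel), so
  gating errors under default conditions are rare; tighter separations
  can be configured to study degradation.
- **Repertoires** — each stage's clone rank-frequency law is a power
  law p(r) ∝ r^(−a) with exponents 0.3, 0.6, 0.9, 1.2, 1.5 along
  P1→P5 (validated increasing), clone pools of 2,500 down to 1,000, and
  30,000 reads drawn multinomially. Steeper exponents concentrate the
  repertoire, so expected Rényi diversity decreases along the path at
  every α. Dominant clones of P4/P5 are seeded into other stages with
  the configured sharing probabilities: between the adjacent late pair
  (P4, P5) a shared clone keeps approximately its source rank (clonal
  continuity — it is expanded in both), whereas clones seeded back into
  P1–P3 land at low ranks. Sharing probabilities decay with stage
  distance (e.g. P4→P3 0.30, P4→P1 0.05).
- **qRT-PCR matrices** — expressing cells draw Ct ~ N(LoD − 8, 2)
  truncated below the LoD; non-expressing cells are missing with
  probability 0.7 or land just above the LoD; 5% of cells lose both
  control genes (failed wells).

Hidden truth (`truth_stage`, `truth_<marker>_on`) is always emitted in
namespaced columns that no analysis operation reads.

**What the generator does not emulate:** donor-to-donor heterogeneity,
spectral spillover and compensation artifacts, chip-position effects,
doublets, or sequencing error in CDR3 sequences. Passing the recovery
tests therefore shows the algorithms are correct and well-calibrated
under the assumed statistical structure, not that they are robust to
every artifact of real instruments.

## Single-cell qRT-PCR preprocessing (`scqpcr`)

Expression is `Log2Ex = LoD − Ct`, clamped to 0 for missing or
at/above-LoD measurements; a cell expresses a gene iff `Log2Ex > 0`.
The default LoD is Ct 24. Per-gene adjustment smooths a 0.5-cycle Ct
histogram with a Gaussian kernel (bandwidth 1 cycle) and, when the
density is bimodal, moves the LoD to the valley between the two most
populated modes, capped at the default; genes with fewer than 20
amplifying cells or unimodal distributions keep the default, and an
explicit per-gene override file wins over the heuristic. Filtering
removes cells without detectable B2M/Spike1, then genes expressed in
fewer than 10 remaining cells (boundary inclusive: 10 expressing cells
retain the gene). Clustering uses Ward linkage on Euclidean distance
over the continuous Log2Ex values — the binarized matrix is a rendering
choice, not the clustering input — with rows pre-sorted by cell
identifier so dendrograms are reproducible under record reordering.
Missing-value sentinels (blank, `NA`, `999`) are normalized at read
time because instrument exports vary.

## Bulk intersection analysis (`bulkde`)

Quantile normalization forces each sample's sorted values onto the
cross-sample mean of order statistics; ties receive the mean of the
reference values they span (verified against limma's
`normalizeQuantiles` in the test suite). Per-gene tests are Welch's
unequal-variance t-test by default — the safer choice when replicate
variances differ — with Student's available by flag; fold change is
`2^(Δ mean log2)`, so "twofold up" means a log2 difference of 1.
Selection requires fold ≥ 2 (inclusive) and p < 0.05 (strict) in every
required comparison; no multiple-testing correction is applied inside
the intersection by default (the intersection across three or four
comparisons is itself the stringency), with an optional
Benjamini–Hochberg mode. Probe-to-gene collapsing is out of scope:
inputs are gene-level matrices.

## Gating and group comparisons (`cytogate`)

Positivity is strict (`intensity > threshold`); events exactly at a
threshold are negative, for determinism. When thresholds are not
supplied they are estimated per channel as the minimum of a
two-component Gaussian-mixture density fitted to log intensities,
between the component means. Treg events (CD25 above threshold, CD127
at/below) are excluded before the CD45RA × CCR7 quadrants are assigned.
`stage_recovery_accuracy` scores the gated 4-bit pattern against the
generator's planted marker states: it isolates threshold quality, since
an event whose true phenotype deviates from its generative stage is
correctly gated as its actual pattern.

Matched ≥3-group comparisons use Friedman's chi-square with Dunn's
post-hoc z tests on within-block mean ranks (SE = √(k(k+1)/6n));
unmatched comparisons use Kruskal–Wallis with Dunn's pooled-rank z
tests including the tie correction. Dunn's adjustment is Bonferroni
over all tested pairs by default (Dunn's original proposal) and
configurable to any statsmodels method. Fully tied data yield statistic
0 and p = 1 rather than an error.

## Repertoire statistics (`repertoire`)

Clonotype identity is the (Vβ gene, Jβ gene, CDR3 amino-acid) triple;
duplicate identities aggregate on construction. Reads with mean Phred
quality below 30 are excluded (exactly 30 is retained). The top-100
selection breaks ties by (count descending, V, J, CDR3), making it
invariant to record order. The Morisita–Horn index is computed in two
algebraically equivalent forms — raw counts with squared totals, and
proportions — and both are asserted equal to 10⁻¹²; this guards the
implementation against the easy-to-make squared/unsquared notational
slip. Rényi profiles use natural logarithms on the default α grid
0, 0.25, 0.5, 1, 2, 4, 8, 16, 32, 64, ∞, with the α ∈ {0, 1, ∞} limits
evaluated analytically. Profile comparison declares dominance only when
one profile is ≥ the other at every grid α and strictly greater
somewhere; crossing profiles are `not_rankable` because the diversity
ordering genuinely depends on α there. Clonal-space rank bins default
to 1–10 / 11–100 / 101+ and are configurable.

## Trajectory (`trajectory`)

Channels (CCR7, CD45RA, KLRB1, KLRG1, KLRF1, GPR56, TNF, IFN-γ) are log
transformed and robust z-scored (median/MAD) per channel before any
geometry, because intensity scales differ by fluorophore.

**Density-dependent downsampling** estimates local density as the
inverse mean distance to the 15 nearest neighbours, retains events with
probability min(1, c/density) with c found by bisection so the expected
kept count equals the 50,000-event default budget, and enforces the
exact output size by a final uniform trim or top-up. This flattens the
k-NN density landscape so rare late-stage populations survive; note
that in d dimensions the k-NN distance compresses raw abundance ratios
(≈ ratio^(1/d)), so equalization is in the k-NN density metric, which
is also how the tests measure it.

**Pseudotime** builds a symmetric k-nearest-neighbour distance graph
(k = 15; disconnected components are joined through their closest
inter-component pair, with a warning). Initiator cells are the naive
phenotype: CD45RA⁺CCR7⁺ and negative for all four KLR markers — the KLR
condition matters because CD45RA re-expression makes some terminally
differentiated cells CD45RA⁺CCR7 *dim*-positive by threshold noise, and
such contaminants would corrupt the anchor. Per ensemble repeat, 50
initiators and 200 waypoints are sampled; the mean shortest-path
distance from the sampled initiators is the starting trajectory
(averaging removes the dependence on any single start cell), and two
refinement sweeps replace each event's position with the
inverse-distance-weighted average of all waypoint perspectives
t(w) ± d(w, event). Each repeat is scaled by its 1st–99th percentiles
(clipped), five repeats are averaged, and the mean is min–max scaled to
[0, 1]. Five repeats with 50 sources and 200 waypoints keep the
run-to-run and input-permutation mean absolute difference under 0.02 on
the default benchmark while remaining interactive (seconds at 4,000–
8,000 events). The validation surface for this module is ordering
recovery — monotone stage means, Spearman ≥ 0.8 against hidden stage,
correct acquisition order — not numeric identity with any particular
trajectory tool.

**Binned curves** split events into 20 pseudotime-quantile bins (ties
merged), take per-bin channel medians, min–max normalize per channel,
and define the acquisition order by the interpolated bin position where
each marker's normalized curve first rises through 0.5 — a scale-free
threshold matching the qualitative readout of relative-expression
plots. Flat channels are excluded from the ordering.

## Problem sizes

The bundled tests run the full benchmark at reduced scale — 4,000–
60,000 events for gating and trajectory, 30,000-read repertoires,
6 replicates per bulk subset — sizes at which every statistical
tolerance (3 SE moment checks, ≥95% gating recovery, Spearman ≥ 0.8)
has comfortable margin. The acceptance script runs the downsampling
stage at its full 200,000-event input.

## Known limitations

- The LoD valley heuristic assumes at most two Ct modes; genes with
  three-mode distributions keep whichever valley lies between the two
  most populated modes.
- The pseudotime is a one-dimensional ordering; branching trajectories
  are out of scope.
- FCS binary parsing, compensation/spillover, V(D)J alignment from raw
  reads, and t-SNE embedding are out of scope; event tables and
  clonotype tables arrive as TSV exports.
- Dunn's z tests use the normal approximation; for very small donor
  counts (n < 5) exact permutation p-values would be preferable.
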