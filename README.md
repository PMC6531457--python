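# klrpath

Analysis pipeline for the progressive classification of human CD4⁺ memory
T cells by combinational expression of three killer-like receptors and
GPR56. During memory T-cell differentiation these surface markers are
acquired sequentially — KLRB1 first, then KLRG1, then GPR56, and finally
KLRF1 — which partitions CD4⁺ T cells into five populations, P1
(all-negative) through P5 (all-positive), that track functional state:
cytokine production (TNF/IFN-γ co-production) rises from P1 to a maximum
at P3/P4 and collapses in the exhausted P5 population, while T-cell
receptor (TCRβ) clonality rises and diversity falls along the same path.

The package is aimed at immunologists analysing cytometry event tables,
single-cell qRT-PCR chips, bulk expression matrices and TCRβ clonotype
tables, and ships a synthetic-data generator that emulates all four input
kinds so every stage of the pipeline runs and is testable without any
external data.

## What it computes

- **`klrpath.scqpcr`** — single-cell qRT-PCR preprocessing. Expression is
  `Log2Ex = LoD − Ct` with a default limit of detection at Ct 24 and an
  optional per-gene LoD tightened to the valley between the expressing
  and noise modes of the Ct histogram. Cells without detectable B2M or
  Spike1 controls and genes expressed in fewer than 10 cells are
  excluded; cells and genes are clustered with Ward linkage on Euclidean
  distance.
- **`klrpath.bulkde`** — intersection differential expression across
  sorted subsets (T_N, T_CM, T_EM, T_EMRA): quantile normalization,
  per-gene two-sample t-tests, and candidate selection requiring at
  least twofold upregulation at p < 0.05 in *every* required pairwise
  comparison, optionally restricted to a surfaceome gene list.
- **`klrpath.cytogate`** — gating: CD45RA × CCR7 quadrants with
  CD25-high/CD127-low Treg exclusion; the 4-bit (KLRB1, KLRG1, GPR56,
  KLRF1) pattern mapped to P1..P5 (non-canonical patterns labelled
  `off_path`); cytokine producer frequencies; Friedman or Kruskal–Wallis
  omnibus tests with Dunn's post-hoc z tests.
- **`klrpath.repertoire`** — TCRβ clonotype statistics. Clonotypes are
  (Vβ, Jβ, CDR3aa) triples; reads below mean Phred quality 30 are
  dropped and the top 100 expanded clones are selected. Similarity is
  the Morisita–Horn index

  S = 2 Σᵢ pᵢqᵢ / (Σᵢ pᵢ² + Σᵢ qᵢ²),

  computed equivalently on raw counts and on proportions. Diversity is
  the Rényi profile H_α = ln(Σᵢ pᵢ^α)/(1 − α), with H₀ = ln richness,
  H₁ = Shannon entropy, H₂ = ln(1/Simpson) and H_∞ = −ln max pᵢ; one
  repertoire is more diverse than another only if its profile dominates
  at every α — crossing profiles are not rankable.
- **`klrpath.trajectory`** — density-dependent downsampling to a
  50,000-event budget and a waypoint-ensemble graph pseudotime anchored
  at naive (CD45RA⁺CCR7⁺, KLR-negative) initiator cells, with binned
  relative median expression curves and the inferred marker acquisition
  order.
- **`klrpath.synth`** — generators for all four input kinds with planted
  ground truth (`truth_*` columns) for recovery testing.

## Worked example

```python
import numpy as np
from klrpath import synth, cytogate, repertoire, trajectory

model = synth.StageModel()
events = synth.gen_events(model, 20000, seed=1)
klr = cytogate.gate_klr(events)
print(cytogate.coproducer_frequency(events, klr)
      .loc[["P1", "P2", "P3", "P4", "P5"], "TNF+IFNG+"].round(1).to_dict())

reps = synth.gen_repertoires(synth.RepertoireModel(), seed=2)
p1 = repertoire.renyi_profile(reps["P1"])
p5 = repertoire.renyi_profile(reps["P5"])
print(p1.as_series()[2.0], p5.as_series()[2.0],
      repertoire.compare_profiles(p1, p5))

ds = trajectory.density_downsample(events, target_total=5000, seed=3)
res = trajectory.binned_curves(trajectory.pseudotime(ds, seed=4), ds)
print(res.acquisition_order)
```

prints

```
{'P1': 3.9, 'P2': 27.5, 'P3': 53.5, 'P4': 50.3, 'P5': 16.0}
7.580... 1.694... more_diverse
['KLRB1', 'KLRG1', 'GPR56', 'KLRF1']
```

The TNF/IFN-γ co-producer percentage per gated population is unimodal —
low in P1, peaking at P3/P4 and collapsing in P5 (the exhausted
phenotype). The order-2 Rényi entropy of the most differentiated
repertoire (1.69 nats) lies far below the all-negative population (7.58
nats) and its whole profile is dominated, so P1 is strictly more
diverse. The pseudotime trajectory recovers the KLRB1 → KLRG1 → GPR56 →
KLRF1 acquisition order from the event intensities alone.

The same analyses are scriptable from the shell:

```bash
klrpath run-all --seed 1 --out runs/demo
```

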