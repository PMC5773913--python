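# Methods

## Scoring model

`scprank` scores each protein in an undirected PPI network by a convex
combination of two independently computed channels.

**Network channel (MPR).** Compartment co-localization is converted into
edge weights: the importance of a compartment is the reciprocal of its
member count (`ISC(C) = 1/N_C`), so small compartments — which concentrate
specific biological processes — weigh interactions up. An interacting pair
sharing at least one compartment receives the *maximum* importance over the
shared compartments; a pair sharing none receives the *minimum* importance
over the union of both compartment sets, treating non-co-located
interactions as no more reliable than the largest compartment either protein
belongs to. The per-protein sum of incident edge weights (IPSC) serves as a
prior. The modified PageRank then iterates

    v  ←  α · M₁ v + (1 − α) · r · Σv ,     v ← v / ‖v‖₁ ,

with `M₁(i,j) = W(i,j) / Σ_k W(i,k)` over the neighbours of `i` and
`r = IPSC / Σ IPSC`. The iteration converges to the dominant eigenvector of
`α M₁ + (1−α) r·1ᵀ` (non-negative and, with a positive reset, primitive), so
the per-step renormalization makes the orientation of `M₁` a modelling
choice rather than a correctness issue; see *Numerical choices*.

**Expression channel (IPCC).** For each edge the sample Pearson correlation
of the two expression profiles; for each protein the signed sum over its
neighbours. Negative correlations subtract — switches for absolute-value or
positive-part summation are provided for sensitivity analysis because prior
centrality measures differ on this point.

**Fusion.** Both channels are min–max normalized to [0, 1] (`NIS`) and mixed
as `SCP = λ·NIS(MPR) + (1−λ)·NIS(IPCC)`. λ = 0.5 weights the channels
equally; λ = 1 and λ = 0 recover the individual channels exactly, which the
tests assert elementwise.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α (dampening) | 0.85 | mass following network links vs. the IPSC reset |
| λ (fusion) | 0.5 | weight of the network channel in SCP |
| tol | 1e−10 (L1) | convergence threshold between successive iterates |
| max_iter | 1000 | power-iteration cap |
| norm | L1 | per-step renormalization (L2 available) |
| orientation | row (MPR), column (classic) | which side of `M₁` is normalized |
| IPCC mode | signed | how neighbour correlations are summed |
| fallback weight | min ISC | edge weight when neither endpoint is annotated |

## Numerical choices

- **Orientation of `M₁`.** The modified solver defaults to row
  normalization (divide by the weighted degree of the row's own protein),
  exposed as a `column` switch. The classic solver defaults to the column
  (random-walk) convention: with row normalization *and a uniform reset* the
  uniform vector is an exact fixed point — every connected graph would score
  flat — whereas the IPSC reset of the modified solver breaks that symmetry.
  The classic/modified degeneracy cross-check therefore compares the two
  implementations at matched orientation.
- **Degenerate inputs.** A constant expression profile has zero variance;
  its PCC is defined as 0 (flat probes carry no co-expression evidence)
  rather than NaN. A score vector with max = min normalizes to all zeros. A
  network whose IPSC sums to zero cannot define a reset distribution; the
  model constructor raises and points to the `uniform_reset` flag.
- **Missing data.** Proteins absent from the annotation have an empty
  compartment set; an edge with exactly one annotated endpoint falls through
  to the union branch verbatim, and an edge with none gets the fallback
  weight (default: the minimum ISC, i.e. the importance of the largest
  compartment), logged once per run. Edges missing an expression profile
  contribute 0 to IPCC by default.
- **Ties and determinism.** All rankings sort by descending score with ties
  broken by ascending protein ID; scores are printed with 10 significant
  digits. Repeated runs on the same inputs are byte-identical.
- **Percent cutoffs** round half-up (`k = ⌊p/100·N + 0.5⌋`); curve areas use
  the trapezoid rule on the swept points. Truncated sweeps (the
  top-|essential| protocol) treat proteins beyond the truncation as
  predicted-negative at every threshold, so a truncated ROC ends short of
  (1, 1).

## Synthetic data

The generator produces the four input kinds with the statistical structure
the score is designed to exploit, each signal independently tunable:

- **Degrees.** Chung–Lu wiring from lognormal expected degrees
  (`degree_heterogeneity` = 1.0, the heavy-tailed regime typical of PPI
  networks), with essential proteins' baselines multiplied by
  `essential_degree_boost` (3.0). The heterogeneity keeps degree centrality
  an informative but noisy predictor — with homogeneous baselines a 3× boost
  would make degree alone a near-perfect separator, which real interaction
  data never shows.
- **Compartments.** Background compartment sizes follow a power-law-ish skew
  (exponent 1.5 over 50 compartments); the smallest fifth are reserved as
  enrichment targets, and each essential protein joins one with probability
  `essential_colocalization` (0.5), shared with interacting essential
  partners.
- **Expression.** Each profile is a latent sinusoid (periodic, echoing
  metabolic-cycle time courses; 36 points) scaled by `coexpression_strength`
  (0.95) plus Gaussian noise (sd 0.2). Interacting pairs inherit each
  other's latent with probability 0.05 (background) or 0.95
  (essential–essential), so essential pairs are strongly co-expressed.
- Defaults (1000 proteins, 20 % essential, mean degree 10) are a
  scaled-down analogue of a yeast-sized dataset; `SyntheticConfig.null()`
  sets the boost to 1 and both enrichment probabilities to background
  levels, making every channel label-blind.

What the generator does **not** emulate: false-positive/false-negative
interactions with realistic bias, a real compartment ontology (compartments
are opaque, non-nested IDs), probe-level expression artefacts, and the exact
yeast degree distribution. Passing tests therefore demonstrate that the
implementation recovers planted structure of the assumed kind — not that the
method attains any particular accuracy on real organism data, whose headline
values depend on specific database snapshots.

## Evaluation protocol

Essential labels are restricted to scored proteins before any metric.
ROC/PR/jackknife curves sweep ranking cutoffs k = 0…limit; AUC is
trapezoidal. Link-proportion analysis induces the subgraph of the top-k
proteins on the full network and classifies each edge by its endpoints'
essentiality (Ess–Ess / Ess–Noness / Noness–Noness); the three fractions sum
to 1 whenever the induced subgraph has an edge.

## Problem sizes

The test suite and `scripts/acceptance.py` use 20 datasets of 1000 proteins
per condition for calibration and signal-recovery checks, and random
connected graphs of ≤ 50 nodes for the dense-eigendecomposition oracle;
these sizes give stable Monte-Carlo estimates (null mean AUC within ±0.01 of
0.5 across seeds) while completing in seconds.

## Known limitations

- Identifier matching across the four inputs is exact string equality; no
  alias mapping is attempted.
- Only undirected simple networks are supported; teleportation targets are
  the IPSC vector or uniform, nothing else.
- The signed IPCC sum can rank a protein with many anti-correlated partners
  below an isolated one; use the `absolute`/`positive` modes to probe
  sensitivity.
- λ is not learned from data — the task is treated as unsupervised, and the
  fusion weight is a fixed parameter.
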