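# scprank

Ranking candidate **essential proteins** in a protein–protein interaction
(PPI) network by fusing two complementary signals:

1. a **modified PageRank** over the PPI network whose edges are weighted by
   subcellular-compartment co-localization, with a teleport (reset)
   distribution derived from the same weights, and
2. a **gene-expression co-expression score** — the sum of Pearson
   correlations between a protein and its interaction partners.

Essential proteins are those whose loss is lethal to the organism. Testing
each protein experimentally is slow and expensive, so network-based scores
are used to prioritise candidates: highly connected proteins tend to be
essential (the centrality–lethality rule), interactions confined to small
subcellular compartments are more reliable, and essential interaction
partners tend to be co-expressed. `scprank` turns these three observations
into a single ranking score.

## The model

Let `N_C` be the number of proteins annotated to compartment `C`, and
`SCL(P)` the compartment set of protein `P`.

- Compartment importance: `ISC(C) = 1 / N_C`.
- Edge weight:
  `W(P_i, P_j) = max{ISC(C) : C ∈ SCL(P_i) ∩ SCL(P_j)}` when the proteins
  share a compartment, otherwise `min{ISC(C) : C ∈ SCL(P_i) ∪ SCL(P_j)}`.
- Prior importance: `IPSC(P_i) = Σ_j W(P_i, P_j)` over the neighbours of
  `P_i`.
- Modified PageRank (MPR): power iteration
  `v ← α M₁ v + (1 − α) r · Σ v`, renormalized each step, where
  `M₁(i, j) = W(i, j) / Σ_k W(i, k)` and `r` is IPSC normalized to sum 1;
  `α = 0.85` by default.
- Co-expression: `PCC(X, Y) = Cov(X, Y) / (σ_X σ_Y)` on the expression
  profiles, and `IPCC(P_i) = Σ_j PCC(P_i, P_j)` over the neighbours.
- Fusion: after min–max normalization `NIS(·)` of both channels,

  `SCP = λ · NIS(MPR) + (1 − λ) · NIS(IPCC)`, `λ = 0.5` by default.

Proteins are ranked by SCP in descending order; the evaluation module
provides ROC/AUC, precision–recall, jackknife curves, top-percent essential
counts and link-proportion analysis of the top-ranked subnetwork, plus
degree centrality (DC) as the standard baseline.

## Worked example

A seeded synthetic dataset with the structure the method assumes (boosted but
noisy essential degrees, essential proteins enriched in small shared
compartments, co-expressed essential interaction pairs):

```python
import scprank as sp
from scprank import evaluation as ev

ds = sp.generate(sp.SyntheticConfig.planted(seed=1))
scores = sp.score_proteins(ds.network, ds.annotation, ds.expression, lam=0.5)
for name in ("MPR", "IPCC", "SCP"):
    print(f"ROC AUC {name}: {ev.roc_curve(scores[name], ds.essential).auc:.4f}")
dc = sp.degree_centrality(ds.network)
print(f"ROC AUC DC : {ev.roc_curve(dc, ds.essential).auc:.4f}")
```

prints

```
ROC AUC MPR: 0.8841
ROC AUC IPCC: 0.7669
ROC AUC SCP: 0.8854
ROC AUC DC : 0.7576
```

The fused SCP score beats both of its individual channels and the degree
baseline on this dataset: the network channel (MPR, 0.884) and the
expression channel (IPCC, 0.767) make partly independent errors, so their
combination ranks the 200 planted essential proteins highest most reliably.

The same workflow is available from the shell:

```bash
scprank simulate --out-dir data/ --seed 1
scprank score --network data/network.tsv --localization data/localization.tsv \
              --expression data/expression.tsv --out-dir run/
scprank evaluate --essential data/essential.txt --scores run/scp.tsv \
                 --network data/network.tsv --out-dir eval/ --plot
```

`score` writes `mpr.tsv`, `ipcc.tsv` and `scp.tsv` rankings plus a
`manifest.json` with parameters and input checksums; `evaluate` writes AUC
and top-percent tables, per-method curve TSVs and (with `--plot`) PNG plots.

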