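# csnn — chemical space networks with labels as features

`csnn` predicts drug–target interactions (DTIs) for sparsely annotated
compound–receptor matrices — the situation of the human GPCR bioactivity
databases, where only ~1.5 % of the ~23.9 million possible
compound×receptor pairs carry a label — by exploiting **network
homophily**: compounds that are close in chemical space tend to share
bioactivity on a receptor. It is aimed at computational chemists and
screening groups who want neighbourhood-aware pre-screening of compound
libraries.

## What it computes

1. **Chemical space network (CSN).** Compounds are encoded as a 4096-bit
   circular-substructure fingerprint (radius 3, chirality-aware)
   concatenated with the 166 MACCS keys (4262 bits, packed to 533 bytes),
   and connected by Tanimoto similarity

       T(a, b) = |a ∩ b| / (|a| + |b| − |a ∩ b|),

   keeping edges with T > ε (default 0.4).
2. **Training-free labels-as-features (LaF) inference.** For a query
   compound and receptor, the labelled neighbours vote: the normalised
   class-frequency vector e_tot is the prediction, argmax(e_tot) the class
   call. No neighbourhood ⇒ no prediction (the out-of-distribution guard).
   The regression analogue aggregates neighbour affinities
   (mean/max/min/similarity-weighted) on the −log10(Ki) scale.
3. **Neighbourhood neural networks.** Each labelled (compound, receptor)
   pair becomes a one-hop star graph with LaF edge features
   (one-hot neighbour class + similarity). A single edge-attributed
   aggregation layer

       r_i = h_Θ((1 + ε)·x_i + Σ_j ReLU(x_j + W_e e_ji))

   feeds an MLP head, with the frequency vector (and, in single-receptor
   mode, a 320-d receptor embedding) as a skip connection: widths
   256+320+6 = 582 (single receptor, 6 class logits) and 64+896 = 960
   (multi-receptor, 128×7 = 896 logits with per-receptor softmax and
   no-data masking). Implemented in plain NumPy with hand-derived,
   finite-difference-verified gradients and Adam.
4. **Screening statistics.** Per-receptor Z-scores of log10 luminescence,
   the robust variant Z_mod = 0.6745·(x − median)/MAD, strict |Z| > 3 hit
   calling, predicted-vs-experimental enrichment tables (hit ⇔ class ≠
   "No Effect" ∧ Ki < 100 nM), and a novelty filter for significant hits
   with no labelled chemical neighbourhood.

A seeded synthetic generator produces homophilous chemical spaces
(clustered bit-vector compounds, tunable homophily h, label sparsity,
affinity noise) so the whole pipeline is testable without downloads.

## Worked example

```python
from csnn import SyntheticSpec, generate_space, build_csn
from csnn.benchmarks import argmax_transductive_eval

space = generate_space(SyntheticSpec(homophily=0.9, seed=11))
csn = build_csn(space.compounds)          # epsilon = 0.4
print(csn.n_nodes, "compounds,", csn.n_edges, "edges")
metrics = argmax_transductive_eval(space, csn)
print("weighted F1", round(metrics.weighted_f1, 3),
      "abstained", metrics.n_abstain)
```

prints

```
180 compounds, 1260 edges
weighted F1 0.908 abstained 0
```

— 180 synthetic compounds in 12 clusters connect into 1260 similarity
edges; with homophily 0.9 the training-free neighbour vote recovers the
observed labels with weighted F1 ≈ 0.91, and no query lacked a labelled
neighbourhood. At homophily 1.0 with no label dropout the same call
returns F1 = 1.0 exactly.

The command line mirrors the library:

```bash
csnn simulate --out fixtures/ --seed 1
csnn build-csn --library fixtures/fingerprints --epsilon 0.4 --out csn/
csnn predict-argmax --csn csn/ --labels fixtures/dti.csv \
     --queries queries.csv --out preds.csv
csnn zscore --screen plate.csv --threshold 3 --out scored.csv
csnn report --seed 2 --out run/        # full pipeline + checksum manifest
```

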