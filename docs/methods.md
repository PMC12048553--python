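# Methods

## Model overview and assumptions

The package rests on one empirical assumption: **network homophily** in
chemical space — compounds with high fingerprint similarity tend to share
bioactivity class and affinity on a given receptor. All inference modes
(training-free argmax, neighbourhood-aggregate regression, and the neural
models) consume the same object: a query compound's thresholded Tanimoto
neighbourhood together with the known labels on those neighbours
("labels as features", LaF). Predictions are transductive — labelled data
is consulted at inference time — with two hard rules: the query's own
label never appears among its features, and a query with no labelled
neighbourhood yields an explicit abstention rather than a guess.

## Fingerprints and similarity

Compounds are encoded as a 4096-bit Morgan fingerprint (radius 3,
chirality on) concatenated with the 166 MACCS keys: 4262 bits, packed
MSB-first into 533 bytes. Packing is lossless, and similarity is computed
by popcount on the packed bytes, so the packed and unpacked Tanimoto
values are identical (a property test asserts the equality on random
pairs). Two all-zero fingerprints get similarity 0, not NaN: an empty bit
set should match nothing. The bit width is configurable; synthetic
fixtures use 512-bit toy fingerprints for speed.

## Chemical space network

Edges require similarity **strictly greater** than ε (default 0.4); the
boundary value is excluded. The adjacency is stored sparse and symmetric
with no self-loops; correctness is defined by (and tested against) the
naive all-pairs double loop. Neighbour queries threshold first, then cap
at the 40 highest-similarity neighbours, ties broken by ascending
compound id for determinism. Multi-hop queries (plain BFS) serve
visualisation and leakage scans only — model inputs are always one-hop.
One-vs-all external queries support compounds outside the network; an
empty result is the out-of-distribution guard.

## Training-free inference

The label-frequency vector divides class counts by the number of
**labelled** neighbours, not by all edges, so it is a proper distribution
whenever support > 0; unlabelled neighbours are dropped rather than
zero-featured (dividing by all edges would deflate every class equally and
could never change the argmax, while downstream skip connections need the
distribution form). Argmax ties resolve to the lowest class index and are
flagged, so consumers can treat ambiguous calls separately. The
"weighted" regression aggregate is the similarity-weighted mean
Σ w_j y_j / Σ w_j with raw Tanimoto weights.

## Neighbourhood graphs and encoders

Each labelled (compound, receptor) pair becomes a directed one-hop star
graph: all edges point at the query, edge features are the one-hot
neighbour class plus the similarity (width 7), or — in multi-receptor
mode — one 7-wide one-hot block per receptor with a reserved no-data
index (width 128×7 = 896 at production scale). Edge rows are stored in a
canonical order (sorted by neighbour id) and the models re-canonicalise
before every summation, which makes all outputs bit-exactly invariant to
edge permutations.

Compound representations (length 300) and receptor embeddings (length
320) come from pluggable encoder interfaces. The defaults are
deterministic seeded stand-ins — a fixed Gaussian random projection of
the fingerprint bits, and one fixed Gaussian vector per receptor id —
chosen so the package builds and tests without any pretrained weights
while preserving the production dimensions; file-backed tables accept
externally computed representations (e.g. from a pretrained molecular
message-passing network or a protein language model) without touching
the graph code.

## Splits and leakage control

Scaffold splitting assigns whole groups (Murcko scaffolds when SMILES are
available, otherwise any supplied group key) greedily, largest group
first with seed-shuffled ties, to the partition with the largest
remaining deficit against the 80/10/10 targets. This is deterministic,
keeps every group in exactly one partition, and approximates the target
fractions at compound granularity. An i.i.d. record-level mode is also
provided. The leakage filter removes any dataset compound with Tanimoto
similarity strictly above 0.65 to a held-out compound; it scans all
pairs rather than only the hold-out's two-hop neighbourhood — a superset
of the scoped scan that can never under-remove, and cheap at desk scale.
The transductive neighbour policy (train refers to train; test/val refer
to train only; never to oneself) is enforced by construction and audited
by an explicit checker in the tests.

## The neighbourhood models

One aggregation layer suffices because every edge already points at the
query: the output is a pooled graph representation. Since edge features
(7 or 896 wide) and node features (300 wide) have different widths, a
learned linear map lifts the edge feature to the node width before the
ReLU — the standard edge-attributed convolution contract. The query
mixing weight ε_gin is a fixed hyperparameter (default 0), named
distinctly from the similarity threshold to avoid collision. The head
emits raw scores; normalisation (softmax) happens exactly once, inside
the cross-entropy and at prediction time — never twice.

Widths: single-receptor mode concatenates r_i (256), the receptor
embedding (320) and the frequency vector (6) → 582 before the head
(2 hidden layers of 512, 6 outputs). Multi-receptor mode uses a 64-wide
r_i and the 896-wide multi-receptor frequency vector → 960, with 896
outputs reshaped to 128×7 and softmaxed per receptor over the six
classes plus the no-data index. The multi-receptor loss masks receptor
positions where the query is unlabelled, and records with no labelled
position at all are excluded from the batch mean entirely — appending
fully-masked records can never change the loss (asserted to 1e-12). The
hidden width of the multi-receptor aggregation MLP is not separately
specified anywhere authoritative; it defaults to the single-receptor
value (256) and is configurable.

The implementation is plain NumPy with hand-derived backpropagation and a
hand-rolled Adam (L2-coupled weight decay, β = 0.9/0.999). This keeps the
model free of heavyweight dependencies and makes the analytic gradients
directly checkable: a finite-difference comparison on toy graphs is part
of the test suite and the acceptance script (agreement to better than
1e-4 relative error). Defaults follow the reference protocol: learning
rate 1e-5 (5e-5 multi-receptor), weight decay 1e-4, batch size 16, 100
epochs, five independent seeded repeats reported as mean ± sd. Tests and
the acceptance script use larger learning rates and ~10 epochs on small
synthetic spaces — a problem-size choice that keeps the default runs in
seconds while still demonstrating loss descent and the confidence
ordering.

## Baselines

Flat-feature baselines concatenate compound representation (300) +
receptor embedding (320), optionally + the frequency vector (6,
classification) or the neighbourhood mean (1, regression). Fits go
through scikit-learn: random forest (class-balanced), MLP, and ridge,
grid-searched with 2-fold cross-validation; the default grids are the
documented production grids, and the fast benchmark harnesses use
single-point grids at matched capacity for the ±N comparisons. CV scoring
is weighted F1 (classification) / MSE (regression), matching the headline
metrics. Regression pools all receptors into one model with the receptor
embedding concatenated; out-of-distribution test records (no labelled
train neighbour) are excluded from ±N comparisons identically for both
variants, per the no-neighbourhood-no-prediction rule.

## Metrics and receptor distances

Per-class precision/recall/F1 are computed from the confusion matrix from
first principles; the weighted F1 weights classes by their share of true
instances, with zero-support classes receiving weight 0 rather than NaN.
scikit-learn serves as an independent cross-check in the tests, never as
the implementation. Abstentions are either excluded (with a reported
count) or counted as errors, under an explicit flag. Cramér's V between
two receptors' label profiles uses the Bergsma bias correction with
max(0, ·) clamping; fewer than 5 co-occurring compounds gives the
maximum distance 1.

## Screening statistics

Raw luminescence is log10-transformed before standardisation (the log
restores approximate normality). The Z-score uses the sample standard
deviation (ddof = 1, configurable — the population convention is the
other common choice and is documented in the tests). The modified
Z-score 0.6745·(x − m)/MAD is consistent with Z under normality (checked
by Monte-Carlo at n = 10⁴, correlation > 0.99). Hit calling is strict
(|Z| > 3, never ≥) and supports two-sided and positive-only modes: the
novelty filter uses two-sided significance, enrichment against activation
assays uses the positive tail. Compounds that perturb the readout
receptor-independently are handled by an explicit exclusion list; no
automatic detection is attempted.

## Synthetic data: what it does and does not emulate

The generator produces clusters of bit-vector compounds around random
prototypes (prototype density 0.3, per-bit flip rate 0.02 by default),
which yields the within-cluster-similar / across-cluster-dissimilar
structure of chemical series. Each (cluster, receptor) draws one latent
class (uniform over 6) and one latent affinity (uniform on 4–9 in
−log10 Ki, the range of public GPCR affinity data); members inherit the
class with probability h (the homophily dial) and the affinity plus
Gaussian noise (sd 0.3). Labels are dropped i.i.d. (default 30 %) to
emulate sparse annotation. Each cluster spans several "scaffold"
subgroups (3 by default), mirroring the fact that a chemical series
contains multiple Murcko scaffolds — so scaffold-disjoint splits remain
meaningful without severing every neighbour relation. Defaults
(12 clusters × 15 compounds, 8 receptors, h = 0.9) were fixed once as a
plausible desk-scale regime.

What passing tests on this generator show: the algorithms recover the
planted homophily structure, the LaF advantage appears whenever
neighbour labels carry signal, and all bookkeeping (thresholds, masks,
splits, policies) is correct. What they do not show: performance on real
chemistry — real fingerprint landscapes are not clean clusters, real
label noise is not uniform over classes, receptors are correlated, and
database sampling is biased toward derivatised actives. Claims about
real-data F1 values are therefore out of scope for the synthetic tests.

## Numerical choices

* Edge sums are computed in canonical edge order; permutation invariance
  is asserted bit-exactly, not approximately.
* Similarity matrices use exact integer popcount arithmetic with one
  final division; network serialization writes weights with `%.17g` and
  reads them with round-trip float parsing, so the CSN round-trips
  bit-identically through text.
* Softmax is computed with max-subtraction; cross-entropy clamps
  probabilities at 1e-300 to keep the loss finite in the saturated limit.
* Parameter initialisation is Glorot-uniform from a single seed; every
  stochastic component (generator, splits, shuffling, repeats) derives
  from explicit seeds and nothing reads the clock.
* Degenerate inputs fail loudly: σ = 0 or MAD = 0 receptors, all-masked
  batches, single-class training data, conflicting DTI duplicates, and
  unknown class names all raise with the offending receptor/row named.

## Known limitations

* The all-pairs similarity search is the naive O(n²) computation —
  correct by construction and fine to a few thousand compounds; the
  norm-bound pruning used for hundred-thousand-compound libraries is not
  implemented.
* The seeded stand-in encoders carry no chemistry beyond the fingerprint;
  with them, compound representations are only as informative as a random
  projection of the bits.
* Multi-receptor mode follows the masked 128×7 formulation (6 classes +
  no-data index); the alternative 128×6 unmasked formulation that appears
  in some descriptions of the approach is not implemented.
* Dose–response curve fitting, plate-position normalisation, and
  tree/dendrogram rendering from receptor distances are out of scope.
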