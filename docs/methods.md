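# Methods

## The identifiability statistic

For a group of subjects, all recordings are band-filtered (optionally), cut
into nonoverlapping segments of `L` samples (default 1,000; at 500 Hz that
is 2 s) and pooled across subjects and, unless a condition filter is set,
across the two resting conditions. For each unordered channel pair the
segments form a perfectly balanced two-class dataset: class = channel of
origin. One *iteration* draws a random half of the segment **slots** for
training and scores each classifier on the other half; the accuracy is the
only score kept, balance making precision/recall redundant. Iterations
(default 100; small profiles use 10) are averaged per model, and the pair's
identifiability is the best model's mean, with ties broken by a fixed
registry order (fcn, resnet, cnn, mcdcnn, mlp, knn_fallback). The best
model's identity is stored per pair, and the full (pair × model ×
iteration) score table is retained so other aggregations can be recovered.

**Why slots, not segments, are split.** Segments of the two channels are
kept aligned in time ("slot" k = samples `[kL, (k+1)L)` of one recording).
Both channels' segments of a slot go to the same half. If each channel were
split independently, a strongly coupled pair — whose time-aligned segments
are near-duplicates carrying opposite labels — would leak near-copies of
test segments into the training set, and instance-based classifiers would
be driven systematically *below* chance (measured ≈ 0.23 at full coupling).
The slot-level split preserves the exchangeability limit (score ≈ 0.5 for a
fully shared pair) and keeps both halves exactly balanced.

## Classifier zoo

Five neural architectures for univariate series run on an in-package numpy
layer engine (dense, 1-D convolution, batch normalisation, average/max
pooling, dropout, residual blocks; Adam, softmax or element-wise sigmoid
heads; manual backpropagation, gradient-checked against finite
differences):

| model | structure | default epochs |
|---|---|---|
| mlp | 3 hidden dense ReLU layers + softmax, dropout | 20 |
| cnn | 2 × (valid conv, sigmoid, avg-pool 3) → dense sigmoid head | 200 |
| resnet | 3 residual blocks of 3 conv+BN layers → GAP → softmax (11 layers) | 20 |
| fcn | 3 × (same conv, BN, ReLU) → GAP → softmax | 20 |
| mcdcnn | 2 × (valid conv, ReLU, max-pool 2) per stream → dense ReLU → softmax | 20 |

The slow-saturating simple CNN needs hundreds of epochs; the others
saturate within tens. MLP is implemented but excluded from the default zoo,
being consistently the weakest. Kernel sizes and filter counts follow the
common reference configurations for these architectures, at reduced default
widths (16/32 convolutional filters) so that CPU-only training of a full
pairwise analysis stays tractable; every width, the learning rate (1e-3,
Adam for all models) and the batch size (16) are overridable per model via
`ModelSpec.hyperparams`. MCDCNN receives the single channel as its one
input stream.

The non-neural fallback is first-class: 1-nearest-neighbour on Euclidean
distance between raw segments (`knn_fallback`). It is exactly
deterministic, which makes whole-pipeline runs hash-reproducible, and it is
surprisingly competent on narrowband signals: the nearest within-class
neighbour of a segment is a phase-aligned one, while cross-class inner
products stay near zero. A summary-feature variant
(`hyperparams={"features": "spectrum"}`) applies the same rule to log
band-averaged periodograms; it trades phase information for much higher
sensitivity to small spectral-composition differences and is the right tool
when couplings must be *ranked* (see validation below).

## Networks, metrics, nulls

Weights are `1 − score`; any strictly decreasing transform yields the same
binary networks, so the choice only fixes reporting. Proportional
thresholding keeps exactly `round(d·N(N−1)/2)` top-weighted links per grid
density `d` (default grid 0.05–0.50 in steps of 0.05), with lexicographic
tie-breaks, which makes edge sets nested along the sweep and link counts
exact. Curves are indexed by the grid density; the realised density differs
by at most one-link rounding. Absolute thresholding is deliberately not
implemented.

Undefined metric values are explicit `nan` markers, never silent zeros:
assortativity on a degree-regular graph, rich club with fewer than two
qualifying nodes, nestedness/modularity of an edgeless graph, transitivity
below three nodes.

- **Transitivity, global efficiency**: standard definitions, delegated to
  networkx.
- **Assortativity**: Pearson correlation of the degrees at the two ends of
  every link (both orientations).
- **Maximum degree**: largest row sum.
- **Rich club**: φ(k) = link density among nodes of degree > k, reported as
  a curve over k; the scalar plotted against density is φ at k = ⌊median
  degree⌋ — an explicit convention, since no single standard scalarisation
  exists. Raw φ is reported; the rewired-null normalised variant is
  available as an option.
- **Modularity**: best Q over five seeded restarts of the igraph multilevel
  (Louvain) algorithm; Q of the returned partition is recomputed with the
  direct Newman formula. (networkx's Louvain was found to not terminate on
  some small graphs for some seeds, so igraph is the backend.)
- **Nestedness**: NODF-style pairwise overlap on the symmetric adjacency,
  scaled 0–100. For each node pair, neighbourhoods are compared with the
  mutual link excluded — the only convention under which an adjacent pair
  can be perfectly nested on a hollow symmetric matrix; the pair
  contributes `100·|overlap|/|smaller residual neighbourhood|`, pairs with
  an empty smaller residual neighbourhood are skipped, and the score is the
  mean. A perfectly nested neighbourhood chain scores 100; disjoint edges
  score 0.
- **Information content**: bits to encode the adjacency matrix given
  inter-row regularities. One root row is stored verbatim (n−1 bits); every
  other row is encoded as a difference from an already-encoded row at a
  cost of `log2(m+1) + log2(C(m, d))` bits (d = Hamming difference over the
  other m = n−2 columns). The cheapest encoding order is the minimum
  spanning tree of the pairwise cost graph; MST total weight is unique even
  under cost ties, so the metric is deterministic and exactly invariant
  under node relabelling (a sequential greedy pairing, tried first, was
  not: tie-breaking propagated into different totals under relabelling).
  Low values mean regular/modular structure, high values random-like
  structure; validated by ordering properties (complete/empty minimal
  exhaustively at n = 4; two-clique modular below density-matched random
  graphs), not by exact values, since no canonical variant exists.

The null model rebuilds the entire pipeline on surrogate segment banks
drawn from all groups pooled together: per surrogate, a group-sized set of
slots is sampled uniformly from the pooled groups (slot alignment across
channels preserved), scored, thresholded and measured. Pooling is at
segment granularity by default — the mixing unit is the slot, not the
subject — with subject granularity available via a flag. Bands are
empirical 10–90 percentiles (linear interpolation between order
statistics); Z-scores are `(observed − null mean)/null sd`, undefined (nan)
where the null variance is zero. No multiple-testing control is applied
across (density × metric × band) cells; Z-scores are reported raw.

## Synthetic cohorts

Each channel's private signal is a unit-variance resonant AR(2) process
(poles at radius `damping`, default 0.98, at the channel's resonance
frequency), giving a controllable spectral fingerprint — the simplest
process with one. Coupling `c_ij ∈ [0, 1]` mixes a latent shared AR(2)
source (frequency drawn between the two privates' peaks) into both channels
with weight `c_ij`, while the private weight shrinks as
`1 − min(1, Σ_j c_ij)`: couplings are variance shares, and a channel's
coupling budget saturates at 1. Crosstalk adds a linear leak of every other
channel (default 0.05, uniform); white sensor noise (default sd 0.5) and
per-subject multiplicative jitter of the resonance frequencies (±5%)
complete the model. Two conditions are generated as independent
realisations of the same statistics. RNG streams are keyed hierarchically
by (seed, group, subject, condition, stream), so output is bit-reproducible
and adding subjects never changes existing ones.

Defaults describe a desk-scale resting-state-like cohort: 10 channels,
fingerprints spread over 5–40 Hz, 250 Hz sampling, 60 s per condition, 5
subjects per group, 2 groups.

What the generator does *not* emulate: volume conduction and realistic
forward models, artefacts (blinks, muscle), nonstationarity, 1/f background
spectra, and real intersubject anatomy. Passing tests on this generator
show that the pipeline recovers planted statistical structure of the kind
the method assumes; they do not certify performance on clinical EEG.

## Validation experiments and their design

- **Chance-level control**: a fully coupled pair (coupling 1, identical
  fingerprint frequencies) is exchangeable up to noise; its score must lie
  within the 95% binomial interval of 0.5 at the test profile (raw 1-NN, 10
  iterations).
- **Planted-structure recovery** uses a 10-channel cohort with a graded
  perfect matching of couplings {0.86, 0.80, 0.74, 0.68, 0.62} and
  geometrically spaced fingerprints, scored with the spectrum-feature
  fallback. Both choices are dictated by measured response curves, not
  convenience: (i) the raw 1-NN's score-vs-coupling response is flat below
  c ≈ 0.3, and the per-channel coupling budget caps how much graded mass a
  sparse design can carry, so raw distance cannot rank many levels; the
  spectral variant holds an exact score ceiling of 1.0 for uncoupled pairs
  — aligning score ties with coupling ties — and resolves the grading on
  c ∈ [0.6, 0.86]. (ii) Subject jitter is multiplicative, so linearly
  spaced fingerprints let high-frequency matched pairs drift toward
  overlap, confounding pair difficulty with coupling; equal relative gaps
  remove the confound. Recovery is then assessed as the Spearman
  correlation between scores and planted couplings over all 45 pairs and
  the Jaccard overlap between the density-0.1 network's links and the
  strongest planted couplings.
- **Correlation baseline**: per aligned slot, the absolute Pearson
  correlation between the two channels' segments, averaged (zero-variance
  segments excluded with a logged warning). On coupled cohorts it
  associates negatively with identifiability — correlated pairs are the
  unidentifiable ones — while the two measures remain distinct.
- **Band profile**: on a cohort whose fingerprints span the α/β/γ range,
  broadband median identifiability must dominate every filtered band
  (filtering discards part of each fingerprint). Filtering uses a 4th-order
  Butterworth applied forward–backward (zero phase) on the continuous
  signal before segmentation, avoiding per-segment edge effects; the
  classical bands are α 8–13, β₁ 13–20, β₂ 20–30, γ 30–50 Hz.
- **Null calibration** runs two groups generated from identical
  configurations with subject jitter 0 — with jitter, each group carries
  its own subjects' fingerprints, a genuine group difference that
  segment-granularity surrogates over-disperse — at 8 channels, since
  6-node thresholded graphs give near-discrete metric distributions whose
  bands hold almost all mass. At this profile (20 surrogates, raw 1-NN, 10
  iterations, densities 0.15–0.55) the observed curves fall inside the
  10–90 band in roughly 80% of cells, matching the band's construction.
- **Determinism**: the full demo pipeline (5 channels, 2 subjects × 2
  groups, fallback classifier) run twice with one seed produces
  hash-identical manifests.
- **Oracle equivalence**: transitivity, efficiency, assortativity, max
  degree, rich club and nestedness agree with brute-force enumeration on
  every graph with up to 5 nodes and on 200 random 8-node graphs.

Problem sizes throughout (channel counts, durations, iteration and
surrogate counts) are the package's test profiles, chosen so the full suite
and the acceptance script each run in minutes on a single CPU; the
statistic itself is unchanged at larger scale.

## Known limitations

- Scores from the 1-NN fallback saturate (ceiling 1.0, floor 0.5), so very
  weak couplings are invisible to it; the neural models and the spectral
  variant push the detection threshold down but do not remove it.
- A single network per group ("group-level design") deliberately forgoes
  per-subject networks; subject-level identifiability networks are possible
  with the same machinery but are not implemented.
- Louvain modularity is a stochastic heuristic: with five restarts its best
  Q is reproducible under a fixed seed but only approximately invariant
  under node relabelling.
- The information-content and rich-club scalarisation conventions are
  package-defined (documented above); comparisons with other
  implementations should be made on orderings, not raw values.
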