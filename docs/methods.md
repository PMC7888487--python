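# Methods

`spikeshare` reconstructs, from multi-unit spike trains, a time-resolved
weighted network of *information sharing* between single units, and then
characterizes that temporal network at three levels: per-node features
(liquidity and core-periphery coreness), whole-network discrete states, and
per-neuron connectivity styles across states. This note records the models,
the defaults, and the numerical and design choices, together with what the
synthetic generator does and does not emulate.

## Information-sharing networks

**Binarization and windows.** Spike trains are binarized at `bin_width`
(default 25 ms; a spike-present/absent indicator per bin) inside sliding
windows of length 10 s stepped by 1 s, giving a 90% overlap between
consecutive windows. Windows are half-open `[start, start + L)`; frames are
indexed from 0.

**Lagged mutual information.** The directed link weight from unit *i* to
unit *j* in a window is

    I_shared(i -> j) = sum_{lambda=0..L} MI[ j(t), i(t - lambda) ],

the plug-in (maximum-likelihood) mutual information of the 2x2 joint
histogram at each lag, in bits, summed over integer-bin lags up to half a
theta period (`max_lag = floor(0.5 * theta_period / bin_width)`; defaults
0.25 s and 25 ms give lags 0–5). The plug-in estimator is biased upward at
finite samples; no analytic bias correction is applied because the surrogate
threshold (below) absorbs the bias for sharing weights. Active information
storage is the same sum applied to a unit's own past; its lag-0 term is the
entropy of the binarized train, and it is reported raw.

**Significance threshold.** For every ordered pair and window, the weight is
`max(I_shared - theta, 0)` where `theta` is the 95th percentile of the same
statistic over surrogate data in which the bin order of every unit is
independently permuted (rate preserved, all temporal structure destroyed).
The default is 400 shuffles per window (`per-window` mode). A `pooled` mode
derives one per-pair threshold from shuffles of a sample of windows (default
25, evenly spaced) and reuses it across the recording; it is much cheaper on
long recordings and is what the packaged recovery experiments use (100
shuffles over 30 windows). By exchangeability the per-pair test retains
~5% of truly unrelated links regardless of firing rate; this false-positive
floor is a property of the percentile test itself and matters when
interpreting "connected" nodes (see Limitations).

**Symmetrization.** Reciprocal asymmetries are summarized per neuron and
state by the asymmetry coefficient `DeltaS% = (s_out - s_in)/(s_out +
s_in)` (+1 pure sender, −1 pure receiver, 0 balanced; defined as 0 for an
isolated neuron). For the downstream analyses the directed network is
symmetrized with the arithmetic mean of the two directed weights, and a
binarized variant keeps an edge wherever the symmetric weight is positive.

## Node features

**Liquidity.** For each node and frame `t >= 1`, the similarity between its
neighborhoods at `t − 1` and `t`: the Jaccard index of the neighbor sets
(unweighted networks) or the cosine similarity of the incident weight
vectors (weighted networks). Conventions: liquidity is 0 when either
neighborhood is empty, and undefined (NaN, treated as 0 where a number is
required) at frame 0.

**Coreness.** The random-walk core-periphery profile. With `m_ij = w_ij /
s_i` the transition matrix of the stationary walk and `pi` its stationary
distribution, the persistence of a node set S is

    alpha_S = sum_{i,j in S} pi_i m_ij / sum_{i in S} pi_i,

the probability that a walker inside S stays in S at the next step. Nodes
are inserted greedily, always choosing the node that keeps `alpha` minimal;
a node's coreness is the persistence at its insertion divided by the
full-graph persistence. Zero-strength nodes enter first with coreness
exactly 0. Ties are broken deterministically (lowest persistence, then
lowest strength, then lowest node index; tolerance 1e-12). Persistence is
scale-free, so weighted coreness is invariant under global weight
rescaling. For the complete graph on N nodes the entry-order values are
`(k−1)/(N−1)` — from any member of a k-subset the walker stays with
probability `(k−1)/(N−1)` — which the test suite checks against an
exhaustive greedy oracle along with star, clique-plus-chain, two-block and
isolate-bearing fixtures up to 8 nodes.

**Core assignment.** The instantaneous core is the set of neurons whose
coreness lies strictly above the 95th percentile of the pooled (all neurons
x all frames) coreness distribution; a per-frame percentile scope is also
available. Per-region core *filling factors* (percent of a region's neurons
inside the core) and the regional composition of the core (fractions
summing to 1 when the core is non-empty) follow directly.

## Network states

Per-frame feature vectors — either the concatenated per-node liquidity and
coreness (2N dimensions, weighted `{Theta, C_w}` or unweighted `{J, C}`) or
three global features (node-averaged liquidity, node-averaged coreness,
total weight / edge count) — are standardized per dimension and K-means
clustered (50 restarts, seeded). K is scanned over 1..8 and chosen by the
best mean silhouette, with K = 1 declared when the best silhouette is below
0.1. Standardization prevents the coreness scale from dominating liquidity;
the floor guards against reading structure into featureless recordings.

Agreement between label sequences uses **relative mutual information**:
plug-in MI divided by the larger of the two entropies. It is 1 for
label-bijective sequences, 0 in expectation for independent ones; the
degenerate conventions are 1 when both sequences are constant and 0 when
exactly one is. Values within 1e-12 of an endpoint are snapped to it.

Clustering quality is the mean silhouette of the partition, compared with a
chance distribution obtained by independently permuting every feature
dimension across frames and re-running the clustering (including K
selection) on each surrogate.

## Null models

Three frame-wise randomizations, each frame seeded independently from the
master seed: an Erdos-Renyi null (same node and edge count; for weighted
input the frame's weight multiset is reassigned uniformly to the new edges,
conserving total weight), a degree-preserving null (Maslov-Sneppen double
edge swaps, 10 accepted swaps per edge by default, self-loops and
multi-edges rejected; frames with no valid swap are returned unchanged with
a warning), and a weight shuffle (weights permuted over the existing edges,
leaving every neighborhood intact).

A caution on interpreting coreness under these nulls: because the profile
is normalized by the full-graph persistence, the last-inserted nodes of
*any* graph approach coreness 1. A homogeneous randomized graph therefore
shows a near-linear profile with roughly half of its connected nodes above
0.5, whereas a genuinely core-peripheral graph keeps the profile low until
the final few insertions and has *fewer* such nodes. The destruction of
core-periphery structure by the ER and weight-shuffle nulls consequently
*raises* the count of nodes above any fixed coreness quantile rather than
lowering it; what the nulls lose is the bimodal shape (a near-zero bulk
plus a late jump) and the state-clustering quality, which drops clearly on
randomized networks.

## Connectivity profiles and styles

For every (neuron, state) pair six features are computed over the state's
frames in temporal order: state-averaged weighted coreness, state-averaged
cosine liquidity, state-averaged strength, the activation number `n_a`
(transitions from isolated to connected; being connected at the state's
first frame counts once), the total connectivity time `tau` (connected
frames), and the Fano factor `phi` of the connection durations (population
variance over mean; 0 with fewer than two durations).

Features are min-max normalized over the pooled profile set and K-means
clustered with k = 5. Because `n_a` and `tau` are raw counts they scale
with the state's length, and state lengths under a semi-Markov schedule
vary several-fold; clustering on raw counts therefore groups profiles by
state duration rather than by connectivity style. The clustering and the
KNN soft labels consequently use the occupancy-corrected variants
`n_a/|T^h|` and `tau/|T^h|` alongside coreness, liquidity, strength and the
Fano factor, while the raw counts remain part of the stored profile.

The cluster whose centroid is nearest the origin is labeled *junk*
(barely-connected profiles) and discarded from style analyses; the
remaining four clusters are mapped to the named styles by centroid
signature: *core* maximizes coreness + strength + liquidity (penalizing
activation rate), *periphery* maximizes activation rate minus coreness and
strength, and the two *core-skin* styles split on the Fano factor (bursty
high, regular low). KNN soft labels (default 10 neighbors, Euclidean
distance in the normalized space, self excluded) give each profile a
4-vector of style probabilities summing to 1, with a merged 3-class view
that sums the two core-skin components.

**Eta index.** Per neuron, the number of style changes along the visited
state sequence (revisits included; junk profiles dropped from the
sequence) divided by `max(n_styles, n_states)` with `n_styles = 4` and
`n_states` the number of distinct states, clipped to [0, 1]. Style
transition tables count style-to-style moves across consecutive visited
states pooled over neurons, row-normalized into rates, in full 5-class
(styles + junk) and merged 3-class forms.

**Enrichment.** Style-by-stratum counts (layer or cell type) are compared
with a null that permutes style labels across neurons within each recording
(1,000 permutations, two-sided alpha = 0.05 by default); strata with fewer
than 3 profiles are reported untestable.

## The synthetic generator

No recordings ship with the package, so every downstream stage is
exercised on a generator that plants the structure the analysis assumes:

* a semi-Markov state schedule (geometric dwells, default mean 150 frames
  at 600 frames total — a handful of minutes-long epochs, with the first
  visits cycling through all states so each occurs at least once) and a
  two-label THE/SO oscillatory track matching each state's preferred label
  with probability 0.9;
* per state, a latent binary assembly process (on/off Markov, mean dwell
  1 s) and a role for every neuron, rotated across states so neurons change
  roles: 20% core, 20% regular skin, 20% bursty skin, 40% periphery;
* engagement gating per role: core always engaged; regular skin in
  near-constant 20 s on/off epochs; bursty skin with on-epochs drawn from a
  short/long two-point mixture (2 s with probability 0.6, else 60 s), which
  makes every bursty neuron realize a stably high duration Fano factor — an
  unbounded heavy-tailed sampler would let a single extreme draw dominate
  the pooled min-max normalization and compress everyone else's Fano to
  ~0; periphery in short bouts (6 s on, 18 s off);
* firing: Bernoulli per 25 ms bin. An engaged neuron fires at
  `baseline * (1 + c * (gain − 1))` when the latent is on (defaults:
  baseline 1 Hz, gain 15, couplings c of 1.0 / 0.9 / 0.8 / 0.6 for core /
  regular skin / bursty skin / periphery, with a small downward jitter) and
  at baseline when it is off; a *disengaged* neuron is suppressed to
  `baseline / (1 + 2.5 * c * (gain − 1))` (tens of millihertz), mirroring
  the near-silent epochs of real units outside their assembly. The
  suppression is tied to the same gain so that `gain = 1` collapses the
  whole model to homogeneous uncoupled Poisson units — the negative
  control under which the surrogate test should retain only ~5% of links.

The quiescent suppression is load-bearing: the percentile test's ~5%
false-positive rate means that with 40 units a neuron firing steadily at
even 1 Hz acquires a spurious link almost every frame, and the planted
activation/duration structure would be invisible. Real units disconnect
because they fall silent; the generator reproduces that mechanism rather
than fighting the test.

What the generator does *not* emulate: oscillatory waveforms or any LFP
structure (the THE/SO track is a label sequence, not a signal), biophysical
spike dynamics, refractoriness, rate drift, electrode drift or sorting
errors, anatomically structured connectivity (region and layer labels are
assigned arbitrarily), and cross-recording heterogeneity. Passing recovery
tests on this generator shows the chain detects the structure it is
designed to detect at realistic rates and timescales; it does not show the
method's behavior under real biological confounds.

## Problem sizes and seeds

The packaged experiments run at the default study conditions — 40 units, 3
states, 600 frames (~10 minutes of recording) — with the pooled per-pair
threshold at 100 shuffles over 30 sampled windows; surrogate-calibration
checks use 20 uncoupled units, 600-bin windows, 100 windows and 200
shuffles per window. All randomness flows from explicit integer seeds
through CRC-derived child seeds per module, operation and frame, so every
stage is reproducible in isolation and reruns are byte-identical.

## Known limitations

* The per-pair percentile test has an irreducible ~5% false-positive link
  rate; retained-link fractions should always be read against it.
* The plug-in MI bias is absorbed by the threshold for sharing weights but
  not for storage, which is reported raw and is comparable only across
  equal window and bin settings.
* Whether the original analysis thresholded per window or per recording is
  ambiguous; both are implemented (`per-window` default, `pooled`
  alternative) and give consistent calibration on homogeneous units, but
  they are not numerically identical on structured data.
* The greedy coreness profile is a heuristic minimizer of the persistence;
  the test oracle verifies the greedy procedure exhaustively per step, not
  global optimality of the insertion order (the underlying combinatorial
  problem is exponential).
* K selection by silhouette is conservative on high-dimensional noisy
  features; strongly overlapping states can collapse to K = 1.
* With k = 5 style clusters on data containing four planted styles, the
  junk cluster absorbs genuinely weak profiles (mostly peripheral ones);
  style recovery is therefore assessed on the classified (non-junk)
  profiles.
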