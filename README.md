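# spikeshare

Temporal-network analysis of information sharing between simultaneously
recorded single units.

Cell assemblies are usually described as sets of co-active neurons.
`spikeshare` instead treats an assembly as a *temporal network*: within
every sliding window of a recording, the functional link from unit *i* to
unit *j* is the time-lagged mutual information between their binarized
spike trains,

    I_shared(i → j) = Σ_λ MI[ j(t), i(t − λ) ],    0 ≤ λ ≤ ½·T_θ,

thresholded at the 95th percentile of bin-order surrogates, so that the
recording becomes an ordered sequence of N×N weighted graphs. On that
object the package computes:

* **node features** — neighborhood *liquidity* (Jaccard index / cosine
  similarity between a node's neighborhoods in consecutive frames) and the
  random-walk core–periphery *coreness* C ∈ [0, 1] (persistence-based
  greedy profile; isolated nodes score exactly 0), plus percentile-cut core
  membership and per-region core filling factors;
* **network states** — K-means clustering of per-frame feature vectors
  (local 2N-dimensional or global 3-dimensional) into discrete recurring
  states, compared with each other and with a THE/SO oscillatory-state
  track via relative mutual information, RMI = MI(a;b)/max(H(a), H(b));
* **null models** — frame-wise Erdős–Rényi, Maslov–Sneppen
  degree-preserving, and weight-shuffle randomizations with exactly
  conserved quantities;
* **connectivity profiles and styles** — six state-averaged features per
  (neuron, state), K-means styles with a discarded junk class (core
  "streamers", peripheral "callers", bursty and regular core-skin
  "helpers"), KNN soft labels, style transition tables, enrichment by layer
  or cell type, and the switching index
  η = #style-changes / max(#styles, #states);
* **asymmetry and storage** — the sender/receiver coefficient
  ΔS% = (s_out − s_in)/(s_out + s_in) and active information storage
  I_storage(i) = Σ_λ MI[i(t), i(t−λ)];
* **a synthetic generator** — multi-hour-style recordings with a planted
  state schedule, planted core/skin/periphery roles per state and a
  correlated oscillatory track, so every stage is testable end-to-end with
  known ground truth.

It is aimed at systems neuroscientists and network scientists working with
spike-sorted multi-unit recordings (e.g. hippocampus/entorhinal cortex
under anesthesia) who want assembly dynamics expressed as temporal-graph
quantities rather than static co-activation patterns.

## Worked example

```python
from spikeshare import (
    SimConfig, generate_spike_data, WindowGrid, LagSpec, ShuffleSpec,
    build_temporal_network, symmetrize_and_binarize, feature_series,
    cluster_network_states, relative_mutual_information,
    oscillation_specificity,
)

config = SimConfig(frame_count=300, dwell_mean=100, seed=42)
spikes, truth = generate_spike_data(config)
print(f"units: {spikes.n_units}, duration: {spikes.duration:.0f} s, "
      f"median rate: {spikes.rates().median():.2f} Hz")

tn = build_temporal_network(
    spikes, WindowGrid(), LagSpec(),
    ShuffleSpec(n_shuffles=100, seed=1, mode="pooled", pooled_windows=20),
)
print(f"frames: {tn.n_frames}, retained links: {(tn.weights > 0).mean():.3f}")

tn_w, tn_u = symmetrize_and_binarize(tn)
feats = feature_series(tn_w, tn_u)
states = cluster_network_states((feats.cosine, feats.coreness_w), (1, 8), seed=2)
rmi = relative_mutual_information(states.labels, truth.state_schedule)
print(f"network states: K={states.n_states}, RMI vs planted schedule: {rmi:.3f}")
print(oscillation_specificity(states, truth.osc_track).round(2))
```

Output:

```
units: 40, duration: 309 s, median rate: 4.06 Hz
frames: 300, retained links: 0.364
network states: K=3, RMI vs planted schedule: 0.866
    THE    SO
1  0.86  0.14
2  0.80  0.20
3  0.13  0.87
```

The generator planted three alternating network states in a 300-frame
recording of 40 units. The sharing network retains 36% of possible links
after the surrogate threshold; K-means on the weighted liquidity+coreness
feature vectors recovers K = 3 states whose sequence matches the planted
schedule with relative mutual information 0.87, and each recovered state
occupies mostly one oscillatory regime (the per-state THE/SO occupancy
fractions in the table sum to 1 per row).

A command-line interface mirrors the library
(`spikeshare simulate | network | features | states | nulls | profiles |
run-all`); `spikeshare run-all --config run.yaml` executes the whole chain
and writes networks (HDF5 + GraphML), feature and state tables (TSV), and
a deterministic `summary.json` stamped with the config hash and seed.

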