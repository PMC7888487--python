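"""Frame-wise randomizations of temporal networks.

Three null models, each destroying part of the observed structure while
conserving a stated quantity exactly, frame by frame:

* Erdos-Renyi: a uniform random graph with the same node and edge count per
  frame (for weighted input the original frame's weight multiset is
  reassigned uniformly at random to the new edges, keeping total weight).
* degree-preserving: Maslov-Sneppen double-edge swaps, conserving every
  node's degree (unweighted frames).
* weight shuffle: the weights are permuted over the existing edges, leaving
  the unweighted structure (every node's neighborhood) untouched.

Frames are randomized independently, each from a child seed of the master
seed.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._rng import child_rng
from .datatypes import TemporalNetwork
from .errors import AnalysisWarning, InvalidConfigError

__all__ = [
    "er_randomize",
    "degree_preserving_randomize",
    "weight_shuffle_randomize",
]


def _frame_edge_list(F: np.ndarray):
    iu = np.triu_indices(F.shape[0], k=1)
    mask = F[iu] > 0
    return iu, mask, F[iu][mask]


def _assemble(N: int, rows, cols, weights) -> np.ndarray:
    out = np.zeros((N, N))
    out[rows, cols] = weights
    out[cols, rows] = weights
    return out


def er_randomize(tn: TemporalNetwork, seed: int = 0) -> TemporalNetwork:
    """Per-frame Erdos-Renyi null: same node count and edge count."""
    if tn.directed:
        raise InvalidConfigError("null models operate on undirected networks")
    N = tn.n_nodes
    iu = np.triu_indices(N, k=1)
    n_pairs = iu[0].size
    frames = np.empty_like(tn.weights)
    for t in range(tn.n_frames):
        rng = child_rng(seed, "er", t)
        _, mask, w = _frame_edge_list(tn.frame(t))
        m = int(mask.sum())
        pick = rng.choice(n_pairs, size=m, replace=False) if m else np.array([], int)
        weights = rng.permutation(w) if tn.weighted else np.ones(m)
        frames[t] = _assemble(N, iu[0][pick], iu[1][pick], weights)
    meta = {**tn.meta, "null_model": "erdos-renyi", "null_seed": seed}
    return tn.replace(weights=frames, meta=meta)


def _maslov_sneppen(
    edges: list, N: int, n_swaps: int, rng: np.random.Generator
) -> tuple[list, int]:
    """Double-edge swaps avoiding self-loops and multi-edges."""
    m = len(edges)
    if m < 2:
        return edges, 0
    edge_set = set(edges)
    accepted = 0
    attempts = 0
    max_attempts = 40 * n_swaps + 100
    batch = max(256, 4 * n_swaps)
    pair_idx = rng.integers(0, m, size=(batch, 2))
    coins = rng.random(batch)
    cursor = 0
    while accepted < n_swaps and attempts < max_attempts:
        if cursor >= batch:
            pair_idx = rng.integers(0, m, size=(batch, 2))
            coins = rng.random(batch)
            cursor = 0
        i, j = pair_idx[cursor]
        coin = coins[cursor]
        cursor += 1
        attempts += 1
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if coin < 0.5:
            new1, new2 = (a, d), (c, b)
        else:
            new1, new2 = (a, c), (b, d)
        if new1[0] > new1[1]:
            new1 = (new1[1], new1[0])
        if new2[0] > new2[1]:
            new2 = (new2[1], new2[0])
        if new1[0] == new1[1] or new2[0] == new2[1] or new1 == new2:
            continue
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = new1
        edges[j] = new2
        accepted += 1
    return edges, accepted


def degree_preserving_randomize(
    tn: TemporalNetwork, n_swaps_per_edge: int = 10, seed: int = 0
) -> TemporalNetwork:
    """Per-frame Maslov-Sneppen rewiring preserving every node's degree."""
    if tn.directed:
        raise InvalidConfigError("null models operate on undirected networks")
    if tn.weighted:
        raise InvalidConfigError(
            "degree-preserving null operates on unweighted frames"
        )
    N = tn.n_nodes
    frames = np.empty_like(tn.weights)
    stuck = 0
    for t in range(tn.n_frames):
        rng = child_rng(seed, "ms", t)
        F = tn.frame(t)
        iu, mask, _ = _frame_edge_list(F)
        rows, cols = iu[0][mask], iu[1][mask]
        edges = list(zip(rows.tolist(), cols.tolist()))
        target = n_swaps_per_edge * len(edges)
        edges, accepted = _maslov_sneppen(edges, N, target, rng)
        if edges and accepted == 0:
            stuck += 1
        if edges:
            r, c = zip(*edges)
            frames[t] = _assemble(N, np.array(r), np.array(c), np.ones(len(edges)))
        else:
            frames[t] = 0.0
    if stuck:
        warnings.warn(
            f"{stuck} frame(s) too sparse to swap; returned unchanged",
            AnalysisWarning,
            stacklevel=2,
        )
    meta = {**tn.meta, "null_model": "degree-preserving", "null_seed": seed}
    return tn.replace(weights=frames, meta=meta)


def weight_shuffle_randomize(tn: TemporalNetwork, seed: int = 0) -> TemporalNetwork:
    """Per-frame weight permutation over existing edges (support preserved)."""
    if tn.directed:
        raise InvalidConfigError("null models operate on undirected networks")
    if not tn.weighted:
        raise InvalidConfigError("weight shuffle needs a weighted network")
    N = tn.n_nodes
    frames = np.empty_like(tn.weights)
    iu = np.triu_indices(N, k=1)
    for t in range(tn.n_frames):
        rng = child_rng(seed, "ws", t)
        _, mask, w = _frame_edge_list(tn.frame(t))
        frames[t] = _assemble(N, iu[0][mask], iu[1][mask], rng.permutation(w))
    meta = {**tn.meta, "null_model": "weight-shuffle", "null_seed": seed}
    return tn.replace(weights=frames, meta=meta)
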