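"""Per-frame node features: liquidity and core-periphery coreness.

Coreness follows the random-walk core-periphery profile: nodes are inserted
greedily, at each step choosing the node that keeps the persistence
probability of the growing set minimal,

    alpha_S = sum_{i,j in S} pi_i m_ij / sum_{i in S} pi_i,

where ``m_ij = w_ij / s_i`` is the walk's transition matrix and ``pi`` its
stationary weight (``pi_i`` proportional to strength ``s_i``).  ``alpha_S``
is the probability that a stationary walker currently inside ``S`` remains
in ``S`` at the next step.  A node's coreness is the persistence of the set
at its insertion, normalized by the final (full-graph) persistence, so
peripheral nodes score near 0 and the innermost core scores near 1.
Zero-strength nodes are inserted first with coreness exactly 0.

Liquidity quantifies neighborhood turnover between consecutive frames: the
Jaccard index of the two neighbor sets for unweighted networks, the cosine
similarity of the two weight vectors for weighted networks.  Low values mean
a rapidly changing neighborhood.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import CoreAssignment, NodeFeatureSeries, TemporalNetwork
from .errors import (
    AlignmentError,
    AnalysisWarning,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "coreness",
    "coreness_series",
    "liquidity_series",
    "feature_series",
    "core_assignment",
]

_TIE_TOL = 1e-12


def coreness(W: np.ndarray) -> np.ndarray:
    """Core-periphery coreness of every node of one snapshot graph.

    Parameters
    ----------
    W
        Square non-negative (weighted) adjacency matrix.  The diagonal is
        ignored.  Works for unweighted graphs as 0/1 matrices.

    Returns
    -------
    ndarray of shape (N,) with values in [0, 1].

    Notes
    -----
    Greedy ties are broken deterministically: lowest persistence, then lowest
    strength, then lowest node index.  Persistence is scale-free, so
    multiplying all weights by a positive constant leaves the result
    unchanged.  A graph with no edges returns all zeros.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError("adjacency must be square")
    if np.any(W < 0):
        raise ValidationError("adjacency weights must be non-negative")
    N = W.shape[0]
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    s = W.sum(axis=1)
    total = s.sum()
    out = np.zeros(N, dtype=float)
    if total <= 0:
        return out
    pi = s / total
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(s[:, None] > 0, W / np.where(s[:, None] > 0, s[:, None], 1.0), 0.0)

    in_set = np.zeros(N, dtype=bool)
    # zero-strength nodes enter first, all with coreness 0; they do not move
    # the walk (pi = 0, empty row of M).
    zero = np.flatnonzero(s <= 0)
    in_set[zero] = True
    num = 0.0  # sum_{i,j in S} pi_i m_ij
    den = 0.0  # sum_{i in S} pi_i
    # incremental bookkeeping for candidate insertion v:
    #   row_in[v] = sum_{j in S} M[v, j]      (walk out of v into S)
    #   col_in[v] = sum_{i in S} pi_i M[i, v] (walk from S into v)
    row_in = np.zeros(N)
    col_in = np.zeros(N)
    alpha_at = np.zeros(N)
    remaining = np.flatnonzero(~in_set)
    while remaining.size:
        cand_num = num + pi[remaining] * row_in[remaining] + col_in[remaining]
        cand_den = den + pi[remaining]
        with np.errstate(divide="ignore", invalid="ignore"):
            alphas = np.where(cand_den > 0, cand_num / np.where(cand_den > 0, cand_den, 1.0), 0.0)
        amin = alphas.min()
        ties = remaining[alphas <= amin + _TIE_TOL]
        # lowest strength, then lowest index
        v = int(ties[np.lexsort((ties, s[ties]))][0])
        alpha_v = float(alphas[np.flatnonzero(remaining == v)[0]])
        num += pi[v] * row_in[v] + col_in[v]
        den += pi[v]
        in_set[v] = True
        alpha_at[v] = alpha_v
        row_in += M[:, v]
        col_in += pi[v] * M[v, :]
        remaining = remaining[remaining != v]
    alpha_final = num / den if den > 0 else 1.0
    if alpha_final <= 0:
        return out
    pos_nodes = np.flatnonzero(s > 0)
    out[pos_nodes] = np.clip(alpha_at[pos_nodes] / alpha_final, 0.0, 1.0)
    return out


def coreness_series(tn: TemporalNetwork) -> np.ndarray:
    """Coreness of every node in every frame, shape (T, N)."""
    return np.stack([coreness(tn.frame(t)) for t in range(tn.n_frames)])


def _jaccard_rows(prev: np.ndarray, cur: np.ndarray) -> np.ndarray:
    a = prev > 0
    b = cur > 0
    inter = (a & b).sum(axis=1).astype(float)
    union = (a | b).sum(axis=1).astype(float)
    return np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)


def _cosine_rows(prev: np.ndarray, cur: np.ndarray) -> np.ndarray:
    num = (prev * cur).sum(axis=1)
    den = np.linalg.norm(prev, axis=1) * np.linalg.norm(cur, axis=1)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def liquidity_series(tn: TemporalNetwork) -> np.ndarray:
    """Per-node liquidity between consecutive frames, shape (T, N).

    Row 0 is NaN (no predecessor frame).  A node isolated at both ``t - 1``
    and ``t`` -- or at exactly one of the two -- has liquidity 0 by
    convention (maximally uninformative / complete turnover).
    """
    if tn.n_frames < 2:
        raise InsufficientDataError("liquidity needs at least two frames")
    T, N = tn.n_frames, tn.n_nodes
    out = np.full((T, N), np.nan)
    fn = _cosine_rows if tn.weighted else _jaccard_rows
    for t in range(1, T):
        out[t] = fn(tn.frame(t - 1), tn.frame(t))
    return out


def feature_series(
    tn_weighted: TemporalNetwork, tn_unweighted: TemporalNetwork
) -> NodeFeatureSeries:
    """Assemble J, Theta, C, C_w for all nodes and frames."""
    if tn_weighted.n_frames != tn_unweighted.n_frames:
        raise AlignmentError("weighted and unweighted networks differ in frames")
    if list(tn_weighted.node_ids) != list(tn_unweighted.node_ids):
        raise AlignmentError("weighted and unweighted networks differ in nodes")
    return NodeFeatureSeries(
        node_ids=list(tn_weighted.node_ids),
        jaccard=liquidity_series(tn_unweighted),
        cosine=liquidity_series(tn_weighted),
        coreness=coreness_series(tn_unweighted),
        coreness_w=coreness_series(tn_weighted),
    )


def core_assignment(
    coreness_values: np.ndarray,
    percentile: float = 95.0,
    regions=None,
    scope: str = "pooled",
) -> CoreAssignment:
    """Core membership by a percentile cut on coreness values.

    ``scope="pooled"`` (default) computes the cut on the pooled (all neurons
    x all frames) distribution of the recording and applies it per frame;
    ``scope="per-frame"`` cuts on each frame's own distribution.  A neuron is
    in the core when its instantaneous coreness lies strictly above the cut,
    so an all-zero frame yields an empty core and ``percentile=0`` admits
    every connected neuron.

    When ``regions`` (one label per neuron) is given, the per-region core
    filling factor (percentage of that region's neurons inside the core) and
    the regional composition of the core (fractions summing to 1 whenever
    the core is non-empty, NaN otherwise) are attached.
    """
    C = np.asarray(coreness_values, dtype=float)
    if C.ndim != 2:
        raise ValidationError("coreness_values must have shape (T, N)")
    T, N = C.shape
    if scope == "pooled":
        cut = np.full(T, float(np.percentile(C, percentile)))
    elif scope == "per-frame":
        cut = np.percentile(C, percentile, axis=1)
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    member = C > cut[:, None]

    filling = None
    fractions = None
    if regions is not None:
        regions = np.asarray(regions)
        if regions.size != N:
            raise AlignmentError("regions must have one label per neuron")
        names = list(pd.unique(regions))
        ff = {}
        fr = {}
        core_sizes = member.sum(axis=1).astype(float)
        empty = core_sizes == 0
        if empty.any():
            warnings.warn(
                f"{int(empty.sum())} frame(s) have an empty core; regional "
                "fractions emitted as missing",
                AnalysisWarning,
                stacklevel=2,
            )
        for name in names:
            mask = regions == name
            in_core = member[:, mask].sum(axis=1).astype(float)
            ff[name] = 100.0 * in_core / mask.sum()
            fr[name] = np.where(empty, np.nan, in_core / np.where(empty, 1.0, core_sizes))
        filling = pd.DataFrame(ff)
        fractions = pd.DataFrame(fr)
    return CoreAssignment(
        member=member,
        cutoff=cut,
        percentile=percentile,
        filling_factor=filling,
        fractions=fractions,
    )
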