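"""Information-sharing networks from binarized spike trains.

The functional link from unit ``i`` to unit ``j`` within a sliding window is
the time-lagged mutual information summed over lags within half a theta
period,

    I_shared(i -> j) = sum_lambda MI[ j(t), i(t - lambda) ],

estimated with the plug-in (maximum-likelihood) estimator on 2x2 joint
histograms of the binarized trains, in bits.  A per-pair significance
threshold -- the 95th percentile of the same statistic over bin-order
shuffles of the trains -- is subtracted, and negative results are set to
zero, so estimator bias is absorbed by the surrogate threshold.  The
directed, weighted frames form a :class:`~spikeshare.datatypes.TemporalNetwork`;
symmetrized and binarized variants feed the downstream feature modules.

Active information storage is the same construction applied to a unit's own
past (a generalized autocorrelation); its lag-0 term is the entropy of the
binarized train and it is reported raw, without bias subtraction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._rng import child_rng
from .datatypes import (
    LagSpec,
    ShuffleSpec,
    SpikeData,
    StateSequence,
    TemporalNetwork,
    WindowGrid,
)
from .errors import (
    AlignmentError,
    AnalysisWarning,
    EmptyNetworkError,
    InsufficientDataError,
    InvalidConfigError,
)

__all__ = [
    "binarize_window",
    "lagged_mutual_information",
    "shuffle_threshold",
    "build_temporal_network",
    "symmetrize_and_binarize",
    "asymmetry_coefficients",
    "active_information_storage",
]


# ---------------------------------------------------------------------------
# binarization


def binarize_window(
    spikes: SpikeData,
    start: float,
    window_length: float,
    bin_width: float,
) -> np.ndarray:
    """Binarize all units within ``[start, start + window_length)``.

    Returns a (N, B) uint8 matrix with ``B = floor(window_length /
    bin_width)`` and entry 1 iff the unit fired at least once in the bin.
    """
    if bin_width <= 0:
        raise InvalidConfigError("bin_width must be positive")
    if start < -1e-9 or start + window_length > spikes.duration + 1e-6:
        raise InvalidConfigError("window must lie within the recording")
    n_bins = int(np.floor(window_length / bin_width + 1e-9))
    out = np.zeros((spikes.n_units, n_bins), dtype=np.uint8)
    for row, uid in enumerate(spikes.unit_ids):
        t = spikes.spike_times[uid]
        if not t.size:
            continue
        rel = t[(t >= start) & (t < start + n_bins * bin_width)] - start
        idx = np.floor(rel / bin_width).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        out[row, idx] = 1
    return out


def _binarize_recording(spikes: SpikeData, bin_width: float) -> np.ndarray:
    """Binarize the full recording on a global bin grid (fast path)."""
    n_bins = int(np.ceil(spikes.duration / bin_width - 1e-9))
    n_bins = max(n_bins, 1)
    out = np.zeros((spikes.n_units, n_bins), dtype=np.uint8)
    for row, uid in enumerate(spikes.unit_ids):
        t = spikes.spike_times[uid]
        if not t.size:
            continue
        idx = np.floor(t / bin_width).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        out[row, idx] = 1
    return out


def _window_slicer(spikes: SpikeData, grid: WindowGrid):
    """Return ``frame -> (N, B) matrix``, slicing a global binarization when
    window starts align with the bin grid, else re-binning per window."""
    ratio = grid.step / grid.bin_width
    n_bins = grid.n_bins
    if abs(ratio - round(ratio)) < 1e-9:
        global_bins = _binarize_recording(spikes, grid.bin_width)
        stride = int(round(ratio))

        def get(t: int) -> np.ndarray:
            b0 = t * stride
            return global_bins[:, b0 : b0 + n_bins]

        return get

    def get(t: int) -> np.ndarray:
        return binarize_window(
            spikes, t * grid.step, grid.window_length, grid.bin_width
        )

    return get


# ---------------------------------------------------------------------------
# plug-in MI


def _plugin_mi_2x2(n11, r1, c1, n):
    """Plug-in MI (bits) of 2x2 tables given co-occurrence and margins.

    Broadcasts: ``n11`` may be a matrix with row margins ``r1`` and column
    margins ``c1``; ``n`` is the number of samples.
    """
    n11 = np.asarray(n11, dtype=np.float64)
    r1 = np.asarray(r1, dtype=np.float64)
    c1 = np.asarray(c1, dtype=np.float64)
    n10 = r1 - n11
    n01 = c1 - n11
    n00 = n - r1 - c1 + n11
    r0 = n - r1
    c0 = n - c1
    mi = np.zeros(np.broadcast(n11, n00).shape, dtype=np.float64)
    for nab, ra, cb in ((n11, r1, c1), (n10, r1, c0), (n01, r0, c1), (n00, r0, c0)):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = nab * (np.log2(nab * n) - np.log2(ra * cb))
        mi += np.where(nab > 0, term, 0.0)
    return np.maximum(mi / n, 0.0)


def _check_length(length: int, max_lag: int):
    if length < max_lag + 2:
        raise InsufficientDataError(
            f"series of length {length} too short for max_lag={max_lag}"
        )


def lagged_mutual_information(x, y, lags: LagSpec) -> float:
    """I_shared with ``x`` as the present and ``y`` as the lagged past.

    Sum over lags ``0..max_lag`` of the plug-in MI between ``x(t)`` and
    ``y(t - lambda)`` on the overlapping support.  Non-negative, in bits.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise AlignmentError("series must have equal length")
    _check_length(x.size, lags.max_lag)
    total = 0.0
    for lag in range(lags.max_lag + 1):
        n = x.size - lag
        a = x[lag:]
        b = y[:n]
        n11 = float(a @ b)
        total += float(_plugin_mi_2x2(n11, float(b.sum()), float(a.sum()), n))
    return total


def _pairwise_lagged_mi(X: np.ndarray, max_lag: int) -> np.ndarray:
    """All-pair lagged MI for binarized window ``X`` of shape (N, B).

    Returns W with ``W[i, j] = I_shared(i -> j)`` (i past, j present).  The
    diagonal holds each unit's active information storage for the window.
    """
    Xf = np.ascontiguousarray(X, dtype=np.float64)
    B = Xf.shape[1]
    _check_length(B, max_lag)
    W = None
    for lag in range(max_lag + 1):
        n = B - lag
        present = Xf[:, lag:]  # receiver series j(t)
        past = Xf[:, :n]  # sender series i(t - lag)
        n11 = past @ present.T
        r1 = past.sum(axis=1)[:, None]
        c1 = present.sum(axis=1)[None, :]
        mi = _plugin_mi_2x2(n11, r1, c1, n)
        W = mi if W is None else W + mi
    return W


def _shuffle_samples(
    X: np.ndarray, max_lag: int, n_shuffles: int, rng: np.random.Generator
) -> np.ndarray:
    """Pairwise lagged MI under bin-order shuffles: shape (S, N, N)."""
    N, B = X.shape
    out = np.empty((n_shuffles, N, N), dtype=np.float64)
    base = np.tile(np.arange(B), (N, 1))
    for s in range(n_shuffles):
        perm = rng.permuted(base, axis=1)
        Xp = np.take_along_axis(X, perm, axis=1)
        out[s] = _pairwise_lagged_mi(Xp, max_lag)
    return out


def shuffle_threshold(x, y, lags: LagSpec, spec: ShuffleSpec) -> float:
    """Significance threshold for one ordered pair.

    The requested percentile of lagged MI over ``n_shuffles`` independent
    bin-order permutations of each series.  Deterministic under
    ``spec.seed``.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise AlignmentError("series must have equal length")
    _check_length(x.size, lags.max_lag)
    rng = child_rng(spec.seed, "pair-shuffle")
    vals = np.empty(spec.n_shuffles)
    for s in range(spec.n_shuffles):
        vals[s] = lagged_mutual_information(
            rng.permutation(x), rng.permutation(y), lags
        )
    return float(np.percentile(vals, spec.percentile))


# ---------------------------------------------------------------------------
# temporal network construction


def _pooled_thresholds(
    get_window, T: int, lags: LagSpec, spec: ShuffleSpec
) -> np.ndarray:
    """One per-pair threshold from shuffles pooled over sampled windows."""
    k = min(spec.pooled_windows, T)
    sample = np.unique(np.linspace(0, T - 1, k).round().astype(int))
    chunks = []
    for t in sample:
        rng = child_rng(spec.seed, "window", int(t))
        chunks.append(
            _shuffle_samples(get_window(int(t)), lags.max_lag, spec.n_shuffles, rng)
        )
    pooled = np.concatenate(chunks, axis=0)
    return np.percentile(pooled, spec.percentile, axis=0)


def build_temporal_network(
    spikes: SpikeData,
    grid: WindowGrid | None = None,
    lags: LagSpec | None = None,
    spec: ShuffleSpec | None = None,
) -> TemporalNetwork:
    """Directed weighted temporal network of information sharing.

    Frame ``t`` holds ``w_ij = max(I_shared(i -> j) - theta_ij(t), 0)`` where
    ``theta`` is the shuffle threshold (per window, or pooled over windows
    depending on ``spec.mode``).  The diagonal is excluded.
    """
    grid = grid or WindowGrid()
    lags = lags or LagSpec(bin_width=grid.bin_width)
    spec = spec or ShuffleSpec()
    if spikes.n_units == 0:
        raise EmptyNetworkError("no units in spike data")
    T = grid.n_frames(spikes.duration)
    N = spikes.n_units
    get_window = _window_slicer(spikes, grid)

    pooled_thr = None
    if spec.mode == "pooled":
        pooled_thr = _pooled_thresholds(get_window, T, lags, spec)

    frames = np.empty((T, N, N), dtype=np.float64)
    for t in range(T):
        X = get_window(t)
        W = _pairwise_lagged_mi(X, lags.max_lag)
        if pooled_thr is None:
            rng = child_rng(spec.seed, "window", t)
            thr = np.percentile(
                _shuffle_samples(X, lags.max_lag, spec.n_shuffles, rng),
                spec.percentile,
                axis=0,
            )
        else:
            thr = pooled_thr
        F = W - thr
        np.clip(F, 0.0, None, out=F)
        np.fill_diagonal(F, 0.0)
        frames[t] = F
    return TemporalNetwork(
        node_ids=spikes.unit_ids,
        weights=frames,
        directed=True,
        weighted=True,
        frame_times=grid.frame_times(spikes.duration),
        meta={
            "window_length": grid.window_length,
            "step": grid.step,
            "bin_width": grid.bin_width,
            "theta_period": lags.theta_period,
            "max_lag": lags.max_lag,
            "n_shuffles": spec.n_shuffles,
            "percentile": spec.percentile,
            "threshold_mode": spec.mode,
            "seed": spec.seed,
        },
    )


def symmetrize_and_binarize(
    tn: TemporalNetwork,
) -> tuple[TemporalNetwork, TemporalNetwork]:
    """Undirected weighted and unweighted variants of a directed network.

    The symmetric weight is the arithmetic mean of the two reciprocal
    weights; the unweighted entry is 1 iff the symmetric weight is positive.
    """
    if not tn.directed:
        sym = tn.weights.copy()
    else:
        sym = 0.5 * (tn.weights + tn.weights.transpose(0, 2, 1))
    und_w = tn.replace(
        weights=sym, directed=False, weighted=True, meta={**tn.meta}
    )
    und_u = tn.replace(
        weights=(sym > 0).astype(float),
        directed=False,
        weighted=False,
        meta={**tn.meta},
    )
    return und_w, und_u


# ---------------------------------------------------------------------------
# asymmetry and storage


def asymmetry_coefficients(
    tn: TemporalNetwork, states: StateSequence
) -> pd.DataFrame:
    """Per-neuron per-state asymmetry coefficient DeltaS%.

    ``s_out`` / ``s_in`` are the unit's outgoing / incoming sharing weights
    summed over the state's frames; ``delta_s = (s_out - s_in) / (s_out +
    s_in)``, with the 0/0 case defined as 0 (an isolated neuron carries no
    flow).  +1 is a perfect sender, -1 a perfect receiver.
    """
    if not tn.directed:
        warnings.warn(
            "asymmetry on an undirected network is identically zero",
            AnalysisWarning,
            stacklevel=2,
        )
    if states.n_frames != tn.n_frames:
        raise AlignmentError("state labels must cover all frames")
    rows = []
    for h, idx in states.frame_sets().items():
        if idx.size == 0:
            warnings.warn(f"state {h} has no frames; skipped", AnalysisWarning,
                          stacklevel=2)
            continue
        A = tn.weights[idx].sum(axis=0)
        s_out = A.sum(axis=1)
        s_in = A.sum(axis=0)
        tot = s_out + s_in
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(tot > 0, (s_out - s_in) / np.where(tot > 0, tot, 1.0), 0.0)
        for i, uid in enumerate(tn.node_ids):
            rows.append(
                {
                    "neuron": uid,
                    "state": h,
                    "s_out": float(s_out[i]),
                    "s_in": float(s_in[i]),
                    "delta_s": float(delta[i]),
                }
            )
    return pd.DataFrame(rows, columns=["neuron", "state", "s_out", "s_in", "delta_s"])


def active_information_storage(
    spikes: SpikeData,
    grid: WindowGrid | None = None,
    lags: LagSpec | None = None,
) -> np.ndarray:
    """Active information storage per unit per frame, shape (T, N), bits.

    For each window, the sum over lags of the plug-in MI between the unit's
    binarized train and its lag-shifted self; the lag-0 term is the train's
    entropy.  Reported raw (no bias subtraction).
    """
    grid = grid or WindowGrid()
    lags = lags or LagSpec(bin_width=grid.bin_width)
    if spikes.n_units == 0:
        raise EmptyNetworkError("no units in spike data")
    T = grid.n_frames(spikes.duration)
    get_window = _window_slicer(spikes, grid)
    out = np.empty((T, spikes.n_units), dtype=np.float64)
    for t in range(T):
        X = get_window(t).astype(np.float64)
        B = X.shape[1]
        _check_length(B, lags.max_lag)
        acc = np.zeros(X.shape[0])
        for lag in range(lags.max_lag + 1):
            n = B - lag
            a = X[:, lag:]
            b = X[:, :n]
            n11 = (a * b).sum(axis=1)
            acc += _plugin_mi_2x2(n11, b.sum(axis=1), a.sum(axis=1), n)
        out[t] = acc
    return out
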