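"""Discrete network states from per-frame feature vectors.

Each frame is summarized by a feature vector -- either the concatenated
per-node liquidity and coreness values (2N dimensions) or three global
summaries (node-averaged liquidity, node-averaged coreness, total weight /
edge count) -- and K-means clustering of the frame vectors yields a sequence
of discrete network states.  K is selected by scanning a range and keeping
the K with the best mean silhouette; if even the best silhouette is below a
floor the sequence is declared single-state.

Agreement between two label sequences (e.g. network states vs. the
oscillatory THE/SO track, or recovered vs. planted states) is measured by
relative mutual information: plug-in MI divided by the larger of the two
entropies, which is 1 for label-bijective sequences and 0 in expectation for
independent ones.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import mutual_info_score, silhouette_score

from ._rng import child_rng, child_seed
from .datatypes import StateSequence, TemporalNetwork
from .errors import AlignmentError, AnalysisWarning, InsufficientDataError

__all__ = [
    "feature_correlation_matrix",
    "cluster_network_states",
    "global_feature_states",
    "relative_mutual_information",
    "oscillation_specificity",
    "clustering_quality_vs_chance",
]


def feature_correlation_matrix(series: np.ndarray) -> np.ndarray:
    """T x T Pearson correlation between per-frame N-vectors.

    Element (t, t') is the correlation between the N feature values at
    frames t and t'.  Zero-variance frames yield 0 entries (with a warning);
    the diagonal is 1.
    """
    F = np.asarray(series, dtype=float)
    if F.ndim != 2 or F.shape[0] < 2 or F.shape[1] < 2:
        raise InsufficientDataError("need at least 2 frames and 2 nodes")
    F = np.where(np.isnan(F), 0.0, F)
    sd = F.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance frame(s); correlations set to 0",
            AnalysisWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.corrcoef(F)
    M = np.where(np.isnan(M), 0.0, M)
    np.fill_diagonal(M, 1.0)
    return np.clip(M, -1.0, 1.0)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _kmeans_states(
    X: np.ndarray,
    k_range: tuple[int, int],
    seed: int,
    n_init: int = 50,
    silhouette_floor: float = 0.1,
) -> StateSequence:
    """K-means over frame vectors with silhouette-based K selection."""
    X = np.asarray(X, dtype=float)
    X = np.where(np.isnan(X), 0.0, X)
    T = X.shape[0]
    k_min, k_max = k_range
    if T < max(k_max, 2):
        raise InsufficientDataError(f"need at least {k_max} frames, got {T}")
    n_unique = np.unique(X, axis=0).shape[0]
    if n_unique == 1:
        warnings.warn(
            "features constant over time; returning a single state",
            AnalysisWarning,
            stacklevel=3,
        )
        return StateSequence(np.ones(T, dtype=int))
    Xs = _standardize(X)
    best = None  # (silhouette, labels)
    for k in range(max(2, k_min), min(k_max, n_unique) + 1):
        km = KMeans(
            n_clusters=k,
            n_init=n_init,
            random_state=child_seed(seed, "kmeans", k),
        )
        labels = km.fit_predict(Xs)
        if np.unique(labels).size < 2:
            continue
        sil = silhouette_score(Xs, labels)
        if best is None or sil > best[0] + 1e-12:
            best = (sil, labels)
    if best is None or best[0] < silhouette_floor:
        return StateSequence(np.ones(T, dtype=int))
    return StateSequence.from_labels(best[1])


def cluster_network_states(
    feature_arrays,
    k_range: tuple[int, int] = (1, 8),
    seed: int = 0,
    n_init: int = 50,
    silhouette_floor: float = 0.1,
) -> StateSequence:
    """Network states from concatenated per-frame node-feature vectors.

    ``feature_arrays`` is a sequence of (T, N) arrays -- typically
    ``(jaccard, coreness)`` for the unweighted analysis or ``(cosine,
    coreness_w)`` for the weighted one -- concatenated frame-wise into
    2N-dimensional vectors.  Features are standardized per dimension before
    clustering; NaN liquidity entries (frame 0) are treated as 0.
    Deterministic under ``seed``; states are relabeled 1..K by first
    occurrence.
    """
    X = np.hstack([np.asarray(a, dtype=float) for a in feature_arrays])
    return _kmeans_states(X, k_range, seed, n_init, silhouette_floor)


def global_feature_states(
    tn: TemporalNetwork,
    liquidity: np.ndarray,
    coreness_values: np.ndarray,
    k_range: tuple[int, int] = (1, 8),
    seed: int = 0,
    n_init: int = 50,
    silhouette_floor: float = 0.1,
) -> StateSequence:
    """Network states from three global per-frame features.

    The features are the node-averaged liquidity, the node-averaged
    coreness, and the total edge weight of the frame (which reduces to the
    edge count for unweighted networks).
    """
    liq = np.asarray(liquidity, dtype=float)
    cor = np.asarray(coreness_values, dtype=float)
    if liq.shape[0] != tn.n_frames or cor.shape[0] != tn.n_frames:
        raise AlignmentError("feature frames must match the network")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_liq = np.nanmean(liq, axis=1)
    mean_liq = np.where(np.isnan(mean_liq), 0.0, mean_liq)
    mean_cor = cor.mean(axis=1)
    iu = np.triu_indices(tn.n_nodes, k=1)
    total_w = np.array([tn.frame(t)[iu].sum() for t in range(tn.n_frames)])
    X = np.column_stack([mean_liq, mean_cor, total_w])
    return _kmeans_states(X, k_range, seed, n_init, silhouette_floor)


def relative_mutual_information(a, b) -> float:
    """Plug-in MI between two label sequences over the larger entropy.

    In [0, 1]; exactly 1 when the sequences are identical up to relabeling
    (both degenerate-constant sequences also count as full agreement), 0
    when one sequence is constant while the other is not, and 0 in
    expectation for independent sequences.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise AlignmentError("sequences must have equal length")
    if a.size == 0:
        raise InsufficientDataError("empty sequences")

    def _entropy(x):
        _, counts = np.unique(x, return_counts=True)
        p = counts / counts.sum()
        return float(-(p * np.log2(p)).sum())

    ha, hb = _entropy(a), _entropy(b)
    if ha == 0 and hb == 0:
        return 1.0
    if ha == 0 or hb == 0:
        return 0.0
    mi_bits = mutual_info_score(a, b) / np.log(2)
    value = float(np.clip(mi_bits / max(ha, hb), 0.0, 1.0))
    # snap float noise at the analytic endpoints (bijection / independence)
    if abs(value - 1.0) < 1e-12:
        return 1.0
    if value < 1e-12:
        return 0.0
    return value


def oscillation_specificity(states: StateSequence, osc) -> pd.DataFrame:
    """Per network state, the fraction of its frames under each oscillatory
    label.  Rows index states; fractions in each row sum to 1."""
    osc = np.asarray(osc)
    if osc.size != states.n_frames:
        raise AlignmentError("oscillatory track must cover all frames")
    labels = list(pd.unique(osc))
    rows = {}
    for h, idx in states.frame_sets().items():
        if idx.size == 0:
            continue
        sub = osc[idx]
        rows[h] = {lab: float((sub == lab).mean()) for lab in labels}
    return pd.DataFrame.from_dict(rows, orient="index")[labels]


def clustering_quality_vs_chance(
    features,
    states: StateSequence,
    n_surrogates: int = 100,
    seed: int = 0,
    k_range: tuple[int, int] = (1, 8),
    n_init: int = 10,
):
    """Silhouette quality of a state partition against a permutation null.

    The chance distribution re-clusters surrogate feature series in which
    every feature dimension has been independently permuted across frames
    (destroying frame-wise structure while keeping marginals), with the same
    K-selection procedure.  Returns ``(quality, percentile)`` where
    ``percentile`` locates the observed quality in the surrogate
    distribution; ``None`` when ``n_surrogates == 0``.  For a single-state
    partition the quality is undefined and returned as NaN.
    """
    if isinstance(features, (list, tuple)):
        X = np.hstack([np.asarray(a, dtype=float) for a in features])
    else:
        X = np.asarray(features, dtype=float)
    X = np.where(np.isnan(X), 0.0, X)
    if states.n_frames != X.shape[0]:
        raise AlignmentError("labels must cover all frames")
    if states.n_states < 2:
        warnings.warn(
            "single-state partition: clustering quality undefined",
            AnalysisWarning,
            stacklevel=2,
        )
        return float("nan"), None
    Xs = _standardize(X)
    quality = float(silhouette_score(Xs, states.labels))
    if n_surrogates == 0:
        return quality, None
    surr = np.empty(n_surrogates)
    for s in range(n_surrogates):
        rng = child_rng(seed, "surrogate", s)
        Xp = np.column_stack(
            [rng.permutation(X[:, d]) for d in range(X.shape[1])]
        )
        labels = _kmeans_states(
            Xp, k_range, child_seed(seed, "surrogate-km", s), n_init=n_init
        )
        if labels.n_states < 2:
            surr[s] = 0.0
        else:
            surr[s] = silhouette_score(_standardize(Xp), labels.labels)
    pct = float(stats.percentileofscore(surr, quality, kind="mean"))
    return quality, pct
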