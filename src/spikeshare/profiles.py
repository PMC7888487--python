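"""Per-neuron per-state connectivity profiles, styles and the eta index.

A neuron's behavior inside one network state is summarized by six features:
state-averaged weighted coreness, state-averaged cosine liquidity,
state-averaged strength, activation number ``n_a`` (how many times the
neuron goes from isolated to connected within the state), total connectivity
time ``tau`` (connected frames), and the Fano factor ``phi`` of the
connection durations (population variance over mean; 0 with fewer than two
durations).  Features are min-max normalized over the pooled profile set and
K-means clustered (k = 5 by default): the cluster whose centroid is closest
to the origin is a discarded "junk" class of barely-connected profiles, and
the remaining four clusters are mapped to the named connectivity styles --
core ("streamers"), periphery ("callers"), bursty core-skin ("freelancer
helpers") and regular core-skin ("staff helpers") -- by their centroid
signatures.

The eta index measures style switching across consecutive network states:
the number of style changes divided by ``max(n_styles, n_states)``, so
``eta = 0`` for a style-constant neuron and ``eta = 1`` only when the style
changes at every one of at least ``max(4, n_states)`` transitions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from ._rng import child_rng, child_seed
from .datatypes import NodeFeatureSeries, StateSequence, TemporalNetwork
from .errors import AlignmentError, AnalysisWarning, InvalidConfigError

__all__ = [
    "PROFILE_FEATURES",
    "STYLES",
    "connection_runs",
    "compute_profiles",
    "normalize_profiles",
    "cluster_styles",
    "soft_classify",
    "eta_index",
    "eta_indices",
    "style_transition_matrix",
    "style_enrichment",
    "feature_rate_correlation",
    "storage_by_style",
]

PROFILE_FEATURES = ("coreness", "liquidity", "strength", "n_act", "tau", "fano")
# clustering uses occupancy-corrected activation/connectivity features:
# raw counts scale with the state's duration, so clustering on them encodes
# epoch length rather than connectivity style
CLUSTER_FEATURES = (
    "coreness",
    "liquidity",
    "strength",
    "n_act_rate",
    "tau_frac",
    "fano",
)
STYLES = ("core", "periphery", "bursty_core_skin", "regular_core_skin")
JUNK = "junk"


def connection_runs(strength_series) -> tuple[int, int, np.ndarray]:
    """Activation count, connected time and run durations of one series.

    A run is a maximal stretch of frames with positive strength; a neuron
    connected at the first frame counts as one activation.
    """
    s = np.asarray(strength_series, dtype=float)
    on = s > 0
    if not on.any():
        return 0, 0, np.array([], dtype=int)
    starts = np.flatnonzero(on & ~np.concatenate(([False], on[:-1])))
    ends = np.flatnonzero(on & ~np.concatenate((on[1:], [False])))
    durations = ends - starts + 1
    return int(starts.size), int(on.sum()), durations


def _fano(durations: np.ndarray) -> float:
    """Population variance over mean of the durations; 0 when degenerate."""
    if durations.size < 2:
        return 0.0
    mean = durations.mean()
    if mean == 0:
        return 0.0
    return float(durations.var() / mean)


def compute_profiles(
    tn_weighted: TemporalNetwork,
    features: NodeFeatureSeries,
    states: StateSequence,
) -> pd.DataFrame:
    """One six-feature connectivity profile per (neuron, state).

    Durations are computed over the state's frame sequence in temporal
    order.  Liquidity averages skip the undefined first frame of the
    recording.
    """
    if tn_weighted.n_frames != states.n_frames:
        raise AlignmentError("states must cover the network frames")
    if features.n_frames != tn_weighted.n_frames:
        raise AlignmentError("features must cover the network frames")
    strengths = tn_weighted.strengths()  # (T, N)
    rows = []
    for h, idx in states.frame_sets().items():
        if idx.size == 0:
            warnings.warn(f"state {h} is empty; skipped", AnalysisWarning,
                          stacklevel=2)
            continue
        cor = features.coreness_w[idx]
        liq = features.cosine[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_liq = np.nanmean(liq, axis=0)
        mean_liq = np.where(np.isnan(mean_liq), 0.0, mean_liq)
        for i, uid in enumerate(tn_weighted.node_ids):
            n_act, tau, durations = connection_runs(strengths[idx, i])
            rows.append(
                {
                    "neuron": uid,
                    "state": h,
                    "coreness": float(cor[:, i].mean()),
                    "liquidity": float(mean_liq[i]),
                    "strength": float(strengths[idx, i].mean()),
                    "n_act": float(n_act),
                    "tau": float(tau),
                    "fano": _fano(durations),
                    "state_frames": int(idx.size),
                    "n_act_rate": float(n_act) / idx.size,
                    "tau_frac": float(tau) / idx.size,
                }
            )
    return pd.DataFrame(rows)


def normalize_profiles(
    profiles: pd.DataFrame, feature_cols=None
) -> pd.DataFrame:
    """Min-max normalize each feature over the pooled profile set.

    Adds ``<feature>_norm`` columns in [0, 1]; a constant feature maps to 0
    with a warning.
    """
    if feature_cols is None:
        feature_cols = tuple(
            dict.fromkeys(PROFILE_FEATURES + CLUSTER_FEATURES)
        )
        feature_cols = tuple(c for c in feature_cols if c in profiles.columns)
    if len(profiles) < 2:
        raise InvalidConfigError("need at least two profiles to normalize")
    out = profiles.copy()
    for col in feature_cols:
        x = out[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi > lo:
            out[col + "_norm"] = (x - lo) / (hi - lo)
        else:
            warnings.warn(
                f"feature {col!r} is constant; normalized to 0",
                AnalysisWarning,
                stacklevel=2,
            )
            out[col + "_norm"] = 0.0
    return out


def _map_styles(centroids: np.ndarray, cluster_ids: list) -> dict:
    """Name four non-junk centroids by their feature signatures.

    Works in normalized feature space, feature order as the clustering
    feature set (coreness, liquidity, strength, activation rate, connected
    fraction, Fano factor).
    """
    C = {cid: centroids[k] for k, cid in enumerate(cluster_ids)}
    rest = list(cluster_ids)
    # core: high coreness + strength + liquidity, persistent (low n_act)
    core = max(rest, key=lambda c: C[c][0] + C[c][2] + C[c][1] - C[c][3])
    rest.remove(core)
    # periphery: many activations but weak, shallow integration
    periphery = max(rest, key=lambda c: C[c][3] - C[c][0] - C[c][2])
    rest.remove(periphery)
    # remaining two are the core-skin styles, split by the Fano factor
    bursty = max(rest, key=lambda c: C[c][5])
    rest.remove(bursty)
    regular = rest[0]
    return {
        core: "core",
        periphery: "periphery",
        bursty: "bursty_core_skin",
        regular: "regular_core_skin",
    }


def cluster_styles(
    profiles: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    n_init: int = 50,
    feature_cols=None,
) -> pd.DataFrame:
    """K-means the normalized profiles into connectivity styles.

    The cluster whose centroid has the smallest Euclidean norm is labeled
    ``junk`` (barely-connected profiles, subsequently discarded from style
    analyses).  With ``k = 5`` the remaining four clusters are mapped to the
    named styles by centroid signature; otherwise they receive generic
    labels with a warning.
    """
    if feature_cols is None:
        feature_cols = tuple(
            c for c in CLUSTER_FEATURES if c in profiles.columns
        ) or PROFILE_FEATURES
    norm_cols = [c + "_norm" for c in feature_cols]
    missing = [c for c in norm_cols if c not in profiles.columns]
    if missing:
        profiles = normalize_profiles(profiles)
    X = profiles[norm_cols].to_numpy(dtype=float)
    if len(X) < k:
        raise InvalidConfigError(f"need at least {k} profiles for k={k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=child_seed(seed, "styles"))
    raw = km.fit_predict(X)
    centroids = km.cluster_centers_
    populated = sorted(set(raw.tolist()))
    norms = np.linalg.norm(centroids, axis=1)
    junk_id = int(np.argmin(norms))
    non_junk = [c for c in populated if c != junk_id]
    if len(non_junk) == 4:
        mapping = _map_styles(centroids[non_junk], non_junk)
    else:
        warnings.warn(
            f"{len(non_junk)} populated non-junk clusters; using generic "
            "style labels",
            AnalysisWarning,
            stacklevel=2,
        )
        mapping = {c: f"style_{r + 1}" for r, c in enumerate(non_junk)}
    mapping[junk_id] = JUNK
    out = profiles.copy()
    out["style"] = [mapping[c] for c in raw]
    return out


def soft_classify(
    profiles: pd.DataFrame, k_neighbors: int = 10, feature_cols=None
) -> pd.DataFrame:
    """KNN soft style membership for every non-junk profile.

    Each profile's soft label is the fraction of its ``k_neighbors`` nearest
    non-self, non-junk neighbors (Euclidean distance in normalized feature
    space) carrying each style; the four components sum to 1.  A merged
    3-class view (``p_core_skin`` = bursty + regular) is included.
    """
    if "style" not in profiles.columns:
        raise InvalidConfigError("profiles must carry hard style labels")
    if feature_cols is None:
        feature_cols = tuple(
            c for c in CLUSTER_FEATURES if c in profiles.columns
        ) or PROFILE_FEATURES
    norm_cols = [c + "_norm" for c in feature_cols]
    pool = profiles[profiles["style"] != JUNK]
    if k_neighbors >= len(pool):
        raise InvalidConfigError(
            f"k_neighbors={k_neighbors} must be smaller than the "
            f"{len(pool)} labeled profiles"
        )
    X = pool[norm_cols].to_numpy(dtype=float)
    styles = pool["style"].to_numpy()
    nn = NearestNeighbors(n_neighbors=min(k_neighbors + 1, len(pool)))
    nn.fit(X)
    _, idx = nn.kneighbors(X)
    probs = np.zeros((len(pool), len(STYLES)))
    for row in range(len(pool)):
        neigh = [j for j in idx[row] if j != row][:k_neighbors]
        labels = styles[neigh]
        for s_i, s in enumerate(STYLES):
            probs[row, s_i] = float((labels == s).mean())
    out = pool.copy()
    for s_i, s in enumerate(STYLES):
        out["p_" + s] = probs[:, s_i]
    out["p_core_skin"] = out["p_bursty_core_skin"] + out["p_regular_core_skin"]
    return out


def eta_index(style_sequence, n_styles: int = 4, n_states: int | None = None) -> float:
    """Style-switching index of one neuron across consecutive states.

    ``style_sequence`` lists the neuron's style in each visited state in
    temporal order.  The numerator counts consecutive entries that differ;
    the denominator is ``max(n_styles, n_states)`` with ``n_states``
    defaulting to the sequence length.  Clipped to [0, 1]; a single-state
    recording gives 0.
    """
    seq = list(style_sequence)
    if n_states is None:
        n_states = len(seq)
    if len(seq) < 2:
        return 0.0
    changes = sum(1 for a, b in zip(seq[:-1], seq[1:]) if a != b)
    denom = max(int(n_styles), int(n_states))
    if denom <= 0:
        return 0.0
    return float(np.clip(changes / denom, 0.0, 1.0))


def _visit_styles(profiles: pd.DataFrame, visits: np.ndarray) -> dict:
    """Per-neuron style sequence along the visited-state sequence.

    Junk profiles are dropped from a neuron's sequence (the junk class is
    discarded before style analyses).
    """
    style_of = {
        (r.neuron, r.state): r.style for r in profiles.itertuples(index=False)
    }
    out = {}
    for neuron in profiles["neuron"].unique():
        seq = []
        for h in visits:
            s = style_of.get((neuron, int(h)))
            if s is not None and s != JUNK:
                seq.append(s)
        out[neuron] = seq
    return out


def eta_indices(
    profiles: pd.DataFrame,
    states: StateSequence,
    n_styles: int = len(STYLES),
) -> pd.Series:
    """Eta index per neuron for a recording's state sequence.

    The visited-state sequence includes revisits; ``n_states`` is the number
    of distinct states in the recording.
    """
    if "style" not in profiles.columns:
        raise InvalidConfigError("profiles must carry hard style labels")
    visits = states.visits()
    n_states = int(np.unique(states.labels).size)
    seqs = _visit_styles(profiles, visits)
    return pd.Series(
        {n: eta_index(seq, n_styles, n_states) for n, seq in seqs.items()},
        name="eta",
    )


def style_transition_matrix(
    profiles: pd.DataFrame, states: StateSequence
) -> dict:
    """Style-to-style transition counts and rates across consecutive states.

    Pooled over neurons and consecutive visited-state pairs.  Returns the
    full 5-class tables (the four styles plus junk) and a merged 3-class
    view (core / core-skin / periphery, junk transitions dropped).  Rates
    are row-normalized over destination styles.
    """
    if "style" not in profiles.columns:
        raise InvalidConfigError("profiles must carry hard style labels")
    visits = states.visits()
    if visits.size < 2:
        warnings.warn("single visited state: no transitions", AnalysisWarning,
                      stacklevel=2)
    style_of = {
        (r.neuron, r.state): r.style for r in profiles.itertuples(index=False)
    }
    full_labels = list(STYLES) + [JUNK]
    counts5 = pd.DataFrame(0, index=full_labels, columns=full_labels, dtype=float)
    merge = {
        "core": "core",
        "periphery": "periphery",
        "bursty_core_skin": "core_skin",
        "regular_core_skin": "core_skin",
    }
    labels3 = ["core", "core_skin", "periphery"]
    counts3 = pd.DataFrame(0, index=labels3, columns=labels3, dtype=float)
    for neuron in profiles["neuron"].unique():
        for a, b in zip(visits[:-1], visits[1:]):
            sa = style_of.get((neuron, int(a)))
            sb = style_of.get((neuron, int(b)))
            if sa is None or sb is None:
                continue
            counts5.loc[sa, sb] += 1
            if sa != JUNK and sb != JUNK:
                counts3.loc[merge[sa], merge[sb]] += 1

    def _rates(counts):
        sums = counts.sum(axis=1)
        rates = counts.div(sums.where(sums > 0, 1.0), axis=0)
        return rates.where(sums > 0, np.nan)

    return {
        "counts5": counts5,
        "rates5": _rates(counts5),
        "counts3": counts3,
        "rates3": _rates(counts3),
    }


def style_enrichment(
    profiles: pd.DataFrame,
    stratum: str,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Over/under-representation of styles per stratum against permutations.

    ``stratum`` names a column of ``profiles`` (e.g. layer or cell type).
    The null permutes style labels across profiles within each recording
    (column ``recording`` if present, else one pooled recording), preserving
    per-recording style counts; observed counts outside the two-sided alpha
    band are flagged ``over`` / ``under``.  Strata with fewer than 3
    profiles are flagged untestable.  With ``n_permutations == 0`` only the
    observed counts are returned.
    """
    if stratum not in profiles.columns:
        raise InvalidConfigError(f"no column {stratum!r} in profiles")
    df = profiles[profiles["style"] != JUNK].copy()
    if "recording" not in df.columns:
        df["recording"] = "rec0"
    strata = list(pd.unique(df[stratum]))
    styles = [s for s in STYLES if (df["style"] == s).any()]

    def _counts(frame):
        return {
            (sty, st): int(
                ((frame["style"] == sty) & (frame[stratum] == st)).sum()
            )
            for sty in styles
            for st in strata
        }

    observed = _counts(df)
    rows = []
    if n_permutations > 0:
        null = {key: np.empty(n_permutations) for key in observed}
        groups = [idx for _, idx in df.groupby("recording").indices.items()]
        style_arr = df["style"].to_numpy()
        stratum_arr = df[stratum].to_numpy()
        for p in range(n_permutations):
            rng = child_rng(seed, "enrich", p)
            perm = style_arr.copy()
            for idx in groups:
                perm[idx] = rng.permutation(perm[idx])
            for sty in styles:
                is_style = perm == sty
                for st in strata:
                    null[(sty, st)][p] = np.sum(is_style & (stratum_arr == st))
    for sty in styles:
        for st in strata:
            n_in_stratum = int((df[stratum] == st).sum())
            row = {
                "style": sty,
                "stratum": st,
                "observed": observed[(sty, st)],
                "stratum_size": n_in_stratum,
            }
            if n_in_stratum < 3:
                row["flag"] = "untestable"
            elif n_permutations > 0:
                dist = null[(sty, st)]
                lo = np.quantile(dist, alpha / 2)
                hi = np.quantile(dist, 1 - alpha / 2)
                if observed[(sty, st)] > hi:
                    row["flag"] = "over"
                elif observed[(sty, st)] < lo:
                    row["flag"] = "under"
                else:
                    row["flag"] = "none"
                row["null_lo"] = float(lo)
                row["null_hi"] = float(hi)
            rows.append(row)
    return pd.DataFrame(rows)


def feature_rate_correlation(
    profiles: pd.DataFrame, rates: pd.DataFrame
) -> pd.Series:
    """Pearson correlation of each profile feature with firing rate.

    ``rates`` must carry columns ``neuron``, ``state`` and ``rate_hz``
    (state-averaged firing rate).  A constant rate yields NaN with a
    warning.
    """
    merged = profiles.merge(rates, on=["neuron", "state"], how="inner")
    if merged.empty:
        raise AlignmentError("rates do not align with profiles")
    r = merged["rate_hz"].to_numpy(dtype=float)
    out = {}
    if np.std(r) == 0:
        warnings.warn("firing rate is constant; correlations undefined",
                      AnalysisWarning, stacklevel=2)
        return pd.Series({f: np.nan for f in PROFILE_FEATURES}, name="pearson_r")
    for f in PROFILE_FEATURES:
        x = merged[f].to_numpy(dtype=float)
        if np.std(x) == 0:
            out[f] = np.nan
        else:
            out[f] = float(np.corrcoef(x, r)[0, 1])
    return pd.Series(out, name="pearson_r")


def storage_by_style(
    storage: np.ndarray,
    profiles: pd.DataFrame,
    states: StateSequence,
    node_ids,
) -> pd.DataFrame:
    """State-averaged active information storage grouped by style.

    Returns one row per non-junk (neuron, state) profile with its style and
    the neuron's mean storage over that state's frames.
    """
    storage = np.asarray(storage, dtype=float)
    if storage.shape[0] != states.n_frames:
        raise AlignmentError("storage frames must match the state sequence")
    col_of = {uid: i for i, uid in enumerate(node_ids)}
    frame_sets = states.frame_sets()
    rows = []
    for r in profiles.itertuples(index=False):
        if getattr(r, "style", None) == JUNK:
            continue
        idx = frame_sets.get(int(r.state))
        if idx is None or idx.size == 0:
            continue
        rows.append(
            {
                "neuron": r.neuron,
                "state": int(r.state),
                "style": getattr(r, "style", None),
                "mean_storage": float(storage[idx, col_of[r.neuron]].mean()),
            }
        )
    return pd.DataFrame(rows)
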