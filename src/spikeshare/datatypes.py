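"""Data containers for the temporal-network pipeline.

The pipeline maps a multi-unit spike recording to a time-ordered sequence of
N x N information-sharing matrices (a :class:`TemporalNetwork`), per-node
feature series, and discrete state label sequences.  These containers are
deliberately thin: heavy computation lives in the analysis modules, and the
containers only validate their own invariants.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    AnalysisWarning,
    InvalidConfigError,
    ValidationError,
)

UNIT_COLUMNS = ("region", "layer", "cell_type")


@dataclass
class SpikeData:
    """Spike times per unit plus unit metadata.

    Parameters
    ----------
    spike_times
        Mapping from unit id to a sorted array of spike times in seconds,
        recording-relative.
    units
        DataFrame indexed by unit id with columns ``region`` (e.g. HPC/mEC),
        ``layer`` and ``cell_type`` (excitatory / inhibitory /
        "unclassified").
    duration
        Recording length in seconds.  Defaults to the last spike time.
    """

    spike_times: dict
    units: pd.DataFrame
    duration: float | None = None

    def __post_init__(self):
        for col in UNIT_COLUMNS:
            if col not in self.units.columns:
                raise ValidationError(f"units table missing column {col!r}")
        if self.units.index.duplicated().any():
            dupes = self.units.index[self.units.index.duplicated()].tolist()
            raise ValidationError(f"duplicate unit rows: {dupes}")
        known = set(self.units.index)
        missing = sorted(set(self.spike_times) - known)
        if missing:
            raise ValidationError(f"spikes reference missing units: {missing}")
        cleaned = {}
        max_t = 0.0
        for uid in self.units.index:
            t = np.asarray(self.spike_times.get(uid, ()), dtype=float)
            if t.size and t.min() < 0:
                bad = t[t < 0]
                raise ValidationError(
                    f"unit {uid!r} has negative spike times: {bad[:5]}"
                )
            t = np.sort(t)
            cleaned[uid] = t
            if t.size:
                max_t = max(max_t, float(t[-1]))
        self.spike_times = cleaned
        if self.duration is None:
            self.duration = max_t
        elif self.duration < max_t - 1e-9:
            raise ValidationError(
                f"duration {self.duration} s shorter than last spike {max_t} s"
            )
        self.duration = float(self.duration)

    @property
    def unit_ids(self) -> list:
        return list(self.units.index)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def rates(self) -> pd.Series:
        """Mean firing rate per unit in Hz over the whole recording."""
        if self.duration <= 0:
            raise ValidationError("recording duration must be positive")
        return pd.Series(
            {u: len(self.spike_times[u]) / self.duration for u in self.unit_ids},
            name="rate_hz",
        )


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window grid: 10-s windows stepped by 1 s by default.

    Consecutive windows then overlap by ``(window_length - step) /
    window_length`` (90% with the defaults).  Windows are half-open
    ``[start, start + window_length)`` and frames are indexed from 0.
    """

    window_length: float = 10.0
    step: float = 1.0
    bin_width: float = 0.025

    def __post_init__(self):
        if self.bin_width <= 0:
            raise InvalidConfigError("bin_width must be positive")
        if not (0 < self.step <= self.window_length):
            raise InvalidConfigError("need 0 < step <= window_length")
        n = self.window_length / self.bin_width
        if abs(n - round(n)) > 1e-6:
            raise InvalidConfigError(
                "window_length must be an integer number of bins"
            )

    @property
    def n_bins(self) -> int:
        """Bins per window."""
        return int(round(self.window_length / self.bin_width))

    @property
    def overlap(self) -> float:
        return (self.window_length - self.step) / self.window_length

    def n_frames(self, duration: float) -> int:
        if duration + 1e-9 < self.window_length:
            raise InvalidConfigError(
                f"duration {duration} s shorter than one window"
            )
        return int(math.floor((duration - self.window_length) / self.step + 1e-9)) + 1

    def window_starts(self, duration: float) -> np.ndarray:
        return np.arange(self.n_frames(duration)) * self.step

    def frame_times(self, duration: float) -> np.ndarray:
        """Window centers in seconds."""
        return self.window_starts(duration) + self.window_length / 2.0


@dataclass(frozen=True)
class LagSpec:
    """Lag grid for time-lagged mutual information.

    Lags run over integer bins ``0..max_lag`` with ``max_lag = floor(0.5 *
    theta_period / bin_width)``: half a theta cycle, the timescale over which
    spike timing relations are summed.
    """

    theta_period: float = 0.25
    bin_width: float = 0.025

    def __post_init__(self):
        if self.theta_period < 0 or self.bin_width <= 0:
            raise InvalidConfigError("theta_period >= 0 and bin_width > 0 required")

    @property
    def max_lag(self) -> int:
        return int(math.floor(0.5 * self.theta_period / self.bin_width + 1e-9))

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.max_lag + 1)


@dataclass(frozen=True)
class ShuffleSpec:
    """Surrogate test for link significance.

    ``mode="per-window"`` draws ``n_shuffles`` independent bin-order
    permutations of every unit inside each window and takes the requested
    percentile of the resulting pairwise lagged-MI values as the per-pair
    threshold for that window.  ``mode="pooled"`` pools shuffle samples from
    ``pooled_windows`` evenly spaced windows into one per-pair threshold for
    the whole recording (much cheaper on long recordings).
    """

    n_shuffles: int = 400
    percentile: float = 95.0
    seed: int = 0
    mode: str = "per-window"
    pooled_windows: int = 25

    def __post_init__(self):
        if not (0 < self.percentile < 100):
            raise InvalidConfigError("percentile must lie in (0, 100)")
        if self.mode not in ("per-window", "pooled"):
            raise InvalidConfigError(f"unknown shuffle mode {self.mode!r}")
        if self.n_shuffles < 1:
            raise InvalidConfigError("n_shuffles must be >= 1")
        if self.n_shuffles < 20:
            warnings.warn(
                f"n_shuffles={self.n_shuffles} resolves the "
                f"{self.percentile}th percentile poorly",
                AnalysisWarning,
                stacklevel=2,
            )


@dataclass
class TemporalNetwork:
    """Ordered sequence of N x N sharing-weight matrices on a fixed node set.

    ``weights`` has shape (T, N, N).  For the directed network,
    ``weights[t, i, j]`` is the information (bits) that unit ``i`` sends to
    unit ``j`` in frame ``t`` after threshold subtraction.  Undirected
    variants hold symmetric matrices; unweighted variants hold {0, 1}.
    """

    node_ids: list
    weights: np.ndarray
    directed: bool = True
    weighted: bool = True
    frame_times: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3 or self.weights.shape[1] != self.weights.shape[2]:
            raise ValidationError("weights must have shape (T, N, N)")
        if self.weights.shape[1] != len(self.node_ids):
            raise ValidationError("node_ids length must match weight matrices")
        if np.any(self.weights < 0):
            raise ValidationError("sharing weights must be non-negative")
        if not self.weighted:
            vals = np.unique(self.weights)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValidationError("unweighted network entries must be 0/1")

    @property
    def n_frames(self) -> int:
        return self.weights.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[1]

    def frame(self, t: int) -> np.ndarray:
        return self.weights[t]

    def strengths(self) -> np.ndarray:
        """Per-frame node strength s_i(t) = sum_j w_ij(t), shape (T, N)."""
        return self.weights.sum(axis=2)

    def replace(self, **kw) -> "TemporalNetwork":
        return dataclasses.replace(self, **kw)


@dataclass
class StateSequence:
    """Per-frame discrete state labels, 1..K, partitioning the frames."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValidationError("labels must be a non-empty 1-D array")
        if self.labels.min() < 1:
            raise ValidationError("state labels must start at 1")

    @classmethod
    def from_labels(cls, raw) -> "StateSequence":
        """Relabel an arbitrary label sequence to 1..K by first occurrence."""
        raw = np.asarray(raw)
        mapping: dict = {}
        out = np.empty(raw.shape, dtype=int)
        for i, v in enumerate(raw):
            key = v.item() if hasattr(v, "item") else v
            if key not in mapping:
                mapping[key] = len(mapping) + 1
            out[i] = mapping[key]
        return cls(out)

    @property
    def n_frames(self) -> int:
        return self.labels.size

    @property
    def n_states(self) -> int:
        return int(self.labels.max())

    def frame_sets(self) -> dict:
        """T^h: frame indices per state, in temporal order."""
        return {
            h: np.flatnonzero(self.labels == h)
            for h in range(1, self.n_states + 1)
        }

    def visits(self) -> np.ndarray:
        """Sequence of visited states (one entry per dwell epoch)."""
        keep = np.ones(self.labels.size, dtype=bool)
        keep[1:] = self.labels[1:] != self.labels[:-1]
        return self.labels[keep]


@dataclass
class NodeFeatureSeries:
    """Per-node per-frame liquidity and coreness.

    ``jaccard``/``cosine`` are the liquidity of each node between frames
    ``t - 1`` and ``t`` (row 0 is NaN: liquidity needs a predecessor frame);
    ``coreness``/``coreness_w`` are the unweighted and weighted core-periphery
    coreness.  All arrays have shape (T, N) with values in [0, 1].
    """

    node_ids: list
    jaccard: np.ndarray
    cosine: np.ndarray
    coreness: np.ndarray
    coreness_w: np.ndarray

    def __post_init__(self):
        shape = None
        for name in ("jaccard", "cosine", "coreness", "coreness_w"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise AlignmentError("feature arrays must share (T, N) shape")
        if shape[1] != len(self.node_ids):
            raise AlignmentError("node_ids length must match feature arrays")

    @property
    def n_frames(self) -> int:
        return self.jaccard.shape[0]


@dataclass
class CoreAssignment:
    """Per-frame core membership from a percentile cut on coreness."""

    member: np.ndarray  # (T, N) bool
    cutoff: np.ndarray  # per-frame cut value (constant for pooled scope)
    percentile: float
    filling_factor: pd.DataFrame | None = None  # % of each region in the core
    fractions: pd.DataFrame | None = None  # regional composition of the core
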