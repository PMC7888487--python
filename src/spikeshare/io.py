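"""Readers, writers and run configuration.

Tabular inputs and outputs are tab-separated UTF-8 with a header row and
"." decimal; temporal networks are stored as HDF5 sparse triplets (frame,
sender, receiver, weight) with a JSON sidecar of metadata, with optional
per-frame GraphML export for inspection.  Every output of the orchestrator
declares the config hash and master seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .datatypes import SpikeData, TemporalNetwork, WindowGrid
from .errors import ValidationError
from .synthetic import SimConfig

__all__ = [
    "RunConfig",
    "read_spike_data",
    "write_spike_data",
    "read_state_track",
    "write_state_track",
    "save_network_h5",
    "load_network_h5",
    "export_graphml",
]


# ---------------------------------------------------------------------------
# spike data


def write_spike_data(spikes: SpikeData, spikes_path, units_path) -> None:
    rows = [
        (uid, t)
        for uid in spikes.unit_ids
        for t in spikes.spike_times[uid]
    ]
    pd.DataFrame(rows, columns=["unit_id", "spike_time_s"]).to_csv(
        spikes_path, sep="\t", index=False
    )
    spikes.units.rename_axis("unit_id").reset_index().to_csv(
        units_path, sep="\t", index=False
    )


def read_spike_data(spikes_path, units_path, duration: float | None = None) -> SpikeData:
    """Load and validate spike and unit tables.

    Spike times are sorted on load; unknown cell types are kept verbatim
    (callers may treat anything outside excitatory/inhibitory as
    "unclassified").  Negative times, duplicate unit rows or spikes
    referencing missing units raise :class:`ValidationError`.
    """
    units = pd.read_csv(units_path, sep="\t")
    for col in ("unit_id", "region", "layer", "cell_type"):
        if col not in units.columns:
            raise ValidationError(f"units table missing column {col!r}")
    units = units.set_index("unit_id")
    units["cell_type"] = units["cell_type"].fillna("unclassified")
    table = pd.read_csv(spikes_path, sep="\t")
    for col in ("unit_id", "spike_time_s"):
        if col not in table.columns:
            raise ValidationError(f"spikes table missing column {col!r}")
    neg = table[table["spike_time_s"] < 0]
    if len(neg):
        raise ValidationError(
            f"negative spike times in rows {neg.index.tolist()[:5]}"
        )
    spike_times = {
        uid: grp["spike_time_s"].to_numpy(dtype=float)
        for uid, grp in table.groupby("unit_id")
    }
    return SpikeData(spike_times=spike_times, units=units, duration=duration)


# ---------------------------------------------------------------------------
# oscillatory state track


def write_state_track(intervals: pd.DataFrame, path) -> None:
    intervals[["start_s", "end_s", "label"]].to_csv(path, sep="\t", index=False)


def intervals_from_labels(labels, step: float = 1.0) -> pd.DataFrame:
    """Collapse a per-second label sequence into (start, end, label) rows."""
    labels = np.asarray(labels)
    edges = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [labels.size]))
    return pd.DataFrame(
        {
            "start_s": starts * step,
            "end_s": ends * step,
            "label": labels[starts],
        }
    )


def read_state_track(path, grid: WindowGrid, duration: float) -> np.ndarray:
    """Project labeled intervals onto the frame grid.

    Each frame takes the label of the interval containing its window
    center; a center exactly on a boundary belongs to the later interval
    (intervals are half-open ``[start, end)``); uncovered frames are
    labeled ``"none"``.  Overlapping intervals raise
    :class:`ValidationError`.
    """
    table = pd.read_csv(path, sep="\t")
    for col in ("start_s", "end_s", "label"):
        if col not in table.columns:
            raise ValidationError(f"state track missing column {col!r}")
    table = table.sort_values("start_s").reset_index(drop=True)
    prev_end = -np.inf
    for row in table.itertuples(index=False):
        if row.start_s < prev_end - 1e-9:
            raise ValidationError("overlapping intervals in state track")
        prev_end = row.end_s
    centers = grid.frame_times(duration)
    out = np.full(centers.size, "none", dtype=object)
    for row in table.itertuples(index=False):
        sel = (centers >= row.start_s) & (centers < row.end_s)
        out[sel] = row.label
    return out


# ---------------------------------------------------------------------------
# temporal networks


def save_network_h5(tn: TemporalNetwork, path) -> None:
    """Store a temporal network as per-frame sparse triplets plus sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        t_idx, i_idx, j_idx = np.nonzero(tn.weights)
        f.create_dataset("frame", data=t_idx.astype(np.int64))
        f.create_dataset("sender", data=i_idx.astype(np.int64))
        f.create_dataset("receiver", data=j_idx.astype(np.int64))
        f.create_dataset("weight", data=tn.weights[t_idx, i_idx, j_idx])
        f.attrs["n_frames"] = tn.n_frames
        f.attrs["n_nodes"] = tn.n_nodes
        f.attrs["directed"] = tn.directed
        f.attrs["weighted"] = tn.weighted
        if tn.frame_times is not None:
            f.create_dataset("frame_times", data=np.asarray(tn.frame_times))
    sidecar = {
        "node_ids": [str(u) for u in tn.node_ids],
        "meta": tn.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True)
    )


def load_network_h5(path) -> TemporalNetwork:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with h5py.File(path, "r") as f:
        T = int(f.attrs["n_frames"])
        N = int(f.attrs["n_nodes"])
        weights = np.zeros((T, N, N))
        weights[f["frame"][:], f["sender"][:], f["receiver"][:]] = f["weight"][:]
        frame_times = f["frame_times"][:] if "frame_times" in f else None
        return TemporalNetwork(
            node_ids=sidecar["node_ids"],
            weights=weights,
            directed=bool(f.attrs["directed"]),
            weighted=bool(f.attrs["weighted"]),
            frame_times=frame_times,
            meta=sidecar.get("meta", {}),
        )


def export_graphml(tn: TemporalNetwork, out_dir, frames=None) -> list:
    """Write one GraphML file per requested frame; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = range(tn.n_frames) if frames is None else frames
    paths = []
    for t in frames:
        G = nx.DiGraph() if tn.directed else nx.Graph()
        G.add_nodes_from(tn.node_ids)
        F = tn.frame(t)
        for i, j in zip(*np.nonzero(F)):
            if not tn.directed and j < i:
                continue
            G.add_edge(tn.node_ids[i], tn.node_ids[j], weight=float(F[i, j]))
        p = out_dir / f"frame_{t:05d}.graphml"
        nx.write_graphml(G, p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults, YAML round-trippable."""

    window_length: float = 10.0
    step: float = 1.0
    bin_width: float = 0.025
    theta_period: float = 0.25
    n_shuffles: int = 400
    percentile: float = 95.0
    threshold_mode: str = "per-window"
    pooled_windows: int = 25
    core_percentile: float = 95.0
    k_min: int = 1
    k_max: int = 8
    silhouette_floor: float = 0.1
    kmeans_n_init: int = 50
    style_k: int = 5
    knn_neighbors: int = 10
    n_permutations: int = 1000
    enrichment_alpha: float = 0.05
    n_swaps_per_edge: int = 10
    n_quality_surrogates: int = 20
    seed: int = 0
    out_dir: str = "results"
    # input: either a simulation config or paths to spike/unit/track files
    simulate: dict | None = None
    spikes_path: str | None = None
    units_path: str | None = None
    track_path: str | None = None

    def sim_config(self) -> SimConfig:
        kw = dict(self.simulate or {})
        kw.setdefault("seed", self.seed)
        kw.setdefault("bin_width", self.bin_width)
        kw.setdefault("frame_step", self.step)
        kw.setdefault("window_length", self.window_length)
        return SimConfig(**kw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]
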