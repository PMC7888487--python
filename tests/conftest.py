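import numpy as np
import pandas as pd
import pytest

from spikeshare.datatypes import SpikeData, TemporalNetwork


def make_units(n, region="HPC", layer="SP", cell_type="excitatory"):
    ids = [f"u{i:03d}" for i in range(n)]
    return pd.DataFrame(
        {"region": region, "layer": layer, "cell_type": cell_type},
        index=pd.Index(ids, name="unit_id"),
    )


@pytest.fixture
def two_unit_spikes():
    units = make_units(2)
    return SpikeData(
        spike_times={"u000": np.array([0.1, 0.5, 2.0]), "u001": np.array([1.0])},
        units=units,
        duration=10.0,
    )


def network_from_frames(frames, directed=False, weighted=True, ids=None):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    ids = ids or [f"u{i:03d}" for i in range(n)]
    return TemporalNetwork(
        node_ids=ids, weights=frames, directed=directed, weighted=weighted
    )


def random_symmetric_frames(rng, T, N, density=0.3, weighted=True):
    """Random undirected weighted frames for property tests."""
    frames = np.zeros((T, N, N))
    iu = np.triu_indices(N, k=1)
    for t in range(T):
        mask = rng.random(iu[0].size) < density
        w = rng.uniform(0.1, 2.0, iu[0].size) * mask if weighted else mask.astype(float)
        F = np.zeros((N, N))
        F[iu] = w
        frames[t] = F + F.T
    return frames
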