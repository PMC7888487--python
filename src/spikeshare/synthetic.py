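"""Synthetic spike trains with planted temporal-network structure.

The generator emulates the statistical skeleton the analysis assumes in a
multi-hour anesthesia recording: a semi-Markov schedule of discrete network
states, a two-label oscillatory track (THE / SO) correlated with the states,
and per-state cell-assembly structure in which each neuron plays one of four
planted roles:

* ``core`` -- continuously coupled to the state's latent assembly process;
* ``regular_skin`` -- coupled only during on-epochs of near-constant
  duration;
* ``bursty_skin`` -- coupled during on-epochs of strongly bimodal (short /
  long mixture) durations;
* ``periphery`` -- weakly coupled in short regular bouts.

Each network state owns a latent binary on/off Markov process (the
"assembly").  While a neuron is engaged (inside one of its on-epochs) it
fires as a Bernoulli-per-bin process at ``baseline_rate * (1 + coupling *
(assembly_rate_gain - 1))`` when the latent is on and ``baseline_rate``
when it is off; while disengaged it is suppressed toward quiescence at
``baseline_rate / (1 + quiescent_suppression * coupling *
(assembly_rate_gain - 1))``, mirroring the near-silent epochs of real
units outside their assembly.  With ``assembly_rate_gain = 1`` both
expressions collapse to the baseline, so the generator degrades gracefully
to homogeneous uncoupled Poisson units.  Spike generation is in discrete
bins (the analysis only ever sees binarized bins).  All randomness flows
from ``SimConfig.seed`` through documented child seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng, child_seed
from .datatypes import SpikeData
from .errors import DegenerateOutputWarning, InvalidConfigError

__all__ = [
    "ROLES",
    "OSC_LABELS",
    "SimConfig",
    "GroundTruth",
    "plant_state_schedule",
    "generate_spike_data",
    "expected_rate",
    "make_toy_graph",
    "generate_label_pair",
]

ROLES = ("core", "regular_skin", "bursty_skin", "periphery")
OSC_LABELS = ("THE", "SO")


def _default_role_fractions() -> dict:
    return {
        "core": 0.2,
        "regular_skin": 0.2,
        "bursty_skin": 0.2,
        "periphery": 0.4,
    }


def _default_couplings() -> dict:
    # engaged-epoch coupling strengths; ordering mirrors the expected
    # integration depth of the roles
    return {
        "core": 1.0,
        "regular_skin": 0.9,
        "bursty_skin": 0.8,
        "periphery": 0.6,
    }


@dataclass
class SimConfig:
    """Study conditions of the synthetic recording.

    Times are seconds, rates Hz.  One planted schedule frame corresponds to
    one ``frame_step`` of the downstream sliding-window grid, so a
    ``frame_count``-frame schedule yields exactly ``frame_count`` analysis
    windows on the generated recording.
    """

    n_neurons: int = 40
    n_states: int = 3
    frame_count: int = 600
    bin_width: float = 0.025
    baseline_rate: float = 1.0
    assembly_rate_gain: float = 15.0
    quiescent_suppression: float = 2.5
    dwell_mean: float = 150.0  # frames; mirrors minutes-long oscillatory epochs
    role_fractions: dict = field(default_factory=_default_role_fractions)
    osc_specificity: float = 0.9
    seed: int = 0
    # grid geometry the schedule is laid out on
    frame_step: float = 1.0
    window_length: float = 10.0
    # latent assembly process: mean dwell (s) of the on and off phases
    latent_dwell: float = 1.0
    # role-specific engagement dynamics (s)
    couplings: dict = field(default_factory=_default_couplings)
    skin_epoch: float = 20.0
    bursty_short: float = 2.0
    bursty_long: float = 60.0
    bursty_mix: float = 0.6
    periphery_on: float = 6.0
    periphery_off: float = 18.0
    coupling_jitter: float = 0.05

    def __post_init__(self):
        if self.n_neurons < 1 or self.n_states < 1:
            raise InvalidConfigError("need at least one neuron and one state")
        if self.frame_count < self.n_states:
            raise InvalidConfigError("frame_count must be >= n_states")
        if self.dwell_mean < 1:
            raise InvalidConfigError("dwell_mean must be >= 1 frame")
        if self.baseline_rate < 0 or self.assembly_rate_gain < 0:
            raise InvalidConfigError("rates and gains must be >= 0")
        if not (0 <= self.osc_specificity <= 1):
            raise InvalidConfigError("osc_specificity is a probability")
        tot = sum(self.role_fractions.values())
        if abs(tot - 1.0) > 1e-6:
            raise InvalidConfigError("role_fractions must sum to 1")
        if set(self.role_fractions) - set(ROLES):
            raise InvalidConfigError(f"unknown roles in role_fractions")

    @property
    def duration(self) -> float:
        """Recording length so the window grid yields frame_count frames."""
        return (self.frame_count - 1) * self.frame_step + self.window_length


@dataclass
class GroundTruth:
    """Planted structure of one synthetic recording.

    ``state_schedule`` / ``osc_track`` are aligned with the analysis frame
    grid (label at each window's center).  ``role_map`` and ``coupling_map``
    are (neuron x state) tables.  ``sec_schedule`` / ``sec_osc`` are the
    underlying second-resolution sequences the spikes were generated from.
    """

    state_schedule: np.ndarray
    osc_track: np.ndarray
    role_map: pd.DataFrame
    coupling_map: pd.DataFrame
    preferred_osc: dict
    sec_schedule: np.ndarray
    sec_osc: np.ndarray


def plant_state_schedule(
    n_states: int,
    frame_count: int,
    dwell_mean: float,
    osc_specificity: float,
    seed: int,
):
    """Semi-Markov state schedule plus correlated oscillatory track.

    Dwell times are geometric with mean ``dwell_mean`` frames; the first
    visits cycle through a random permutation of all states (with dwells
    capped at ``frame_count // n_states``) so every state occurs at least
    once.  Each frame's oscillatory label equals its state's preferred label
    with probability ``osc_specificity``.

    Returns ``(state_schedule, osc_track, preferred_osc)`` with states
    labeled 1..n_states and oscillatory labels from ``OSC_LABELS``.
    """
    if n_states < 1:
        raise InvalidConfigError("n_states must be >= 1")
    if frame_count < n_states:
        raise InvalidConfigError("frame_count must be >= n_states")
    if dwell_mean < 1:
        raise InvalidConfigError("dwell_mean must be >= 1")
    rng = child_rng(seed, "schedule")
    p = 1.0 / dwell_mean
    first_cycle = list(rng.permutation(n_states) + 1)
    cap = max(1, frame_count // n_states)
    schedule = np.empty(frame_count, dtype=int)
    filled = 0
    current = None
    while filled < frame_count:
        if first_cycle:
            state = first_cycle.pop(0)
            dwell = min(int(rng.geometric(p)), cap)
        else:
            if n_states == 1:
                state = 1
            else:
                others = [s for s in range(1, n_states + 1) if s != current]
                state = int(rng.choice(others))
            dwell = int(rng.geometric(p))
        dwell = min(dwell, frame_count - filled)
        schedule[filled : filled + dwell] = state
        filled += dwell
        current = state
    preferred = {
        h: OSC_LABELS[(h - 1) % len(OSC_LABELS)] for h in range(1, n_states + 1)
    }
    other = {"THE": "SO", "SO": "THE"}
    keep = rng.random(frame_count) < osc_specificity
    osc = np.array(
        [
            preferred[s] if k else other[preferred[s]]
            for s, k in zip(schedule, keep)
        ],
        dtype=object,
    )
    return schedule, osc, preferred


def _assign_roles(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Role per (neuron, state): fixed role counts, rotated across states."""
    n = config.n_neurons
    counts = {}
    acc = 0
    roles_sorted = [r for r in ROLES if r in config.role_fractions]
    for r in roles_sorted[:-1]:
        counts[r] = int(round(config.role_fractions[r] * n))
        acc += counts[r]
    counts[roles_sorted[-1]] = n - acc
    role_vector = np.array(
        [r for r in roles_sorted for _ in range(counts[r])], dtype=object
    )
    perm = rng.permutation(n)
    shift = max(1, n // max(config.n_states, 1))
    data = {}
    for h in range(1, config.n_states + 1):
        rotated = np.roll(perm, (h - 1) * shift)
        roles_h = np.empty(n, dtype=object)
        roles_h[rotated] = role_vector
        data[h] = roles_h
    return pd.DataFrame(data, index=[f"u{i:03d}" for i in range(n)])


def _epoch_gating(
    n_bins: int,
    bin_width: float,
    on_sampler,
    off_sampler,
    rng: np.random.Generator,
) -> np.ndarray:
    """Alternating on/off boolean series from duration samplers (seconds)."""
    out = np.zeros(n_bins, dtype=bool)
    # random initial phase: start inside an off epoch of random residual
    pos = -int(rng.uniform(0, off_sampler()) / bin_width)
    on = False
    while pos < n_bins:
        dur = on_sampler() if on else off_sampler()
        nb = max(1, int(round(dur / bin_width)))
        if on:
            out[max(pos, 0) : pos + nb] = True
        pos += nb
        on = not on
    return out


def _latent_process(
    n_bins: int, bin_width: float, dwell: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-state Markov on/off latent with mean dwell ``dwell`` seconds."""
    out = np.zeros(n_bins, dtype=bool)
    pos = 0
    on = bool(rng.random() < 0.5)
    p = bin_width / dwell
    while pos < n_bins:
        nb = int(rng.geometric(p))
        if on:
            out[pos : pos + nb] = True
        pos += nb
        on = not on
    return out


def _gating_samplers(config: SimConfig, role: str, rng: np.random.Generator):
    """(on_sampler, off_sampler) in seconds for one neuron's role."""
    jitter = lambda base: base * rng.uniform(0.9, 1.1)  # noqa: E731
    if role == "regular_skin":
        return (lambda: jitter(config.skin_epoch)), (
            lambda: jitter(config.skin_epoch)
        )
    if role == "bursty_skin":
        # two-point mixture of short and long epochs: every bursty neuron
        # realizes a stably high Fano factor of its connection durations,
        # which a heavy-tailed unbounded sampler would not guarantee after
        # pooled min-max normalization
        def on():
            base = (
                config.bursty_short
                if rng.random() < config.bursty_mix
                else config.bursty_long
            )
            return jitter(base)

        return on, (lambda: jitter(config.skin_epoch))
    if role == "periphery":
        return (lambda: jitter(config.periphery_on)), (
            lambda: jitter(config.periphery_off)
        )
    raise InvalidConfigError(f"unknown role {role!r}")


def generate_spike_data(config: SimConfig) -> tuple[SpikeData, GroundTruth]:
    """Generate a synthetic recording and its planted ground truth."""
    seed = config.seed
    duration = config.duration
    n_sec = int(np.ceil(duration / config.frame_step))
    sec_schedule, sec_osc, preferred = plant_state_schedule(
        config.n_states,
        n_sec,
        config.dwell_mean,
        config.osc_specificity,
        child_seed(seed, "plant"),
    )
    center_offset = int(round(0.5 * config.window_length / config.frame_step))
    idx = np.arange(config.frame_count) + center_offset
    idx = np.clip(idx, 0, n_sec - 1)
    state_schedule = sec_schedule[idx]
    osc_track = sec_osc[idx]

    role_map = _assign_roles(config, child_rng(seed, "roles"))
    jit_rng = child_rng(seed, "coupling-jitter")
    coupling = pd.DataFrame(
        {
            h: [
                float(
                    np.clip(
                        config.couplings[role_map.loc[u, h]]
                        + jit_rng.uniform(-config.coupling_jitter, 0),
                        0.0,
                        1.0,
                    )
                )
                for u in role_map.index
            ]
            for h in role_map.columns
        },
        index=role_map.index,
    )

    n_bins = int(np.ceil(duration / config.bin_width))
    sec_of_bin = np.minimum(
        (np.arange(n_bins) * config.bin_width / config.frame_step).astype(int),
        n_sec - 1,
    )
    state_of_bin = sec_schedule[sec_of_bin]  # 1..K

    # latent assembly per state
    latents = {
        h: _latent_process(
            n_bins, config.bin_width, config.latent_dwell, child_rng(seed, "latent", h)
        )
        for h in range(1, config.n_states + 1)
    }
    active_latent = np.zeros(n_bins, dtype=bool)
    for h, z in latents.items():
        sel = state_of_bin == h
        active_latent[sel] = z[sel]

    gain = config.assembly_rate_gain - 1.0
    p_base = config.baseline_rate * config.bin_width
    if p_base <= 0 or (gain <= 0 and p_base <= 0):
        warnings.warn(
            "all roles have zero firing rate; output will be silent",
            DegenerateOutputWarning,
            stacklevel=2,
        )
    units = role_map.index.tolist()
    spike_times = {}
    meta_rng = child_rng(seed, "unit-meta")
    for ui, uid in enumerate(units):
        rng = child_rng(seed, "unit", ui)
        mult = np.ones(n_bins)
        for h in range(1, config.n_states + 1):
            role = role_map.loc[uid, h]
            sel = state_of_bin == h
            if role == "core":
                engaged = np.ones(n_bins, dtype=bool)
            else:
                on_s, off_s = _gating_samplers(config, role, rng)
                engaged = _epoch_gating(n_bins, config.bin_width, on_s, off_s, rng)
            c = coupling.loc[uid, h]
            boost = np.where(
                engaged,
                1.0 + c * gain * (active_latent & engaged).astype(float),
                1.0 / (1.0 + config.quiescent_suppression * c * gain),
            )
            mult = np.where(sel, boost, mult)
        p = np.clip(p_base * mult, 0.0, 1.0)
        fired = rng.random(n_bins) < p
        bins = np.flatnonzero(fired)
        times = (bins + rng.uniform(0.0, 1.0, size=bins.size)) * config.bin_width
        spike_times[uid] = np.sort(np.minimum(times, duration - 1e-9))

    half = config.n_neurons // 2
    regions = ["HPC"] * half + ["mEC"] * (config.n_neurons - half)
    layer_cycle = {"HPC": ("SP", "SR", "SLM"), "mEC": ("L2", "L3", "L5")}
    layers = [
        layer_cycle[r][i % 3] for i, r in enumerate(regions)
    ]
    cell_types = np.where(
        meta_rng.random(config.n_neurons) < 0.2, "inhibitory", "excitatory"
    )
    units_df = pd.DataFrame(
        {"region": regions, "layer": layers, "cell_type": cell_types},
        index=pd.Index(units, name="unit_id"),
    )
    spikes = SpikeData(spike_times=spike_times, units=units_df, duration=duration)
    truth = GroundTruth(
        state_schedule=state_schedule,
        osc_track=osc_track,
        role_map=role_map,
        coupling_map=coupling,
        preferred_osc=preferred,
        sec_schedule=sec_schedule,
        sec_osc=sec_osc,
    )
    return spikes, truth


def expected_rate(config: SimConfig, role: str, coupling: float) -> float:
    """Closed-form expected firing rate (Hz) of a neuron in one state.

    ``rate = duty * baseline * (1 + c * (gain - 1) * p_on) + (1 - duty) *
    baseline / (1 + quiescent_suppression * c * (gain - 1))`` with the
    latent on half the time and ``duty`` the role's engaged fraction (1 for
    core; on/(on+off) for the gated roles, using the untruncated lognormal
    mean for bursty skin).
    """
    duty = {
        "core": 1.0,
        "regular_skin": 0.5,
        "bursty_skin": config.skin_epoch
        / (config.skin_epoch + config.skin_epoch),
        "periphery": config.periphery_on
        / (config.periphery_on + config.periphery_off),
    }[role]
    gain = config.assembly_rate_gain - 1.0
    engaged = config.baseline_rate * (1.0 + coupling * gain * 0.5)
    quiescent = config.baseline_rate / (
        1.0 + config.quiescent_suppression * coupling * gain
    )
    return duty * engaged + (1.0 - duty) * quiescent


def make_toy_graph(kind: str, size: int) -> np.ndarray:
    """Deterministic weighted snapshot graphs used as coreness fixtures.

    Kinds
    -----
    ``star``
        Node 0 is the hub; spokes have weight 1.
    ``complete``
        All pairs connected with weight 1.
    ``clique_plus_chain``
        A weight-2 clique on the first ``size // 2 + 1`` nodes with a
        weight-0.5 chain hanging off the last clique node.
    ``two_block``
        Two complete blocks (weights 1 and 0.5) joined by a single
        weight-0.1 bridge between nodes 0 and ``size - 1``.
    ``with_isolate``
        A weight-1 complete graph on the first ``size - 1`` nodes plus one
        isolated (zero-strength) node.
    """
    if size < 3:
        raise InvalidConfigError("size must be >= 3")
    W = np.zeros((size, size))
    if kind == "star":
        W[0, 1:] = 1.0
        W[1:, 0] = 1.0
    elif kind == "complete":
        W[:] = 1.0
        np.fill_diagonal(W, 0.0)
    elif kind == "clique_plus_chain":
        k = size // 2 + 1
        W[:k, :k] = 2.0
        np.fill_diagonal(W, 0.0)
        for a in range(k - 1, size - 1):
            W[a, a + 1] = W[a + 1, a] = 0.5
    elif kind == "two_block":
        half = size // 2
        W[:half, :half] = 1.0
        W[half:, half:] = 0.5
        np.fill_diagonal(W, 0.0)
        W[0, size - 1] = W[size - 1, 0] = 0.1
    elif kind == "with_isolate":
        W[: size - 1, : size - 1] = 1.0
        np.fill_diagonal(W, 0.0)
    else:
        raise InvalidConfigError(f"unknown toy graph kind {kind!r}")
    return W


def generate_label_pair(joint_table, length: int, seed: int = 0):
    """I.i.d. draws of a label pair from a joint probability table.

    ``joint_table`` is an (A, B) array of probabilities over label pairs;
    returns two integer sequences of the given length whose empirical joint
    converges to the table.
    """
    J = np.asarray(joint_table, dtype=float)
    if J.ndim != 2 or np.any(J < 0) or abs(J.sum() - 1.0) > 1e-9:
        raise InvalidConfigError(
            "joint_table must be a non-negative matrix summing to 1"
        )
    rng = child_rng(seed, "label-pair")
    flat = rng.choice(J.size, size=length, p=J.ravel())
    a, b = np.unravel_index(flat, J.shape)
    return a, b
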