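"""End-to-end orchestration: spikes -> networks -> features -> states ->
null models -> connectivity profiles -> summary.

``run_pipeline`` executes the full analysis on either a synthetic recording
(``config.simulate``) or user-supplied spike/unit/track files, writes every
intermediate product under ``config.out_dir``, and returns a machine-
readable summary.  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import features, nulls, profiles as prof, sharing, states as st
from ._rng import child_seed
from .datatypes import LagSpec, ShuffleSpec, WindowGrid
from .errors import ValidationError
from .io import (
    RunConfig,
    intervals_from_labels,
    read_spike_data,
    read_state_track,
    save_network_h5,
    write_spike_data,
    write_state_track,
)
from .synthetic import generate_spike_data

log = logging.getLogger("spikeshare.pipeline")

__all__ = ["run_pipeline"]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def _load_inputs(config: RunConfig, out: Path):
    if config.simulate is not None:
        sim = config.sim_config()
        spikes, truth = generate_spike_data(sim)
        write_spike_data(spikes, out / "spikes.tsv", out / "units.tsv")
        track = intervals_from_labels(truth.sec_osc, step=sim.frame_step)
        write_state_track(track, out / "osc_track.tsv")
        (out / "ground_truth.json").write_text(
            json.dumps(
                {
                    "state_schedule": truth.state_schedule.tolist(),
                    "osc_track": list(truth.osc_track),
                    "role_map": {
                        str(h): truth.role_map[h].tolist()
                        for h in truth.role_map.columns
                    },
                    "coupling_map": {
                        str(h): truth.coupling_map[h].round(6).tolist()
                        for h in truth.coupling_map.columns
                    },
                    "preferred_osc": {
                        str(h): v for h, v in truth.preferred_osc.items()
                    },
                },
                indent=2,
                sort_keys=True,
            )
        )
        return spikes, truth
    if not config.spikes_path or not config.units_path:
        raise ValidationError("need either simulate config or spike/unit paths")
    for p in (config.spikes_path, config.units_path, config.track_path):
        if p and not Path(p).exists():
            raise ValidationError(f"missing input file: {p}")
    return read_spike_data(config.spikes_path, config.units_path), None


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    spikes, truth = _load_inputs(config, out)
    grid = WindowGrid(config.window_length, config.step, config.bin_width)
    lags = LagSpec(config.theta_period, config.bin_width)
    spec = ShuffleSpec(
        n_shuffles=config.n_shuffles,
        percentile=config.percentile,
        seed=child_seed(config.seed, "shuffle"),
        mode=config.threshold_mode,
        pooled_windows=config.pooled_windows,
    )
    T = grid.n_frames(spikes.duration)
    log.info("building temporal network: %d units, %d frames", spikes.n_units, T)
    tn_dir = sharing.build_temporal_network(spikes, grid, lags, spec)
    tn_w, tn_u = sharing.symmetrize_and_binarize(tn_dir)
    save_network_h5(tn_dir, out / "network_directed.h5")
    retained = float((tn_dir.weights > 0).mean())
    summary["n_frames"] = T
    summary["n_units"] = spikes.n_units
    summary["retained_link_fraction"] = retained
    log.info("retained-link fraction %.4f", retained)

    feats = features.feature_series(tn_w, tn_u)
    feat_df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(T), spikes.n_units),
            "neuron": np.tile(feats.node_ids, T),
            "jaccard": feats.jaccard.ravel(),
            "cosine": feats.cosine.ravel(),
            "coreness": feats.coreness.ravel(),
            "coreness_w": feats.coreness_w.ravel(),
        }
    )
    feat_df.to_csv(out / "node_features.tsv", sep="\t", index=False)
    core = features.core_assignment(
        feats.coreness_w,
        percentile=config.core_percentile,
        regions=spikes.units["region"].to_numpy(),
    )
    summary["core_cutoff"] = float(core.cutoff[0])

    seq_w = st.cluster_network_states(
        (feats.cosine, feats.coreness_w),
        (config.k_min, config.k_max),
        seed=child_seed(config.seed, "states-w"),
        n_init=config.kmeans_n_init,
        silhouette_floor=config.silhouette_floor,
    )
    seq_u = st.cluster_network_states(
        (feats.jaccard, feats.coreness),
        (config.k_min, config.k_max),
        seed=child_seed(config.seed, "states-u"),
        n_init=config.kmeans_n_init,
        silhouette_floor=config.silhouette_floor,
    )
    seq_g = st.global_feature_states(
        tn_w,
        feats.cosine,
        feats.coreness_w,
        (config.k_min, config.k_max),
        seed=child_seed(config.seed, "states-g"),
        n_init=config.kmeans_n_init,
        silhouette_floor=config.silhouette_floor,
    )
    pd.DataFrame(
        {
            "frame": np.arange(T),
            "state_weighted": seq_w.labels,
            "state_unweighted": seq_u.labels,
            "state_global": seq_g.labels,
        }
    ).to_csv(out / "network_states.tsv", sep="\t", index=False)
    summary["k_weighted"] = seq_w.n_states
    summary["k_unweighted"] = seq_u.n_states
    summary["k_global"] = seq_g.n_states
    summary["rmi_weighted_vs_unweighted"] = st.relative_mutual_information(
        seq_w.labels, seq_u.labels
    )
    summary["rmi_weighted_vs_global"] = st.relative_mutual_information(
        seq_w.labels, seq_g.labels
    )

    osc = None
    if truth is not None:
        osc = truth.osc_track
    elif config.track_path:
        osc = read_state_track(config.track_path, grid, spikes.duration)
    if osc is not None:
        summary["rmi_weighted_vs_osc"] = st.relative_mutual_information(
            seq_w.labels, osc
        )
        spec_df = st.oscillation_specificity(seq_w, osc)
        spec_df.to_csv(out / "oscillation_specificity.tsv", sep="\t")
    if truth is not None:
        summary["rmi_weighted_vs_planted"] = st.relative_mutual_information(
            seq_w.labels, truth.state_schedule
        )
        summary["rmi_unweighted_vs_planted"] = st.relative_mutual_information(
            seq_u.labels, truth.state_schedule
        )

    quality, pct = st.clustering_quality_vs_chance(
        (feats.cosine, feats.coreness_w),
        seq_w,
        n_surrogates=config.n_quality_surrogates,
        seed=child_seed(config.seed, "quality"),
        k_range=(config.k_min, config.k_max),
    )
    summary["clustering_quality"] = quality
    summary["clustering_quality_percentile"] = pct

    # null models and their high-coreness content
    high_core_orig = int((feats.coreness_w > 0.5).sum())
    summary["high_coreness_count"] = high_core_orig
    null_summary = {}
    null_nets = {
        "erdos_renyi": nulls.er_randomize(tn_w, seed=child_seed(config.seed, "er")),
        "degree_preserving": nulls.degree_preserving_randomize(
            tn_u, config.n_swaps_per_edge, seed=child_seed(config.seed, "ms")
        ),
        "weight_shuffle": nulls.weight_shuffle_randomize(
            tn_w, seed=child_seed(config.seed, "ws")
        ),
    }
    for name, tn_null in null_nets.items():
        save_network_h5(tn_null, out / f"network_null_{name}.h5")
        c_null = features.coreness_series(tn_null)
        null_summary[name] = {
            "high_coreness_count": int((c_null > 0.5).sum()),
        }
    summary["null_models"] = null_summary

    # asymmetry and storage
    asym = sharing.asymmetry_coefficients(tn_dir, seq_w)
    asym.to_csv(out / "asymmetry.tsv", sep="\t", index=False)
    summary["mean_abs_delta_s"] = float(asym["delta_s"].abs().mean())
    storage = sharing.active_information_storage(spikes, grid, lags)

    # connectivity profiles and styles
    profile_df = prof.compute_profiles(tn_w, feats, seq_w)
    profile_df = prof.normalize_profiles(profile_df)
    profile_df = prof.cluster_styles(
        profile_df, k=config.style_k, seed=child_seed(config.seed, "styles")
    )
    n_profiles = len(profile_df)
    junk_frac = float((profile_df["style"] == "junk").mean())
    summary["n_profiles"] = n_profiles
    summary["junk_fraction"] = junk_frac
    soft = prof.soft_classify(
        profile_df, k_neighbors=min(config.knn_neighbors, max(1, n_profiles - 2))
    )
    soft.to_csv(out / "connectivity_profiles.tsv", sep="\t", index=False)
    eta = prof.eta_indices(profile_df, seq_w)
    eta.rename_axis("neuron").reset_index().to_csv(
        out / "eta.tsv", sep="\t", index=False
    )
    summary["median_eta"] = float(eta.median())
    trans = prof.style_transition_matrix(profile_df, seq_w)
    (out / "style_transitions.json").write_text(
        json.dumps(
            {k: v.fillna(-1).to_dict() for k, v in trans.items()},
            indent=2,
            sort_keys=True,
        )
    )

    prof_meta = profile_df.merge(
        spikes.units.rename_axis("neuron").reset_index()[
            ["neuron", "layer", "cell_type"]
        ],
        on="neuron",
        how="left",
    )
    enrich = prof.style_enrichment(
        prof_meta,
        "layer",
        n_permutations=config.n_permutations,
        alpha=config.enrichment_alpha,
        seed=child_seed(config.seed, "enrich"),
    )
    enrich.to_csv(out / "style_enrichment_layer.tsv", sep="\t", index=False)

    # firing-rate correlations and storage by style
    state_rates = []
    frame_sets = seq_w.frame_sets()
    counts = {
        uid: np.array(
            [
                np.searchsorted(spikes.spike_times[uid], (t + 1) * config.step)
                - np.searchsorted(spikes.spike_times[uid], t * config.step)
                for t in range(T)
            ]
        )
        for uid in spikes.unit_ids
    }
    for h, idx in frame_sets.items():
        for uid in spikes.unit_ids:
            state_rates.append(
                {
                    "neuron": uid,
                    "state": h,
                    "rate_hz": float(counts[uid][idx].mean() / config.step),
                }
            )
    rates_df = pd.DataFrame(state_rates)
    corr = prof.feature_rate_correlation(profile_df, rates_df)
    summary["feature_rate_correlation"] = {
        k: (None if pd.isna(v) else float(v)) for k, v in corr.items()
    }
    sbs = prof.storage_by_style(storage, profile_df, seq_w, feats.node_ids)
    sbs.to_csv(out / "storage_by_style.tsv", sep="\t", index=False)
    summary["median_storage_by_style"] = {
        k: float(v)
        for k, v in sbs.groupby("style")["mean_storage"].median().items()
    }

    summary_path = out / "summary.json"
    summary_path.write_text(
        json.dumps(_round_floats(summary), indent=2, sort_keys=True) + "\n"
    )
    log.info("pipeline complete; summary at %s", summary_path)
    return summary
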