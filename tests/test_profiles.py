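"""Connectivity profiles, styles, soft labels, eta, transitions, enrichment."""

import numpy as np
import pandas as pd
import pytest

from spikeshare import (
    NodeFeatureSeries,
    StateSequence,
    cluster_styles,
    compute_profiles,
    eta_index,
    eta_indices,
    normalize_profiles,
    soft_classify,
    style_transition_matrix,
)
from spikeshare.errors import AnalysisWarning, InvalidConfigError
from spikeshare.profiles import (
    CLUSTER_FEATURES,
    STYLES,
    connection_runs,
    feature_rate_correlation,
    storage_by_style,
    style_enrichment,
)

from conftest import network_from_frames


# ---------------------------------------------------------------------------
# archetype fixture: profiles planted at the four style signatures plus junk

ARCHETYPES = {
    # coreness liquidity strength n_act_rate tau_frac fano
    "core": [0.9, 0.9, 0.9, 0.02, 1.0, 0.02],
    "periphery": [0.1, 0.3, 0.1, 0.8, 0.6, 0.05],
    "bursty_core_skin": [0.5, 0.7, 0.5, 0.3, 0.7, 0.9],
    "regular_core_skin": [0.5, 0.7, 0.5, 0.3, 0.7, 0.05],
    "junk": [0.02, 0.02, 0.02, 0.05, 0.03, 0.0],
}


def archetype_profiles(rng, n_per=20, noise=0.04):
    rows = []
    for name, center in ARCHETYPES.items():
        for i in range(n_per):
            vals = np.clip(center + rng.normal(0, noise, 6), 0, 1.2)
            rows.append(
                dict(
                    neuron=f"{name}_{i}",
                    state=1,
                    planted=name,
                    **dict(zip(CLUSTER_FEATURES, vals)),
                )
            )
    df = pd.DataFrame(rows)
    return normalize_profiles(df, feature_cols=CLUSTER_FEATURES)


class TestConnectionRuns:
    def test_worked_example(self):
        n_act, tau, dur = connection_runs([0, 2, 3, 0, 0, 1, 0])
        assert n_act == 2 and tau == 3
        assert list(dur) == [2, 1]
        # population variance over mean: var{2,1}/mean{2,1} = 0.25/1.5
        assert dur.var() / dur.mean() == pytest.approx(1 / 6)

    def test_connected_at_state_start_counts_one_activation(self):
        n_act, tau, dur = connection_runs([1, 1, 0, 1])
        assert n_act == 2 and tau == 3 and list(dur) == [2, 1]

    def test_never_connected(self):
        n_act, tau, dur = connection_runs([0, 0, 0])
        assert n_act == 0 and tau == 0 and dur.size == 0


class TestComputeProfiles:
    def _setup(self):
        T, N = 7, 3
        frames = np.zeros((T, N, N))
        # neuron 0 strength series within state 1: [0,2,3,0,0,1,0]
        for t, w in enumerate([0, 2, 3, 0, 0, 1, 0]):
            frames[t, 0, 1] = frames[t, 1, 0] = w / 2
            frames[t, 0, 2] = frames[t, 2, 0] = w / 2
        tn = network_from_frames(frames)
        feats = NodeFeatureSeries(
            node_ids=tn.node_ids,
            jaccard=np.zeros((T, N)),
            cosine=np.full((T, N), 0.5),
            coreness=np.zeros((T, N)),
            coreness_w=np.full((T, N), 0.25),
        )
        return tn, feats

    def test_worked_example_features(self):
        tn, feats = self._setup()
        states = StateSequence(np.ones(7, dtype=int))
        df = compute_profiles(tn, feats, states).set_index("neuron")
        row = df.loc["u000"]
        assert row["n_act"] == 2
        assert row["tau"] == 3
        assert row["fano"] == pytest.approx(1 / 6)
        assert row["tau_frac"] == pytest.approx(3 / 7)

    def test_constant_durations_have_zero_fano(self):
        n_act, tau, dur = connection_runs([1, 1, 0, 1, 1, 0, 1, 1])
        assert dur.var() / dur.mean() == 0.0

    def test_never_connected_neuron_is_all_zero(self):
        tn, feats = self._setup()
        feats.coreness_w[:] = 0.0
        feats.cosine[:] = 0.0
        states = StateSequence(np.ones(7, dtype=int))
        df = compute_profiles(tn, feats, states).set_index("neuron")
        # make neuron 2 isolated by zeroing its links
        # (here u001/u002 share neuron 0's links, so test a silent series)
        n_act, tau, dur = connection_runs(np.zeros(7))
        assert n_act == 0 and tau == 0
        assert df.loc["u000", "coreness"] == 0.0


class TestNormalize:
    def test_min_max_arithmetic(self):
        df = pd.DataFrame(
            {
                "neuron": list("abc"),
                "state": 1,
                "coreness": [1.0, 3.0, 5.0],
                "liquidity": [0.0, 0.5, 1.0],
                "strength": [2.0, 2.0, 2.0],
                "n_act": [0, 1, 2],
                "tau": [1, 2, 3],
                "fano": [0.0, 0.0, 1.0],
            }
        )
        with pytest.warns(AnalysisWarning):
            out = normalize_profiles(df, feature_cols=("coreness", "strength"))
        assert list(out["coreness_norm"]) == [0.0, 0.5, 1.0]
        assert list(out["strength_norm"]) == [0.0, 0.0, 0.0]

    def test_full_range_feature_unchanged(self):
        df = pd.DataFrame(
            {"neuron": list("ab"), "state": 1, "coreness": [0.0, 1.0]}
        )
        out = normalize_profiles(df, feature_cols=("coreness",))
        assert list(out["coreness_norm"]) == [0.0, 1.0]


class TestClusterStyles:
    def test_archetype_recovery(self):
        rng = np.random.default_rng(0)
        df = archetype_profiles(rng)
        out = cluster_styles(df, seed=0)
        agreement = (out["style"] == out["planted"]).mean()
        assert agreement >= 0.9

    def test_all_zero_profiles_dominated_by_junk(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(40):
            vals = np.abs(rng.normal(0, 0.01, 6))
            rows.append(
                dict(neuron=f"n{i}", state=1, **dict(zip(CLUSTER_FEATURES, vals)))
            )
        # a couple of structured profiles so clustering has contrast
        for i, name in enumerate(("core", "periphery", "bursty_core_skin")):
            for r in range(3):
                vals = np.clip(
                    ARCHETYPES[name] + rng.normal(0, 0.02, 6), 0, 1.2
                )
                rows.append(
                    dict(
                        neuron=f"x{i}_{r}",
                        state=1,
                        **dict(zip(CLUSTER_FEATURES, vals)),
                    )
                )
        df = normalize_profiles(pd.DataFrame(rows), feature_cols=CLUSTER_FEATURES)
        out = cluster_styles(df, seed=1)
        junk = out[out["style"] == "junk"]
        assert len(junk) >= 35
        assert all(n.startswith("n") for n in junk["neuron"])

    def test_seed_contract(self):
        rng = np.random.default_rng(2)
        df = archetype_profiles(rng, noise=0.08)
        a = cluster_styles(df, seed=3)["style"]
        b = cluster_styles(df, seed=3)["style"]
        assert a.equals(b)


class TestSoftClassify:
    def test_archetype_probability_near_one_and_sums(self):
        rng = np.random.default_rng(3)
        df = cluster_styles(archetype_profiles(rng), seed=0)
        soft = soft_classify(df, k_neighbors=8)
        probs = soft[[f"p_{s}" for s in STYLES]].to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0)
        deep = soft[soft["planted"] == "core"]
        assert deep["p_core"].mean() > 0.95

    def test_profile_between_two_clouds_splits(self):
        rng = np.random.default_rng(4)
        df = archetype_profiles(rng, n_per=15)
        df = cluster_styles(df, seed=0)
        # plant an extra profile exactly between the two core-skin styles
        mid = (
            np.array(ARCHETYPES["bursty_core_skin"])
            + np.array(ARCHETYPES["regular_core_skin"])
        ) / 2
        row = dict(neuron="mid", state=1, planted="mid",
                   **dict(zip(CLUSTER_FEATURES, mid)))
        for c in CLUSTER_FEATURES:
            row[c + "_norm"] = row[c]
        row["style"] = "bursty_core_skin"
        df = pd.concat([df, pd.DataFrame([row])], ignore_index=True)
        soft = soft_classify(df, k_neighbors=10)
        m = soft[soft["neuron"] == "mid"].iloc[0]
        assert 0.2 <= m["p_bursty_core_skin"] <= 0.8
        assert 0.2 <= m["p_regular_core_skin"] <= 0.8
        assert m["p_core_skin"] == pytest.approx(
            m["p_bursty_core_skin"] + m["p_regular_core_skin"]
        )

    def test_too_many_neighbors_rejected(self):
        rng = np.random.default_rng(5)
        df = cluster_styles(archetype_profiles(rng, n_per=3), seed=0)
        with pytest.raises(InvalidConfigError):
            soft_classify(df, k_neighbors=100)


class TestEtaIndex:
    def test_constant_style_gives_zero(self):
        assert eta_index(["core"] * 5, n_styles=4, n_states=5) == 0.0

    def test_alternation_over_four_states(self):
        seq = ["core", "skin", "core", "skin"]
        assert eta_index(seq, n_styles=4, n_states=4) == pytest.approx(0.75)

    def test_two_changes_over_five_states(self):
        seq = ["a", "a", "b", "b", "c"]
        assert eta_index(seq, n_styles=4, n_states=5) == pytest.approx(0.4)

    def test_single_state_recording_gives_zero(self):
        assert eta_index(["core"], n_styles=4, n_states=1) == 0.0

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(1, 8))
            seq = rng.choice(["a", "b", "c", "d"], n)
            eta = eta_index(seq, 4, n)
            assert 0.0 <= eta <= 1.0
            if len(set(seq)) == 1:
                assert eta == 0.0

    def test_eta_indices_follow_visit_sequence(self):
        profiles = pd.DataFrame(
            {
                "neuron": ["a"] * 3 + ["b"] * 3,
                "state": [1, 2, 3] * 2,
                "style": ["core", "periphery", "core", "core", "core", "core"],
            }
        )
        states = StateSequence(np.array([1] * 4 + [2] * 4 + [1] * 4 + [3] * 4))
        eta = eta_indices(profiles, states)
        # visits 1,2,1,3 -> a: core,periphery,core,core = 2 changes / max(4,3)
        assert eta["a"] == pytest.approx(2 / 4)
        assert eta["b"] == 0.0


class TestTransitions:
    def _profiles(self, styles_by_state):
        rows = []
        for neuron, styles in styles_by_state.items():
            for h, s in enumerate(styles, start=1):
                rows.append({"neuron": neuron, "state": h, "style": s})
        return pd.DataFrame(rows)

    def test_style_keepers_give_identity_rates(self):
        profiles = self._profiles(
            {"a": ["core", "core", "core"], "b": ["periphery"] * 3}
        )
        states = StateSequence(np.array([1, 1, 2, 2, 3, 3]))
        out = style_transition_matrix(profiles, states)
        rates = out["rates5"]
        assert rates.loc["core", "core"] == 1.0
        assert rates.loc["periphery", "periphery"] == 1.0

    def test_deterministic_alternation_has_unit_off_diagonal(self):
        profiles = self._profiles({"a": ["core", "regular_core_skin"]})
        states = StateSequence(np.array([1, 2, 1, 2]))
        out = style_transition_matrix(profiles, states)
        assert out["rates5"].loc["core", "regular_core_skin"] == 1.0
        assert out["rates5"].loc["regular_core_skin", "core"] == 1.0
        # merged 3-class view
        assert out["rates3"].loc["core", "core_skin"] == 1.0

    def test_observed_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        styles = list(STYLES) + ["junk"]
        profiles = self._profiles(
            {f"n{i}": rng.choice(styles, 4) for i in range(12)}
        )
        states = StateSequence(np.tile([1, 2, 3, 4], 5))
        out = style_transition_matrix(profiles, states)
        for key in ("rates5", "rates3"):
            sums = out[key].sum(axis=1)
            observed = sums[~out[key].isna().all(axis=1)]
            assert np.allclose(observed, 1.0)


class TestEnrichment:
    def _df(self, styles, strata):
        return pd.DataFrame(
            {
                "neuron": [f"n{i}" for i in range(len(styles))],
                "state": 1,
                "style": styles,
                "layer": strata,
            }
        )

    def test_planted_concentration_flagged_over(self):
        styles = ["core"] * 10 + ["periphery"] * 30
        strata = ["L2"] * 10 + ["L3"] * 30  # all core in L2
        df = self._df(styles, strata)
        out = style_enrichment(df, "layer", n_permutations=300, seed=0)
        flag = out.set_index(["style", "stratum"]).loc[("core", "L2"), "flag"]
        assert flag == "over"

    def test_independent_assignment_flag_rate_near_alpha(self):
        rng = np.random.default_rng(8)
        flags = 0
        cells = 0
        for rep in range(6):
            styles = rng.choice(list(STYLES), 60)
            strata = rng.choice(["L2", "L3", "L5"], 60)
            out = style_enrichment(
                self._df(styles, strata),
                "layer",
                n_permutations=200,
                alpha=0.05,
                seed=rep,
            )
            testable = out[out["flag"] != "untestable"]
            flags += (testable["flag"] != "none").sum()
            cells += len(testable)
        assert flags / cells <= 0.15

    def test_tiny_stratum_untestable(self):
        styles = ["core"] * 10
        strata = ["L2"] * 8 + ["L9"] * 2
        out = style_enrichment(self._df(styles, strata), "layer",
                               n_permutations=50, seed=0)
        assert (
            out[out["stratum"] == "L9"]["flag"].eq("untestable").all()
        )

    def test_zero_permutations_counts_only(self):
        styles = ["core"] * 5 + ["periphery"] * 5
        strata = ["L2"] * 5 + ["L3"] * 5
        out = style_enrichment(self._df(styles, strata), "layer",
                               n_permutations=0, seed=0)
        assert "flag" not in out.columns or out["flag"].isna().all()
        assert out["observed"].sum() == 10


class TestRateCorrelationAndStorage:
    def _profiles(self, n, feature_values):
        return pd.DataFrame(
            {
                "neuron": [f"n{i}" for i in range(n)],
                "state": 1,
                "coreness": feature_values,
                "liquidity": 0.5,
                "strength": feature_values,
                "n_act": 1,
                "tau": 5,
                "fano": 0.0,
            }
        )

    def test_exact_linear_and_antilinear(self):
        rates = pd.DataFrame(
            {"neuron": [f"n{i}" for i in range(10)], "state": 1,
             "rate_hz": np.arange(10, dtype=float)}
        )
        df = self._profiles(10, 2.0 * np.arange(10))
        corr = feature_rate_correlation(df, rates)
        assert corr["coreness"] == pytest.approx(1.0)
        df2 = self._profiles(10, -2.0 * np.arange(10))
        assert feature_rate_correlation(df2, rates)["strength"] == pytest.approx(-1.0)

    def test_independent_feature_nearly_uncorrelated(self):
        rng = np.random.default_rng(9)
        n = 1000
        rates = pd.DataFrame(
            {"neuron": [f"n{i}" for i in range(n)], "state": 1,
             "rate_hz": rng.uniform(0.5, 5.0, n)}
        )
        df = self._profiles(n, rng.uniform(0, 1, n))
        assert abs(feature_rate_correlation(df, rates)["coreness"]) < 0.1

    def test_constant_rate_emits_missing(self):
        rates = pd.DataFrame(
            {"neuron": [f"n{i}" for i in range(5)], "state": 1, "rate_hz": 1.0}
        )
        df = self._profiles(5, np.arange(5.0))
        with pytest.warns(AnalysisWarning):
            corr = feature_rate_correlation(df, rates)
        assert corr.isna().all()

    def test_storage_groups_partition_non_junk_profiles(self):
        rng = np.random.default_rng(10)
        T, N = 12, 6
        node_ids = [f"n{i}" for i in range(N)]
        storage = rng.uniform(0, 1, (T, N))
        states = StateSequence(np.array([1] * 6 + [2] * 6))
        profiles = pd.DataFrame(
            {
                "neuron": node_ids * 2,
                "state": [1] * N + [2] * N,
                "style": (["core", "junk", "periphery"] * 4),
            }
        )
        out = storage_by_style(storage, profiles, states, node_ids)
        assert len(out) == (profiles["style"] != "junk").sum()
        row = out.iloc[0]
        idx = states.frame_sets()[row["state"]]
        col = node_ids.index(row["neuron"])
        assert row["mean_storage"] == pytest.approx(storage[idx, col].mean())
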