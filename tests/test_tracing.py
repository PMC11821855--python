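"""Layer tracing: threshold rules, exclusions, overlap, and strength stats."""

import numpy as np
import pandas as pd
import pytest

import taste_connectome as tc
from taste_connectome import tracing

from conftest import brute_force_layers, make_graph


def test_two_grn_example(two_grn_graph):
    g, seeds = two_grn_graph
    lm = tc.trace_second_order(g, seeds, "sugar")
    assert lm.second_order_ids == {10, 11, 12}
    # fan-in and total synapses recorded per 2N
    assert lm.hop1_strength.loc[10].tolist() == [2, 13]
    assert lm.hop1_strength.loc[11].tolist() == [1, 5]
    # 4-synapse connection excluded
    assert 13 not in lm.second_order_ids


def test_threshold_below_one_rejected(two_grn_graph):
    g, seeds = two_grn_graph
    with pytest.raises(ValueError):
        tc.trace_second_order(g, seeds, "sugar", threshold=0)


def test_planted_recovery_matches_bruteforce(default_synth):
    graph, seeds, truth = default_synth
    maps = tc.trace_all(graph, seeds)
    oracle = brute_force_layers(graph, seeds)
    for m, lm in maps.items():
        assert lm.second_order_ids == oracle[m]["2n"] == set(truth.layers[m]["2n"])
        assert lm.third_order_ids == oracle[m]["3n"] == set(truth.layers[m]["3n"])


def test_networkx_oracle_agrees_on_small_graph(small_synth):
    """Cross-check the dict-based oracle route with an igraph-free
    networkx traversal on the small fixture."""
    import networkx as nx

    graph, seeds, _ = small_synth
    G = nx.DiGraph()
    for pre, post, _np_, _nt, syn in graph.edges.itertuples(index=False, name=None):
        w = G.get_edge_data(pre, post, {}).get("syn", 0)
        G.add_edge(pre, post, syn=w + syn)
    all_grn = set().union(*(s.grn_ids for s in seeds.values()))
    maps = tc.trace_all(graph, seeds)
    for m, lm in maps.items():
        grns = seeds[m].grn_ids
        n2 = {
            v
            for g in grns
            for v in G.successors(g)
            if G[g][v]["syn"] >= 5 and v not in all_grn
        }
        assert n2 == lm.second_order_ids


def test_hop1_gate_blocks_weak_2ns():
    """A 2N with only 9 total GRN synapses qualifies as 2N but its targets
    never become 3Ns through it."""
    neurons = [{"neuron_id": 1, "class_label": "gustatory"}] + [
        {"neuron_id": i} for i in (2, 3)
    ]
    edges = [(1, 2, "GNG", "ACH", 9), (2, 3, "GNG", "ACH", 50)]
    g = make_graph(neurons, edges)
    seeds = tc.seed_sets_from_ids({"sugar": [1]})
    lm2 = tc.trace_second_order(g, seeds, "sugar")
    assert lm2.second_order_ids == {2}
    lm3 = tc.trace_third_order(g, seeds, lm2)
    assert lm3.third_order_ids == frozenset()


def test_monotonicity_raising_thresholds_never_adds_members(default_synth):
    graph, seeds, _ = default_synth
    base = tc.trace_all(graph, seeds, threshold_2n=5, hop2_threshold=10)
    strict = tc.trace_all(graph, seeds, threshold_2n=8, hop2_threshold=15)
    for m in seeds:
        assert strict[m].second_order_ids <= base[m].second_order_ids
        assert strict[m].third_order_ids <= base[m].third_order_ids


def test_exclusion_invariants_enforced(default_synth):
    graph, seeds, _ = default_synth
    maps = tc.trace_all(graph, seeds)
    grns = set().union(*(s.grn_ids for s in seeds.values()))
    for lm in maps.values():
        assert not (lm.second_order_ids & grns)
        assert not (lm.third_order_ids & grns)
        assert not (lm.third_order_ids & lm.second_order_ids)


def test_per_neuropil_mode_is_stricter():
    neurons = [{"neuron_id": 1, "class_label": "gustatory"}, {"neuron_id": 2}]
    edges = [(1, 2, "GNG", "ACH", 3), (1, 2, "SLP_L", "ACH", 4)]
    g = make_graph(neurons, edges)
    seeds = tc.seed_sets_from_ids({"sugar": [1]})
    pair_total = tc.trace_second_order(g, seeds, "sugar", per_neuropil=False)
    per_np = tc.trace_second_order(g, seeds, "sugar", per_neuropil=True)
    assert pair_total.second_order_ids == {2}  # 3 + 4 = 7 >= 5
    assert per_np.second_order_ids == frozenset()  # no single neuropil >= 5


class TestOverlap:
    def test_planted_counts_equal_ground_truth(self, small_synth):
        graph, seeds, truth = small_synth
        maps = tc.trace_all(graph, seeds)
        ov2 = tc.modality_overlap(maps, "2N")
        assert ov2.count("sugar", "water") == truth.overlap_2n["sugar|water"]
        ov3 = tc.modality_overlap(maps, "3N")
        assert ov3.count("bitter", "ir94e") == truth.overlap_3n["bitter|ir94e"]

    def test_disjoint_sets_give_zero(self):
        maps = {
            "sugar": tracing.LayerMap("sugar", frozenset(), frozenset({1, 2})),
            "water": tracing.LayerMap("water", frozenset(), frozenset({3, 4})),
        }
        ov = tc.modality_overlap(maps, "2N")
        assert ov.count("sugar", "water") == 0
        assert not ov.multimodal_ids

    def test_inclusion_exclusion_consistency(self, default_synth):
        graph, seeds, _ = default_synth
        maps = tc.trace_all(graph, seeds)
        ov = tc.modality_overlap(maps, "3N")
        # |A u B| = |A| + |B| - |A n B| checked against the membership matrix
        for a in ("sugar", "bitter"):
            for b in ("water", "ir94e"):
                union = int((ov.membership[a] | ov.membership[b]).sum())
                assert union == ov.sizes[a] + ov.sizes[b] - ov.count(a, b)

    def test_multimodal_flag(self, small_synth):
        graph, seeds, truth = small_synth
        maps = tc.trace_all(graph, seeds)
        ov = tc.modality_overlap(maps, "2N")
        shared = set(truth.layers["sugar"]["2n"]) & set(truth.layers["water"]["2n"])
        assert shared <= ov.multimodal_ids


def test_grn_grn_matrix_hand_sum():
    neurons = [
        {"neuron_id": i, "class_label": "gustatory", "superclass": "sensory"}
        for i in (1, 2, 3)
    ]
    edges = [
        (1, 2, "GNG", "ACH", 4),  # sugar -> sugar
        (1, 3, "GNG", "ACH", 2),  # sugar -> water
        (3, 2, "GNG", "ACH", 7),  # water -> sugar
    ]
    g = make_graph(neurons, edges)
    seeds = tc.seed_sets_from_ids({"sugar": [1, 2], "water": [3]})
    mat, norm = tc.grn_grn_matrix(g, seeds)
    assert mat.loc["sugar", "sugar"] == 4
    assert mat.loc["sugar", "water"] == 2
    assert mat.loc["water", "sugar"] == 7
    assert mat.loc["water", "water"] == 0
    assert norm.loc["sugar", "sugar"] == 2.0  # 4 synapses / 2 sugar GRNs
    assert norm.loc["water", "sugar"] == 7.0


def test_grn_grn_zero_matrix_when_no_edges(two_grn_graph):
    g, seeds = two_grn_graph
    mat, _ = tc.grn_grn_matrix(g, seeds)
    assert (mat.values == 0).all()


def test_input_strength_distribution_additivity(two_grn_graph):
    g, seeds = two_grn_graph
    lm = tc.trace_second_order(g, seeds, "sugar")
    d = tc.input_strength_distribution(lm, hop=1)
    assert d["table"].loc[10, "total_syn"] == 13
    assert d["table"].loc[10, "n_inputs"] == 2
    assert d["median_total_syn"] == pytest.approx(12.0)  # medians of 13, 5, 12


def test_input_strength_empty_layer_warns():
    lm = tracing.LayerMap("sugar", frozenset())
    with pytest.warns(UserWarning, match="empty"):
        d = tc.input_strength_distribution(lm, hop=1)
    assert np.isnan(d["median_total_syn"])


class TestFaninRegression:
    @staticmethod
    def _layer_map(n_inputs, totals):
        lm = tracing.LayerMap("sugar", frozenset())
        lm.hop1_strength = pd.DataFrame(
            {"n_inputs": n_inputs, "total_syn": totals}, index=range(len(n_inputs))
        )
        return lm

    def test_colinear_points_closed_form(self):
        # mean strength per input = 2 * n_inputs exactly
        lm = self._layer_map([1, 2, 3], [2, 8, 18])
        fit = tc.fanin_strength_regression(lm)
        assert fit["slope"] == pytest.approx(2.0, abs=1e-12)
        assert fit["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_regressor_raises(self):
        lm = self._layer_map([2, 2, 2], [4, 6, 8])
        with pytest.raises(ValueError, match="degenerate"):
            tc.fanin_strength_regression(lm)

    def test_too_few_points_raises(self):
        lm = self._layer_map([1, 2], [2, 4])
        with pytest.raises(ValueError):
            tc.fanin_strength_regression(lm)

    def test_matches_numpy_closed_form(self, default_synth):
        graph, seeds, _ = default_synth
        lm = tc.trace_second_order(graph, seeds, "sugar")
        fit = tc.fanin_strength_regression(lm)
        x = lm.hop1_strength["n_inputs"].to_numpy(float)
        y = (lm.hop1_strength["total_syn"] / lm.hop1_strength["n_inputs"]).to_numpy(float)
        slope, intercept = np.polyfit(x, y, 1)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert fit["slope"] == pytest.approx(slope, abs=1e-10)
        assert fit["r_squared"] == pytest.approx(r2, abs=1e-10)
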