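"""Excitatory/inhibitory statistics: feedback matrices, net excitation,
convergence null, chi-squared, and sign motifs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import taste_connectome as tc
from taste_connectome import stats as cstats
from taste_connectome import tracing

from conftest import make_graph


class TestFeedbackMatrix:
    def test_single_ach_edge(self):
        g = make_graph(
            [{"neuron_id": 1, "nt_neuron": "ACH"}, {"neuron_id": 2}],
            [(1, 2, "GNG", "ACH", 6)],
        )
        fm = tc.feedback_matrix(g, {"sugar": {1}}, {"sugar": {2}})
        assert fm.excitatory.loc["sugar", "sugar"] == 6
        assert fm.inhibitory.loc["sugar", "sugar"] == 0

    def test_all_gaba_edges_leave_excitatory_zero(self):
        g = make_graph(
            [{"neuron_id": i, "nt_neuron": "GABA"} for i in (1, 2, 3)],
            [(1, 3, "GNG", "GABA", 4), (2, 3, "SLP_L", "GABA", 9)],
        )
        fm = tc.feedback_matrix(g, {"sugar": {1}, "water": {2}}, {"sugar": {3}})
        assert (fm.excitatory.values == 0).all()
        assert fm.inhibitory.loc["water", "sugar"] == 9

    def test_matches_bruteforce_triple_loop(self, small_synth):
        graph, seeds, truth = small_synth
        maps = tc.trace_all(graph, seeds)
        src = {m: lm.second_order_ids for m, lm in maps.items()}
        tgt = {m: seeds[m].grn_ids for m in seeds}
        fm = tc.feedback_matrix(graph, src, tgt)
        for a in sorted(src):
            for b in sorted(tgt):
                expected = {"excitatory": 0, "inhibitory": 0, "other": 0}
                for pre, post, _np_, nt, syn in graph.edges.itertuples(
                    index=False, name=None
                ):
                    if pre in src[a] and post in tgt[b]:
                        expected[tc.nt_sign(nt)] += syn
                assert fm.excitatory.loc[a, b] == expected["excitatory"]
                assert fm.inhibitory.loc[a, b] == expected["inhibitory"]
                assert fm.other.loc[a, b] == expected["other"]

    def test_conservation_total_equals_raw(self, small_synth):
        graph, seeds, _ = small_synth
        maps = tc.trace_all(graph, seeds)
        src = {m: lm.second_order_ids for m, lm in maps.items()}
        tgt = {m: lm.second_order_ids for m, lm in maps.items()}
        fm = tc.feedback_matrix(graph, src, tgt)  # internal audit also runs
        for a in sorted(src):
            raw = graph.pair_totals_from(src[a])
            for b in sorted(tgt):
                tot = int(raw.loc[raw["post_id"].isin(tgt[b]), "syn_count"].sum())
                assert int(fm.total.loc[a, b]) == tot


class TestNetExcitation:
    def test_symmetric_inputs_cancel(self):
        g = make_graph(
            [
                {"neuron_id": 1, "nt_neuron": "ACH"},
                {"neuron_id": 2, "nt_neuron": "GABA"},
                {"neuron_id": 3},
            ],
            [(1, 3, "GNG", "ACH", 20), (2, 3, "GNG", "GABA", 20)],
        )
        ne = tc.net_excitation(g, {1: "excitatory", 2: "inhibitory"}, 3)
        assert ne.e_syn == 20 and ne.i_syn == 20 and ne.net == 0

    def test_arithmetic(self):
        g = make_graph(
            [
                {"neuron_id": 1, "nt_neuron": "ACH"},
                {"neuron_id": 2, "nt_neuron": "GLUT"},
                {"neuron_id": 3},
            ],
            [(1, 3, "GNG", "ACH", 30), (2, 3, "GNG", "GLUT", 10)],
        )
        ne = tc.net_excitation(g, {1: "excitatory", 2: "inhibitory"}, 3)
        assert ne.net == 20

    def test_subthreshold_inputs_ignored(self):
        g = make_graph(
            [{"neuron_id": 1, "nt_neuron": "ACH"}, {"neuron_id": 3}],
            [(1, 3, "GNG", "ACH", 9)],
        )
        ne = tc.net_excitation(g, {1: "excitatory"}, 3, threshold=10)
        assert ne.e_syn == 0

    def test_table_matches_ground_truth_recomputation(self, small_synth):
        graph, seeds, truth = small_synth
        maps = tc.trace_all(graph, seeds)
        for m, lm in maps.items():
            table = tc.net_excitation_table(graph, lm, min_inputs=1)
            # recompute from planted edges + planted neuron signs
            grns = seeds[m].grn_ids
            hop1_tot = {}
            for pre, post, syn in truth.planted_edges["hop1"]:
                if pre in grns:
                    hop1_tot[post] = hop1_tot.get(post, 0) + syn
            strong = {p for p, t in hop1_tot.items() if t >= 10}
            expect = {}
            for pre, post, syn in truth.planted_edges["hop2"]:
                if pre in strong and post in lm.third_order_ids and syn >= 10:
                    sign = tc.nt_sign(truth.nt_by_neuron[pre])
                    e, i = expect.get(post, (0, 0))
                    if sign == "excitatory":
                        e += syn
                    elif sign == "inhibitory":
                        i += syn
                    expect[post] = (e, i)
            for post, (e, i) in expect.items():
                assert int(table.loc[post, "e_syn"]) == e
                assert int(table.loc[post, "i_syn"]) == i


class TestConvergenceExpected:
    def test_worked_example(self):
        assert tc.convergence_expected(0.3, 2) == pytest.approx(
            (0.09, 0.49, 0.42), abs=1e-12
        )

    def test_boundary_all_excitatory(self):
        assert tc.convergence_expected(1.0, 3) == (1.0, 0.0, 0.0)

    def test_k3_mixed_by_enumeration(self):
        # enumerate the 8 equally likely sign sequences at p = 0.5
        p = 0.5
        seqs = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
        mixed = sum(1 for s in seqs if 0 < sum(s) < 3) / 8
        got = tc.convergence_expected(p, 3)
        assert got[2] == pytest.approx(mixed) == pytest.approx(0.75)
        assert sum(got) == pytest.approx(1.0)

    @given(p=st.floats(0.0, 1.0), k=st.sampled_from([2, 3]))
    @settings(max_examples=80, derandomize=True)
    def test_proportions_sum_to_one(self, p, k):
        assert sum(tc.convergence_expected(p, k)) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            tc.convergence_expected(0.5, 4)


class TestChiSquared:
    def test_hand_computed_value(self):
        # observed (10,0,0) vs uniform expectation at n=10: sum (O-E)^2/E = 20
        chi2, _p = tc.chi_squared_gof([10, 0, 0], [1 / 3, 1 / 3, 1 / 3])
        assert chi2 == pytest.approx(20.0, abs=1e-10)

    def test_zero_statistic_when_observed_equals_expected(self):
        chi2, p = tc.chi_squared_gof([30, 50, 20], [0.3, 0.5, 0.2])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "obs,props",
        [
            ([12, 7, 31], [0.2, 0.2, 0.6]),
            ([5, 5], [0.5, 0.5]),
            ([100, 1, 9], [0.8, 0.05, 0.15]),
        ],
    )
    def test_matches_scipy_reference(self, obs, props):
        chi2, p = tc.chi_squared_gof(obs, props)
        ref = sps.chisquare(obs, np.asarray(props) * np.sum(obs))
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_expectation_category_warns(self):
        with pytest.warns(UserWarning, match="zero-expectation"):
            tc.chi_squared_gof([5, 5], [1.0, 0.0])

    def test_null_rejection_rate_near_alpha(self):
        """Simulated multinomial draws under the null reject at about the
        nominal rate (independent calibration of the goodness-of-fit test)."""
        rng = np.random.default_rng(42)
        props = np.array(tc.convergence_expected(0.3, 2))
        n, reps, alpha = 200, 500, 0.05
        rejections = 0
        for _ in range(reps):
            obs = rng.multinomial(n, props)
            _chi2, p = tc.chi_squared_gof(obs, props)
            rejections += p < alpha
        assert abs(rejections / reps - alpha) < 0.03


class TestConvergenceTest:
    def test_on_synthetic_circuit(self, default_synth):
        graph, seeds, _ = default_synth
        maps = tc.trace_all(graph, seeds)
        r = tc.convergence_test(maps["sugar"], graph, k=2)
        assert sum(r.observed.values()) == r.n
        assert sum(r.expected.values()) == pytest.approx(1.0)
        # chi-squared audit against scipy on the reported counts
        obs = [r.observed[c] for c in ("all_e", "all_i", "mixed")]
        props = np.array([r.expected[c] for c in ("all_e", "all_i", "mixed")])
        keep = props > 0
        ref = sps.chisquare(np.asarray(obs)[keep], props[keep] * r.n)
        assert r.chi2 == pytest.approx(ref.statistic, abs=1e-10)

    def test_min_n_flag(self, small_synth):
        graph, seeds, _ = small_synth
        maps = tc.trace_all(graph, seeds)
        r = tc.convergence_test(maps["ir94e"], graph, k=3, min_n=10)
        assert r.insufficient_n == (r.n < 10)


class TestCrossModality:
    @staticmethod
    def _maps_with_identical_inputs():
        # one shared pool of 2Ns feeding the same 3Ns for both modalities
        neurons = (
            [{"neuron_id": i, "class_label": "gustatory"} for i in (1, 2)]
            + [
                {"neuron_id": i, "nt_neuron": nt}
                for i, nt in [(10, "ACH"), (11, "GABA"), (12, "ACH"), (13, "GABA")]
            ]
            + [{"neuron_id": i} for i in (20, 21, 22)]
        )
        edges = [(1, i, "GNG", "ACH", 15) for i in (10, 11)] + [
            (2, i, "GNG", "ACH", 15) for i in (12, 13)
        ]
        for t, (e_syn, i_syn) in zip((20, 21, 22), [(40, 10), (15, 25), (30, 30)]):
            edges += [
                (10, t, "GNG", "ACH", e_syn),
                (11, t, "GNG", "GABA", i_syn),
                (12, t, "GNG", "ACH", e_syn),
                (13, t, "GNG", "GABA", i_syn),
            ]
        g = make_graph(neurons, edges)
        seeds = tc.seed_sets_from_ids({"sugar": [1], "water": [2]})
        return g, tc.trace_all(g, seeds)

    def test_identical_planted_inputs_give_r2_one(self):
        g, maps = self._maps_with_identical_inputs()
        out = tc.cross_modality_net_excitation(maps, g, ("sugar", "water"))
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-12)
        assert out["slope"] == pytest.approx(1.0, abs=1e-12)
        assert out["double_counting_possible"] is True

    def test_four_point_closed_form(self):
        x = np.array([-30.0, -10.0, 10.0, 40.0])
        y = np.array([-20.0, 5.0, 12.0, 30.0])
        slope, intercept = np.polyfit(x, y, 1)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        import statsmodels.api as sm

        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.params[1] == pytest.approx(slope, abs=1e-10)
        assert fit.rsquared == pytest.approx(r2, abs=1e-10)

    def test_too_few_shared_3ns_raises(self, small_synth):
        graph, seeds, _ = small_synth
        maps = tc.trace_all(graph, seeds)
        lonely = {
            "sugar": maps["sugar"],
            "ir94e": tracing.LayerMap("ir94e", frozenset()),
        }
        with pytest.raises(ValueError, match="shared"):
            tc.cross_modality_net_excitation(lonely, graph, ("sugar", "ir94e"))


class TestSignMotifs:
    def test_all_ach_circuit_only_ee(self):
        neurons = [{"neuron_id": 1, "class_label": "gustatory"}] + [
            {"neuron_id": i, "nt_neuron": "ACH"} for i in (2, 3)
        ]
        edges = [(1, 2, "GNG", "ACH", 15), (2, 3, "GNG", "ACH", 20)]
        g = make_graph(neurons, edges)
        seeds = tc.seed_sets_from_ids({"sugar": [1]})
        maps = tc.trace_all(g, seeds)
        mc = tc.sign_motif_census(maps["sugar"], g)
        assert mc.loc["E->E", "count"] == 1
        assert mc.drop(index="E->E")["count"].sum() == 0

    def test_matches_ground_truth_motifs(self, small_synth):
        graph, seeds, truth = small_synth
        maps = tc.trace_all(graph, seeds)
        for m, lm in maps.items():
            mc = tc.sign_motif_census(lm, graph)
            grns = seeds[m].grn_ids
            hop1_tot = {}
            for pre, post, syn in truth.planted_edges["hop1"]:
                if pre in grns:
                    hop1_tot[post] = hop1_tot.get(post, 0) + syn
            strong = {p for p, t in hop1_tot.items() if t >= 10}
            abbr = {"excitatory": "E", "inhibitory": "I"}
            expect = {k: 0 for k in ("E->E", "E->I", "I->E", "I->I")}
            for pre, post, syn in truth.planted_edges["hop2"]:
                if pre not in strong or syn < 10 or post not in lm.third_order_ids:
                    continue
                s_in = tc.nt_sign(truth.nt_by_neuron[pre])
                s_out = tc.nt_sign(truth.nt_by_neuron[post])
                if s_in in abbr and s_out in abbr:
                    expect[f"{abbr[s_in]}->{abbr[s_out]}"] += 1
            for k, v in expect.items():
                assert int(mc.loc[k, "count"]) == v

    def test_empty_layer_warns(self):
        lm = tracing.LayerMap("sugar", frozenset())
        g = make_graph([{"neuron_id": 1}], [])
        with pytest.warns(UserWarning, match="empty"):
            mc = tc.sign_motif_census(lm, g)
        assert mc["count"].sum() == 0
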