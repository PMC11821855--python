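"""Shared fixtures: hand-built toy graphs and seeded synthetic connectomes."""

from __future__ import annotations

from collections import defaultdict

import pandas as pd
import pytest

from taste_connectome import SynthSpec, build_graph, generate, seed_sets_from_ids


def make_graph(neurons: list[dict], edges: list[tuple]):
    """Build a graph from terse specs.

    neurons: dicts with neuron_id and optional superclass/class_label/side/
    nt_neuron; edges: (pre, post, neuropil, nt, syn) tuples.
    """
    ndf = pd.DataFrame(
        [
            dict(
                neuron_id=n["neuron_id"],
                superclass=n.get("superclass", "central"),
                class_label=n.get("class_label", "unknown"),
                side=n.get("side", "left"),
                nt_neuron=n.get("nt_neuron", "ACH"),
            )
            for n in neurons
        ]
    ).set_index("neuron_id")
    edf = pd.DataFrame(
        [
            dict(pre_id=p, post_id=q, neuropil=np_, nt_edge=nt, syn_count=s)
            for (p, q, np_, nt, s) in edges
        ],
        columns=["pre_id", "post_id", "neuropil", "nt_edge", "syn_count"],
    )
    return build_graph(ndf, edf)


def brute_force_layers(graph, seeds, t2=5, h1=10, h2=10):
    """Independent two-hop enumerator over the raw pair table (oracle)."""
    pt: dict[tuple, int] = defaultdict(int)
    for pre, post, _np, _nt, syn in graph.edges.itertuples(index=False, name=None):
        pt[(pre, post)] += syn
    all_grn = set().union(*(s.grn_ids for s in seeds.values()))
    out = {}
    for m, s in seeds.items():
        grns = s.grn_ids
        n2 = {
            post
            for (pre, post), syn in pt.items()
            if pre in grns and syn >= t2 and post not in all_grn
        }
        totals = defaultdict(int)
        for (pre, post), syn in pt.items():
            if pre in grns and syn >= t2:
                totals[post] += syn
        strong = {p for p in n2 if totals[p] >= h1}
        n3 = {
            post
            for (pre, post), syn in pt.items()
            if pre in strong and syn >= h2 and post not in all_grn and post not in n2
        }
        out[m] = {"2n": n2, "3n": n3}
    return out


@pytest.fixture(scope="session")
def small_spec():
    return SynthSpec(
        rng_seed=11,
        n_grn_per_modality={"sugar": 4, "water": 3, "bitter": 3, "ir94e": 2},
        n_2n_per_modality={"sugar": 10, "water": 8, "bitter": 8, "ir94e": 5},
        n_3n_per_modality={"sugar": 14, "water": 10, "bitter": 10, "ir94e": 6},
        overlap_2n={("sugar", "water"): 3, ("bitter", "ir94e"): 1},
        overlap_3n={("sugar", "water"): 4, ("bitter", "ir94e"): 2},
        n_background=30,
        n_decoy_per_modality=4,
    )


@pytest.fixture(scope="session")
def small_synth(small_spec):
    return generate(small_spec)


@pytest.fixture(scope="session")
def default_synth():
    """The full-size default synthetic connectome (seeded)."""
    return generate(SynthSpec(rng_seed=7))


@pytest.fixture()
def two_grn_graph():
    """Two sugar GRNs, three planted 2Ns, plus a 4-synapse decoy target."""
    neurons = [
        {"neuron_id": i, "superclass": "sensory", "class_label": "gustatory"}
        for i in (1, 2)
    ] + [{"neuron_id": i} for i in (10, 11, 12, 13)]
    edges = [
        (1, 10, "GNG", "ACH", 6),
        (2, 10, "GNG", "ACH", 7),
        (1, 11, "GNG", "ACH", 5),
        (2, 12, "GNG", "ACH", 12),
        (1, 13, "GNG", "ACH", 4),  # decoy, below threshold
    ]
    g = make_graph(neurons, edges)
    seeds = seed_sets_from_ids({"sugar": [1, 2]})
    return g, seeds
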