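"""Layer tracing: identify second- and third-order taste neurons.

A neuron is a second-order neuron (2N) for a modality if at least one of
that modality's seed GRNs connects to it with a pair-total of >= 5 synapses
(the false-positive threshold recommended for this connectome), and it is
not itself an annotated GRN of any modality.  Third-order neurons (3Ns) are
traced with a more stringent 10-synapse rule on both hops: only 2Ns
receiving >= 10 total same-modality GRN synapses are expanded, and a 2N->3N
connection must itself carry >= 10 synapses.  3N lists exclude all GRNs and
same-modality 2Ns; a 3N may be a 2N for a different modality.

Thresholds apply to pair totals summed across neuropils by default; a
per-neuropil mode (any single-neuropil connection clearing the threshold)
is available via ``per_neuropil=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ConnectomeGraph, SeedSet, all_grn_ids


@dataclass
class LayerMap:
    """Per-modality layer assignments with input-strength records.

    ``hop1_strength`` has one row per 2N (n_inputs, total_syn over
    qualifying GRN connections); ``hop2_strength`` likewise per 3N over
    qualifying 2N connections.
    """

    modality: str
    grn_ids: frozenset
    second_order_ids: frozenset = frozenset()
    third_order_ids: frozenset = frozenset()
    hop1_strength: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["n_inputs", "total_syn"])
    )
    hop2_strength: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["n_inputs", "total_syn"])
    )

    def check_exclusions(self, all_grns: frozenset) -> None:
        if self.second_order_ids & all_grns:
            raise AssertionError("2N list contains annotated GRNs")
        if self.third_order_ids & all_grns:
            raise AssertionError("3N list contains annotated GRNs")
        if self.third_order_ids & self.second_order_ids:
            raise AssertionError("3N list contains same-modality 2Ns")


def _qualifying_pairs(
    graph: ConnectomeGraph,
    pre_ids: Iterable,
    threshold: int,
    per_neuropil: bool,
) -> pd.DataFrame:
    """(pre_id, post_id, syn_count) pair totals meeting the threshold.

    In per-neuropil mode a pair qualifies if any single neuropil row meets
    the threshold, but the reported syn_count is still the pair total.
    """
    totals = graph.pair_totals_from(pre_ids)
    if per_neuropil:
        pre = set(pre_ids) if not isinstance(pre_ids, (set, frozenset)) else pre_ids
        rows = graph.edges[graph.edges["pre_id"].isin(pre)]
        per_np = rows.groupby(["pre_id", "post_id", "neuropil"])["syn_count"].sum()
        ok = set(
            per_np[per_np >= threshold].reset_index()[["pre_id", "post_id"]].itertuples(
                index=False, name=None
            )
        )
        mask = [
            (p, q) in ok for p, q in totals[["pre_id", "post_id"]].itertuples(index=False, name=None)
        ]
        return totals[np.array(mask, dtype=bool)] if len(totals) else totals
    return totals[totals["syn_count"] >= threshold]


def _strength_table(pairs: pd.DataFrame) -> pd.DataFrame:
    if pairs.empty:
        return pd.DataFrame(columns=["n_inputs", "total_syn"])
    g = pairs.groupby("post_id")["syn_count"]
    return pd.DataFrame({"n_inputs": g.size(), "total_syn": g.sum()})


def trace_second_order(
    graph: ConnectomeGraph,
    seeds: Mapping[str, SeedSet],
    modality: str | None = None,
    threshold: int = 5,
    per_neuropil: bool = False,
) -> LayerMap | dict[str, LayerMap]:
    """Identify 2Ns per modality.  Returns one LayerMap, or a dict if
    ``modality`` is None."""
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    if modality is None:
        return {
            m: trace_second_order(graph, seeds, m, threshold, per_neuropil)
            for m in seeds
        }
    grns = seeds[modality].grn_ids
    excluded = all_grn_ids(seeds)
    pairs = _qualifying_pairs(graph, grns, threshold, per_neuropil)
    pairs = pairs[~pairs["post_id"].isin(excluded)]
    strength = _strength_table(pairs)
    return LayerMap(
        modality=modality,
        grn_ids=frozenset(grns),
        second_order_ids=frozenset(strength.index),
        hop1_strength=strength,
    )


def trace_third_order(
    graph: ConnectomeGraph,
    seeds: Mapping[str, SeedSet],
    layer2: LayerMap,
    hop1_total_threshold: int = 10,
    hop2_threshold: int = 10,
    per_neuropil: bool = False,
) -> LayerMap:
    """Extend a 2N layer map with its 3Ns."""
    if hop1_total_threshold < 1 or hop2_threshold < 1:
        raise ValueError("thresholds must be >= 1")
    strong_2n = frozenset(
        layer2.hop1_strength.index[
            layer2.hop1_strength["total_syn"] >= hop1_total_threshold
        ]
    )
    excluded = all_grn_ids(seeds) | layer2.second_order_ids
    pairs = _qualifying_pairs(graph, strong_2n, hop2_threshold, per_neuropil)
    pairs = pairs[pairs["syn_count"] >= hop2_threshold]
    pairs = pairs[~pairs["post_id"].isin(excluded)]
    strength = _strength_table(pairs)
    return LayerMap(
        modality=layer2.modality,
        grn_ids=layer2.grn_ids,
        second_order_ids=layer2.second_order_ids,
        third_order_ids=frozenset(strength.index),
        hop1_strength=layer2.hop1_strength,
        hop2_strength=strength,
    )


def trace_all(
    graph: ConnectomeGraph,
    seeds: Mapping[str, SeedSet],
    threshold_2n: int = 5,
    hop1_total_threshold: int = 10,
    hop2_threshold: int = 10,
    per_neuropil: bool = False,
) -> dict[str, LayerMap]:
    """Trace both layers for every modality and assert the exclusion rules."""
    maps: dict[str, LayerMap] = {}
    grns = all_grn_ids(seeds)
    for m in seeds:
        lm2 = trace_second_order(graph, seeds, m, threshold_2n, per_neuropil)
        lm = trace_third_order(
            graph, seeds, lm2, hop1_total_threshold, hop2_threshold, per_neuropil
        )
        lm.check_exclusions(grns)
        maps[m] = lm
    return maps


# --- overlap -----------------------------------------------------------------


@dataclass
class OverlapTable:
    """Pairwise and higher-order intersection counts for one layer."""

    layer: str
    sizes: dict[str, int]
    intersections: dict[tuple[str, ...], int]
    membership: pd.DataFrame  # neuron x modality booleans
    multimodal_ids: frozenset  # members of >= 2 modality sets

    def count(self, *modalities: str) -> int:
        return self.intersections[tuple(sorted(modalities))]


def modality_overlap(layer_maps: Mapping[str, LayerMap], layer: str) -> OverlapTable:
    """Intersection counts between modality layer sets ('2N' or '3N')."""
    if len(layer_maps) < 2:
        raise ValueError("need at least two layer maps")
    attr = {"2N": "second_order_ids", "3N": "third_order_ids"}[layer]
    sets = {m: getattr(lm, attr) for m, lm in layer_maps.items()}
    universe = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {m: [i in sets[m] for i in universe] for m in sorted(sets)}, index=universe
    )
    inter: dict[tuple[str, ...], int] = {}
    mods = sorted(sets)
    for r in range(2, len(mods) + 1):
        for combo in combinations(mods, r):
            s = sets[combo[0]]
            for m in combo[1:]:
                s = s & sets[m]
            inter[combo] = len(s)
    multi = frozenset(membership.index[membership.sum(axis=1) > 1])
    return OverlapTable(
        layer=layer,
        sizes={m: len(sets[m]) for m in mods},
        intersections=inter,
        membership=membership,
        multimodal_ids=multi,
    )


# --- GRN-GRN matrix ----------------------------------------------------------


def grn_grn_matrix(
    graph: ConnectomeGraph,
    seeds: Mapping[str, SeedSet],
    threshold: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Modality x modality GRN-GRN synapse matrix and its per-source-GRN
    normalization.  By default all edges count (no threshold)."""
    mods = sorted(seeds)
    mat = pd.DataFrame(0, index=mods, columns=mods, dtype=float)
    totals = graph.pair_totals.reset_index()
    if threshold is not None:
        totals = totals[totals["syn_count"] >= threshold]
    for a in mods:
        sub = totals[totals["pre_id"].isin(seeds[a].grn_ids)]
        for b in mods:
            mat.loc[a, b] = sub.loc[
                sub["post_id"].isin(seeds[b].grn_ids), "syn_count"
            ].sum()
    norm = mat.div(
        pd.Series({m: max(len(seeds[m].grn_ids), 1) for m in mods}), axis=0
    )
    return mat, norm


# --- strength distributions and regression -----------------------------------


def input_strength_distribution(layer_map: LayerMap, hop: int = 1) -> dict:
    """Distribution and medians of (total input synapses, n input cells)."""
    table = layer_map.hop1_strength if hop == 1 else layer_map.hop2_strength
    if table.empty:
        warnings.warn(
            f"empty layer for {layer_map.modality!r} hop {hop}", stacklevel=2
        )
        return {
            "modality": layer_map.modality,
            "table": table,
            "median_total_syn": float("nan"),
            "median_n_inputs": float("nan"),
        }
    return {
        "modality": layer_map.modality,
        "table": table,
        "median_total_syn": float(table["total_syn"].median()),
        "median_n_inputs": float(table["n_inputs"].median()),
    }


def fanin_strength_regression(layer_map: LayerMap, hop: int = 1) -> dict:
    """OLS of mean synapses-per-input-cell against number of input cells.

    Returns slope, intercept, r_squared, p_value (slope test).
    """
    table = layer_map.hop1_strength if hop == 1 else layer_map.hop2_strength
    if len(table) < 3:
        raise ValueError("need >= 3 neurons in layer for regression")
    x = table["n_inputs"].to_numpy(dtype=float)
    y = (table["total_syn"] / table["n_inputs"]).to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate regressor: all fan-in values identical")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "modality": layer_map.modality,
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r_squared": float(model.rsquared),
        "p_value": float(model.pvalues[1]),
        "n": int(len(table)),
    }


def layer_map_frame(layer_maps: Mapping[str, LayerMap]) -> pd.DataFrame:
    """Long-format export: neuron_id, modality, layer, n_inputs, total_syn."""
    rows = []
    for m, lm in sorted(layer_maps.items()):
        for layer, table in (("2N", lm.hop1_strength), ("3N", lm.hop2_strength)):
            for nid, rec in table.iterrows():
                rows.append(
                    dict(
                        neuron_id=nid,
                        modality=m,
                        layer=layer,
                        n_inputs=int(rec["n_inputs"]),
                        total_syn=int(rec["total_syn"]),
                    )
                )
    return pd.DataFrame(rows, columns=["neuron_id", "modality", "layer", "n_inputs", "total_syn"])
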