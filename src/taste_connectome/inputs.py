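"""Input censuses: how much of a taste neuron's input is taste-derived,
and what else feeds the pathway.

"Known taste neurons" are the union of annotated seed GRNs, 2Ns, and 3Ns
across all four modalities (a deliberate underestimate of taste input,
since right-hemisphere and non-labellar taste neurons are not annotated).
Input fractions are computed over *all* input synapses (no threshold on the
denominator); partner censuses count distinct presynaptic neurons whose
pair-total connection clears the 5-synapse threshold.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .io import ConnectomeGraph
from .tracing import LayerMap


def known_taste_ids(layer_maps: Mapping[str, LayerMap]) -> frozenset:
    """Union of GRN, 2N, and 3N ids over all modalities."""
    out: set = set()
    for lm in layer_maps.values():
        out |= lm.grn_ids | lm.second_order_ids | lm.third_order_ids
    return frozenset(out)


def _layer_ids(lm: LayerMap, target_layer: str) -> frozenset:
    return {"2N": lm.second_order_ids, "3N": lm.third_order_ids}[target_layer]


def input_fractions(
    graph: ConnectomeGraph,
    layer_maps: Mapping[str, LayerMap],
    target_layer: str = "2N",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-neuron fractions of input synapses from seed GRNs and from known
    taste neurons, plus per-modality medians of the known-taste fraction.

    Neurons with zero input synapses are excluded (fraction undefined) and
    counted in the returned frame's attrs under ``n_excluded``.
    """
    known = known_taste_ids(layer_maps)
    seed_grns: set = set()
    for lm in layer_maps.values():
        seed_grns |= lm.grn_ids
    records = []
    n_excluded = 0
    totals_all = graph.pair_totals.reset_index()
    for m, lm in sorted(layer_maps.items()):
        targets = _layer_ids(lm, target_layer)
        inputs = totals_all[totals_all["post_id"].isin(targets)]
        by_post = inputs.groupby("post_id")
        denom = by_post["syn_count"].sum()
        from_grn = (
            inputs[inputs["pre_id"].isin(seed_grns)].groupby("post_id")["syn_count"].sum()
        )
        from_taste = (
            inputs[inputs["pre_id"].isin(known)].groupby("post_id")["syn_count"].sum()
        )
        for nid in sorted(targets):
            tot = int(denom.get(nid, 0))
            if tot == 0:
                n_excluded += 1
                continue
            g = int(from_grn.get(nid, 0))
            t = int(from_taste.get(nid, 0))
            records.append(
                dict(
                    neuron_id=nid,
                    layer=target_layer,
                    modality=m,
                    frac_from_seed_grns=g / tot,
                    frac_from_known_taste=t / tot,
                    total_input_synapses=tot,
                )
            )
    frame = pd.DataFrame(
        records,
        columns=[
            "neuron_id",
            "layer",
            "modality",
            "frac_from_seed_grns",
            "frac_from_known_taste",
            "total_input_synapses",
        ],
    )
    frame.attrs["n_excluded"] = n_excluded
    medians = (
        frame.groupby("modality")["frac_from_known_taste"].median().to_dict()
        if len(frame)
        else {}
    )
    return frame, medians


def input_partner_census(
    graph: ConnectomeGraph,
    layer_maps: Mapping[str, LayerMap],
    target_layer: str = "2N",
    conn_threshold: int = 5,
    weight: str = "neurons",
) -> dict[str, pd.DataFrame]:
    """Superclass and class censuses of input partners per modality.

    Each distinct presynaptic partner is counted once per (modality, layer)
    regardless of how many targets it contacts (``weight="neurons"``); with
    ``weight="synapses"`` partners are weighted by their total synapses onto
    the layer.  Partners must clear ``conn_threshold`` on at least one
    pair-total connection onto the layer (``conn_threshold=None`` disables).
    """
    if weight not in ("neurons", "synapses"):
        raise ValueError(f"weight={weight!r}")
    totals_all = graph.pair_totals.reset_index()
    sc_frames, cls_frames = {}, {}
    for m, lm in sorted(layer_maps.items()):
        targets = _layer_ids(lm, target_layer)
        inputs = totals_all[totals_all["post_id"].isin(targets)]
        if conn_threshold is not None:
            qualifying = inputs[inputs["syn_count"] >= conn_threshold]
        else:
            qualifying = inputs
        partners = qualifying.groupby("pre_id")["syn_count"].sum()
        if weight == "neurons":
            w = pd.Series(1, index=partners.index)
        else:
            w = partners
        anno = graph.neurons.loc[partners.index]
        sc_frames[m] = w.groupby(anno["superclass"].values).sum()
        cls_frames[m] = w.groupby(anno["class_label"].values).sum()
    sc = pd.DataFrame(sc_frames).fillna(0).astype(int)
    cls = pd.DataFrame(cls_frames).fillna(0).astype(int)
    return {"superclass": sc.sort_index(), "class_label": cls.sort_index()}


def top_classes(
    class_census: pd.DataFrame, top_n: int, exclude_unknown: bool = True
) -> dict:
    """Top-n classes overall with per-modality coverage of assigned partners."""
    table = class_census
    if exclude_unknown and "unknown" in table.index:
        table = table.drop(index="unknown")
    order = table.sum(axis=1).sort_values(ascending=False)
    chosen = order.index[:top_n]
    coverage = {
        m: float(table.loc[chosen, m].sum() / table[m].sum()) if table[m].sum() else float("nan")
        for m in table.columns
    }
    return {"table": table.loc[chosen], "coverage": coverage}
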