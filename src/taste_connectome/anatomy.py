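"""Anatomical partitioning of neuron outputs.

The subesophageal zone (SEZ), the primary taste region, is defined as the
neuropil set {GNG, PRW, SAD, FLA, CAN}; membership is decided on the
neuropil base code after stripping any hemisphere suffix, so X_L is SEZ iff
X_R is.  Neurons are "local" if every qualifying output connection
(per-neuropil, >= 5 synapses) lies in the SEZ, "projection" (non-local) if
at least one qualifying connection lies outside, and "no-brain-output" if
they have no qualifying output connection at all.

Synapse-level partitions split non-SEZ outputs into ipsilateral /
contralateral / non-lateralized using the trailing _L/_R token (ipsilateral
defaults to the left hemisphere, where the traced GRN arbors live), and
pool homologous _L/_R regions for ranked region profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats as sps

from .io import ConnectomeGraph, nt_sign_series

DEFAULT_SEZ = frozenset({"GNG", "PRW", "SAD", "FLA", "CAN"})


@dataclass(frozen=True)
class SezDefinition:
    neuropils: frozenset = DEFAULT_SEZ

    def __post_init__(self) -> None:
        if not self.neuropils:
            raise ValueError("SEZ definition must be non-empty")

    def contains(self, neuropil: str) -> bool:
        base, _side = split_neuropil(neuropil)
        return base in self.neuropils


def split_neuropil(code: str) -> tuple[str, str | None]:
    """Split a neuropil code into (base, side); side is 'L', 'R', or None."""
    if code.endswith("_L") or code.endswith("_R"):
        return code[:-2], code[-1]
    return code, None


@dataclass
class SynapsePartition:
    """Output-synapse tallies for one neuron set."""

    total: int
    sez: int
    outside: int
    ipsi: int
    contra: int
    non_lateralized: int
    unannotated: int
    region_counts: pd.Series = field(default_factory=pd.Series)  # base region -> syn
    region_by_sign: pd.DataFrame = field(default_factory=pd.DataFrame)
    sign_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sez + self.outside != self.total:
            raise AssertionError("SEZ + outside != total output synapses")
        if self.ipsi + self.contra + self.non_lateralized != self.outside:
            raise AssertionError("ipsi + contra + non-lateralized != outside")


def classify_local_projection(
    graph: ConnectomeGraph,
    neuron_ids: Iterable,
    sez: SezDefinition | None = None,
    conn_threshold: int = 5,
) -> pd.Series:
    """Classify each neuron as 'local', 'projection', or 'no-brain-output'."""
    sez = sez or SezDefinition()
    ids = set(neuron_ids)
    rows = graph.outputs_of(ids)
    conns = rows.groupby(["pre_id", "neuropil"])["syn_count"].sum()
    conns = conns[conns >= conn_threshold].reset_index()
    conns["in_sez"] = conns["neuropil"].map(sez.contains)
    out = pd.Series("no-brain-output", index=sorted(ids), dtype=object)
    per = conns.groupby("pre_id")["in_sez"].all()
    out.loc[per.index[per]] = "local"
    out.loc[per.index[~per]] = "projection"
    return out


def partition_output_synapses(
    graph: ConnectomeGraph,
    neuron_ids: Iterable,
    sez: SezDefinition | None = None,
    ipsi_side: str = "left",
    known_neuropils: Iterable[str] | None = None,
) -> SynapsePartition:
    """Synapse-level partition of all outputs of ``neuron_ids``.

    ``known_neuropils`` optionally restricts which codes count as annotated;
    anything else is tallied under ``unannotated`` (and kept inside the
    conservation identities via the non-lateralized bucket).
    """
    sez = sez or SezDefinition()
    ipsi_token = {"left": "L", "right": "R"}[ipsi_side]
    rows = graph.outputs_of(set(neuron_ids)).copy()
    total = int(rows["syn_count"].sum())
    if rows.empty:
        empty = pd.Series(dtype=int)
        return SynapsePartition(0, 0, 0, 0, 0, 0, 0, empty, pd.DataFrame(), {})
    parsed = rows["neuropil"].map(split_neuropil)
    rows["base"] = parsed.map(lambda t: t[0])
    rows["side"] = parsed.map(lambda t: t[1])
    rows["in_sez"] = rows["base"].isin(sez.neuropils)
    if known_neuropils is not None:
        known = {split_neuropil(c)[0] for c in known_neuropils}
        rows["annotated"] = rows["base"].isin(known)
    else:
        rows["annotated"] = rows["base"] != "unknown"
    unannotated = int(rows.loc[~rows["annotated"], "syn_count"].sum())

    sez_syn = int(rows.loc[rows["in_sez"], "syn_count"].sum())
    out_rows = rows[~rows["in_sez"]]
    outside = int(out_rows["syn_count"].sum())
    ipsi = int(out_rows.loc[out_rows["side"] == ipsi_token, "syn_count"].sum())
    contra = int(
        out_rows.loc[
            out_rows["side"].map(lambda s: s is not None and s != ipsi_token),
            "syn_count",
        ].sum()
    )
    non_lat = int(out_rows.loc[out_rows["side"].isna(), "syn_count"].sum())

    region_counts = (
        out_rows[out_rows["annotated"]]
        .groupby("base")["syn_count"]
        .sum()
        .sort_values(ascending=False)
    )
    out_signed = out_rows.copy()
    out_signed["sign"] = nt_sign_series(out_signed["nt_edge"])
    region_by_sign = (
        out_signed[out_signed["annotated"]]
        .pivot_table(
            index="base", columns="sign", values="syn_count", aggfunc="sum", fill_value=0
        )
        .astype(int)
    )
    rows["sign"] = nt_sign_series(rows["nt_edge"])
    sign_counts = rows.groupby("sign")["syn_count"].sum().astype(int).to_dict()
    return SynapsePartition(
        total=total,
        sez=sez_syn,
        outside=outside,
        ipsi=ipsi,
        contra=contra,
        non_lateralized=non_lat,
        unannotated=unannotated,
        region_counts=region_counts,
        region_by_sign=region_by_sign,
        sign_counts=sign_counts,
    )


def region_profile_topk(partition: SynapsePartition, k: int) -> dict:
    """Top-k non-SEZ regions by pooled synapse count, with NT-sign columns.

    Ties are broken by count (descending) then lexicographic region code;
    ties at the boundary are flagged.  Coverage is the fraction of non-SEZ
    annotated synapses captured by the selected regions.
    """
    counts = partition.region_counts
    note = None
    if k > len(counts):
        note = f"requested top {k} but only {len(counts)} regions present"
        k = len(counts)
    ordered = counts.reset_index()
    ordered.columns = ["region", "syn_count"]
    ordered = ordered.sort_values(
        ["syn_count", "region"], ascending=[False, True]
    ).reset_index(drop=True)
    top = ordered.iloc[:k]
    tie_flag = bool(
        k and k < len(ordered) and ordered.iloc[k - 1]["syn_count"] == ordered.iloc[k]["syn_count"]
    )
    denom = int(counts.sum())
    coverage = float(top["syn_count"].sum() / denom) if denom else float("nan")
    table = top.set_index("region")
    signs = partition.region_by_sign.reindex(table.index).fillna(0).astype(int)
    return {
        "table": table.join(signs),
        "coverage": coverage,
        "tie_at_boundary": tie_flag,
        "note": note,
    }


def census(
    neurons: pd.DataFrame, ids: Iterable, attr: str = "superclass"
) -> pd.Series:
    """Exhaustive counts of a neuron attribute over ``ids`` (incl. unknown)."""
    if attr not in ("superclass", "class_label", "nt_neuron"):
        raise ValueError(f"unsupported census attribute {attr!r}")
    ids = sorted(set(ids))
    return neurons.loc[ids, attr].value_counts().sort_index()


def fisher_proportion_test(
    count_a1: int, count_a2: int, count_b1: int, count_b2: int
) -> float:
    """Two-sided Fisher's exact p-value for the 2x2 table
    [[a1, a2], [b1, b2]]."""
    cells = (count_a1, count_a2, count_b1, count_b2)
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table")
    _odds, p = sps.fisher_exact(
        [[count_a1, count_a2], [count_b1, count_b2]], alternative="two-sided"
    )
    return float(p)
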