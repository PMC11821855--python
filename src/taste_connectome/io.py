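"""Reading, validating, and indexing FlyWire-dialect connectome tables.

The connectome is distributed as two flat tables: a neuron table (one row
per neuron, with coarse "superclass" and free-text "class" annotations, a
hemisphere label, and a neuron-level neurotransmitter prediction) and an
edge table (one row per pre/post/neuropil combination with a synapse count
and an edge-level neurotransmitter prediction).  Seed gustatory receptor
neurons (GRNs) arrive as per-modality id lists.

On load, duplicate (pre, post, neuropil, nt) rows are summed and a
pair-total index (synapses per pre/post pair, summed over neuropils) is
built, since layer tracing operates on pair totals while anatomical
partitions operate on per-neuropil rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# --- controlled vocabularies -------------------------------------------------

SUPERCLASSES = frozenset(
    {
        "sensory",
        "ascending",
        "central",
        "descending",
        "motor",
        "endocrine",
        "visual_projection",
        "visual_centrifugal",
        "optic",
    }
)

NT_TYPES = frozenset({"ACH", "GABA", "GLUT", "DA", "SER", "OCT", "unknown"})
SIDES = frozenset({"left", "right", "center", "unknown"})
MODALITIES = ("sugar", "water", "bitter", "ir94e")

#: Default neurotransmitter -> sign map.  Acetylcholine is the principal
#: excitatory transmitter in the fly CNS; GABA and glutamate are the
#: principal inhibitory transmitters.  Monoamines (DA/SER/OCT) have no
#: settled sign and are bucketed as "other".
DEFAULT_SIGN_MAP: dict[str, str] = {
    "ACH": "excitatory",
    "GABA": "inhibitory",
    "GLUT": "inhibitory",
    "DA": "other",
    "SER": "other",
    "OCT": "other",
    "unknown": "other",
}

# Column aliases: codex dumps have varied header names across releases.
NEURON_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "neuron_id": ("neuron_id", "root_id", "pt_root_id", "id"),
    "superclass": ("superclass", "super_class"),
    "class_label": ("class_label", "class", "cell_class"),
    "side": ("side", "hemisphere"),
    "nt_neuron": ("nt_neuron", "nt_type", "predicted_nt", "top_nt"),
}

EDGE_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "pre_id": ("pre_id", "pre_root_id", "pre_pt_root_id"),
    "post_id": ("post_id", "post_root_id", "post_pt_root_id"),
    "neuropil": ("neuropil", "neuropil_group", "region"),
    "syn_count": ("syn_count", "syn_cnt", "synapse_count", "weight"),
    "nt_edge": ("nt_edge", "nt_type", "predicted_nt"),
}


class FormatError(ValueError):
    """A required column or field is missing or malformed."""


class ReferentialIntegrityError(ValueError):
    """An id is referenced that does not exist where it must."""


class AmbiguityError(ValueError):
    """An id is claimed by more than one seed modality."""


# --- domain containers -------------------------------------------------------


@dataclass(frozen=True)
class SeedSet:
    """Seed GRN ids for one taste modality."""

    modality: str
    grn_ids: frozenset

    def __len__(self) -> int:
        return len(self.grn_ids)


@dataclass
class ConnectomeGraph:
    """Indexed connectome: neuron annotations plus aggregated directed edges.

    Attributes
    ----------
    neurons : DataFrame indexed by neuron_id with columns
        superclass, class_label, side, nt_neuron.
    edges : DataFrame with one row per (pre_id, post_id, neuropil, nt_edge)
        and a summed syn_count.
    pair_totals : Series indexed by (pre_id, post_id) with synapse counts
        summed over neuropils.
    """

    neurons: pd.DataFrame
    edges: pd.DataFrame
    pair_totals: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        total_pairs = int(self.pair_totals.sum()) if len(self.pair_totals) else 0
        total_edges = int(self.edges["syn_count"].sum()) if len(self.edges) else 0
        if total_pairs != total_edges:
            raise AssertionError(
                f"pair_totals not conserved: {total_pairs} != {total_edges}"
            )

    @property
    def neuron_ids(self) -> pd.Index:
        return self.neurons.index

    def outputs_of(self, ids: Iterable) -> pd.DataFrame:
        """Edge rows whose presynaptic neuron is in ``ids``."""
        ids = _as_set(ids)
        return self.edges[self.edges["pre_id"].isin(ids)]

    def inputs_to(self, ids: Iterable) -> pd.DataFrame:
        """Edge rows whose postsynaptic neuron is in ``ids``."""
        ids = _as_set(ids)
        return self.edges[self.edges["post_id"].isin(ids)]

    def pair_totals_from(self, pre_ids: Iterable) -> pd.DataFrame:
        """Pair totals restricted to presynaptic ``pre_ids``.

        Returns a DataFrame with columns pre_id, post_id, syn_count.
        """
        pre_ids = _as_set(pre_ids)
        df = self.pair_totals.reset_index()
        return df[df["pre_id"].isin(pre_ids)]

    def nt_of(self, ids: Iterable) -> pd.Series:
        """Neuron-level neurotransmitter labels for ``ids``."""
        return self.neurons.loc[list(ids), "nt_neuron"]


def _as_set(ids: Iterable) -> set:
    return ids if isinstance(ids, (set, frozenset)) else set(ids)


# --- loading -----------------------------------------------------------------


def _canonicalize(
    df: pd.DataFrame, aliases: Mapping[str, tuple[str, ...]], table: str
) -> pd.DataFrame:
    rename: dict[str, str] = {}
    for canonical, options in aliases.items():
        hit = next((c for c in options if c in df.columns), None)
        if hit is None:
            raise FormatError(
                f"{table} table is missing required column {canonical!r} "
                f"(accepted aliases: {', '.join(options)})"
            )
        rename[hit] = canonical
    return df.rename(columns=rename)[list(aliases)]


def _clean_nt(series: pd.Series) -> pd.Series:
    up = series.fillna("unknown").astype(str).str.strip().str.upper()
    up = up.replace({"": "UNKNOWN", "NAN": "UNKNOWN", "NONE": "UNKNOWN"})
    out = up.where(up.isin(NT_TYPES - {"unknown"}), "unknown")
    return out


def _clean_enum(series: pd.Series, vocab: frozenset) -> pd.Series:
    low = series.fillna("unknown").astype(str).str.strip().str.lower()
    return low.where(low.isin(vocab), "unknown")


def load_connectome(
    neuron_table_path: str | Path,
    edge_table_path: str | Path,
    *,
    neuron_aliases: Mapping[str, tuple[str, ...]] | None = None,
    edge_aliases: Mapping[str, tuple[str, ...]] | None = None,
    on_missing_neuron: str = "error",
) -> ConnectomeGraph:
    """Load and index neuron and edge tables into a :class:`ConnectomeGraph`.

    Duplicate (pre, post, neuropil, nt) rows are summed.  Unknown NT strings
    map to ``"unknown"``.  Edge endpoints absent from the neuron table raise
    :class:`ReferentialIntegrityError` (``on_missing_neuron="warn_drop"``
    downgrades this to a warning and drops the offending rows — useful for
    surviving truncated downloads).
    """
    if on_missing_neuron not in ("error", "warn_drop"):
        raise ValueError(f"on_missing_neuron={on_missing_neuron!r}")

    neurons_raw = pd.read_csv(neuron_table_path)
    edges_raw = pd.read_csv(edge_table_path)

    neurons = _canonicalize(
        neurons_raw, dict(neuron_aliases or NEURON_COLUMN_ALIASES), "neuron"
    )
    edges = _canonicalize(edges_raw, dict(edge_aliases or EDGE_COLUMN_ALIASES), "edge")

    if neurons["neuron_id"].duplicated().any():
        dupes = neurons.loc[neurons["neuron_id"].duplicated(), "neuron_id"].tolist()
        raise FormatError(f"duplicate neuron ids in neuron table: {dupes[:5]}")

    neurons["superclass"] = _clean_enum(neurons["superclass"], SUPERCLASSES)
    neurons["side"] = _clean_enum(neurons["side"], SIDES)
    neurons["class_label"] = (
        neurons["class_label"].fillna("unknown").astype(str).str.strip()
    )
    neurons.loc[neurons["class_label"] == "", "class_label"] = "unknown"
    neurons["nt_neuron"] = _clean_nt(neurons["nt_neuron"])
    neurons = neurons.set_index("neuron_id")

    if (edges["syn_count"] < 1).any():
        raise FormatError("edge table contains syn_count < 1")
    edges["nt_edge"] = _clean_nt(edges["nt_edge"])
    edges["neuropil"] = edges["neuropil"].fillna("unknown").astype(str).str.strip()

    known = set(neurons.index)
    endpoint_ok = edges["pre_id"].isin(known) & edges["post_id"].isin(known)
    if not endpoint_ok.all():
        bad = edges.loc[~endpoint_ok]
        missing = sorted(
            (set(bad["pre_id"]) | set(bad["post_id"])) - known
        )
        if on_missing_neuron == "error":
            raise ReferentialIntegrityError(
                f"{len(missing)} edge endpoint id(s) absent from neuron table, "
                f"e.g. {missing[:5]}"
            )
        warnings.warn(
            f"dropping {int((~endpoint_ok).sum())} edge rows with "
            f"{len(missing)} unknown endpoint id(s)",
            stacklevel=2,
        )
        edges = edges.loc[endpoint_ok]

    return build_graph(neurons, edges)


def build_graph(neurons: pd.DataFrame, edges: pd.DataFrame) -> ConnectomeGraph:
    """Aggregate edge rows and assemble the indexed graph (in-memory entry)."""
    known = set(neurons.index)
    ok = edges["pre_id"].isin(known) & edges["post_id"].isin(known)
    if not ok.all():
        bad = edges.loc[~ok]
        missing = sorted((set(bad["pre_id"]) | set(bad["post_id"])) - known)
        raise ReferentialIntegrityError(
            f"{len(missing)} edge endpoint id(s) absent from neuron table, "
            f"e.g. {missing[:5]}"
        )
    agg = (
        edges.groupby(["pre_id", "post_id", "neuropil", "nt_edge"], as_index=False)[
            "syn_count"
        ]
        .sum()
        .sort_values(["pre_id", "post_id", "neuropil", "nt_edge"])
        .reset_index(drop=True)
    )
    pair_totals = agg.groupby(["pre_id", "post_id"])["syn_count"].sum()
    return ConnectomeGraph(neurons=neurons, edges=agg, pair_totals=pair_totals)


def write_connectome(graph: ConnectomeGraph, out_dir: str | Path) -> dict[str, Path]:
    """Write the indexed graph back to the CSV dialect (round-trippable)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    neuron_path = out / "neurons.csv"
    edge_path = out / "edges.csv"
    graph.neurons.reset_index().to_csv(neuron_path, index=False)
    graph.edges.to_csv(edge_path, index=False)
    return {"neurons": neuron_path, "edges": edge_path}


def load_seed_sets(
    paths_by_modality: Mapping[str, str | Path], graph: ConnectomeGraph
) -> dict[str, SeedSet]:
    """Load per-modality GRN id lists (one id per line, or CSV with an id column).

    Ids are deduplicated within a modality; an id claimed by two modalities
    raises :class:`AmbiguityError`; an id absent from the graph raises
    :class:`ReferentialIntegrityError`.  An empty list warns but loads.
    """
    seeds: dict[str, SeedSet] = {}
    claimed: dict[object, str] = {}
    known = set(graph.neuron_ids)
    for modality, path in paths_by_modality.items():
        ids = _read_id_list(Path(path))
        if not ids:
            warnings.warn(f"seed list for {modality!r} is empty", stacklevel=2)
        missing = sorted(ids - known)
        if missing:
            raise ReferentialIntegrityError(
                f"seed ids for {modality!r} absent from graph: {missing[:5]}"
            )
        for i in ids:
            if i in claimed:
                raise AmbiguityError(
                    f"id {i} listed for both {claimed[i]!r} and {modality!r}"
                )
            claimed[i] = modality
        seeds[modality] = SeedSet(modality=modality, grn_ids=frozenset(ids))
    return seeds


def seed_sets_from_ids(ids_by_modality: Mapping[str, Iterable]) -> dict[str, SeedSet]:
    """Build SeedSets directly from in-memory id collections."""
    seeds: dict[str, SeedSet] = {}
    claimed: dict[object, str] = {}
    for modality, ids in ids_by_modality.items():
        idset = frozenset(ids)
        overlap = {i for i in idset if i in claimed}
        if overlap:
            i = next(iter(overlap))
            raise AmbiguityError(
                f"id {i} listed for both {claimed[i]!r} and {modality!r}"
            )
        claimed.update({i: modality for i in idset})
        seeds[modality] = SeedSet(modality=modality, grn_ids=idset)
    return seeds


def _read_id_list(path: Path) -> set:
    text = path.read_text().strip()
    if not text:
        return set()
    first = text.splitlines()[0]
    if "," in first:  # CSV with a header containing an id column
        df = pd.read_csv(path)
        col = next(
            (c for c in df.columns if c.lower() in ("neuron_id", "root_id", "id")),
            df.columns[0],
        )
        values = df[col].tolist()
    else:
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        if lines and not _looks_numeric(lines[0]):
            lines = lines[1:]  # single-column file with a header
        values = lines
    return {_coerce_id(v) for v in values}


def _looks_numeric(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def _coerce_id(value) -> object:
    try:
        return int(value)
    except (TypeError, ValueError):
        return value


def all_grn_ids(seeds: Mapping[str, SeedSet]) -> frozenset:
    """Union of seed GRN ids over all modalities."""
    out: set = set()
    for s in seeds.values():
        out |= s.grn_ids
    return frozenset(out)


def nt_sign(nt: str, sign_map: Mapping[str, str] | None = None) -> str:
    """Map a neurotransmitter label to 'excitatory' / 'inhibitory' / 'other'."""
    if nt not in NT_TYPES:
        raise ValueError(f"unknown neurotransmitter label {nt!r}")
    return (sign_map or DEFAULT_SIGN_MAP).get(nt, "other")


def nt_sign_series(nts: pd.Series, sign_map: Mapping[str, str] | None = None) -> pd.Series:
    """Vectorized :func:`nt_sign`."""
    m = sign_map or DEFAULT_SIGN_MAP
    return nts.map(lambda x: m.get(x, "other"))
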