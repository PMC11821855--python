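"""Synthetic connectome generator with planted taste layers and ground truth.

Emits neuron/edge/seed tables in the same CSV dialect the loader reads,
with a known three-layer taste circuit planted inside background noise:

* seed GRNs per modality, each modality's planted second-order neurons
  (2Ns) wired so that every planted GRN->2N pair total clears the 5-synapse
  threshold and every planted 2N receives >= 10 total GRN synapses;
* planted third-order neurons (3Ns) wired from *modality-exclusive* 2Ns
  with pair totals >= 10 (shared 2Ns carry no planted forward edges, so the
  planted 3N sets are exactly what tracing must recover);
* decoy edges below each threshold, feedback/lateral edges in the 5-9
  synapse band (visible to feedback matrices, invisible to 3N tracing),
  GRN-GRN edges, background neurons and non-taste inputs.

All randomness flows through one seeded generator; the same seed yields
byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    MODALITIES,
    ConnectomeGraph,
    SeedSet,
    build_graph,
    seed_sets_from_ids,
)

SEZ_POOL = ("GNG", "PRW", "SAD", "FLA", "CAN")
NONSEZ_POOL = (
    "SLP",
    "SMP",
    "LH",
    "SCL",
    "AVLP",
    "LAL",
    "MB_CA",
    "VES",
    "SIP",
    "PLP",
    "CRE",
    "SPS",
)
# Decaying draw weights so ranked region profiles have a stable, testable head.
_NONSEZ_WEIGHTS = np.array([0.24, 0.18, 0.14, 0.11, 0.08, 0.07, 0.05, 0.04, 0.03, 0.025, 0.02, 0.015])

BACKGROUND_CLASSES = (
    "mechanosensory",
    "ALPN",
    "ALLN",
    "LHLN",
    "LHCENT",
    "MBON",
    "AN",
    "DN",
    "unknown",
)
_BG_SUPERCLASS = {
    "mechanosensory": "sensory",
    "AN": "ascending",
    "DN": "descending",
}


def _default_n_grn() -> dict[str, int]:
    return {"sugar": 22, "water": 18, "bitter": 20, "ir94e": 9}


def _default_n_2n() -> dict[str, int]:
    return {"sugar": 76, "water": 51, "bitter": 64, "ir94e": 24}


def _default_n_3n() -> dict[str, int]:
    # ~1/3-scale third layer keeps the default brain at desk scale.
    return {"sugar": 170, "water": 110, "bitter": 130, "ir94e": 75}


def _default_overlap_2n() -> dict[tuple[str, str], int]:
    return {
        ("sugar", "water"): 28,
        ("bitter", "ir94e"): 8,
        ("bitter", "water"): 6,
    }


def _default_overlap_3n() -> dict[tuple[str, str], int]:
    return {
        ("sugar", "water"): 67,
        ("bitter", "sugar"): 43,
        ("ir94e", "sugar"): 22,
        ("bitter", "water"): 25,
        ("ir94e", "water"): 16,
        ("bitter", "ir94e"): 20,
    }


def _default_ei() -> dict[tuple[str, str], float]:
    # Excitatory fraction by (modality, layer): appetitive pathways are
    # near-balanced, aversive 2Ns skew inhibitory, aversive 3Ns skew excitatory.
    return {
        ("sugar", "2N"): 0.50,
        ("water", "2N"): 0.50,
        ("bitter", "2N"): 0.30,
        ("ir94e", "2N"): 0.20,
        ("sugar", "3N"): 0.46,
        ("water", "3N"): 0.47,
        ("bitter", "3N"): 0.62,
        ("ir94e", "3N"): 0.63,
    }


def _default_sez() -> dict[tuple[str, str], float]:
    # SEZ share of output synapses by (modality, layer).
    return {
        ("sugar", "2N"): 0.96,
        ("water", "2N"): 0.95,
        ("bitter", "2N"): 0.79,
        ("ir94e", "2N"): 0.79,
        ("sugar", "3N"): 0.85,
        ("water", "3N"): 0.82,
        ("bitter", "3N"): 0.88,
        ("ir94e", "3N"): 0.89,
    }


def _default_feedback() -> dict[str, float]:
    return {"2n_to_grn": 0.20, "2n_to_2n": 0.25, "3n_to_2n": 0.08, "3n_to_grn": 0.03}


def _default_grn_grn() -> dict[tuple[str, str], float]:
    # Within-type synapses per GRN; water->sugar crosstalk is the one
    # prominent cross-type motif.
    return {
        ("sugar", "sugar"): 23.0,
        ("water", "water"): 9.0,
        ("bitter", "bitter"): 0.5,
        ("ir94e", "ir94e"): 35.0,
        ("water", "sugar"): 2.0,
    }


@dataclass
class SynthSpec:
    """Parameters of the planted synthetic connectome.

    Synapse counts for suprathreshold edges follow a shifted geometric
    (``threshold - 1 + Geometric(p)``), giving the heavy right tail seen in
    real connection-strength distributions.
    """

    rng_seed: int = 0
    n_grn_per_modality: dict[str, int] = field(default_factory=_default_n_grn)
    n_2n_per_modality: dict[str, int] = field(default_factory=_default_n_2n)
    n_3n_per_modality: dict[str, int] = field(default_factory=_default_n_3n)
    overlap_2n: dict[tuple[str, str], int] = field(default_factory=_default_overlap_2n)
    overlap_3n: dict[tuple[str, str], int] = field(default_factory=_default_overlap_3n)
    syn_geom_p_hop1: float = 0.35
    syn_geom_p_hop2: float = 0.20
    ei_fraction: dict[tuple[str, str], float] = field(default_factory=_default_ei)
    p_feedback: dict[str, float] = field(default_factory=_default_feedback)
    sez_fraction: dict[tuple[str, str], float] = field(default_factory=_default_sez)
    contra_fraction: float = 0.30
    n_background: int = 150
    n_decoy_per_modality: int = 10
    grn_grn_syn_per_grn: dict[tuple[str, str], float] = field(
        default_factory=_default_grn_grn
    )
    background_input_mean: float = 2.0
    no_output_fraction: float = 0.03
    other_nt_fraction: float = 0.03
    fanin_strength_coupling: bool = False
    threshold_2n: int = 5
    threshold_3n: int = 10

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(sorted(self.n_grn_per_modality))

    def validate(self) -> None:
        for d, nm in (
            (self.ei_fraction, "ei_fraction"),
            (self.sez_fraction, "sez_fraction"),
        ):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{nm}[{k}]={v} outside [0, 1]")
        if not 0.0 <= self.contra_fraction <= 1.0:
            raise ValueError("contra_fraction outside [0, 1]")
        for (pair, table, sizes) in (
            *(((a, b), "2N", self.n_2n_per_modality) for a, b in self.overlap_2n),
            *(((a, b), "3N", self.n_3n_per_modality) for a, b in self.overlap_3n),
        ):
            a, b = pair
            ov = (self.overlap_2n if table == "2N" else self.overlap_3n)[pair]
            if ov > min(sizes.get(a, 0), sizes.get(b, 0)):
                raise ValueError(
                    f"planted {table} overlap {pair} = {ov} exceeds layer size"
                )
        for table, sizes, overlaps in (
            ("2N", self.n_2n_per_modality, self.overlap_2n),
            ("3N", self.n_3n_per_modality, self.overlap_3n),
        ):
            for m in sizes:
                shared = sum(v for k, v in overlaps.items() if m in k)
                if shared > sizes[m]:
                    raise ValueError(
                        f"sum of planted {table} overlaps involving {m!r} "
                        f"({shared}) exceeds layer size {sizes[m]}"
                    )


@dataclass
class GroundTruth:
    """Planted structure of a generated connectome."""

    rng_seed: int
    layers: dict[str, dict[str, list]]  # modality -> {"grn"/"2n"/"3n": [ids]}
    nt_by_neuron: dict  # id -> nt label (signs derivable via nt_sign)
    overlap_2n: dict[str, int]  # "a|b" -> planted shared count
    overlap_3n: dict[str, int]
    feedback_edges: dict[str, list]  # kind -> [(pre, post, syn)]
    decoy_edges: list  # [(pre, post, syn)] below-threshold GRN edges
    planted_edges: dict[str, list]  # "hop1"/"hop2" -> [(pre, post, syn)]

    def layer_sets(self, modality: str) -> dict[str, frozenset]:
        d = self.layers[modality]
        return {k: frozenset(v) for k, v in d.items()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), default=str, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        raw["nt_by_neuron"] = {int(k): v for k, v in raw["nt_by_neuron"].items()}
        return cls(**raw)


def _pairkey(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


def _allocate_layer(
    next_id: int,
    sizes: Mapping[str, int],
    overlaps: Mapping[tuple[str, str], int],
) -> tuple[dict[str, list[int]], int]:
    """Allocate ids per modality honouring planted pairwise overlaps."""
    sets: dict[str, list[int]] = {m: [] for m in sorted(sizes)}
    for (a, b) in sorted(tuple(sorted(k)) for k in overlaps):
        n = overlaps.get((a, b), overlaps.get((b, a), 0))
        for _ in range(n):
            sets[a].append(next_id)
            sets[b].append(next_id)
            next_id += 1
    for m in sorted(sizes):
        while len(sets[m]) < sizes[m]:
            sets[m].append(next_id)
            next_id += 1
    return sets, next_id


def generate(spec: SynthSpec) -> tuple[ConnectomeGraph, dict[str, SeedSet], GroundTruth]:
    """Generate the planted connectome. Deterministic given ``spec.rng_seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    mods = spec.modalities

    next_id = 1001
    grn: dict[str, list[int]] = {}
    for m in mods:
        grn[m] = list(range(next_id, next_id + spec.n_grn_per_modality[m]))
        next_id += spec.n_grn_per_modality[m]

    n2, next_id = _allocate_layer(next_id, spec.n_2n_per_modality, spec.overlap_2n)
    n3, next_id = _allocate_layer(next_id, spec.n_3n_per_modality, spec.overlap_3n)
    background = list(range(next_id, next_id + spec.n_background))
    next_id += spec.n_background

    all_2n = sorted({i for ids in n2.values() for i in ids})
    all_3n = sorted({i for ids in n3.values() for i in ids})
    shared_2n = {i for i in all_2n if sum(i in n2[m] for m in mods) > 1}
    exclusive_2n = {m: [i for i in n2[m] if i not in shared_2n] for m in mods}

    # --- neuron attributes ---------------------------------------------------
    nt_by_neuron: dict[int, str] = {}
    rows: list[dict] = []

    def _draw_nt(p_exc: float) -> str:
        if rng.random() < spec.other_nt_fraction:
            return "DA"
        if rng.random() < p_exc:
            return "ACH"
        return "GABA" if rng.random() < 0.5 else "GLUT"

    for m in mods:
        for i in grn[m]:
            nt_by_neuron[i] = "ACH"
            rows.append(
                dict(
                    neuron_id=i,
                    superclass="sensory",
                    class_label="gustatory",
                    side="left",
                    nt_neuron="ACH",
                )
            )

    def _primary_modality(i: int, layer_sets: dict[str, list[int]]) -> str:
        return next(m for m in mods if i in layer_sets[m])

    sc_2n = np.array(["central", "ascending", "descending"])
    for i in all_2n:
        m = _primary_modality(i, n2)
        nt_by_neuron[i] = _draw_nt(spec.ei_fraction[(m, "2N")])
        sc = sc_2n[rng.choice(3, p=[0.80, 0.10, 0.10])]
        cls = {"ascending": "AN", "descending": "DN"}.get(sc, "unknown")
        rows.append(
            dict(neuron_id=i, superclass=sc, class_label=cls, side="left", nt_neuron=nt_by_neuron[i])
        )

    no_output_3n: set[int] = set()
    sc_3n = np.array(["central", "descending", "ascending", "sensory", "motor", "endocrine"])
    for i in all_3n:
        m = _primary_modality(i, n3)
        nt_by_neuron[i] = _draw_nt(spec.ei_fraction[(m, "3N")])
        if rng.random() < spec.no_output_fraction:
            no_output_3n.add(i)
            sc = "motor" if rng.random() < 0.5 else "descending"
        else:
            sc = sc_3n[rng.choice(6, p=[0.66, 0.12, 0.04, 0.08, 0.06, 0.04])]
        cls = {"ascending": "AN", "descending": "DN"}.get(sc, "unknown")
        rows.append(
            dict(neuron_id=i, superclass=sc, class_label=cls, side="left", nt_neuron=nt_by_neuron[i])
        )

    for i in background:
        cls = BACKGROUND_CLASSES[rng.choice(len(BACKGROUND_CLASSES))]
        sc = _BG_SUPERCLASS.get(cls, "central")
        nt = ("ACH", "GABA", "GLUT", "DA")[rng.choice(4, p=[0.55, 0.22, 0.15, 0.08])]
        nt_by_neuron[i] = nt
        side = ("left", "right")[rng.choice(2)]
        rows.append(
            dict(neuron_id=i, superclass=sc, class_label=cls, side=side, nt_neuron=nt)
        )

    # --- edges ---------------------------------------------------------------
    edge_rows: list[dict] = []

    def _add_edge(pre: int, post: int, syn: int, neuropil: str) -> None:
        edge_rows.append(
            dict(
                pre_id=pre,
                post_id=post,
                neuropil=neuropil,
                syn_count=int(syn),
                nt_edge=nt_by_neuron[pre],
            )
        )

    def _syn(base: int, p: float, n: int = 1) -> np.ndarray:
        return base - 1 + rng.geometric(p, size=n)

    def _output_neuropil(m: str, layer: str) -> str:
        if rng.random() < spec.sez_fraction[(m, layer)]:
            return SEZ_POOL[rng.choice(len(SEZ_POOL), p=[0.6, 0.1, 0.1, 0.1, 0.1])]
        base = NONSEZ_POOL[rng.choice(len(NONSEZ_POOL), p=_NONSEZ_WEIGHTS / _NONSEZ_WEIGHTS.sum())]
        side = "R" if rng.random() < spec.contra_fraction else "L"
        return f"{base}_{side}"

    planted_hop1: list[tuple[int, int, int]] = []
    planted_hop2: list[tuple[int, int, int]] = []

    # GRN -> 2N: every planted 2N clears the 5-synapse pair threshold and
    # accumulates >= 10 total GRN synapses per modality it belongs to.
    for m in mods:
        g = grn[m]
        for post in n2[m]:
            fanin = int(rng.integers(1, min(4, len(g)) + 1))
            pres = rng.choice(len(g), size=fanin, replace=False)
            syns = _syn(spec.threshold_2n, spec.syn_geom_p_hop1, fanin)
            if spec.fanin_strength_coupling:
                syns = syns + 2 * (fanin - 1)
            deficit = spec.threshold_3n - int(syns.sum())  # hop-1 gate
            if deficit > 0:
                syns[0] += deficit
            for j, s in zip(pres, syns):
                _add_edge(g[int(j)], post, int(s), "GNG")
                planted_hop1.append((g[int(j)], post, int(s)))

    # Decoy GRN edges: single sub-threshold (1-4 syn) edges onto background.
    # Pairs are kept distinct so aggregation cannot push a decoy over threshold.
    decoys: list[tuple[int, int, int]] = []
    decoy_pairs: set[tuple[int, int]] = set()
    for m in mods:
        for _ in range(spec.n_decoy_per_modality):
            if not background:
                break
            pre = grn[m][int(rng.integers(len(grn[m])))]
            post = background[int(rng.integers(len(background)))]
            if (pre, post) in decoy_pairs:
                continue
            decoy_pairs.add((pre, post))
            syn = int(rng.integers(1, spec.threshold_2n))
            _add_edge(pre, post, syn, "GNG")
            decoys.append((pre, post, syn))

    # GRN -> GRN lateral edges.
    for (src, dst), per_grn in sorted(spec.grn_grn_syn_per_grn.items()):
        if src not in grn or dst not in grn:
            continue
        total = int(round(per_grn * len(grn[src])))
        while total > 0:
            pre = grn[src][int(rng.integers(len(grn[src])))]
            cands = [i for i in grn[dst] if i != pre] or grn[dst]
            post = cands[int(rng.integers(len(cands)))]
            syn = int(min(total, rng.integers(1, 9)))
            _add_edge(pre, post, syn, "GNG")
            total -= syn

    # 2N -> 3N: drawn from modality-exclusive 2Ns only, pair totals >= 10.
    for m in mods:
        pool = exclusive_2n[m]
        for post in n3[m]:
            fanin = int(rng.choice([1, 2, 3], p=[0.55, 0.30, 0.15]))
            fanin = min(fanin, len(pool))
            pres = rng.choice(len(pool), size=fanin, replace=False)
            syns = _syn(spec.threshold_3n, spec.syn_geom_p_hop2, fanin)
            for j, s in zip(pres, syns):
                pre = pool[int(j)]
                _add_edge(pre, post, int(s), _output_neuropil(m, "2N"))
                planted_hop2.append((pre, post, int(s)))

    # Sub-threshold-band edges (5-9 syn) with a 2N presynaptic side must stay
    # pair-unique: two such edges on one pair would aggregate past the 3N
    # threshold and plant an unintended 3N.
    soft_pairs: set[tuple[int, int]] = set()

    # Sub-threshold 2N output decoys (5-9 syn, invisible to 3N tracing).
    for m in mods:
        for pre in n2[m]:
            if background and rng.random() < 0.3:
                post = background[int(rng.integers(len(background)))]
                if (pre, post) in soft_pairs:
                    continue
                soft_pairs.add((pre, post))
                syn = int(rng.integers(spec.threshold_2n, spec.threshold_3n))
                _add_edge(pre, post, syn, _output_neuropil(m, "2N"))

    # Feedback / lateral edges, kept in the 5-9 band so they are visible to
    # feedback matrices but never create spurious layer members.
    feedback: dict[str, list[tuple[int, int, int]]] = {k: [] for k in spec.p_feedback}

    def _feedback(kind: str, sources: list[int], targets: list[int], m: str, layer: str) -> None:
        p = spec.p_feedback.get(kind, 0.0)
        for pre in sources:
            if targets and rng.random() < p:
                post = targets[int(rng.integers(len(targets)))]
                if post == pre or (pre, post) in soft_pairs:
                    continue
                soft_pairs.add((pre, post))
                syn = int(rng.integers(spec.threshold_2n, spec.threshold_3n))
                _add_edge(pre, post, syn, _output_neuropil(m, layer))
                feedback[kind].append((pre, post, syn))

    for m in mods:
        _feedback("2n_to_grn", n2[m], grn[m], m, "2N")
        _feedback("2n_to_2n", n2[m], [i for i in all_2n if True], m, "2N")
        _feedback("3n_to_2n", n3[m], n2[m], m, "3N")
        _feedback("3n_to_grn", n3[m], grn[m], m, "3N")

    # 3N outputs onto background (anatomy / local-projection substrate).
    for m in mods:
        for pre in n3[m]:
            if pre in no_output_3n or not background:
                continue
            for _ in range(int(rng.integers(1, 4))):
                post = background[int(rng.integers(len(background)))]
                syn = int(_syn(spec.threshold_2n, spec.syn_geom_p_hop1)[0])
                _add_edge(pre, post, syn, _output_neuropil(m, "3N"))

    # Non-taste background inputs onto 2Ns and 3Ns.
    if background:
        for post in all_2n + all_3n:
            for _ in range(int(rng.poisson(spec.background_input_mean))):
                pre = background[int(rng.integers(len(background)))]
                syn = int(_syn(spec.threshold_2n, spec.syn_geom_p_hop1)[0])
                _add_edge(pre, post, syn, "GNG")

    neurons = (
        pd.DataFrame(rows).sort_values("neuron_id").set_index("neuron_id")
    )
    edges = pd.DataFrame(
        edge_rows, columns=["pre_id", "post_id", "neuropil", "syn_count", "nt_edge"]
    )
    graph = build_graph(neurons, edges)
    seeds = seed_sets_from_ids({m: grn[m] for m in mods})

    truth = GroundTruth(
        rng_seed=spec.rng_seed,
        layers={
            m: {"grn": sorted(grn[m]), "2n": sorted(n2[m]), "3n": sorted(n3[m])}
            for m in mods
        },
        nt_by_neuron=nt_by_neuron,
        overlap_2n={
            _pairkey(a, b): v for (a, b), v in spec.overlap_2n.items()
        },
        overlap_3n={
            _pairkey(a, b): v for (a, b), v in spec.overlap_3n.items()
        },
        feedback_edges={k: v for k, v in feedback.items()},
        decoy_edges=decoys,
        planted_edges={"hop1": planted_hop1, "hop2": planted_hop2},
    )
    return graph, seeds, truth


def write_dialect(
    graph: ConnectomeGraph,
    seeds: Mapping[str, SeedSet],
    out_dir: str | Path,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write generated objects to the loader's CSV dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["neurons"] = out / "neurons.csv"
    graph.neurons.reset_index().to_csv(paths["neurons"], index=False)
    paths["edges"] = out / "edges.csv"
    graph.edges.to_csv(paths["edges"], index=False)
    for m, s in seeds.items():
        p = out / f"seeds_{m}.txt"
        p.write_text("\n".join(str(i) for i in sorted(s.grn_ids)) + "\n")
        paths[f"seeds_{m}"] = p
    if truth is not None:
        paths["ground_truth"] = out / "ground_truth.json"
        truth.to_json(paths["ground_truth"])
    return paths
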