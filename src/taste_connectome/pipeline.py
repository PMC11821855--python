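"""End-to-end pipeline: load/generate -> trace -> statistics -> anatomy ->
input census -> simulation, with per-stage CSV outputs and a hashed manifest.

A single integer seed drives every stochastic stage; each stage derives its
own child seed from it, so stages can be rerun independently yet
reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import anatomy as anat
from . import inputs as cen
from . import io as cio
from . import lif
from . import stats as cstats
from . import synth
from . import tracing

log = logging.getLogger("taste_connectome")

_ANATOMY_COLUMNS = (
    "modality",
    "layer",
    "n_local",
    "n_projection",
    "n_no_output",
    "syn_total",
    "syn_sez",
    "syn_outside",
    "syn_ipsi",
    "syn_contra",
    "syn_non_lateralized",
)

FEEDBACK_PAIRS = (
    ("2N", "GRN"),
    ("2N", "2N"),
    ("3N", "2N"),
    ("3N", "GRN"),
)


@dataclass
class PipelineConfig:
    """All knobs for a full run; defaults mirror the tracing conventions."""

    out_dir: str = "pipeline_out"
    rng_seed: int = 0
    # input: either real tables ...
    neuron_table: str | None = None
    edge_table: str | None = None
    seed_lists: dict[str, str] = field(default_factory=dict)
    # ... or a synthetic spec (used when neuron_table is None)
    synth_overrides: dict[str, Any] = field(default_factory=dict)
    threshold_2n: int = 5
    threshold_3n_hop1: int = 10
    threshold_3n_hop2: int = 10
    sez_neuropils: tuple[str, ...] = tuple(sorted(anat.DEFAULT_SEZ))
    ipsi_side: str = "left"
    top_k_regions_2n: int = 6
    top_k_regions_3n: int = 12
    run_simulation: bool = True
    sim_rates: tuple[float, ...] = (25.0, 50.0, 100.0, 150.0, 200.0)
    sim_params: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        def canon(obj):
            if isinstance(obj, Mapping):
                return {str(k): canon(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple)):
                return [canon(v) for v in obj]
            return obj

        payload = json.dumps(
            canon(dataclasses.asdict(self)), sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _write(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=True)
    return path


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns in-memory outputs and writes CSVs plus a
    manifest (file hashes, config hash, seeds) under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    outputs: dict[str, Any] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        written.append(_write(df, out / f"{name}.csv"))

    # stage: io ---------------------------------------------------------------
    try:
        if config.neuron_table:
            graph = cio.load_connectome(config.neuron_table, config.edge_table)
            seeds = cio.load_seed_sets(config.seed_lists, graph)
            truth = None
        else:
            spec = synth.SynthSpec(
                rng_seed=_stage_seed(config.rng_seed, "synth"),
                **config.synth_overrides,
            )
            graph, seeds, truth = synth.generate(spec)
    except Exception as exc:  # noqa: BLE001 - stage-tagged diagnostics
        raise RuntimeError(f"[stage:io] {exc}") from exc
    outputs["graph"], outputs["seeds"], outputs["ground_truth"] = graph, seeds, truth

    # stage: trace ------------------------------------------------------------
    try:
        layer_maps = tracing.trace_all(
            graph,
            seeds,
            threshold_2n=config.threshold_2n,
            hop1_total_threshold=config.threshold_3n_hop1,
            hop2_threshold=config.threshold_3n_hop2,
        )
        emit("layers", tracing.layer_map_frame(layer_maps).set_index("neuron_id"))
        for layer in ("2N", "3N"):
            ov = tracing.modality_overlap(layer_maps, layer)
            rows = [
                {"modalities": "&".join(k), "count": v}
                for k, v in sorted(ov.intersections.items())
            ]
            emit(
                f"overlap_{layer.lower()}",
                pd.DataFrame(rows).set_index("modalities"),
            )
            outputs[f"overlap_{layer.lower()}"] = ov
        mat, norm = tracing.grn_grn_matrix(graph, seeds)
        emit("grn_grn_matrix", mat)
        emit("grn_grn_per_grn", norm)
        outputs["layer_maps"] = layer_maps
        outputs["grn_grn"] = (mat, norm)
    except Exception as exc:
        raise RuntimeError(f"[stage:trace] {exc}") from exc

    # stage: stats ------------------------------------------------------------
    try:
        ids_by_layer = {
            "GRN": {m: lm.grn_ids for m, lm in layer_maps.items()},
            "2N": {m: lm.second_order_ids for m, lm in layer_maps.items()},
            "3N": {m: lm.third_order_ids for m, lm in layer_maps.items()},
        }
        fb_frames = []
        for src, tgt in FEEDBACK_PAIRS:
            fm = cstats.feedback_matrix(
                graph, ids_by_layer[src], ids_by_layer[tgt], src, tgt
            )
            longf = cstats.feedback_matrix_long(fm)
            longf.insert(0, "source_layer", src)
            longf.insert(1, "target_layer", tgt)
            fb_frames.append(longf)
        emit("feedback_matrices", pd.concat(fb_frames, ignore_index=True))
        conv_rows = []
        for m, lm in layer_maps.items():
            for k in (2, 3):
                r = cstats.convergence_test(
                    lm, graph, k, hop2_threshold=config.threshold_3n_hop2
                )
                conv_rows.append(
                    dict(
                        modality=m,
                        k=k,
                        n=r.n,
                        p_exc=r.p_exc,
                        chi2=r.chi2,
                        p=r.p,
                        insufficient_n=r.insufficient_n,
                        **{f"obs_{c}": v for c, v in r.observed.items()},
                        **{f"exp_{c}": v for c, v in r.expected.items()},
                    )
                )
        emit("convergence", pd.DataFrame(conv_rows).set_index("modality"))
        net_frames = []
        for m, lm in layer_maps.items():
            t = cstats.net_excitation_table(graph, lm, config.threshold_3n_hop2)
            t = t.copy()
            t["modality"] = m
            net_frames.append(t)
        emit("net_excitation", pd.concat(net_frames))
        motif_frames = []
        for m, lm in layer_maps.items():
            mc = cstats.sign_motif_census(lm, graph, config.threshold_3n_hop2)
            mc = mc.copy()
            mc["modality"] = m
            motif_frames.append(mc)
        emit("sign_motifs", pd.concat(motif_frames))
        outputs["convergence"] = conv_rows
    except Exception as exc:
        raise RuntimeError(f"[stage:stats] {exc}") from exc

    # stage: anatomy ----------------------------------------------------------
    try:
        sez = anat.SezDefinition(frozenset(config.sez_neuropils))
        anat_rows, region_frames = [], []
        for m, lm in layer_maps.items():
            for layer, ids in (("2N", lm.second_order_ids), ("3N", lm.third_order_ids)):
                if not ids:
                    continue
                cls = anat.classify_local_projection(
                    graph, ids, sez, config.threshold_2n
                )
                part = anat.partition_output_synapses(
                    graph, ids, sez, config.ipsi_side
                )
                anat_rows.append(
                    dict(
                        modality=m,
                        layer=layer,
                        n_local=int((cls == "local").sum()),
                        n_projection=int((cls == "projection").sum()),
                        n_no_output=int((cls == "no-brain-output").sum()),
                        syn_total=part.total,
                        syn_sez=part.sez,
                        syn_outside=part.outside,
                        syn_ipsi=part.ipsi,
                        syn_contra=part.contra,
                        syn_non_lateralized=part.non_lateralized,
                    )
                )
                k = config.top_k_regions_2n if layer == "2N" else config.top_k_regions_3n
                prof = anat.region_profile_topk(part, k)
                tab = prof["table"].copy()
                tab["modality"] = m
                tab["layer"] = layer
                region_frames.append(tab)
        emit(
            "anatomy_partition",
            pd.DataFrame(anat_rows, columns=_ANATOMY_COLUMNS).set_index("modality"),
        )
        emit(
            "region_profiles",
            pd.concat(region_frames)
            if region_frames
            else pd.DataFrame(columns=["syn_count", "modality", "layer"]),
        )
        census_frames = []
        for attr in ("superclass", "class_label", "nt_neuron"):
            for m, lm in layer_maps.items():
                for layer, ids in (
                    ("2N", lm.second_order_ids),
                    ("3N", lm.third_order_ids),
                ):
                    if not ids:
                        continue
                    c = anat.census(graph.neurons, ids, attr)
                    census_frames.append(
                        pd.DataFrame(
                            {
                                "attribute": attr,
                                "modality": m,
                                "layer": layer,
                                "category": c.index,
                                "count": c.values,
                            }
                        )
                    )
        emit(
            "censuses",
            pd.concat(census_frames, ignore_index=True)
            if census_frames
            else pd.DataFrame(
                columns=["attribute", "modality", "layer", "category", "count"]
            ),
        )
    except Exception as exc:
        raise RuntimeError(f"[stage:anatomy] {exc}") from exc

    # stage: census -----------------------------------------------------------
    try:
        for layer in ("2N", "3N"):
            frac, medians = cen.input_fractions(graph, layer_maps, layer)
            emit(f"input_fractions_{layer.lower()}", frac.set_index("neuron_id"))
            outputs[f"input_medians_{layer.lower()}"] = medians
            partners = cen.input_partner_census(
                graph, layer_maps, layer, config.threshold_2n
            )
            emit(f"input_partners_superclass_{layer.lower()}", partners["superclass"])
            emit(f"input_partners_class_{layer.lower()}", partners["class_label"])
    except Exception as exc:
        raise RuntimeError(f"[stage:census] {exc}") from exc

    # stage: simulate ---------------------------------------------------------
    if config.run_simulation:
        try:
            params = lif.LifParams(**config.sim_params)
            network = lif.build_network(graph, w_unit=params.w_unit)
            sweep_frames = []
            for m, lm in layer_maps.items():
                sweep, _results = lif.intensity_sweep(
                    network,
                    params,
                    lm.grn_ids,
                    rates=config.sim_rates,
                    populations={"2N": lm.second_order_ids, "3N": lm.third_order_ids},
                    rng_seed=_stage_seed(config.rng_seed, f"sim:{m}"),
                )
                sweep = sweep.copy()
                sweep.insert(0, "modality", m)
                sweep_frames.append(sweep)
            emit("activation_by_rate", pd.concat(sweep_frames, ignore_index=True))
            outputs["activation_by_rate"] = pd.concat(sweep_frames, ignore_index=True)
        except Exception as exc:
            raise RuntimeError(f"[stage:simulate] {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(written)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    outputs["manifest"] = manifest
    log.info("pipeline complete: %d files in %s", len(written), out)
    return outputs


# --- reporting ---------------------------------------------------------------

REPORT_TABLES = (
    "overlap_2n",
    "overlap_3n",
    "grn_grn_per_grn",
    "convergence",
    "anatomy_partition",
    "activation_by_rate",
)


def report(out_dir: str | Path) -> str:
    """Human-readable summary assembled from a completed run's CSVs.

    Missing stage outputs produce warnings rather than a failure.
    """
    out = Path(out_dir)
    lines = [f"taste-connectome report: {out}"]
    for key in REPORT_TABLES:
        path = out / f"{key}.csv"
        if not path.exists():
            lines.append(f"\n== {key} == MISSING (stage not run?)")
            continue
        df = pd.read_csv(path)
        lines.append(f"\n== {key} ==")
        lines.append(df.to_string(index=False, max_rows=30))
    return "\n".join(lines)
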