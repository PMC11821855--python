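"""Excitatory/inhibitory circuit statistics.

Sign conventions follow the connectome's two neurotransmitter channels:
feedback/lateral matrices use the *edge-level* prediction (synapse-pooled
per connection), while convergence, net excitation, and sign-motif censuses
use the *neuron-level* prediction so that each 2N->3N pair is counted once
with a single sign.

The convergence null treats each of a 3N's k same-modality 2N inputs as an
independent draw that is excitatory with probability p (estimated from the
analyzed population), so the expected category proportions are the binomial
p^k (all-excitatory), (1-p)^k (all-inhibitory), and the remainder (mixed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .io import ConnectomeGraph, nt_sign_series
from .tracing import LayerMap


@dataclass
class FeedbackMatrix:
    """Synapse counts between two traced layers, split by edge-level sign."""

    source_layer: str
    target_layer: str
    excitatory: pd.DataFrame  # source modality x target modality
    inhibitory: pd.DataFrame
    other: pd.DataFrame

    @property
    def total(self) -> pd.DataFrame:
        return self.excitatory + self.inhibitory + self.other


def feedback_matrix(
    graph: ConnectomeGraph,
    source_ids_by_modality: Mapping[str, Iterable],
    target_ids_by_modality: Mapping[str, Iterable],
    source_layer: str = "2N",
    target_layer: str = "GRN",
    sign_map: Mapping[str, str] | None = None,
) -> FeedbackMatrix:
    """Synapse counts from each source-modality set onto each target-modality
    set, split by the sign of the edge-level NT label.  Neurons belonging to
    several modalities contribute to each."""
    src_mods = sorted(source_ids_by_modality)
    tgt_mods = sorted(target_ids_by_modality)
    frames = {
        s: pd.DataFrame(0, index=src_mods, columns=tgt_mods, dtype=int)
        for s in ("excitatory", "inhibitory", "other")
    }
    edges = graph.edges.copy()
    edges["sign"] = nt_sign_series(edges["nt_edge"], sign_map)
    for a in src_mods:
        sub = edges[edges["pre_id"].isin(set(source_ids_by_modality[a]))]
        for b in tgt_mods:
            hit = sub[sub["post_id"].isin(set(target_ids_by_modality[b]))]
            for s, g in hit.groupby("sign")["syn_count"]:
                frames[s].loc[a, b] = int(g.sum())
    fm = FeedbackMatrix(
        source_layer=source_layer,
        target_layer=target_layer,
        excitatory=frames["excitatory"],
        inhibitory=frames["inhibitory"],
        other=frames["other"],
    )
    _check_feedback_conservation(graph, fm, source_ids_by_modality, target_ids_by_modality)
    return fm


def _check_feedback_conservation(graph, fm, src, tgt) -> None:
    for a in fm.total.index:
        for b in fm.total.columns:
            pairs = graph.pair_totals_from(set(src[a]))
            raw = int(pairs.loc[pairs["post_id"].isin(set(tgt[b])), "syn_count"].sum())
            if int(fm.total.loc[a, b]) != raw:
                raise AssertionError(
                    f"feedback matrix not conserved for ({a}->{b}): "
                    f"{int(fm.total.loc[a, b])} != {raw}"
                )


def feedback_matrix_long(fm: FeedbackMatrix) -> pd.DataFrame:
    """Long-format (source_modality, target_modality, sign, synapses)."""
    rows = []
    for sign, frame in (
        ("excitatory", fm.excitatory),
        ("inhibitory", fm.inhibitory),
        ("other", fm.other),
    ):
        for a in frame.index:
            for b in frame.columns:
                rows.append(
                    dict(
                        source_modality=a,
                        target_modality=b,
                        sign=sign,
                        synapses=int(frame.loc[a, b]),
                    )
                )
    return pd.DataFrame(rows)


# --- net excitation ----------------------------------------------------------


@dataclass
class NetExcitation:
    neuron_id: object
    modality: str
    e_syn: int
    i_syn: int

    @property
    def net(self) -> int:
        return self.e_syn - self.i_syn


def _qualifying_input_pairs(
    graph: ConnectomeGraph, layer_map: LayerMap, hop2_threshold: int = 10
) -> pd.DataFrame:
    """(pre 2N, post 3N, syn, sign) pairs used for convergence/net-excitation
    analyses: same-modality 2Ns passing the hop-1 gate, pair totals >= 10,
    signed by the presynaptic neuron-level NT."""
    strong_2n = set(
        layer_map.hop1_strength.index[layer_map.hop1_strength["total_syn"] >= 10]
    )
    pairs = graph.pair_totals_from(strong_2n)
    pairs = pairs[pairs["syn_count"] >= hop2_threshold]
    pairs = pairs[pairs["post_id"].isin(layer_map.third_order_ids)]
    pairs = pairs.copy()
    pairs["sign"] = nt_sign_series(graph.nt_of(pairs["pre_id"]).reset_index(drop=True)).values
    return pairs


def net_excitation(
    graph: ConnectomeGraph,
    input_ids_with_sign: Mapping[object, str],
    target_id,
    threshold: int = 10,
) -> NetExcitation:
    """Net excitation onto one target from the given signed inputs.

    Inputs with sign 'other' are excluded from both tallies; connections
    below the threshold are ignored.
    """
    pairs = graph.pair_totals_from(set(input_ids_with_sign))
    pairs = pairs[(pairs["post_id"] == target_id) & (pairs["syn_count"] >= threshold)]
    e = i = 0
    for pre, _post, syn in pairs.itertuples(index=False, name=None):
        sign = input_ids_with_sign[pre]
        if sign == "excitatory":
            e += int(syn)
        elif sign == "inhibitory":
            i += int(syn)
    return NetExcitation(neuron_id=target_id, modality="", e_syn=e, i_syn=i)


def net_excitation_table(
    graph: ConnectomeGraph,
    layer_map: LayerMap,
    hop2_threshold: int = 10,
    min_inputs: int = 2,
) -> pd.DataFrame:
    """Net excitation for every 3N with >= ``min_inputs`` qualifying
    same-modality 2N inputs.  Columns: e_syn, i_syn, net, n_inputs."""
    pairs = _qualifying_input_pairs(graph, layer_map, hop2_threshold)
    if pairs.empty:
        return pd.DataFrame(columns=["e_syn", "i_syn", "net", "n_inputs"])
    g = pairs.groupby("post_id")
    out = pd.DataFrame(
        {
            "e_syn": g.apply(
                lambda d: int(d.loc[d["sign"] == "excitatory", "syn_count"].sum()),
                include_groups=False,
            ),
            "i_syn": g.apply(
                lambda d: int(d.loc[d["sign"] == "inhibitory", "syn_count"].sum()),
                include_groups=False,
            ),
            "n_inputs": g.size(),
        }
    )
    out["net"] = out["e_syn"] - out["i_syn"]
    out = out[out["n_inputs"] >= min_inputs]
    return out


# --- convergence -------------------------------------------------------------


@dataclass
class ConvergenceResult:
    modality: str
    k: int
    observed: dict[str, int]  # category -> count
    expected: dict[str, float]  # category -> proportion
    p_exc: float
    chi2: float
    p: float
    n: int
    insufficient_n: bool


def convergence_expected(p_exc: float, k: int) -> tuple[float, float, float]:
    """Expected (all-excitatory, all-inhibitory, mixed) proportions under
    independent input signs with excitatory probability ``p_exc``."""
    if not 0.0 <= p_exc <= 1.0:
        raise ValueError(f"p_exc={p_exc} outside [0, 1]")
    if k not in (2, 3):
        raise ValueError(f"k must be 2 or 3, got {k}")
    all_e = p_exc**k
    all_i = (1.0 - p_exc) ** k
    return (all_e, all_i, 1.0 - all_e - all_i)


def chi_squared_gof(
    observed: np.ndarray | list, expected_props: np.ndarray | list
) -> tuple[float, float]:
    """Chi-squared goodness of fit of observed counts against expected
    proportions (no continuity correction).  Categories with zero
    expectation are dropped (with a warning if they hold observations);
    dof = retained categories - 1."""
    obs = np.asarray(observed, dtype=float)
    n = obs.sum()
    exp = np.asarray(expected_props, dtype=float) * n
    keep = exp > 0
    if (~keep & (obs > 0)).any():
        warnings.warn(
            "observed counts in a zero-expectation category; "
            "dropping it from the chi-squared statistic",
            stacklevel=2,
        )
    chi2 = float(((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum())
    dof = max(int(keep.sum()) - 1, 1)
    return chi2, float(sps.chi2.sf(chi2, dof))


def convergence_test(
    layer_map: LayerMap,
    graph: ConnectomeGraph,
    k: int,
    hop2_threshold: int = 10,
    min_n: int = 10,
) -> ConvergenceResult:
    """Observed vs expected sign-convergence categories for 3Ns with exactly
    ``k`` same-modality 2N inputs; chi-squared goodness of fit (no
    continuity correction), flagged when fewer than ``min_n`` 3Ns qualify."""
    pairs = _qualifying_input_pairs(graph, layer_map, hop2_threshold)
    counts = pairs.groupby("post_id").size()
    targets = counts.index[counts == k]
    # exclude 3Ns with any input of sign 'other'
    sub = pairs[pairs["post_id"].isin(targets)]
    has_other = set(sub.loc[sub["sign"] == "other", "post_id"])
    sub = sub[~sub["post_id"].isin(has_other)]
    n = sub["post_id"].nunique()
    p_exc = float((sub["sign"] == "excitatory").mean()) if len(sub) else float("nan")
    cats = {"all_e": 0, "all_i": 0, "mixed": 0}
    for _tid, d in sub.groupby("post_id"):
        n_e = int((d["sign"] == "excitatory").sum())
        if n_e == k:
            cats["all_e"] += 1
        elif n_e == 0:
            cats["all_i"] += 1
        else:
            cats["mixed"] += 1
    exp_props = dict(zip(("all_e", "all_i", "mixed"), convergence_expected(p_exc, k))) if n else {
        "all_e": float("nan"), "all_i": float("nan"), "mixed": float("nan")
    }
    chi2 = p = float("nan")
    if n:
        obs = [cats[c] for c in ("all_e", "all_i", "mixed")]
        props = [exp_props[c] for c in ("all_e", "all_i", "mixed")]
        chi2, p = chi_squared_gof(obs, props)
    return ConvergenceResult(
        modality=layer_map.modality,
        k=k,
        observed=cats,
        expected=exp_props,
        p_exc=p_exc,
        chi2=chi2,
        p=p,
        n=int(n),
        insufficient_n=n < min_n,
    )


# --- cross-modality correlation ----------------------------------------------


def cross_modality_net_excitation(
    layer_maps: Mapping[str, LayerMap],
    graph: ConnectomeGraph,
    modality_pair: tuple[str, str],
    hop2_threshold: int = 10,
) -> dict:
    """OLS of net excitation in modality A vs modality B over 3Ns shared by
    both modalities (each receiving >= 2 qualifying inputs in each).

    2Ns belonging to both modalities are deliberately counted as inputs for
    both (``double_counting_possible`` flags this convention).
    """
    a, b = modality_pair
    ta = net_excitation_table(graph, layer_maps[a], hop2_threshold)
    tb = net_excitation_table(graph, layer_maps[b], hop2_threshold)
    shared = ta.index.intersection(tb.index)
    if len(shared) < 3:
        raise ValueError(
            f"fewer than 3 shared multi-input 3Ns between {a!r} and {b!r}"
        )
    x = ta.loc[shared, "net"].to_numpy(dtype=float)
    y = tb.loc[shared, "net"].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "modality_pair": (a, b),
        "slope": float(model.params[1]),
        "r_squared": float(model.rsquared),
        "p_value": float(model.pvalues[1]),
        "n": int(len(shared)),
        "paired_values": pd.DataFrame({a: x, b: y}, index=shared),
        "double_counting_possible": True,
    }


# --- sign motifs -------------------------------------------------------------


def sign_motif_census(
    layer_map: LayerMap,
    graph: ConnectomeGraph,
    hop2_threshold: int = 10,
) -> pd.DataFrame:
    """Counts of (2N sign -> 3N sign) connection motifs for one modality.

    Rows indexed by motif ('E->E', 'E->I', 'I->E', 'I->I'); inputs or
    targets with sign 'other' (neuron-level) are excluded.
    """
    motifs = ["E->E", "E->I", "I->E", "I->I"]
    if not layer_map.third_order_ids:
        warnings.warn(f"empty 3N layer for {layer_map.modality!r}", stacklevel=2)
        return pd.DataFrame({"count": [0] * 4}, index=motifs)
    pairs = _qualifying_input_pairs(graph, layer_map, hop2_threshold)
    tgt_sign = nt_sign_series(graph.nt_of(pairs["post_id"]).reset_index(drop=True))
    pairs = pairs.copy()
    pairs["tgt_sign"] = tgt_sign.values
    pairs = pairs[
        pairs["sign"].isin(("excitatory", "inhibitory"))
        & pairs["tgt_sign"].isin(("excitatory", "inhibitory"))
    ]
    abbr = {"excitatory": "E", "inhibitory": "I"}
    key = pairs["sign"].map(abbr) + "->" + pairs["tgt_sign"].map(abbr)
    counts = key.value_counts().reindex(motifs).fillna(0).astype(int)
    return pd.DataFrame({"count": counts})
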