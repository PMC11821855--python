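"""Leaky integrate-and-fire whole-network simulation.

Every neuron is an identical point neuron: the membrane relaxes toward the
resting potential with time constant ``tau_mem`` while integrating a
synaptic drive variable ``g`` (in mV) that decays with ``tau_syn``.  Each
presynaptic spike increments the target's drive by the connection weight —
``w_unit`` mV per synapse, signed by the presynaptic neuron's predicted
neurotransmitter — after an axonal/synaptic delay ``t_delay``.  Crossing
the threshold emits a spike, resets the membrane, and holds it for the
refractory period.

    dv/dt = (v_rest - v + g) / tau_mem        dg/dt = -g / tau_syn

Integration uses a fixed-step exponential integrator that is exact for the
linear (v, g) system between spike-arrival boundaries; delays are
implemented as a ring buffer of pending drive increments.  Seed neurons are replaced by
Poisson spike sources at the stimulus rate (a regular-train mode exists
for deterministic tests).  A neuron is "activated" by a stimulus if its
mean firing rate across trials is above zero.

``tau_mem`` is not constrained by the connectome itself; the 20 ms default
is a conventional fly central-neuron value and is echoed into every result
so reported numbers carry the assumption with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

from .io import ConnectomeGraph

#: Sign of each neuron-level NT for synaptic weights.  Monoamines default to
#: +1 here (the convention of public whole-brain LIF models); neurons with
#: unknown NT default to weight 0 (no drive) — switchable via build_network.
DEFAULT_WEIGHT_SIGNS: dict[str, int] = {
    "ACH": 1,
    "DA": 1,
    "SER": 1,
    "OCT": 1,
    "GABA": -1,
    "GLUT": -1,
    "unknown": 0,
}


@dataclass(frozen=True)
class LifParams:
    """Biophysical and protocol parameters (mV, ms, s, Hz)."""

    v_rest: float = -52.0
    v_reset: float = -52.0
    v_threshold: float = -45.0
    t_refractory: float = 2.2
    tau_syn: float = 5.0
    t_delay: float = 1.8
    w_unit: float = 0.275
    tau_mem: float = 20.0
    dt: float = 0.1
    stim_duration: float = 1.0
    n_trials: int = 30

    def validate(self) -> None:
        if self.v_threshold <= self.v_rest:
            raise ValueError("v_threshold must exceed v_rest")
        for name in ("t_refractory", "tau_syn", "t_delay", "tau_mem", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dt >= min(self.tau_syn, self.tau_mem, self.t_refractory, self.t_delay):
            raise ValueError(
                f"dt={self.dt} ms is not below the smallest time constant; "
                "integration would be unstable"
            )


@dataclass
class LifNetwork:
    """Weighted signed network ready for simulation."""

    ids: np.ndarray  # neuron ids, position = matrix index
    weights: sparse.csc_matrix  # (post, pre) in mV per spike
    index: dict = field(repr=False, default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.ids)

    def idx(self, ids: Iterable) -> np.ndarray:
        return np.array([self.index[i] for i in ids], dtype=int)


def build_network(
    graph: ConnectomeGraph,
    sign_map: Mapping[str, int] | None = None,
    w_unit: float = 0.275,
    unknown_nt: str = "zero",
) -> LifNetwork:
    """One signed weight per (pre, post) pair: w_unit x pair-total synapses x
    sign of the presynaptic neuron-level NT."""
    signs = dict(sign_map or DEFAULT_WEIGHT_SIGNS)
    if unknown_nt == "excitatory":
        signs["unknown"] = 1
    elif unknown_nt != "zero":
        raise ValueError(f"unknown_nt={unknown_nt!r}")
    ids = np.array(sorted(graph.neuron_ids))
    index = {i: k for k, i in enumerate(ids)}
    pairs = graph.pair_totals.reset_index()
    pre_sign = graph.neurons.loc[pairs["pre_id"], "nt_neuron"].map(
        lambda nt: signs.get(nt, 0)
    )
    w = w_unit * pairs["syn_count"].to_numpy(dtype=float) * pre_sign.to_numpy(dtype=float)
    rows = pairs["post_id"].map(index).to_numpy(dtype=int)
    cols = pairs["pre_id"].map(index).to_numpy(dtype=int)
    keep = w != 0.0
    mat = sparse.csc_matrix(
        (w[keep], (rows[keep], cols[keep])), shape=(len(ids), len(ids))
    )
    return LifNetwork(ids=ids, weights=mat, index=index)


@dataclass
class SimulationResult:
    stim_ids: frozenset
    stim_rate: float
    params: LifParams
    mean_rate: pd.Series  # neuron id -> Hz, averaged over trials
    trial_counts: np.ndarray = field(repr=False)  # (n_trials, n) spike counts
    rng_seed: int = 0
    spike_times: list | None = field(default=None, repr=False)

    @property
    def activated(self) -> frozenset:
        return frozenset(self.mean_rate.index[self.mean_rate > 0])

    def activated_downstream(self) -> frozenset:
        """Activated neurons excluding the stimulated seeds themselves."""
        return self.activated - self.stim_ids


def simulate(
    network: LifNetwork,
    params: LifParams,
    stim_ids: Iterable,
    stim_rate: float,
    rng_seed: int = 0,
    stim_mode: str = "poisson",
    record_spike_times: bool = False,
) -> SimulationResult:
    """Simulate ``params.n_trials`` trials of ``params.stim_duration`` seconds
    with the seed neurons firing at ``stim_rate`` Hz.  Deterministic given
    ``rng_seed``."""
    params.validate()
    if stim_rate < 0:
        raise ValueError("stim_rate must be >= 0")
    if stim_mode not in ("poisson", "regular"):
        raise ValueError(f"stim_mode={stim_mode!r}")
    stim_ids = frozenset(stim_ids)
    missing = stim_ids - set(network.index)
    if missing:
        raise ValueError(f"stim ids not in network: {sorted(missing)[:5]}")

    n = network.n
    dt = params.dt
    n_steps = int(round(params.stim_duration * 1000.0 / dt))
    delay_steps = max(int(round(params.t_delay / dt)), 1)
    ref_steps = max(int(round(params.t_refractory / dt)), 1)
    decay_m = np.exp(-dt / params.tau_mem)
    decay_s = np.exp(-dt / params.tau_syn)
    # Exact update of the linear (v, g) system between arrival boundaries:
    # v(h) = v_rest + B g0 e^{-h/tau_syn} + (v0 - v_rest - B g0) e^{-h/tau_mem}
    # with B = tau_syn / (tau_syn - tau_mem); falls back to a held-drive
    # exponential-Euler step in the degenerate tau_syn == tau_mem case.
    if abs(params.tau_syn - params.tau_mem) > 1e-9:
        b_coef = params.tau_syn / (params.tau_syn - params.tau_mem)
    else:
        b_coef = None
    stim_idx = network.idx(sorted(stim_ids))
    is_stim = np.zeros(n, dtype=bool)
    is_stim[stim_idx] = True
    p_spike = stim_rate * dt * 1e-3  # per-step Bernoulli approximation
    regular_period = (
        max(int(round(1000.0 / (stim_rate * dt))), 1) if stim_rate > 0 else 0
    )
    W = network.weights

    master = np.random.default_rng(rng_seed)
    trial_seeds = master.integers(0, 2**31 - 1, size=params.n_trials)
    counts = np.zeros((params.n_trials, n), dtype=np.int64)
    spike_log: list | None = [] if record_spike_times else None

    for trial in range(params.n_trials):
        rng = np.random.default_rng(int(trial_seeds[trial]))
        v = np.full(n, params.v_rest)
        g = np.zeros(n)
        refrac = np.zeros(n, dtype=int)
        ring = np.zeros((delay_steps, n))
        trial_times: list[tuple[int, np.ndarray]] = []
        for t in range(n_steps):
            slot = t % delay_steps
            g0 = g + ring[slot]
            ring[slot] = 0.0
            active = refrac == 0
            if b_coef is not None:
                bg = b_coef * g0
                v_new = params.v_rest + bg * decay_s + (v - params.v_rest - bg) * decay_m
            else:
                target = params.v_rest + g0
                v_new = target + (v - target) * decay_m
            v = np.where(active, v_new, v)
            g = g0 * decay_s
            spikes = active & (v >= params.v_threshold) & ~is_stim
            if stim_rate > 0:
                if stim_mode == "poisson":
                    stim_fire = (rng.random(len(stim_idx)) < p_spike) & active[stim_idx]
                else:
                    stim_fire = np.full(len(stim_idx), t % regular_period == 0) & active[
                        stim_idx
                    ]
                spikes[stim_idx[stim_fire]] = True
            if spikes.any():
                idx = np.flatnonzero(spikes)
                v[idx] = params.v_reset
                # +1 so the membrane stays frozen for the full refractory
                # window: the first re-integrated interval starts at
                # t_spike + t_refractory, not one step before it
                refrac[idx] = ref_steps + 1
                contrib = np.asarray(W[:, idx].sum(axis=1)).ravel()
                ring[(t + delay_steps) % delay_steps] += contrib
                counts[trial, idx] += 1
                if spike_log is not None:
                    trial_times.append((t, idx.copy()))
            refrac[refrac > 0] -= 1
        if spike_log is not None:
            spike_log.append(trial_times)

    rates = counts.mean(axis=0) / params.stim_duration
    mean_rate = pd.Series(rates, index=network.ids)
    return SimulationResult(
        stim_ids=stim_ids,
        stim_rate=float(stim_rate),
        params=params,
        mean_rate=mean_rate,
        trial_counts=counts,
        rng_seed=rng_seed,
        spike_times=spike_log,
    )


def intensity_sweep(
    network: LifNetwork,
    params: LifParams,
    stim_ids: Iterable,
    rates: Iterable[float] = (25.0, 50.0, 100.0, 150.0, 200.0),
    populations: Mapping[str, Iterable] | None = None,
    rng_seed: int = 0,
    stim_mode: str = "poisson",
) -> tuple[pd.DataFrame, dict[float, SimulationResult]]:
    """Fraction of each population activated at each stimulation rate.

    Stimulated seeds are excluded from every population before computing
    fractions.  Returns the tidy summary and the per-rate results.
    """
    stim_ids = frozenset(stim_ids)
    pops = {"all": set(network.ids.tolist())}
    if populations:
        pops.update({k: set(v) for k, v in populations.items()})
    pops = {k: v - stim_ids for k, v in pops.items()}
    rows = []
    results: dict[float, SimulationResult] = {}
    for j, rate in enumerate(rates):
        res = simulate(
            network, params, stim_ids, rate, rng_seed=rng_seed + j, stim_mode=stim_mode
        )
        results[float(rate)] = res
        act = res.activated_downstream()
        for name, members in pops.items():
            frac = len(act & members) / len(members) if members else float("nan")
            rows.append(
                dict(rate_hz=float(rate), population=name, fraction_activated=frac)
            )
    return pd.DataFrame(rows), results


def activation_vs_input_strength(
    result: SimulationResult,
    layer_map,
    graph: ConnectomeGraph,
    hop2_threshold: int = 10,
) -> pd.DataFrame:
    """Median/IQR of taste-input synapse counts for activated vs
    non-activated members of a layer map.

    For 2Ns the metric is total GRN input synapses (hop-1 record); for 3Ns,
    total, excitatory, and net 2N-input synapses (neuron-level signs).
    """
    from .stats import net_excitation_table  # local import avoids a cycle

    act = result.activated_downstream()
    rows = []

    def _summarize(values: pd.Series, layer: str, metric: str) -> None:
        for group, sub in (
            ("activated", values[values.index.isin(act)]),
            ("non_activated", values[~values.index.isin(act)]),
        ):
            if len(sub) == 0:
                rows.append(
                    dict(
                        modality=layer_map.modality,
                        layer=layer,
                        metric=metric,
                        group=group,
                        n=0,
                        median=float("nan"),
                        q1=float("nan"),
                        q3=float("nan"),
                    )
                )
                continue
            rows.append(
                dict(
                    modality=layer_map.modality,
                    layer=layer,
                    metric=metric,
                    group=group,
                    n=int(len(sub)),
                    median=float(sub.median()),
                    q1=float(sub.quantile(0.25)),
                    q3=float(sub.quantile(0.75)),
                )
            )

    if len(layer_map.hop1_strength):
        _summarize(layer_map.hop1_strength["total_syn"], "2N", "grn_input_synapses")
    net = net_excitation_table(graph, layer_map, hop2_threshold, min_inputs=1)
    if len(net):
        _summarize(net["e_syn"] + net["i_syn"], "3N", "total_2n_input_synapses")
        _summarize(net["e_syn"], "3N", "excitatory_2n_input_synapses")
        _summarize(net["net"], "3N", "net_2n_input_synapses")
    return pd.DataFrame(rows)
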