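# taste-connectome

Tools for tracing and quantifying gustatory circuits in a whole-brain
*Drosophila* connectome, and for predicting taste-evoked activity with a
leaky integrate-and-fire (LIF) network model.

## Who this is for

Connectomics and sensory-circuits researchers who want to go from raw
FlyWire-style neuron/connection tables plus lists of seed gustatory
receptor neurons (GRNs — the labellar taste sensory neurons for the sugar,
water, bitter, and IR94e modalities) to a quantitative description of the
downstream taste pathway:

- **Layer tracing** — second-order neurons (2Ns) are neurons receiving a
  GRN connection with a pair total of ≥ 5 synapses; third-order neurons
  (3Ns) require ≥ 10 synapses on both hops (only 2Ns with ≥ 10 total
  same-modality GRN synapses are expanded). 2N/3N lists exclude all
  annotated GRNs, and 3N lists exclude same-modality 2Ns.
- **Circuit statistics** — excitatory/inhibitory feedback and lateral
  matrices (ACh excitatory; GABA and glutamate inhibitory), net excitation
  per 3N (E − I input synapses), a binomial null for sign convergence
  (all-E = pᵏ, all-I = (1−p)ᵏ, mixed = remainder) with a chi-squared
  goodness-of-fit test, sign-motif censuses, and cross-modality
  correlations of net excitation.
- **Anatomy** — partition of output synapses into the subesophageal zone
  (SEZ = {GNG, PRW, SAD, FLA, CAN}) versus other neuropils, ipsi/contra
  laterality from `_L`/`_R` suffixes, local vs projection classification,
  ranked region profiles, superclass/class/neurotransmitter censuses, and
  Fisher exact proportion tests.
- **Input census** — fraction of each 2N/3N's input synapses arriving from
  seed GRNs and from "known taste neurons" (the union of traced GRNs, 2Ns,
  and 3Ns), plus superclass/class censuses of all input partners.
- **LIF simulation** — every neuron is an identical point neuron
  (rest/reset −52 mV, threshold −45 mV, refractory 2.2 ms, synaptic decay
  5 ms, delay 1.8 ms, 0.275 mV per synapse signed by the presynaptic
  neurotransmitter); seed GRNs fire Poisson trains for 1 s over 30 trials
  and any neuron with a nonzero mean rate counts as activated.

A seeded **synthetic connectome generator** emits tables in the same CSV
dialect with planted GRN → 2N → 3N layers, configurable overlap, E/I
composition, SEZ/laterality placement, feedback edges, decoy sub-threshold
edges, and non-taste background — with full ground truth, so every stage is
testable without any external download.

## Worked example

```python
import taste_connectome as tc

graph, seeds, truth = tc.generate(tc.SynthSpec(rng_seed=1))
maps = tc.trace_all(graph, seeds)
for m in ("sugar", "water", "bitter", "ir94e"):
    lm = maps[m]
    print(f"{m:>6}: {len(lm.grn_ids)} GRNs -> {len(lm.second_order_ids)} 2Ns "
          f"-> {len(lm.third_order_ids)} 3Ns")
ov = tc.modality_overlap(maps, "2N")
print("sugar/water shared 2Ns:", ov.count("sugar", "water"))
dist = tc.input_strength_distribution(maps["sugar"], hop=1)
print("median GRN synapses per sugar 2N:", dist["median_total_syn"])
conv = tc.convergence_test(maps["sugar"], graph, k=2)
print(f"sugar k=2 convergence: observed {conv.observed}, "
      f"chi2={conv.chi2:.2f}, p={conv.p:.3f}")
```

prints

```
 sugar: 22 GRNs -> 76 2Ns -> 170 3Ns
 water: 18 GRNs -> 51 2Ns -> 110 3Ns
bitter: 20 GRNs -> 64 2Ns -> 130 3Ns
 ir94e: 9 GRNs -> 24 2Ns -> 75 3Ns
sugar/water shared 2Ns: 28
median GRN synapses per sugar 2N: 17.5
sugar k=2 convergence: observed {'all_e': 12, 'all_i': 7, 'mixed': 21}, chi2=0.18, p=0.915
```

Tracing recovers exactly the planted layers (compare against
`truth.layer_sets(m)`); the 2N counts and the 28-neuron sugar/water overlap
are the generator's defaults. The convergence test here does *not* reject
the binomial null — expected for this generator, which draws 2N signs
independently. The chi-squared statistic is near zero precisely because the
planted circuit has no same-sign convergence structure beyond chance.

Real data work the same way through `tc.load_connectome(neurons_csv,
edges_csv)` and `tc.load_seed_sets({...}, graph)`; column aliases for the
common dump dialects are built in.

The full pipeline (all stages, per-stage CSVs, hashed manifest) runs from
the shell:

```bash
taste-connectome run --seed 1 --out-dir out/       # synthetic input
taste-connectome report out/
```

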