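# Methods

## Scope and data model

The package operates on a whole-brain connectome distributed as two flat
tables: a neuron table (id, superclass, free-text class, hemisphere,
neuron-level neurotransmitter prediction) and an edge table (pre id, post
id, neuropil, synapse count, edge-level neurotransmitter prediction). On
load, duplicate (pre, post, neuropil, NT) rows are summed, and a pair-total
index (synapses per directed pair summed over neuropils) is built. A
"connection" is all synapses between one pre/post pair in one neuropil;
layer tracing, however, operates on pair totals (below). Seed GRNs are
per-modality id lists for the four labellar taste modalities (sugar, water,
bitter, IR94e), left hemisphere.

## Layer tracing

A neuron is a **2N** for modality *m* iff at least one GRN of *m* connects
to it with pair-total synapses ≥ 5 and it is not an annotated GRN of any
modality. **3Ns** use a stricter 10-synapse rule on both hops: only 2Ns
with ≥ 10 total same-modality GRN synapses are expanded, and a 2N→3N pair
must itself carry ≥ 10 synapses; 3N lists exclude all GRNs and
same-modality 2Ns (a 3N may be a 2N of another modality).

Two conventions were genuinely open and are both implemented:

- **Pair-total vs per-neuropil thresholds.** The default applies thresholds
  to pair totals summed across neuropils — the more inclusive reading,
  consistent with "total synapses" language for the hop-1 gate. A
  per-neuropil mode (any single-neuropil connection clearing the threshold)
  is available via `per_neuropil=True`.
- **Strength bookkeeping.** Per-2N fan-in and total GRN synapses count only
  qualifying connections (pair total ≥ the 2N threshold). Counting
  sub-threshold synapses into totals would let connections that failed the
  false-positive filter influence downstream gates; excluding them keeps
  one definition of "connection" throughout.

Raising any threshold can only shrink a layer (tested as a property).
GRN–GRN tallies use raw synapse sums with no threshold by default
(configurable), since they describe crosstalk, not layer membership.

## Sign conventions

ACh is treated as excitatory; GABA and glutamate as inhibitory; dopamine,
serotonin, octopamine, and unknown labels as "other" and excluded from E/I
tallies. Two NT channels exist and are used for different statistics:

- **Edge-level** labels (pooled synapse predictions per connection) drive
  the feedback/lateral matrices and output-composition summaries.
- **Neuron-level** labels (one NT per neuron) drive convergence, net
  excitation, and sign motifs, where each 2N→3N pair must be counted once
  with a single sign.

## Convergence null and statistics

For 3Ns receiving exactly *k* (2 or 3) qualifying same-modality 2N inputs,
input signs are modelled as independent draws that are excitatory with
probability *p*, estimated from the analyzed population's inputs; expected
category proportions are all-E = pᵏ, all-I = (1−p)ᵏ, mixed = the
remainder. Observed counts are compared with a plain chi-squared goodness
of fit (no continuity correction; categories with zero expectation are
dropped with a warning; dof = retained categories − 1). Results with fewer
than 10 analyzable 3Ns are flagged, not suppressed silently. 3Ns with any
"other"-signed input are excluded. Note the null's *p* is estimated from
the same sample, which makes the test slightly conservative; the package
reports the statistic as the field convention dictates.

Net excitation per 3N is e_syn − i_syn over qualifying inputs.
Cross-modality correlation regresses net excitation in one modality on
another over shared multi-input 3Ns via OLS (statsmodels); 2Ns belonging to
both modalities are deliberately counted for both, and the result carries a
`double_counting_possible` flag. Fisher exact tests (scipy) compare
proportions between modalities.

## Anatomy

The SEZ is the neuropil set {GNG, PRW, SAD, FLA, CAN}; membership is
decided on the base code after stripping `_L`/`_R`, so lateralized halves
agree by construction. Local neurons have all qualifying output connections
(per-neuropil, ≥ 5 synapses) inside the SEZ; neurons with no qualifying
output at all are reported separately. Synapse-level partitions conserve
two identities asserted on every run: SEZ + outside = total, and ipsi +
contra + non-lateralized = outside. Region profiles pool `_L`/`_R`, rank by
pooled synapse count with ties broken by count then lexicographic code
(ties at the boundary flagged), and report coverage of the selected top-k.
"Ipsilateral" defaults to the left hemisphere, where the traced GRN arbors
live; it is configurable.

## Input census

"Known taste neurons" are the union of seed GRNs, 2Ns, and 3Ns over all
four modalities — an underestimate of true taste input, since
right-hemisphere and non-labellar taste neurons are not annotated. Input
fractions use all input synapses in the denominator (no threshold);
neurons with zero input synapses are excluded with a count recorded.
Partner censuses count distinct presynaptic neurons (once per modality and
layer) whose pair-total connection clears the 5-synapse threshold; a
synapse-weighted variant and a no-threshold switch exist.

## LIF model

Identical point neurons with

    dv/dt = (v_rest − v + g) / tau_mem,   dg/dt = −g / tau_syn,

v_rest = v_reset = −52 mV, threshold −45 mV, refractory 2.2 ms,
tau_syn = 5 ms, delay 1.8 ms, and 0.275 mV of drive per synapse, signed by
the presynaptic neuron-level NT (ACh/DA/SER/OCT +1, GABA/GLUT −1 by
default; unknown-NT neurons contribute no drive by default, switchable to
excitatory). One weight per directed pair = w_unit × pair-total × sign.
**tau_mem is not constrained by the connectome data; the 20 ms default is a
conventional fly central-neuron membrane time constant** and is echoed into
every result object so reported numbers carry the assumption.

Numerics: fixed step dt = 0.1 ms; the linear (v, g) system is advanced with
an exponential integrator that is exact between spike-arrival boundaries
(falling back to a held-drive exponential-Euler step in the degenerate
tau_syn = tau_mem case); delays use a ring buffer of pending drive
increments quantized to whole steps; the membrane is frozen for the full
refractory window (the first re-integrated interval starts at
t_spike + t_refractory). dt must be below every time constant or the run is
refused. Stimulated seeds are Bernoulli-per-step approximations of Poisson
trains at the nominal rate (exact to O(rate·dt)); a regular-train mode
exists for deterministic tests. Trials derive child seeds from one master
seed, so identical seeds give identical rasters. Stimulation protocol
defaults: 1 s, 30 trials, rates {25, 50, 100, 150, 200} Hz; "activated"
means mean rate > 0, and stimulated seeds are excluded from downstream
activation summaries.

## Synthetic connectome generator

The generator emulates the structural features the analyses depend on, with
full ground truth:

- Layer sizes default to the study conditions (22/18/20/9 GRNs,
  76/51/64/24 2Ns) with planted pairwise 2N overlaps 28 (sugar–water),
  8 (bitter–IR94e), and 6 (bitter–water). Default 3N layers are scaled to
  about a third of the study's (170/110/130/75) to keep the default brain
  at desk scale (~700 neurons); the sugar-pair 3N overlaps (67/43/22) are
  scaled from the study's stated percentages of sugar 3Ns, and the
  remaining pairs (25/16/20) are plausible mid-range choices made once.
- Suprathreshold synapse counts follow threshold − 1 + Geometric(p)
  (p = 0.35 hop 1, 0.20 hop 2), giving the heavy right tail of real
  connection-strength distributions and hop-1 medians near 15–17 synapses
  from 1–4 GRNs. An optional mode couples fan-in to per-input strength
  (off by default).
- Excitatory fractions per (modality, layer), SEZ output fractions, and a
  contralateral fraction of 0.3 mirror the qualitative modality
  differences (aversive 2Ns more inhibitory and more projecting).
- Decoy GRN edges (1–4 synapses), sub-threshold-band 2N outputs and
  feedback/lateral edges (5–9 synapses), GRN–GRN crosstalk, and non-taste
  background inputs (mechanosensory, olfactory, ascending/descending
  classes) exercise every filter.

Planting discipline: every planted GRN→2N pair clears the 5-synapse
threshold and every planted 2N accumulates ≥ 10 GRN synapses per modality;
planted 2N→3N edges (≥ 10 synapses) are drawn only from modality-*exclusive*
2Ns, and all edges with a 2N presynaptic side outside the planted set stay
in the 5–9 band and pair-unique — so the planted layer sets are *exactly*
what correct tracing must return, which is what the recovery tests assert.

What the generator does **not** emulate: morphology and spatial synapse
placement, the real brain's global degree distribution and scale (~140k
neurons), triple or higher-order planted overlaps, cross-layer identity
(planted 3Ns are never 2Ns of another modality, although the tracer
supports it), correlated sign structure between converging inputs (signs
are drawn independently, so the convergence null is *true* in synthetic
data — tests assert calibration, not rejection), and synapse-level NT noise
(edge labels equal the presynaptic neuron label). Passing tests therefore
demonstrate correctness of the machinery under known ground truth, not any
biological claim about real connectomes.

## Pipeline

`run_all` executes io → trace → stats → anatomy → census → simulate,
writing per-stage CSVs and a manifest with a config hash and SHA-256 of
every output; one master seed fans out per-stage child seeds so stages
rerun independently yet reproducibly. Stage failures abort with
stage-tagged diagnostics. The CLI exposes `synthesize`, `run` (with
threshold flags and `--no-simulation`), and `report`; per-stage
operations are the library functions themselves rather than separate
subcommands.

## Problem sizes

Default test and reproduction runs use the ~700-neuron default synthetic
brain (full-size 2N layers, one-third-scale 3N layers); unit fixtures use
hand-built graphs of 2–10 neurons and a ~170-neuron small spec. The
reproduction script's LIF stage runs the full 30-trial, 1-second protocol
at two rates on that brain.

## Known limitations

- Real codex dumps vary in column naming and filtering; the alias table
  covers the common variants but not every release.
- The chi-squared null uses estimated p with dof 2 (field convention),
  slightly conservative.
- The LIF model assumes identical biophysics for every neuron and signs
  monoamines as excitatory; both are explicit, configurable assumptions.
- Region assignment comes entirely from the edge table's neuropil field;
  there is no synapse-coordinate-based assignment.
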