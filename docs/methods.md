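# Methods

## Model

Neurons are conductance-based leaky integrate-and-fire units on a
two-dimensional "dish", a minimal stand-in for dissociated neuronal
culture. The membrane potential of every neuron follows

    tau_m dV/dt = (V_rest - V) + R_m [ g_e (E_e - V) + g_i (E_i - V) ]

with tau_m = 30 ms, R_m = 100 MOhm, V_rest = -60 mV, E_e = 0 mV,
E_i = -100 mV. Synaptic conductances decay exponentially (tau_e = 2 ms,
tau_i = 4 ms) and jump instantaneously when a presynaptic spike arrives.
Spikes are delivered, and voltages reset, in the integration step after
emission (dt = 1 ms by default); there are no conduction delays and no
stochasticity anywhere, so identical inputs give byte-identical output.

Two short-term plasticity mechanisms operate on excitatory neurons only:

- **Short-term depression (STD).** Each excitatory neuron carries a resource
  variable x in (0, 1]; a spike releases the fraction U = 0.4 of it
  (conductance jump proportional to U x w, then x -> (1 - U) x) and x
  recovers toward 1 with tau_x = 150 ms. Because transmission is
  deterministic, x lives on the presynaptic neuron rather than on
  individual synapses.
- **Threshold adaptation (TA).** The firing threshold is
  V_theta = theta0 + theta with theta0 = -54 mV; every spike increments
  theta by 1 mV and theta decays with tau_theta = 1 s. Inhibitory neurons
  are fast-spiking cells with a fixed threshold theta0 and a 2 ms
  refractory period (3 ms for excitatory neurons; V is clamped to
  V_reset = -74 mV during the clamp while conductances, x and theta keep
  evolving).

Ablations: `std_enabled=False` pins x to 1 (instant recovery) while
keeping the U factor in the increments, so the recovered EPSP is unchanged;
`ta_enabled=False` pins the threshold to theta0.

### Calibrated quantities

Three quantities of the model are fixed by function rather than printed
value:

- **epsp_scale** (fitted, ~137 at default parameters): the raw weight
  w = 0.1 nS does not by itself produce the model's defining unitary EPSP
  of k = 1.4 mV under any standard delta-pulse convention, so all
  conductance jumps carry one dimensionless factor fitted (by bisection on
  a two-neuron simulation) so that a single fully recovered excitatory
  spike depolarizes a resting neuron by exactly k. Everything downstream —
  the depression-loss estimate D, the stimulus calibration, the network
  regime — uses this calibrated synapse.
- **inh_scale = 0.7**: the relative size of inhibitory conductance jumps
  (in units of w * epsp_scale). No functional anchor for inhibition is
  available at the single-synapse level, but two network-level constraints
  bracket it tightly: stimulus responses must recruit most of the network
  from the recovered state (at least 500 of 1000 responders at every
  stimulation site — the responsiveness screen), which fails for
  inh_scale >= ~0.85 at any stimulus amplitude, and responses must die out
  within the trial window even with all plasticity ablated (no ongoing
  activity; this is also what makes the no-plasticity deviance detection
  index exactly zero), which fails below ~0.6 where networks reverberate.
  The default sits at the midpoint of the feasible band, fixed once before
  any ensemble statistics were computed.
- **stim_amplitude** (calibrated per network, ~1.6 uS at defaults):
  stimulation is a one-time g_e increment to the 10 neurons nearest a site
  center, sized to trigger 2-3 spikes in each. Because recurrent feedback
  adds occasional extra spikes on top of any direct response, the
  calibration counts each stimulated neuron's response in isolation;
  neurons are homogeneous within a type, so this reduces to the two cell
  types. The direct spike count is monotone in the amplitude, giving one
  contiguous valid band (~0.5-5.6 uS); the returned amplitude is the grid
  point at the band's geometric middle, keeping the stimulus robustly in
  the 2-3 spike regime. The band's lower edge, where every neuron fires
  exactly 2 direct spikes, does not recruit the network at all.

## Networks

800 excitatory and 200 inhibitory neurons are placed uniformly by area in
a 4 mm-radius disk (radius sampled as R sqrt(u)). Each neuron forms
synapses of weight w = 0.1 nS onto 50 partners drawn uniformly without
replacement among the neurons within 2 mm (excitatory) or 1 mm
(inhibitory); no self-connections, at most one synapse per ordered pair,
and all in-range candidates are used when fewer than 50 exist. Five
stimulation sites sit on a concentric 2.5 mm circle, site 1 at angle 0 and
the rest at 72-degree steps; nearest-neuron ties break by index.
Uniform-by-area placement puts on average ~227 of 1000 neurons within 2 mm
of a site center (the analytic circle-intersection fraction 0.2270), which
is what the local/global fatigue split relies on.

Generated networks are screened: each site is stimulated once from the
fully recovered state, and the network is kept only if every site recruits
at least 500 neurons (one spike or more within the trial window).
Candidates failing screening (or stimulus calibration) are regenerated
with incremented seeds, so an accepted ensemble is reproducible from its
master seed; roughly half to two thirds of random networks pass at default
parameters.

## Paradigm

Sequences present 500 instantaneous stimuli at a regular stimulus onset
asynchrony (SOA, default 500 ms), in three compositions around a target
site A and a non-target B: 80% A / 20% B (`A-as-std`), 20% A / 80% B
(`A-as-dev`), and 20% of each of the five sites (`A-in-con`, the
many-standards control). Orders are unconstrained uniform shuffles with
exact composition. Each network contributes four data sets with the
target/non-target pairings 1/2, 2/1, 3/5 and 5/3; the two pairings of a
site pair read the same physical oddball stream in opposite roles, and one
control sequence is shared within a network, so a network-condition cell
costs five sequence runs. The state is reset to fully recovered between
sequences, and sequence seeds are shared across plasticity conditions so
conditions are compared on identical streams.

The deviance detection index of a data set is

    DDI = (R_dev - R_con) / (R_dev + R_con)

where R_dev and R_con are the across-neuron mean target responses (spikes
per target trial) in the deviant and control sequences. Means include the
10 stimulated neurons; their contribution changes the index negligibly.
Population summaries use the median across the indicated neurons unless a
mean is stated. The contrast of any quantity is deviant-sequence minus
control-sequence. The depression-loss estimate for neuron i and stimulus S
sums, over its excitatory presynaptic partners j, the partner's
cross-sequence mean response to S times (1 - mean x_j at S-trial onsets)
times k — the peak EPSP (in mV) the neuron did not receive because its
inputs were depressed.

## Numerics

- Conductances, x and theta decay by exact per-step exponential factors;
  only the voltage equation uses forward Euler (unconditionally stable at
  dt = 1 ms given the exact conductance decay). One step runs: deliver
  pending spikes, decay, integrate V, threshold test, apply spike updates.
  The voltage is additionally clipped to [min(E_i, V_reset), E_e] — the
  physical reversal bounds — which matters only in the stimulus-delivery
  step, where the commanded conductance is enormous.
- Euler voltage integration converges linearly in dt against the exact
  membrane solution: on scripted-input trajectories the deviation is
  ~2.3% of the trajectory range at dt = 0.1 ms and under 1% at
  dt = 0.025 ms. At the working dt = 1 ms the discretization is part of
  the model definition (as is common for fixed-step network simulations),
  not an approximation target.
- Between trials, once the network is provably quiescent (no spikes in
  flight, conductances below 1e-12 nS, no refractory clamp, every V below
  theta0), no threshold crossing can occur before the next stimulus, and
  the state is advanced to the next onset in closed form. Membrane
  residuals below 1 uV are flushed to rest and plasticity residuals below
  1e-12 to their fixed points during this jump; sub-microvolt offsets are
  orders of magnitude below anything that could move a spike. This is what
  makes 500-trial runs cheap (most of each 500 ms window is silence) and
  it also guarantees that the no-plasticity model returns to exactly the
  recovered state before every trial, making its per-trial responses
  bitwise identical and its DDI exactly zero. Fast-forward is suspended
  while dense trace averaging is active, and disabling it entirely changes
  no spike times.
- Dense traces for the threshold-vs-voltage attribution analysis are
  accumulated as running trial averages (spike probability, V, theta per
  excitatory neuron and in-trial time step), which is all the attribution
  consumes; per-trial dense traces are never materialized. Attribution
  bins where the firing difference is positive but neither a lower
  threshold nor a higher voltage is present (a 0/0 case) are dropped from
  the mask. The weighted network time courses divide by the mask size at
  each step.
- Wilcoxon signed-rank tests drop exact zeros, use exact enumeration for
  n <= 15 and the normal approximation with continuity and tie correction
  otherwise; the Z statistic always comes from the approximation. The
  Pearson "Wald" p-value refers the slope z-score to the standard normal.
  Bootstrap median intervals are percentile intervals over 10000 seeded
  resamples. Brown-Forsythe is the median-centered Levene F; the t-test is
  pooled-variance. All delegated to scipy.stats behind stable contracts.

## Scaling and what the tests show

Full scale is 30 networks x 4 pairings x 4 conditions (120 data sets per
condition) — an overnight run. The test suite and the acceptance script
use a scaled-down ensemble of 6 networks (24 data sets) with full-length
500-trial sequences, which reproduces the ensemble medians to within the
stated tolerances while keeping a run in minutes; single-network checks
use 1-3 networks, and unit tests use ~150-neuron networks with the same
geometry. Medians of the deviance detection index over 24 data sets still
carry sampling scatter of roughly +-0.03-0.05 across master seeds because
the per-data-set DDI distribution is wide (roughly -0.3 to +0.6 with bulk
between 0 and 0.2).

The synthetic networks emulate spatially random, distance-limited
connectivity with homogeneous cell parameters; they do not model laminar
or columnar structure, distance-dependent connection probability or
weights, conduction delays, synaptic facilitation, inhibitory-neuron
adaptation, spontaneous activity, or stimulus tuning. Passing tests
therefore show that the local/global fatigue mechanism produces true
deviance detection in this idealized medium, not that it quantitatively
matches any particular biological tissue.

## Known limitations

- The no-plasticity condition is the slowest to simulate (no adaptation
  quenches the response, so activity lasts longer per trial) and is run on
  a single network where exactness, not ensemble statistics, is at stake.
- The inhibitory strength and the stimulus amplitude are fixed by
  network-level function (see Calibrated quantities); other choices inside
  their feasible bands would change ensemble DDI magnitudes somewhat.
- At very short SOAs (50-100 ms) trials overlap with the tail of the
  previous response; the trial-windowed response attribution still holds
  but "recovered-state" normalizations become less meaningful.
- `run_experiment` keeps one network-condition cell of spike records in
  memory at a time (~30 MB); full-scale runs are CPU-bound, not
  memory-bound.
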