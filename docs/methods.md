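# Methods

`dgnet` implements a multi-scale model of the dentate gyrus (DG): single
conductance-based granule cells (GC) and basket cells (BC), stochastically
searched heterogeneous populations of them, virtual ion-channel knockouts,
a GC-BC microcircuit driven by simulated entorhinal inputs during a
virtual arena traversal, and response ("channel") decorrelation
statistics. This note records the models, the tunable parameters, the
numerical choices, and what the synthetic data do and do not emulate.

## Single-neuron models

Each neuron is a single cylindrical compartment. The GC base geometry is
63 um x 63 um with V_RMP = -75 mV, R_m = 38 kOhm cm^2 and
C_m = 1 uF/cm^2, which fixes the passive skeleton at R_in = R_m / (pi d L)
= 305 MOhm and tau = R_m C_m = 38 ms. The BC is 66 um x 66 um with
V_RMP = -65 mV and R_m = 7.1 kOhm cm^2 (passive R_in ~ 52 MOhm).

Active currents: GCs express NaF, KDR, KA, HCN, SK, BK (ohmic, Nernstian
driving force; E_Na = +54.3 mV, E_K = -88.2 mV, E_HCN = -30 mV at 34 C)
and CaT, CaN, CaL (GHK current equation with the dynamic cytosolic
calcium as the inner concentration, 2 mM outside). BCs express NaF, KDR,
KA and HCN only. Ion concentrations (mM): Na 18/140, K 140/5, Cl 5/98,
Ca 5e-5/2.

Cytosolic calcium follows a single-shell first-order scheme,

    d[Ca]/dt = -10000 I_Ca / (3.6 dpt F) + ([Ca]_inf - [Ca]) / tau_Ca,

with I_Ca in mA/cm^2, shell depth dpt = 0.1 um, [Ca]_inf = 50 nM and
tau_Ca = 160 ms, giving mM/ms. The influx denominator constant (3.6) is
configurable (`CalciumHandling.influx_denominator`); it only rescales the
influx gain, which the search ranges absorb.

### Gating kinetics

Published DG models cite channel kinetics to a body of experimental
literature rather than printing them; `dgnet` therefore ships its own
calibrated registry in the canonical Hodgkin-Huxley idiom: Boltzmann
steady states `x_inf(v) = 1/(1+exp(-(v-v_half)/k))` and sigmoidal
voltage-dependent time constants, with gate exponents NaF m^3 h, KDR n^2,
KA a b, HCN single gate, CaT/CaN m^2 h, CaL m^2. SK is gated purely by
calcium (Hill coefficient 4, kd 5 uM, tau 15 ms); BK needs depolarization
and calcium (Hill 2, kd 2 uM, Boltzmann v_half -5 mV, tau 1.2 ms). The
registry values were hand-calibrated so that the GC base model lands
inside all nine experimental validation bounds (slow adapting firing,
f150 ~ 13 Hz) and the BC base model is fast-spiking (f150 ~ 40 Hz, no
adaptation). Every entry is per-model configuration, not fixed physics.

The leak reversal is *balanced* at construction: E_leak is chosen so the
full model rests exactly at V_RMP with every gate at steady state. A
knockout copy keeps the base model's E_leak, so deleting a
resting-active channel (HCN) hyperpolarizes the cell and raises R_in, as
it should.

## Measurements

Nine measurements, computed from fixed current-clamp protocols at
dt = 25 us after a 500 ms settling period:

| symbol  | definition | protocol |
|---------|------------|----------|
| R_in    | slope of V-I fit over steady-state deflections | 11 pulses, -50..+50 pA, 1000 ms |
| sag     | steady-state / peak deflection | -50 pA pulse |
| V_AP    | first-AP peak minus resting potential | +150 pA, 1000 ms |
| V_th    | voltage where dV/dt first crosses 20 V/s | same trace |
| T_APHW  | width at half-maximum relative to threshold (linear interpolation) | same |
| V_fAHP  | post-AP minimum minus threshold | same |
| SFA     | first ISI / last ISI (undefined below 3 spikes) | same |
| f50, f150 | spike count in the 1 s window | +50 / +150 pA |

Steady-state windows are the final 100 ms of a pulse; spike counting for
rates uses an upward 0 mV crossing with a 2 ms refractory hold (distinct
from the 20 V/s threshold *measurement* rule). Defaults use 1000 ms
pulses throughout; durations are arguments where a shorter variant is
wanted.

## Stochastic search (MPMOSS)

Rejection sampling: parameter vectors are drawn uniformly and
independently within configured ranges and a candidate is retained only
if all nine measurements fall inside closed experimentally derived
intervals (GC: V_AP 95-115 mV, V_th -55..-40 mV, T_APHW 0.53-1.6 ms,
V_fAHP -25..-3.4 mV, sag 0.9-1, SFA 0.1-0.8, R_in 107-228 MOhm, f50 = 0,
f150 10-15 Hz; BC analogous with fast-spiking bounds). The GC space has
exactly 40 dimensions (9 maximal conductances/permeabilities at 0.5-2x
the base values; R_m, C_m, V_RMP; tau_Ca, dpt; 11 per-gate half-voltage
shifts of +/-3 mV; 11 per-gate time-constant scale factors 0.8-1.3x; SK
kd/tau and BK kd/tau), the BC space exactly 18. The exact composition of
the published search tables is not available; the shipped tables are a
documented stand-in with the correct dimensionality, and all ranges are
configuration.

The search evaluates the 150 pA and -50 pA protocols first and discards
candidates that already violate the suprathreshold or sag bounds before
running the 11-pulse battery; retained models are always re-measured in
full, so the staging changes speed, not results. Integration failures
(numerically exploding parameter combinations) count as rejections.

The shipped populations (`dgnet/data/*.json`) come from a 4000-sample GC
search (27 valid, 0.68%) and a 1500-sample BC search (38 valid, 2.5%;
first 20 stored). Every stored model re-passes validation bit-exactly
when rebuilt from its parameters (asserted in the test suite).

## Virtual knockouts

A knockout zeroes one channel's maximal conductance/permeability in a
copy of the model; everything else, including E_leak, is untouched.
Impact on a measurement is the percentage change
`100 (M_ko - M_base) / M_base`; undefined values (no spikes, zero base)
propagate as missing, never as zero, and are excluded pairwise. Sweeps
summarise per-channel distributions as quartiles (linear interpolation).
NaF and KDR are excluded from sweeps (their removal abolishes firing or
repolarization), as is f50 (pinned at zero by validation).

## Afferent synthesis

The virtual animal starts at the centre of a 1 m x 1 m arena; direction
(uniform 0-360 deg) and step length (uniform 2.5-3.5 mm, the printed
speed band applied per 1 ms update) are redrawn every millisecond, and
steps that would cross the boundary are redrawn. ~1000 s suffices to
visit essentially every 1/25th of the arena.

Each DG neuron receives 5 MEC grid-cell and 5 LEC tile inputs, weighted
equally. A grid cell's drive is the hexagonal three-cosine field psi
(wave angles theta + {pi/12, 5pi/12, 3pi/4}, spatial prefactor
k = 4 pi lambda / sqrt(6)); lambda is drawn uniformly from 2-6 per
metre (the printed "2-6 Hz" read as a spatial frequency over the 1 m
arena, giving several firing fields per cell) and theta from 0-360 deg.
psi is exactly 1 at the cell's offset and bounded in [0, 1]. LEC cells
are random binary 5 x 5 tilings (tiles independently active with
probability 0.5, a configurable parameter). The total afferent current is
`gain * scale * (mean grid + mean LEC)/2` in pA, piecewise constant per
millisecond.

## Network

Default 100 GC / 15 BC (large variant 500/75, same ratio). Bernoulli
connectivity: P(BC->GC) = 0.1 (GABA_A), P(GC->BC) = 0.05 (AMPA). Both
receptor currents are GHK: AMPA as equal-permeability Na + K components
(composite reversal -2.3 mV, i.e. ~0 mV), GABA_A as chloride (reversal
-78.8 mV). Gates are normalized double exponentials (rise 2 ms, decay
10 ms, peak exactly 1 for a single spike); multiple presynaptic spikes
superpose linearly with the gate clipped at 1. There is no synaptic
transmission delay (configurable choice left at zero). Synaptic
heterogeneity multiplies each synapse's permeability by U[0.5, 1.5]; the
bounded range maintains the excitation-inhibition regime by
construction. Permeabilities are densities over the postsynaptic
membrane, so a synapse onto a smaller cell delivers proportionally less
absolute current -- consistent with the low synaptic connectivity of
immature neurons.

### Heterogeneity axes

* **Intrinsic** -- draw distinct valid models (without replacement while
  the pool lasts) vs clones of one model.
* **Synaptic** -- per-synapse permeability factors U[0.5, 1.5] vs fixed.
* **Structural** -- GC diameters: mature 63 um, fully immature U[2, 9] um,
  heterogeneous age U[2, 63] um (length scales with diameter; BCs stay
  mature). Densities are untouched, so R_in scales inversely with area.
* **Afferent** -- identical (one spec set shared; input correlations
  exactly 1) vs heterogeneous (independent per-neuron draws).

A single-compartment model whose drive scales exactly with membrane area
is scale-invariant -- structural heterogeneity would be a no-op. Two
deliberate asymmetries break this degeneracy, both with biological
grounding: synapses follow the density convention above, and the
afferent area-ratio scaling `(d/63)^2` is floor-clipped at 0.005, so the
smallest cells are relatively over-driven. The floor was calibrated
against the rate targets alone: among {0.005, 0.0075, 0.01}, 0.005 gives
a fully-immature network whose median peak GC rate (6.9 Hz) matches the
mature configuration with the lowest across-cell variability and no
silent cells. The high excitability of immature neurons thus survives
the drive reduction, as the biology requires.

### Calibration

The global afferent gain (210 pA at unit drive) and the BC gain factor
(1.2, compensating the basket cells' ~6x lower input resistance) were
chosen so that on the scaled reference network the median per-cell peak
firing rate (2 s Gaussian smoothing) sits at ~7 Hz for GCs (experimental
band 4-10 Hz) and ~38 Hz for BCs (band 30-50 Hz), across all four
heterogeneity presets.

### Network knockouts

`network_knockout` zeroes one channel across the GC or the BC population,
leaving connectivity, synapses, seeds and the afferent bank untouched;
base and knockout simulations therefore consume bit-identical input
streams. NaF and KDR are refused with an explanatory error: without
spiking there is no rate or correlation to compare. Seven GC channels
and two BC channels are eligible; crossed with the base condition and
the four heterogeneity presets this yields the 40-configuration grid in
`dgnet.experiment`.

## Analysis

Instantaneous rates: 1 ms binarized spike trains convolved with a
normalized Gaussian (sigma 50 ms for all correlation computations; 2 s
for display/peak-rate maps -- the kernel width materially changes
pairwise correlations, so the two defaults are kept separate). Reflected
boundaries preserve the spike count exactly. Overall rate = count /
duration. Spatial maps are occupancy-weighted mean rates on a 50 x 50
grid (unvisited bins are missing, not zero).

Channel decorrelation: Pearson correlations between GC rate arrays
(output matrix) and between total afferent currents (input matrix);
lower-triangle vectors feed cumulative histograms and the
input-correlation-binned summaries (bin width 0.1; mean +/- SEM per
bin; identical afferents collapse to the single bin at 1). Knockout
impact: dF = F_ko - F_base (plain difference, Hz) per cell and
dR = 100 (R_ko - R_base)/R_base per pair, with |R_base| < 0.01 flagged
undefined (the percentage otherwise explodes) and the exclusion count
always reported. Zero-variance (silent) cells yield missing
correlations, excluded the same way.

## Numerics

Exponential Euler for all gating variables, forward Euler for voltage
and calcium. dt = 25 us everywhere, including network simulations: the
fast-spiking BC model (strong NaF) is unstable at 50 us under forward
Euler, so the coarser step is not used. Halving dt changes the GC base
measurements by < 2% (f150 by at most one spike). Cytosolic calcium is
floored at 0.1 nM to keep the GHK logarithms defined. The kernels detect
numerical blow-up (|v| > 500 mV) and abort with the offending neuron
identified; the search treats such candidates as rejections. Simulations
settle 200-500 ms at rest before stimuli or traversal. All randomness
flows through explicit seeds (`numpy.random.default_rng` in Python,
seeded `numpy.random` inside the compiled trajectory kernel), making
traces, populations, networks and experiment cells bit-reproducible.

## Problem sizes

Full-scale runs of the published design (1000 s traversals of a 100/15
network across 40 configurations) are cluster-scale. The package's own
reference conditions, used by the test suite and examples, are a
20 GC / 3 BC network driven by a 100 s traversal (the structure of the
analysis is size-invariant; the 500/75 variant runs through the same
code path and is smoke-tested at short duration). The robustness
comparison (knockout-induced |median dR| in fully-immature vs
fully-mature networks) is asserted at these conditions with the BK
knockout, the channel with the largest single-cell rate impact.

## What the synthetic data do not emulate

The virtual animal is a bounded random walk, not rodent locomotion (no
speed autocorrelation, head direction or wall-following); entorhinal
inputs are noise-free deterministic currents, not spiking afferents;
networks lack mossy cells, other interneuron classes, synaptic
transmission delays, plasticity, and any compensatory response to
knockout (the acute impact only). Passing tests therefore show that the
implemented mechanisms -- degeneracy under validation, channel-specific
knockout signatures, input-correlation-dependent decorrelation,
structural-heterogeneity resilience -- behave correctly in this idealized
setting; they do not certify quantitative transfer to real DG circuits.
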