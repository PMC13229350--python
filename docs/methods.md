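# Methods

## Scope and model summary

`pfceeg` simulates a human prefrontal layer-2/3 microcircuit of 1000
neurons — 72% pyramidal (Pyr), 9% parvalbumin (PV), 5% somatostatin (SST)
and 14% VIP interneurons — placed uniformly at random in a
500 × 500 × 950 µm³ block 250–1200 µm below the pia, and connected by
independent Bernoulli draws per ordered pair with class-specific
probabilities and compartment targeting.  The human Pyr→Pyr connection
probability (0.15) is a measured constraint; the remaining entries of the
probability/conductance table follow standard rodent L2/3 motifs and are
free calibration parameters exposed in the config.

The purpose of the model is to map graded reductions of PV and SST
interneuron inhibition — the microcircuit changes implicated in
schizophrenia by postmortem expression studies — onto three families of
observables: baseline and oddball-response spiking, the mismatch-negativity
(MMN) amplitude of the simulated EEG, and resting-EEG spectral features
(aperiodic offset/exponent, band powers, dominant periodic peak).

## Reduced neuron and synapse model

Neurons are adaptive exponential integrate-and-fire (AdEx) somata.  Pyr
cells additionally have one passive apical compartment coupled to the soma
by a fixed conductance g_c; interneurons are single-compartment.  Per-type
parameters (capacitance, leak, threshold, adaptation a/b/τ_w) give regular
spiking with slow adaptation for Pyr, fast spiking with negligible
adaptation for PV, and adapting profiles for SST and VIP.  This replaces
the multi-channel reconstructed-morphology models of the detailed-modelling
literature; what is retained is exactly the architecture that carries the
effects studied here: compartment targeting (PV→basal/somatic, SST→apical),
receptor kinetics, background drive and tonic inhibition.

Synapses are conductance-based double exponentials, peak-normalized, with
AMPA (τ 0.3/3 ms), NMDA (2/65 ms) and GABA_A (1/10 ms), reversals 0 /
−80 mV, and a fixed 0.5 ms delay.  AMPA:NMDA is 1:1 for excitatory
connections except onto PV interneurons (1:0.2 recurrent, 1:0.5 for
stimulus afferents).  NMDA carries the Jahr–Stevens magnesium block
1/(1 + ([Mg]/3.57)·e^(−0.062V)) at 1 mM.  Multi-contact synapses are
collapsed into one effective conductance per connection (per-contact
conductance × contact count).

Tonic inhibition is an outward-rectifying conductance of density
0.938 mS/cm² on every neuron (rectification sigmoid: midpoint −60 mV, slope
10 mV), converted to nS through a per-compartment effective membrane area.
Its attribution — what disease scaling acts on — is split 50/50 between PV
and SST sources; on Pyr cells the PV share sits on the basal/somatic
compartment and the SST share on the apical compartment, mirroring the
synaptic targeting of the two classes.

## Background drive and calibration

Background excitation is an excitatory Ornstein–Uhlenbeck (OU) conductance
per neuron (base means 28/280/30/66 pS for Pyr/PV/SST/VIP before scaling),
with correlation time 3 ms at the soma.  Pyr apical dendrites receive five
further OU processes at relative distances 0.1–0.9, each scaled by
exp(x_rel); because same-τ OU processes are closed under addition, the five
are simulated as their exact sum (an OU with μ = Σμᵢ, σ = √Σσᵢ²).  The
apical processes use a slower correlation time (25 ms), representing the
slow envelope of background cortical/thalamic input to the distal tree;
this is what gives the simulated EEG its falling (1/f-like) background over
3–30 Hz, since the apical-somatic potential gradient is the dipole source.
OU SD is 70% of the mean and conductances are clipped at zero.

Per-neuron excitability heterogeneity is a lognormal factor (CV 0.4, unit
mean) on each neuron's OU mean, drawn from the circuit's placement seed —
it is part of the randomized microcircuit's identity, not of the run.
Without heterogeneity the population f–I relation is implausibly steep
(all-or-none recruitment), population rates are brittle under calibration,
and the sparse participation that carries the circuit rhythm (below) cannot
form.

`calibrate_background` scales the per-population OU means to reach the
target baseline rates — Pyr 0.94 Hz, PV 7.44 Hz, SST 3.28 Hz, VIP 2.22 Hz,
the rates the detailed-model literature reports for this circuit in health
— by per-population multiplicative bracketing/bisection inside an outer
loop over populations (rate is monotone in own drive; cross-couplings are
absorbed by repeating the outer loop).  Default tolerance ±15%; a
non-converged calibration is reported, never silent.  The shipped config
stores scales for which the default circuit calibrates at factors ≈ 1.

## The circuit rhythm

The resting EEG of the healthy circuit shows a periodic peak on the 1/f
background, generated by a slow excitatory-inhibitory loop: recurrent
Pyr→Pyr excitation onto apical dendrites (AMPA+NMDA, with the 65 ms NMDA
tail), feedback through SST interneurons onto the same apical compartments,
and spike-frequency adaptation in Pyr cells pacing burst recovery.  Sparse
participation (~10% of Pyr per cycle at 0.94 Hz mean rate) requires the
excitability heterogeneity above.  At the calibrated operating point the
dominant peak sits in the high-alpha/low-beta range (circuit-to-circuit
centers spread over roughly 9–19 Hz; see limitations), higher than the
11.2 Hz the detailed models produce; a tight ~10 Hz rhythm emerges in this
reduction only when SST interneurons run well above their calibrated 3.28 Hz
target, so the calibration constraint and the rhythm position trade off.
The fast PV loop also sustains a weaker gamma-band (~40 Hz) oscillation
outside the analysis range.

Pyr→Pyr recurrence targets the apical compartment by design: lateral and
top-down excitation in cortex arrives predominantly on the apical tree,
and in a two-compartment reduction this is what makes the recurrent drive
an apical current sink — the generator of the negative-going mismatch
deflection — while bottom-up stimulus input targets the basal compartment.

## EEG forward model

Each Pyr cell contributes a current dipole p_z = g_c·(V_s − V_a)·d with
separation d = 400 µm along the apical (radial) axis; the somatic
action-potential excursion is clamped at threshold in the dipole sum (the
point-soma spike waveform is not a physical dipole source).  A depolarized
apical compartment (apical sink) therefore yields a negative potential at
an overlying electrode.  The summed moment is placed as a single equivalent
radial dipole 0.7 mm below the brain surface of a four-sphere head model
(radii 79/80/85/90 mm; conductivities 0.47/1.71/0.02/0.41 S/m) and read out
at a vertex electrode directly above.  The solution is the standard
Legendre series with matched boundary conditions per shell, solved
numerically per harmonic in a normalized basis (default order 60 with a
tail-convergence check and automatic order escalation).  Its oracle in the
test suite is the closed-form homogeneous-sphere dipole potential, which
the model must match to <1% when all conductivities are equal.

## Oddball protocol and MMN

A deviant tone at t₀ activates 150 Pyr cells (three basal-input phases,
97–117/117–137/137–152 ms post-tone at 1.3/2.75/1.4 nS per synapse; each of
the five synapses per target fires at its own uniform-random time within
the phase window, so the drive is graded rather than one compound EPSP),
40 PV interneurons (five-synapse 2.5 nS pulses every 10 ms over
[95, 155) ms — a half-open grid, so pulses at 95…145 ms — starting 2 ms
before the Pyr activation; pulses within a train are synchronous, so they
are collapsed exactly) and 30 SST interneurons (same over [110, 130) ms).
The standard-tone response is baseline activity epoched at a sham t₀.
`calibrate_stimulus` finds one scalar on the bottom-up Pyr-phase
conductances — the PV/SST activation strengths stay at their printed
values, so the scalar adjusts the stimulus E/I balance to the reduced
neuron model — targeting the 6/11/7 Hz stimulated-Pyr profile in
100–120/120–140/140–160 ms (±20% per window for convergence; when the
point-neuron supralinearity prevents a per-window match the mean rate is
matched and non-convergence is reported).  The factor is persisted and
reused unchanged for all disease conditions.  Trials are 2 s with
t₀ = 1.6 s, giving the 0.5 s transient, a ≥1 s settled pre-stimulus
baseline and 400 ms post-stimulus.

ERPs: EEG is zero-phase lowpass filtered at 40 Hz (4th-order Butterworth),
downsampled to 100 Hz, epoched, averaged, and baseline corrected with the
0–500 ms pre-stimulus mean.  MMN amplitude is the largest negative peak of
the deviant-minus-standard trace in 100–200 ms.  Disease conditions scale
the stimulus NMDA component onto PV by the same NMDA-input reduction as the
recurrent Pyr→PV synapses.

## Disease conditions

A condition is (PV-output, PV-NMDA-input, SST) reduction fractions.
Scaling is linear on the edge list and tonic shares: PV-presynaptic GABA ×
(1−pv), SST-presynaptic GABA × (1−sst), Pyr→PV NMDA × (1−nmda) with AMPA
untouched, PV-/SST-attributed tonic shares likewise, applied to all
neurons.  The reference model pairs 22% output with 20% NMDA reduction (the
expression-derived estimates); graded variants pair equal percentages.
Neuron counts never change (no cell loss), and VIP is never perturbed.

## Spectral analysis

Welch PSD: Hann taper, 3 s segments (or the full signal if shorter), 50%
overlap, constant detrend, restricted to 3–30 Hz.  The
aperiodic/periodic decomposition fits offset+exponent in log-log space
robustly (refit on the low-residual subset), extracts up to four Gaussian
peaks greedily from the residual (threshold: 2 residual SDs and an absolute
floor of 0.12 log₁₀ units — the detection resolution; smaller bumps are
treated as estimation noise), then refits the aperiodic part on the
peak-subtracted spectrum.  "Broadband power" is the aperiodic component
integrated over 3–30 Hz.  Band-power integrals include both band edges
(adjacent bands partition the spectrum); half-open edges apply to peak
membership.  Because the disease shift moves the dominant peak across the
alpha/beta boundary, experiment summaries report the dominant periodic peak
in 8–20 Hz.

## Experiment design

Circuits are seed-matched across conditions: circuit i uses identical
placement, connectivity, heterogeneity and background-noise streams in
every condition, so contrasts isolate the perturbation.  Desk-scale
defaults are 10 circuits per condition (`paper_scale` restores 30 baseline
/ 50 oddball / 25 resting).  Resting runs are 4.5 s and oddball trials 2 s
(durations are config fields; the first 0.5 s of every run is discarded
from all statistics).  One oddball trial per circuit, averaging across
circuits.  Group comparisons use pooled-variance two-sample t-tests and
Cohen's d (n-weighted pooling); no multiple-comparison correction is
applied, matching the raw-p reporting convention of the source literature.

## Numerical choices

Forward Euler for membrane voltages at dt = 0.025 ms; exponential Euler for
receptor states; exact discretization for OU processes on a 0.2 ms substep
(held between updates — exact at update times; the ~50 µs-scale structure
this ignores is far above the analysis band).  Spike: threshold crossing at
0 mV, reset, 2 ms refractory, adaptation increment.  Divergence (|V| >
200 mV) raises an error naming the neuron and time.  The synaptic delay is
implemented as a ring buffer of spike events.  Determinism: every source of
randomness derives from named SeedSequence streams (placement,
connectivity, heterogeneity, OU, stimulus jitter), so identical seeds give
bit-identical results.

## What the surrogate generators emulate

`surrogate` produces 1/f+peaks spectra by randomized-phase spectral
synthesis, stereotyped ERP troughs in white noise, and homogeneous Poisson
spike trains.  These carry exactly the statistical structure the analysis
chain assumes — no nonstationarity, no cross-frequency coupling, no
spike-field relation — so surrogate-based tests validate the analysis
operators (recovery of known parameters), not the biology.  Passing them
says the pipeline measures what it claims to measure; it says nothing about
whether the simulator produces realistic signals, which is what the
simulation-level experiments and calibration targets address.

## Known limitations

- The reduced two-compartment neuron cannot reproduce dendritic
  nonlinearities beyond the NMDA voltage dependence, axonal/dendritic
  propagation, or morphology-specific synapse placement.
- The oddball ERP trough in this model is dominated by response spiking
  (recurrent drive to the dendritic compartment), so reduced inhibition
  deepens rather than shrinks it: the mismatch-amplitude *decrease* that
  detailed models produce under PV-inhibition loss is not reproduced —
  disease conditions here leave the MMN amplitude flat to mildly increased.
  Variants that route recurrence to the basal compartment or strengthen the
  PV→SST→apical channel do not flip the direction either; the effect appears
  to require genuine sink/source separation along an apical cable.
- The three-phase oddball rate profile (6/11/7 Hz) cannot be matched within
  ±20% per window by a scalar on the bottom-up drive: the point-neuron
  response is supralinear in synaptic conductance, so the printed phase
  strengths map to much steeper rate ratios.  Stimulus calibration matches
  the mean response rate and reports non-convergence of the per-window
  profile honestly.
- Population rates and disease contrasts carry substantial circuit-to-circuit
  spread (the explicit heterogeneity, amplified by supralinear population
  gain, especially for PV); small-n experiment means inherit that spread.
- The disinhibition gain of the reduced model is steeper than the detailed
  model's: a 50% PV-inhibition reduction roughly augments baseline Pyr rates
  by ~150% here versus +86% there.
- Absolute EEG amplitudes are small (nV scale) because only a 1000-neuron
  L2/3 patch generates the signal; relative contrasts between conditions
  are the meaningful outputs.
- Connection probabilities and conductances other than Pyr→Pyr (0.15) are
  calibration parameters, not measurements; conclusions should be read as
  conditional on the calibrated operating point.
- The aperiodic exponent of the simulated EEG is shallower and more
  variable across circuits than scalp EEG, because a single OU timescale
  plus synaptic kinetics stand in for the full dendritic cable filtering.
- Short-term synaptic plasticity is not modelled (static synapses); the
  config exposes no dynamics for it.
- Population rates vary more between random circuits than the detailed
  models report, a consequence of the explicit excitability heterogeneity.
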