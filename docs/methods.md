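# Methods

This note documents the model, the default parameters and why they were
chosen, what the simulations do and do not emulate, and the numerical
decisions a user should know before trusting or extending the package.

## Network and single-cell model

Neurons follow the Izhikevich quadratic model, advanced on a 1-ms
network grid with two 0.5-ms forward-Euler half-steps for `v` and one
full step for `u` — the model family's standard integration.  Within a
step, a membrane potential crossing the 30 mV cutoff is clamped there
until the end-of-step reset to `(c, u + d)`; without the clamp, strong
synaptic input can blow up the quadratic nonlinearity inside a step.
Every neuron starts at its own subthreshold fixed point so the settling
transient cannot produce spurious spikes.

Excitatory cells interpolate between regular-spiking
(a=0.02, b=0.2, c=−65, d=8) and intrinsically-bursting (c=−55, d=4)
endpoints via the canonical squared-uniform heterogeneity deviate;
inhibitory cells are fast-spiking (a=0.1, b=0.2, c=−65, d=2) with a
linear perturbation of (a, b).

The tissue is an open 1-D strip: 200 excitatory neurons with one
inhibitory neuron interleaved per five, unit spacing, distance =
coordinate difference.  Every neuron receives exactly 5 excitatory
in-edges from a ±6-rank local window, each rewired with probability
0.08 to a source up to 50 ranks away, plus 2 in-edges from the nearest
inhibitory cells.  Two deliberate choices shape propagation:

* **Open line, not a ring.**  On a ring the last group is adjacent to
  the first, so activity would reach group 4 immediately rather than
  last, and blocking group 3 could never isolate group 4.  The strip of
  tissue the model represents is an open chain of regions.
* **Bounded shortcut length.**  Rewired edges are capped at about one
  group-width so the small-world shortcuts accelerate local recruitment
  without letting the wave skip an intermediate group.  At the cut ends
  the candidate window stretches inward with doubled span; sliding it
  instead creates a dense reciprocal clique of boundary cells that acts
  as an artifactual autonomous pacemaker.

## Synapses and ephaptic coupling

Receptor conductances decay exponentially (AMPA 5 ms, NMDA 150 ms,
GABA_A 6 ms, GABA_B 150 ms; reversals 0/0/−70/−90 mV; NMDA gated by
((v+80)/60)²/(1+((v+80)/60)²)).  A presynaptic spike increments the
target conductance by (weight × depression resource); resources deplete
by the release fraction U = 0.85 per spike and recover with
τ_rec = 60 ms.  The strong, fast depression makes each synapse
effectively transmit once per population burst, which is what lets the
network recover quickly enough to sustain a theta-range rhythm; with
shallow depression the network falls into deep, slow (1–2 Hz)
charge–discharge cycles.  NMDA and GABA_B increments are 0.1 of the
AMPA/GABA_A increment on the same edge.  Additive STDP on
excitatory-excitatory weights exists but is off by default: the
headline simulations span 8 s, over which short-term dynamics dominate.
GABA_A increments are zeroed by default (bicuculline condition); all
SLE simulations here are disinhibited.

Ephaptic transmission is instantaneous: each neuron's membrane current
is the unit-capacitance voltage derivative of the previous 1-ms step,
with the pre-reset voltage capped at the spike cutoff so the reset jump
never enters the field — the field carries the action-potential
upstroke, not the bookkeeping discontinuity.  The received current is
`α Σ_j I_m(j)/max(r_ij, 1)` with a cutoff radius of one group-width
(60 units).  The cutoff matters: without it the 1/r field relays the
rhythm *across* a silenced group, so stimulating group 3 would leave
group 4 paced remotely by groups 1–2, which contradicts the
downstream-suppression phenomenology the field's rapid decay with
distance implies.

## SLE induction, focus, calibration

SLEs are ignited by 1 s of i.i.d. Gaussian pulses (mean 10, s.d. 5)
into the 25 excitatory neurons at the start of group 1, beginning at
200 ms.  These focus neurons also carry a sustained bias (8 current
units, passing through the v_c gate like all network-borne drive) from
trigger onset onward: the focus is modeled as intrinsically
hyperexcitable tissue.  This bias is what gives the established rhythm
a consistent direction — every stable-state wave initiates at the focus
and travels group 1 → 4 — and its magnitude sets the ~8 Hz pacing
(an RS neuron driven at ~10.5 total units re-fires ~125 ms after each
burst-adaptation cycle).  All other excitatory cells receive a constant
background drive of 2.25 units, well below the rheobase of 4, plus
per-step Gaussian noise of configurable variance (default 1, mapped
1:1 onto the model's current units).  With the trigger disabled and
zero noise the network is exactly silent.

The synaptic:field ratio is realized by calibration: short
trigger-to-stable runs measure the time-averaged population-mean
|I_syn| and |I_field| over active neurons (≥1 Hz in the stable window),
and a multiplicative fixed-point iteration scales (weights, α) until
the field share is within 2 percentage points of target while the
total stays within 25% of a synapse-only reference at the default
weight scale (0.33).  Calibration converges in ≤8 iterations for all
cells used here; each (ratio, noise) cell is calibrated once and its
parameters reused across replicate seeds.

## Stimulation effect and suppression classification

High-frequency stimulation is represented by its effect only: in the
stimulated group, v_Ek rises as `e_k0 + k ln(1 + t/τ)`
(e_k0 = −95 mV, k = 12 mV, τ = 250 ms, saturating at −60 mV),
integrated in time-local form so no onset clock is carried, and
`v_c = σ((v_c-center − v_Ek)/3 mV)` (center −80 mV, normalized to 1 at
rest) gates the neuron's entire network-borne input.  With these
defaults a continuously driven neuron stops spiking 1–2 s after
stimulation onset.  Recovery after stimulation is zero by default
(suppressed neurons are never shown re-igniting within the simulated
window); a recovery rate is exposed.  Whether the experimental waveform
parameters (130 Hz, 1 ms, 500 µA) should modulate the v_Ek rise is left
as a configuration hook; the defaults are waveform-independent.

A group counts as suppressed when, after a 2-s latency from
stimulation onset, its LFP amplitude (s.d. of the detrended channel)
falls below 0.25× and its mean excitatory rate below 0.2× of the
pre-stimulation stable values; the overall label is local (stimulated
group only), whole (all groups), downstream (the stimulated group plus
exactly the groups activated after it), or none.

## LFP and analysis defaults

Each group's LFP is the mean of its 50 excitatory membrane potentials
after subtracting each neuron's pre-trigger median (so the resting mean
sits near 0 mV), zero-phase low-passed with a 4th-order Butterworth at
50 Hz, sampled at 1 kHz.  Note the 4th-order zero-phase filter
attenuates 60 Hz by ~14 dB, not the ~20 dB an ideal brick-wall reading
of "50-Hz cutoff" would suggest.

Band edges are the conventional EEG bands truncated at the LFP cutoff
(δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–50 Hz).  The spectrogram uses a
256-sample Kaiser window (β = 0.5), 85% overlap and 8192-point
transforms.  Peak detection for delays uses prominence 0.5× the
channel s.d. and a 50-ms minimum inter-peak interval (SLE spikes run at
5–10 Hz); peaks are matched across adjacent channels to the nearest
within 25 ms.  The PLV band-passes with a zero-phase 4th-order
Butterworth, takes phases from the analytic signal, and reports as its
headline the average over the six channel pairs of the per-pair
time-locked PLVs; the literal instantaneous form (pair-mean phasor
magnitude averaged over time) is returned alongside.

## What the simulations show — and what they do not

With the defaults, calibrated networks at 85:15 and 75:25 produce SLEs
with dominant frequencies of ~7.5–8 Hz, adjacent-group positive-peak
delays of ~9–13 ms, theta-dominant band power with minimal gamma, and
suppression behavior that dissociates cleanly by noise level: local
stimulation of the focus suppresses the entire network in a low-noise
environment (variance 0.25), only the stimulated group in a high-noise
environment (variance 4), and stimulating a non-focus group suppresses
that group and its downstream neighbor while upstream groups persist.

Two aspects of the original phenomenology are *not* reproduced, and we
report them rather than tune them away:

* **The ratio dissociation at intermediate noise.**  At noise
  variance 1, both calibrated ratios yield local suppression.
  Post-stimulation persistence of the non-stimulated groups is governed
  by spontaneous noise-driven re-ignition, and at wave-capable synaptic
  weights a single spontaneous spike always recruits a cascade (one
  EPSP moves the membrane tens of mV against a subthreshold basin of a
  few mV), so persistence is insensitive to the weight/field split.
  Making single spikes subcritical requires weights ~10× smaller, which
  destroys the delay and frequency phenomenology.  This is a genuine
  limitation of the five-in-edge Izhikevich architecture at this
  operating point.
* **PLV texture at the spectral extremes.**  The simulated stable
  rhythm is stationary, so its delta band carries no coherent signal
  (δ-PLV ≈ 0.6–0.7 rather than ≈ 0.99), and its bursts are sharply
  time-locked across groups, so gamma coherence is high (≈ 0.75 rather
  than ≈ 0.26).  Tissue recordings carry large coherent slow shifts and
  desynchronized gamma noise that the 240-neuron model does not
  generate.  The ordering θ ≥ α ≥ β ≥ γ does hold.

The synthetic-fixture generator covers the analysis suite
independently of the simulator: known lags, fixed phase offsets, band
mixtures and i.i.d. noise, each with a ground-truth sidecar.  Passing
those tests shows the estimators are correct on signals with known
structure; it does not validate the simulator's texture against tissue.

## Problem sizes

The default experiment battery (each cell: one calibration of ~6 short
runs plus five 8-s replicate runs of the 240-neuron network at 1 kHz)
was sized so a full ratio × noise sweep plus the stimulation-site
experiment completes in a few minutes on a single CPU; single runs take
on the order of a second.
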