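# Methods

## Model

The substrate is a sparse random network of 800 excitatory and 200
inhibitory rate neurons (directed connection probability 0.1, no
self-connections).  Neuron *i* integrates
*uᵢ = Σⱼ wⱼᵢ vⱼ κⱼ* with κⱼ = +1 for excitatory and −5 for inhibitory
presynaptic neurons, and emits
*vᵢ(t+Δt) = tanh(γ uᵢ) + ξᵢ* if *uᵢ ≥ 0*, else *vᵢ = ξᵢ*, with ξᵢ fresh
uniform noise on [−0.1, 0.1].  The sampling step Δt = 0.2 s doubles as
the propagation time, so one step is also the lag of the Hebbian
product below.  Within a step the order is: integrate the previous
outputs, add external drives (+10 to the state of each member of an
active stimulus group; ±10 winner/loser action feedback), emit outputs.

Stimulus and action channels are disjoint groups of 60 excitatory
neurons sampled without replacement.  Input-group members receive no
network connections and output-group members project none back; under
the long, persistent stimuli used here this prevents Hebbian-grown
recurrent loops from locking the network into self-sustained activity.
A channel's macroscopic activity is the mean output of its members, and
the macroscopic learning readout is the *pathway strength*: the mean
weight over existing synapses from one group to another.

Plasticity applies to afferents of excitatory neurons, confined to
[0, 1]; afferents of inhibitory neurons are fixed at their initial
values.  Learning combines:

* the RCHP rule — per synapse, +α if the lagged product
  vⱼ(t−Δt)·vᵢ(t) strictly exceeds θ_hi, −β if strictly below θ_lo
  (α = β = 0.1), zero otherwise;
* homeostatic thresholds — FIFO queues hold the per-step network-wide
  correlation and decorrelation counts of the last 10 s; when the
  windowed rate (counts / (window · n_synapses), per second) leaves the
  band [μ/5, 5μ] around the target μ = 0.5 %/s, the corresponding
  threshold magnitude moves by η = 0.002/s (θ_hi floored at 0, θ_lo
  capped at 0).  Detection runs over all existing synapses — the
  statistic is network-wide — while weight updates touch plastic
  synapses only;
* eligibility traces — ċ = −c/τ_c + RCHP(t) with τ_c = 4 s; events are
  added impulsively at full magnitude; traces are not clipped (their
  decay bounds them);
* modulation and weight update — ṁ = −m/τ_m + λ·r(t) + b with
  τ_m = 1 s, and ẇ = m·c.  A reward episode holds r at its magnitude
  for one sampling step.

All integrations are explicit Euler steps at Δt.  Per step the order is
detect → adapt thresholds → decay/accumulate traces → update m → update
weights, so a reward arriving in a step acts on that step's weights.

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| γ | 0.5 | output gain; saturates a group driven by +10 (tanh 5 ≈ 1) |
| α, β | 0.1 | correlation/decorrelation event magnitudes |
| τ_c | 4 s | trace memory; sets the bridgeable reward delay (~10–12 s) |
| τ_m | 1 s | modulation decay; a reward acts for a few seconds |
| λ | 0.25 | reward-to-modulation gain (see below) |
| reward pulse | 1 s (classical), 0.2 s (operant) | the tutor's touch is sustained; graded operant rewards are brief events |
| b | −0.001 /s | tonic negative baseline; produces slow extinction of stimulated but unrewarded pathways |
| μ | 0.5 %/s | target rare-correlation rate |
| η | 0.002 /s | threshold adaptation speed |
| θ_hi, θ_lo init | ±0.1 | starting thresholds; the controller then tracks the noise floor (~±0.01 in a quiet network) |
| initial weights | U[0, 0.05] | see below |

Initial weights (plastic and fixed alike) are uniform on [0, 0.05].
This is deliberately small: with ~6 convergent synapses per group pair,
a driven group then evokes a sub-noise response (~0.07 against noise of
half-width 0.1) in downstream neurons.  In that regime the lagged
products on off-target synapses straddle both thresholds symmetrically,
so their +α and −β events cancel in the traces, and only synapses whose
postsynaptic partner is *consistently* driven high (the winner group
during action feedback, or a pathway that has already started to grow)
accumulate net eligibility.  With larger initial weights (e.g. U[0, 0.2])
the pre-learning response (~0.3) is uniformly positive, every stimulus
tags all of its efferent pathways positively, and repeated strong
rewards potentiate the network nonspecifically until background
activity becomes self-sustained — an operating regime in which
discrimination and reversal fail.

The reward gain λ and the pulse widths are calibrated jointly.  A
classical reward (r = 1 sustained for 1 s) injects ∫λr dt = 0.25 of
modulation drive, enough to convert a well-tagged pathway's traces into
a weight step of ~0.2 per episode — gradual acquisition over a handful
of episodes.  An operant reward (r = 5 for one step) injects the same
0.25, so two or three correct, rewarded answers establish a reliable
choice.  Larger gains make single rewards quasi-one-shot but also
amplify a slow failure mode: each reward converts the small
positive-mean traces that the decision window lays on *all* of the
presented color's pathways, so with hard clipping at 1 the winner's
relative margin erodes over many rewards and choices can start to flip
late in a session.  At λ = 0.25 this collateral drift is four times
slower and the gradual rise of θ_hi during the session gates the
decision-window products out before the drift matters.

Action selection monitors the eight action-group activities for 1 s
after stimulus onset.  The earliest group to reach 30 % of the maximum
attainable activity wins; if several cross on the same step the highest
activity at that step wins (an exact tie falls to the lowest index),
and if none crosses, the highest activity at the window end wins even
by a small margin.  The winning action is enunciated at the end of the
window in all cases, with ±10 feedback applied for 1 s; the stimulus
stays on for 2 s total.  Each correct choice schedules r = +5 and each
wrong one r = −0.5 (a reversal-phase perseveration r = −5), delivered
at a uniform delay in [0, 5] s.

## Synthetic stimulus generators

The classical scenario draws, per stimulus, a Bernoulli-per-step onset
process (probability 0.15 %/s), durations uniform on [3, 30] s, and one
reward (magnitude 1) per CS appearance at onset + U[0, 5] s.  The
brief-stimulus variant shortens durations to [1, 2] s and delays the
reward from stimulus *offset*, so the network must bridge the gap with
traces alone; the delay-capacity sweep fixes this delay.  The operant
scenario presents the five colors sequentially and circularly every
20 s.  These generators emulate the *timing statistics* of a live
interaction — independent asynchronous visitors, variable tutor
reaction delays — but not its perceptual properties: stimuli here are
clean binary channels, whereas real marker/color detection flickers and
drops out.  Passing tests therefore demonstrate robustness to timing
uncertainty, overlap and delay, not to sensor noise (which the trace
mechanism is argued to absorb, but which is not simulated).

The toy model abstracts the same arithmetic combinatorially: N =
100,000 synapses, an eligible fraction p = (1 %/s) × (3 s hard
eligibility window) = 3 %, one always-eligible reward-triggering
synapse, and independent eligibility draws per episode.  Analytics use
the hard window (the 3,000 / 90 / ≤3 attrition sequence is N·pᵏ); the
Monte-Carlo draws the eligible-set size from its exact binomial
marginal and thins survivors by Bernoulli sampling, which is
distributionally identical to materializing full eligibility masks.

## Measurements

Recordings log per-step scalars (modulation, group activities, windowed
correlation rate, thresholds) and per-second pathway strengths; events
(stimuli, rewards, actions, conditioned responses — output activity
≥ 0.5 while the CS is the sole stimulus, once per presentation) are
kept as a typed log.  A color counts as *learned at T* when its trial
at T and all its subsequent trials in the run choose the rewarded
action; operant runs use the protocol's 30-minute window.  Reversal
runs are segmented into four phases with operational boundaries:
exploit-old ends at the first post-switch trial not choosing the old
action; convergence ends when the old pathway first loses strict
dominance (margin 0.05); exploration ends at the final consecutive run
of new-action choices.  Punishment erodes the old pathway throughout
the first two phases — the behavioral switch lags the weight decline,
which is the "belief robustness" the protocol probes.  Multi-run
summaries report median/quartile/extreme pathway strengths per 3-min
bin plus per-run verdicts.

## Numerical conventions

Strict inequalities in the RCHP rule (a product exactly at a threshold
is no event).  The windowed rate always divides by the full 10-s window
even while the queue is filling (a negligible downward bias in the
first seconds).  Event times are binned to the step containing them.
Geometric-series decay makes event-free traces scale exactly by
(1 − Δt/τ_c)ᵏ over k steps, which the tests assert.  With m = 0 the
weight array is returned bit-identical.  Identical seed and
configuration give bit-identical trajectories; multi-run experiments
derive per-run seeds from one base seed via `numpy` seed sequences.

## Problem sizes

Full-size experiments use the 1,000-neuron network throughout: ten 2-h
classical runs, ten 30-min operant runs, and a 5 × 5-seed sweep of
40-min brief-stimulus runs (~0.3 ms per network step; the whole
acceptance computation takes on the order of ten minutes on one CPU).
Unit and property tests use a reduced substrate (250–375 neurons,
20-neuron groups) with identical physics.

## Limitations

The fixed-step homeostat can deadlock under sustained correlation
floods: a single color rewarded every 20 s for many minutes saturates
its collateral pathways, the flood drives θ_hi above the attainable
product ceiling faster than it can recover, and trace creation — hence
all further learning — freezes.  The reversal protocol therefore
switches the policy shortly after the association is established
(default 300 s) rather than after prolonged over-consolidation.

No reward expectation or prediction-error is modeled: rewards act
directly, so blocking does not emerge, and extinction arises only from
the tonic negative baseline rather than from omission of an expected
reward.  The homeostatic controller is deliberately crude; its windowed
rate excursions during strong stimuli are large (the rarity constraint
holds on average, not instantaneously).  Reward delays beyond ~3τ_c are
unlearnable by construction.  The robot-embodiment layer (vision,
speech, haptics) is outside the package's scope; its timing is emulated
by the generators above.
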