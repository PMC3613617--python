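# rchp — neural conditioning with rarely correlating Hebbian plasticity

`rchp` simulates classical and operant conditioning in a rate-based
neural network that solves the **distal reward problem**: attributing a
reward to the cue or action that caused it when the reward arrives
seconds later, amid unrelated, disturbing stimuli.  It is aimed at
computational-neuroscience and neuro-robotics researchers who want a
compact, fully reproducible substrate for experiments on
reward-modulated plasticity, eligibility traces, and
exploration/exploitation dynamics.

## The model

Neurons are rate units: state *uᵢ = Σⱼ wⱼᵢ vⱼ κⱼ* (κ = +1 excitatory,
−5 inhibitory) and output *vᵢ(t+Δt) = tanh(γuᵢ) + ξᵢ* when *uᵢ ≥ 0*
(noise ξ only otherwise), with Δt = 200 ms also serving as the synaptic
propagation time.  Learning has three stages:

1. **Rare-correlation detection (RCHP).**  Per synapse and step,

       RCHPⱼᵢ(t) = +α  if vⱼ(t−t_pt)·vᵢ(t) > θ_hi
                   −β  if vⱼ(t−t_pt)·vᵢ(t) < θ_lo
                   0   otherwise

   with α = β = 0.1.  The thresholds are tuned online by a homeostatic
   controller so that only ~0.5 %/s of synapses register correlations —
   the rarity is what makes later credit assignment possible.

2. **Eligibility traces.**  Each synapse integrates its events:
   *ċⱼᵢ = −cⱼᵢ/τ_c + RCHPⱼᵢ(t)*, τ_c = 4 s.  Traces mark synapses as
   eligible for change if a reward follows.

3. **Delayed neuromodulation.**  A network-wide signal
   *ṁ = −m/τ_m + λr(t) + b* (τ_m = 1 s) is driven by the reward r(t);
   weights change as *ẇⱼᵢ = m·cⱼᵢ* on plastic synapses, clipped to
   [0, 1].

Because traces thin out geometrically across unrelated events, only the
synapses that *consistently* precede rewards accumulate weight — a
handful of reward episodes singles out the reward-predicting pathway.

The packaged experiments mirror a tutor/robot interaction: nine
Poisson-arriving "person" stimuli of which one (the CS) predicts a
delayed reward (classical conditioning, plus a brief-stimulus variant
where the reward arrives only after the CS has ceased); five color
stimuli and eight competing winner-take-all action groups with +5/−0.5
delayed feedback (operant conditioning); and a behavior-reversal
protocol in which an acquired association is punished until the network
re-explores and adopts a new one.

## Worked example

The combinatorial toy model reproduces the credit-assignment
arithmetic: 100,000 synapses, correlations tagging 1 %/s of them,
traces negligible after 3 s, so ~3,000 synapses (3 %) are eligible at
any instant and the crowd of coincidentally reinforced synapses shrinks
by ×0.03 per reward episode:

```bash
$ rchp toy --episodes 5 --replications 200 --seed 1
 episode  expected_survivors  mean_survivors  median_survivors  std_survivors  mean_eligible
       1          3000.00000        2999.295            2998.0      51.318573       3000.080
       2            90.00000          90.375              91.5       8.988791       2997.825
       3             2.70000           2.600               2.0       1.469967       2994.205
       4             0.08100           0.080               0.0       0.289862       3001.770
       5             0.00243           0.000               0.0       0.000000       2998.155
```

`expected_survivors` is the closed form N·pᵏ (p = 0.03); the Monte-Carlo
columns agree within sampling error, and by episode 5 no coincidental
synapse survives — only the reward-triggering one.

A 40-minute classical-conditioning run from the library:

```python
from rchp import ClassicalConfig, classical_experiment

rec = classical_experiment(seed=1, config=ClassicalConfig(total_time=2400.0))
print(rec.pathways.iloc[-1].round(3).to_dict())
```

prints the final pathway strengths (mean weight from each stimulus
group to the output group):

```
{'time': 2399.2, 'S1->A0': 0.936, 'S2->A0': 0.005, 'S3->A0': 0.01,
 'S4->A0': 0.007, 'S5->A0': 0.007, 'S6->A0': 0.016, 'S7->A0': 0.008,
 'S8->A0': 0.202, 'S9->A0': 0.189}
```

S1 is the conditioned stimulus: its pathway has grown an order of
magnitude above the eight disturbing pathways (S8/S9 show the small
occasional increments expected when a disturbing stimulus happens to
precede a reward), and the recording's event log contains the
conditioned responses the output group now fires when the CS appears.

The CLI exposes all scenarios: `rchp classical`, `rchp classical-brief`,
`rchp operant`, `rchp reversal`, `rchp toy`, `rchp sweep-delay`
(see `rchp COMMAND --help`); each writes per-step scalar series (CSV),
pathway strengths (CSV), an event log (JSON-lines) and a summary JSON.

## Documentation

`docs/methods.md` describes the model assumptions, parameter choices,
what the simulated stimulus generators do and do not emulate, numerical
conventions, and known limitations.
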