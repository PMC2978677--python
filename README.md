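# boutonsim

Stochastic, spatially explicit simulation of vesicular release at a
hippocampal CA3–CA1 presynaptic bouton, for synaptic physiologists and
computational neuroscientists studying release timing, refractoriness
and short-term plasticity at small central synapses.

An action potential opens a cluster of P/Q-type voltage-dependent
calcium channels (a 5-state Markov chain per channel, rates
a_i(v) = a_i0·e^(v/v_i), b_i(v) = b_i0·e^(−v/v_i)); the entering Ca²⁺
diffuses through a calbindin-buffered cytosol with PMCA extrusion and
boundary-clamped resting calcium (100 nM); and each of 7 docked
vesicles fuses under a **dual calcium-sensor** scheme — five
synchronous binding sites fusing at γ from full occupancy, two
asynchronous sites fusing at aγ (a = 0.025), spontaneous fusion δ from
the unbound state, with unbinding slowed by a cooperativity factor
b = 0.25 per bound ion. Any release closes a zone-wide **refractory
gate** that reopens with time constant ε = 6.34 ms, and depletes the
7-vesicle readily-releasable pool. Variants: synchronous-sensor
knockout, asynchronous knockout (SAKO), a phenomenological single-gate
active zone, refractory on/off, and depletion-free zones.

Two engines share one parameterization: a particle-based 3-D
reaction–diffusion engine (explicit ions, mobile buffer, pumps,
collision-driven sensors) and a fast *hybrid* mode in which stochastic
channel gating drives a calcium template calibrated against the
spatial engine, making 10⁴-trial ensembles a matter of minutes. See
`docs/methods.md` for the model, calibration chain and estimators.

## Worked example

```bash
python examples/single_ap_time_course.py
```

prints (exact numbers vary with the seed):

```
824 release events in 4000 trials
overall release probability p_r = 0.191 (the fraction of trials with at least one release)
two-exponential decomposition (10 ms bins, from 3 ms):
  tau_fast = 5.6 ms   (delayed synchronous release)
  tau_slow = 150 ms   (asynchronous release)
three-exponential decomposition (1 ms bins):
  tau_superfast = 0.61 ms (phasic release tracking the calcium pulse)
```

The 48-channel cluster 250 nm from the active zone gives a synapse
that releases on ~20% of stimuli. Release decays on three time
scales: a superfast phase locked to the local calcium pulse, a fast
(~6 ms) delayed-synchronous phase set by the synchronous sensor's
unbinding cascade, and a slow (~10² ms) asynchronous phase carried by
the two-site sensor's memory and the residual bulk calcium.

Other examples: `spontaneous_release.py` (deterministic steady-state
fusion flux vs a long stochastic run), `facilitation_train.py`
(10 Hz train, wild type vs SAKO), `spatial_calcium_peak.py`
(particle-engine local calcium peak and buffered effective diffusion).

A thin CLI wraps the same library:

```bash
boutonsim simulate --config my.json --trials 2000 --seed 1 --out runs/
boutonsim analyze --events runs/run-events.csv --bin 10 --fit 2exp
boutonsim calibrate --target-peak 12
boutonsim fixtures --kind multi_exp_events
```

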