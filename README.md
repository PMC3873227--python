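# rtcnet

Simulation and information-theoretic analysis of sensory transfer across
the thalamic gateway: a population of Hodgkin–Huxley-type thalamocortical
(TC) relay cells of the dLGN, driven by gamma-process retinal spike trains
and by stochastic corticothalamic conductance bombardment, converges onto
a single layer-4 cortical neuron. The package quantifies how the
*statistics* of the bombardment — its mean amplitude, its fluctuations,
and above all its **temporal correlation across TC cells** — gate the
transfer of retinal information to cortex.

## The model

Each single-compartment cell obeys

```
Cm dV/dt = −gL(V−EL) − Σ_ch g̅_ch m^a h^b (V−E_ch) + I_syn + I_fluct + I_inj
```

with Traub–Miles I_Na/I_K spike currents in both cells, the low-threshold
Ca²⁺ current I_T and hyperpolarization-activated I_h in the TC cell, and
the slow muscarinic-type I_M in the cortical cell. Synapses are alpha
conductances `g(s) = w (s/τ) e^(1−s/τ)` (AMPA: E=0 mV, τ=1 ms; GABA_A
feedforward inhibition: E=−75 mV, τ=2 ms). The corticothalamic
bombardment is a dual Ornstein–Uhlenbeck conductance pair per cell
(τ_exc=2.7 ms, τ_inh=10.5 ms), parameterized by normalized *conductance
amplitudes* `a_x = g0_x / g_in0` and *variation ratios* `v_x = σ_x/g0_x`,
with cross-cell correlation imposed by a homogeneous (shared + private
mixing) or heterogeneous (all-shared subset) schema.

Transfer efficiency (TE) is the bias-corrected mutual information between
retinal and cortical spike trains: both are binarized (1 ms bins), cut
into 30 ms windows, and the plug-in MI of the word pairs is corrected by
shuffle-subtraction and a finite-size extrapolation, then expressed in
bits/s.

## Worked example

```python
import numpy as np
from rtcnet import stimuli, cortical_noise, circuit_sim, info_metrics

# 100 s of a 30 Hz gamma-3 retinal train into the optimized 30-cell circuit
ret = stimuli.gamma_spike_train(
    stimuli.RetinalGenSpec(duration=100_000.0), np.random.default_rng(42))
circ = circuit_sim.build_circuit("single", 30)           # w_tc = 7 nS
res = circuit_sim.simulate(
    circ, [ret],
    noise=cortical_noise.lc_optimal(),      # a_e=1.5, a_i=1.0, v=0.2
    corr=cortical_noise.CorrelationSpec(),  # uncorrelated across cells
    duration=100_000.0, seed=1)

print(np.mean([t.rate for t in res.tc_spikes]))   # 35.6  (TC rate, Hz)
print(res.ctx_spikes.rate)                        # 26.9  (cortical rate, Hz)
print(info_metrics.transfer_efficiency(ret, res.ctx_spikes))   # ~89 bits/s
```

The TC population relays the 30 Hz retinal drive at ~35 Hz and the
cortical cell recovers ~89 bits/s of retinal information. Re-running with
`corr=CorrelationSpec(c_pop=1.0)` (every TC cell receives the identical
bombardment realization) collapses TE to ~21 bits/s — a ~76 % drop with
per-cell input statistics unchanged: decorrelation of the background
noise across the thalamic population is itself the facilitation
mechanism.

## Layout

- `src/rtcnet/` — the library: `cell_models` (HH cells + calibration),
  `stimuli` (gamma retinal trains, jitter, currents), `cortical_noise`
  (OU bombardment, correlation schemas), `circuit_sim` (topology and the
  compiled network integrator), `hybrid_replay` (pseudo-recording
  sequence sets and hybrid-layer replay), `info_metrics` (TE and
  auxiliary measures), `experiments` (parametric sweeps; CLI `rtc`).
- `analysis/01…07_*.py` — numbered drivers for each study stage
  (calibration, convergence, bombardment statistics, correlation
  collapse, hybrid replay, heterogeneity, oscillations); each writes its
  table under `results/`.
- `tests/` — unit, property and quantitative-reproduction tests.

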