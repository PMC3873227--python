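# Methods

## Circuit and cellular models

The circuit is a feedforward retino-thalamo-cortical convergence: 1 or 15
retinal generators → N thalamocortical (TC) relay cells → one layer-4
cortical cell. Conduction delays are neglected and no plasticity is
modeled. Two presets are shipped: `single` (one afferent of 12.5 nS shared
by all TC cells) and `mixed` (15 retinal lines, 30 TC cells; every retinal
cell contacts 4 TC cells, every TC cell receives 2, with the 12.5 nS
weight split 75 %/25 % into 9.375 + 3.125 nS). Thalamocortical AMPA
weights follow the optimized trade-off N×w ≈ 210 nS (2.33 nS at N=90 —
the biological estimate — 7 nS at 30, 21 nS at 10).

Cells are single compartments with conductances in nS at the soma. The
passive parameters are fixed (TC: Cm 0.21 nF, gL 9.12 nS, EL −76.5 mV;
cortical: Cm 0.29 nF, gL 29 nS, EL −70 mV). Channel kinetics are the
standard published single-compartment schemes: Traub–Miles I_Na/I_K
(voltage offset `vt` as the excitability parameter), the
Huguenard/Destexhe I_T with a first-order Ca²⁺ pool and Nernst reversal,
the Huguenard–McCormick I_h, and the Destexhe–Paré I_M rate functions.

**Calibration.** The maximal conductances of the borrowed schemes and the
Na/K offsets are calibration parameters, fixed once against published
operating points and then frozen:

- (g_T, g_h) of the TC cell solve the two-constraint problem
  V_rest = −74.3 mV and g_in = 8.34 nS exactly (g_T = 140.99 nS,
  g_h = 0.208 nS). The depolarization from EL and the sub-leak input
  conductance are both carried by the I_T window current.
- g_M of the cortical cell targets g_in = 33.4 nS (g_M = 135.64 nS),
  leaving V_rest at −70.93 mV, 0.5 % from the −70.6 mV reference; with
  these I_M kinetics no g_M reproduces both numbers exactly.
- vt_ctx = −50 mV sets the cortical single-AMPA-event spike threshold to
  ~80 nS (≈ one third of a 30–35-cell volley at 2.33 nS).
- vt_tc = −47.5 mV sets the TC operating point under the low-conductance
  (LC) optimal bombardment: ~35 Hz thalamic firing against the 30 Hz
  retinal drive.

The calibrated TC cell fires a low-threshold rebound burst (3 spikes) on
release from a 500 ms, −0.15 nA hyperpolarizing step; the burst vanishes
without I_T. Its latency (~80 ms) is set by passive recovery
(τ_m = Cm/g_in ≈ 25 ms) because the calibrated g_h is small.

**Integration.** Gates use exponential-Euler updates; the membrane uses
an exponential-Euler update as well (conductances frozen over the step, V
relaxing toward Σ gE/Σ g), which is unconditionally stable. Stability
matters because heterogeneity randomization can halve Cm while doubling
g_Na, where a forward V update at dt = 0.025 ms diverges. Default
dt = 0.025 ms; halving it changes the relaxed V_rest by ≪ 0.05 mV and
leaves rebound-burst timing unchanged. Rate-function singularities are
evaluated by series limits below 10⁻⁶ relative argument. Spikes are
upward crossings of −30 mV, re-armed below −45 mV (one count per action
potential). Integrators are numba-compiled; identical seeds give
bit-identical results.

## Stimuli and bombardment

Retinal trains are gamma renewal processes (shape 3, mean ISI 33.33 ms =
30 Hz; ISI CV = 1/√3). Synchronization across N lines replays one common
train on M = 1 + round(S(N−1)) lines. Spike-time jitter delays each spike
by an independent exponential draw (mean J); in circuit experiments the
jitter is applied per synaptic contact, so it desynchronizes the retinal
input *across* TC cells even when the lines themselves are identical.
Injected currents are a constant plus a zero-offset sine; "coherent"
oscillation conditions share one phase, "desynchronized" conditions draw
phases uniformly per cell.

Bombardment is a dual OU conductance pair per cell (exact AR(1)
discretization, initialized at the mean), normalized by the TC rest
conductance g_in0 = 8.34 nS: amplitudes a_x = g0_x/g_in0 ∈ [0,3],
variation ratios v_x = σ_x/g0_x ∈ [0,1], so a_x = 0 also silences the
fluctuations. The LC optimum is (a_e, a_i, v) = (1.5, 1.0, 0.2), total
20.85 nS (normalized 2.5); the HC point is (2, 2, 0.2), 33.36 nS
(normalized 4). Negative conductance excursions are clipped only at
current evaluation, preserving the OU state statistics (a documented
divergence risk at large v). Exc–inh correlation mixes the inhibitory
innovations with √-weights against (optionally lagged) excitatory
innovations; the homogeneous population schema mixes each cell's private
realization with one shared realization with √(1−c)/√c weights —
the unique linear mixing preserving mean and variance exactly, hence the
first-order invariance every cell sees — while the heterogeneous schema
gives the first M = 1 + round(c(N−1)) cells the shared realization
verbatim (round-half-up; ties cannot occur on the grids used).

## Transfer-efficiency estimation

TE is the direct-method mutual information between two spike trains:
binarize (1 ms bins for model circuits, 3 ms for replayed hybrid layers;
multiple spikes in a bin count once), shift the response back by the
transfer lag (6/4/2 ms for retinocortical/retinothalamic/thalamocortical
legs), cut into consecutive non-overlapping 30 ms windows aligned at
t = 0, and compute the plug-in MI of the empirical (stimulus word,
response word) distribution. The residual bias is estimated by ≥20 random
re-pairings of stimulus and response windows and subtracted; small
negative results clip to zero with a flag.

At the reference protocol size (100 s → 3333 windows) the
plug-in-minus-shuffle estimate still carries a downward finite-size error
of order 10 % (measured against 300 s controls). The pipeline therefore
reports the *extrapolated* estimate: the corrected MI is recomputed on
nested data fractions (1, 1/2, 1/4, 1/8) and extrapolated quadratically
in inverse window count — the standard finite-size treatment for direct
MI estimates — and `finite_size_check` exposes the corresponding
diagnostic fraction (flagged above 1 %). `mutual_information` without
`extrapolate` retains the plain corrected estimate. Closed-form checks
(binary symmetric channel at three flip rates, identity channel,
independence) bound the estimator's error at the 2 % level at the data
sizes the tests use.

Auxiliary measures: transfer efficacy (probability a retinal spike is
followed by a cortical spike within a window) and contribution
(transmitted retinal spikes / cortical spikes); binarized Pearson
pairwise spike correlation with a population wrapper; spike-triggered
average of summed thalamic counts in the 30 × 1 ms bins preceding each
cortical spike; firing rate and ISI CV (population or windowed SDs);
spike-count MI (a lower bound on the word MI by data processing); and the
cross-correlogram normalized so both zero-lag autocorrelations are 1.
Membrane-potential SD after spike removal excises [−1, +4] ms around each
spike by default.

## Pseudo-recording hybrid layers

The hybrid-replay stage stands in for hybrid circuits built from
sequentially recorded biological TC cells; it reproduces the recording
*protocol* and the statistical role of biological variability, not any
actual recording. For each of (by default) 13 pseudo-cells — the base TC
model perturbed by ±20 % parameter randomization — 20 trials are
simulated with a shared retinal train: 10 under one common bombardment
realization and 10 under independent realizations, the same 11 patterns
reused across cells. Trial-to-trial variability is emulated by a ±2 %
per-trial parameter jitter plus a low-amplitude OU current (SD 15 pA,
τ 5 ms), calibrated so the per-trace voltage SD after removal of the
EPSP–spike–AHP complex ([−3, +12] ms; the narrow [−1, +4] ms excision
measures the 12.5 nS EPSP deflections instead and cannot reach the band)
falls inside the biologically observed 0.9–3.5 mV.

Layers: `small_single` (10 pseudo-cells from one set, mixing m common +
10−m independent trials, c_pop = (m−1)/9); `large_mixed` (up to 130
pseudo-cells across sets; "correlated" draws common-noise trials,
"partially decorrelated" draws the 10-pattern independent pool, for which
a correlation strength is deliberately not defined); `large_single` (one
set duplicated 13 times). Replay drives the cortical model through
exactly the integration used in direct simulation, so replaying a
simulation's own thalamic spike trains reproduces its cortical output
bit-for-bit.

## Experiments and scaling

`experiments.run_experiment` executes each parametric study (convergence
size and weight, retinal synchronization × jitter, thalamic jitter, the
two bombardment planes, impaired layers, correlation schemas, hybrid
replay, heterogeneity, coherent oscillations, and the single-event,
depolarization, FFI and exc–inh-correlation controls) from an
`ExperimentSpec`. The scale factor shortens durations and repetition
counts only (10 repetitions at full scale, 3 reduced); grids, equations
and analysis settings are never rescaled. Base seeds expand via
`SeedSequence` to per-grid-point, per-repetition, per-stream sub-seeds;
re-running a spec reproduces its table exactly. The quantitative test
suite runs the reference 100 s protocols for the operating-point numbers
and 20 s sweeps for the optimum-location checks; the analysis drivers
default to scale 0.2.

## Known limitations

- The cortical resting pair cannot be matched exactly with the adopted
  I_M kinetics; g_in is exact and V_rest is 0.5 % off.
- At the HC point (a_e = a_i = 2) the recalibrated TC cell sits slightly
  off the optimal ridge: the doubled total conductance shunts the fixed
  12.5 nS retinal EPSP and thalamic firing drops to ~27 Hz, so the HC
  transfer is substantially below the LC value rather than matching it.
- TC membrane SD under the LC bombardment measures ~4.9 mV with the
  [−1, +4] ms excision — dominated by EPSP deflections and post-spike
  recovery, not by the OU noise — several-fold above the ~1 mV scale
  that the OU statistics alone would suggest.
- TE is more sensitive to retinal spike-time jitter here (≈28 % drop at
  3 ms, with per-condition lag re-estimation) than the ≲20 % robustness
  the operating points are described with.
- The bombardment is open-loop: it never depends on the cortical output.
  NRT and interneuron inhibition are folded into the inhibitory OU
  component; no receptive-field structure, OFF cells, or naturalistic
  retinal statistics are modeled.
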