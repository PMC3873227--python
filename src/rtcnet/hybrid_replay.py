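"""Hybrid thalamic layers built from pseudo-recording libraries.

This is a synthetic stand-in for hybrid circuits in which the model TC
cells are replaced by replayed voltage traces of sequentially recorded
biological relay cells. A *sequence set* is the library recorded from one
(pseudo-)cell: 10 trials under one common bombardment realization plus 10
trials under independent realizations, all with the same retinal train and
identical noise statistics; the same 11 distinct bombardment patterns are
reused across cells. Trial-to-trial variability of real recordings is
emulated by a small per-trial parameter perturbation and a low-amplitude
independent OU current -- these are statistical surrogates, not
reproductions of any recording.

Three hybrid layer types are assembled from the libraries:

* small_single -- 10 pseudo-cells from one sequence set, mixing m common-
  and 10-m independent-noise trials (c_pop = (m-1)/9);
* large_mixed  -- up to 130 pseudo-cells sampled across distinct cells,
  either all sharing the common pattern ("correlated") or drawn from the
  10 independent patterns ("partially decorrelated", where a correlation
  strength is deliberately not defined);
* large_single -- as large_mixed but from a single sequence set duplicated
  13 times.

Replayed layers drive the model cortical cell through exactly the same
integration as direct simulation, so replay is output-equivalent to
simulating the same circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cell_models as cm
from . import _kernels as K
from .circuit_sim import CircuitSpec, SimResult, simulate_cortical_cell, tc_weight_for
from .cortical_noise import OUSpec, ou_generate
from .info_metrics import membrane_sd
from .stimuli import SpikeTrain

__all__ = [
    "PseudoTrial", "SequenceSet", "HybridLayerSpec",
    "generate_pseudo_recordings", "assemble_layer", "replay",
]

#: default per-trial parameter perturbation (fraction, randomize_cell H)
TRIAL_H = 0.02
#: default SD (nA) and correlation time (ms) of the trial-variability current
TRIAL_I_SD = 0.015
TRIAL_I_TAU = 5.0


@dataclass
class PseudoTrial:
    """One recorded trace: spikes, subsampled voltage, provenance."""

    condition: str            # "common" | "independent"
    pattern_id: int           # bombardment pattern index (0 = common)
    seed: int                 # trial-variability seed
    spikes: SpikeTrain
    v: np.ndarray             # subsampled membrane trace (mV)
    rec_dt: float             # ms


@dataclass
class SequenceSet:
    """The 20-trial library recorded from one pseudo-cell."""

    cell_id: int
    params: cm.MembraneParams
    duration: float
    trials: list = field(default_factory=list)

    def common(self) -> list:
        return [t for t in self.trials if t.condition == "common"]

    def independent(self) -> list:
        return [t for t in self.trials if t.condition == "independent"]

    def membrane_sds(self, excise=(-3.0, 12.0)) -> np.ndarray:
        """Per-trace voltage SD after spike removal (mV).

        The default excision covers the stereotyped EPSP-spike-AHP complex
        (wider than the 1-ms-scale spike itself), matching how spike
        removal is done on recorded traces before quantifying background
        fluctuations.
        """
        return np.array([membrane_sd(t.v, t.rec_dt, t.spikes.times, excise)
                         for t in self.trials])


@dataclass(frozen=True)
class HybridLayerSpec:
    """How to assemble one hybrid thalamic layer."""

    kind: str                 # small_single | large_mixed | large_single
    n: int = 10
    condition: str = "correlated"   # correlated | decorrelated
    n_common: int = 1         # small_single: trials from the common pool

    def __post_init__(self):
        if self.kind not in ("small_single", "large_mixed", "large_single"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "small_single":
            if self.n != 10 or not 1 <= self.n_common <= 10:
                raise ValueError("small_single layers mix m common + (10-m) "
                                 "independent trials out of 10")
        elif not 0 <= self.n <= 130:
            raise ValueError("large layers hold 0-130 pseudo-cells")

    @property
    def c_pop(self) -> float | None:
        """Heterogeneous-schema correlation strength (small_single only)."""
        if self.kind == "small_single":
            return (self.n_common - 1) / 9.0
        if self.condition == "correlated":
            return 1.0
        return None   # not defined for partially decorrelated large layers


def _simulate_trial(params: cm.MembraneParams, retinal: SpikeTrain,
                    noise: OUSpec, duration: float, dt: float,
                    pattern_seed: int, trial_seed: int,
                    trial_jitter: float, retinal_w: float,
                    rec_stride: int) -> PseudoTrial:
    trng = np.random.default_rng(trial_seed)
    if trial_jitter > 0:
        p = cm.randomize_cell(params, min(1.0, trial_jitter * TRIAL_H), trng)
    else:
        p = params
    n_steps = int(round(duration / dt))
    trace = ou_generate(noise, duration, dt, np.random.default_rng(pattern_seed))

    if trial_jitter > 0:
        # low-amplitude OU current emulating biological trial variability
        from scipy.signal import lfilter
        ef = np.exp(-dt / TRIAL_I_TAU)
        amp = trial_jitter * TRIAL_I_SD * np.sqrt(1.0 - ef * ef)
        i_arr = lfilter([amp], [1.0, -ef], trng.standard_normal(n_steps))
    else:
        i_arr = np.empty(0)

    steps = np.floor(retinal.times / dt).astype(np.int64)
    wts = np.full(steps.size, retinal_w)
    par = cm.params_to_vector(p)
    v, sp, nsp = K.simulate_cell(
        par, dt, n_steps, p.el,
        steps, wts, 1.0, 0.0,
        np.empty(0, dtype=np.int64), np.empty(0), 2.0, -75.0,
        trace.g_exc, trace.g_inh, noise.e_exc, noise.e_inh,
        0.0, 0.0, 0.0, 0.0, int(duration * 0.3) + 64,
        0.0, -1, -1, i_arr)
    if nsp < 0:
        raise RuntimeError("numerical blow-up in pseudo-recording")
    return PseudoTrial(
        condition="", pattern_id=-1, seed=trial_seed,
        spikes=SpikeTrain(sp[:nsp], duration, "pseudo_tc"),
        v=v[::rec_stride].copy(), rec_dt=dt * rec_stride)


def generate_pseudo_recordings(retinal: SpikeTrain, noise: OUSpec,
                               n_cells: int = 13,
                               base_params: cm.MembraneParams | None = None,
                               cell_heterogeneity: float = 0.2,
                               trial_jitter: float = 1.0,
                               duration: float | None = None,
                               dt: float = 0.025,
                               retinal_w: float = 12.5,
                               rec_stride: int = 40,
                               rng: np.random.Generator | None = None
                               ) -> list[SequenceSet]:
    """Generate sequence sets for `n_cells` perturbed pseudo-cells.

    The same 11 bombardment patterns (1 common + 10 independent) are reused
    in every cell, mirroring the recording protocol. `trial_jitter` scales
    the trial-to-trial variability surrogates (1.0 = default; 0 makes the
    10 common-noise trials of a cell bit-identical).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if base_params is None:
        base_params = cm.tc_default()
    if duration is None:
        duration = retinal.duration
    if duration > retinal.duration:
        raise ValueError("retinal train shorter than requested duration")

    pattern_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=11)]
    sets = []
    for c in range(n_cells):
        p = (cm.randomize_cell(base_params, cell_heterogeneity, rng)
             if cell_heterogeneity > 0 else base_params.copy())
        sset = SequenceSet(cell_id=c, params=p, duration=duration)
        for trial in range(20):
            if trial < 10:
                cond, pid = "common", 0
            else:
                cond, pid = "independent", 1 + (trial - 10)
            tr = _simulate_trial(
                p, retinal, noise, duration, dt,
                pattern_seeds[pid], int(rng.integers(0, 2**31 - 1)),
                trial_jitter, retinal_w, rec_stride)
            tr.condition, tr.pattern_id = cond, pid
            sset.trials.append(tr)
        sets.append(sset)
    return sets


def assemble_layer(spec: HybridLayerSpec, sets: list[SequenceSet],
                   rng: np.random.Generator | None = None
                   ) -> list[SpikeTrain]:
    """Pick pseudo-cell spike trains for one hybrid thalamic layer."""
    if rng is None:
        rng = np.random.default_rng(0)
    if not sets:
        raise ValueError("no sequence sets available")

    if spec.kind == "small_single":
        sset = sets[0]
        pool = sset.common()[:spec.n_common] + \
            sset.independent()[:10 - spec.n_common]
        return [t.spikes for t in pool]

    if spec.kind == "large_mixed":
        if spec.condition == "correlated":
            pool = [t for s in sets for t in s.common()]
        else:
            pool = [t for s in sets for t in s.independent()]
        if spec.n > len(pool):
            raise ValueError(
                f"requested {spec.n} distinct sequences, only {len(pool)}")
        idx = rng.choice(len(pool), size=spec.n, replace=False)
        return [pool[i].spikes for i in idx]

    # large_single: one set duplicated 13 times
    sset = sets[0]
    pool = (sset.common() if spec.condition == "correlated"
            else sset.independent()) * 13
    if spec.n > len(pool):
        raise ValueError("large_single layers hold at most 130 pseudo-cells")
    idx = rng.choice(len(pool), size=spec.n, replace=False)
    return [pool[i].spikes for i in idx]


def replay(layer: list[SpikeTrain], w_tc: float | None = None,
           ctx_params: cm.MembraneParams | None = None,
           ffi=None, dt: float = 0.025) -> SimResult:
    """Drive the model cortical cell with a hybrid layer's spike trains.

    The thalamocortical weight defaults to the optimum for the layer size
    (21 nS for 10 cells, the biological 2.33 nS for large layers).
    """
    if not layer:
        raise ValueError("empty hybrid layer")
    durations = {t.duration for t in layer}
    if len(durations) > 1:
        raise ValueError("layer traces have mismatched durations")
    duration = durations.pop()
    n = len(layer)
    if w_tc is None:
        w_tc = tc_weight_for(n) if n in (10, 30, 90) else 2.33
    circ = CircuitSpec(
        n_ret=0, n_tc=n, ret_edges=[], w_tc=np.full(n, w_tc), ffi=ffi,
        tc_params=[], ctx_params=ctx_params or cm.ctx_default())
    ctx_v, ctx_spikes = simulate_cortical_cell(circ, layer, duration, dt)
    return SimResult(tc_spikes=list(layer), ctx_spikes=ctx_spikes,
                     tc_v=np.empty((0, 0)), ctx_v=ctx_v, rec_dt=dt, dt=dt,
                     duration=duration, meta=dict(w_tc=w_tc, kind="replay"))
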