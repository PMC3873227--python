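"""Retino-thalamo-cortical circuit construction and simulation.

Topology: 1 or 15 retinal lines drive N thalamocortical (TC) relay cells;
every TC cell contacts one layer-4 cortical cell through a single AMPA
synapse; optional feedforward inhibition (FFI) couples a lagged GABA_A
event to every thalamocortical spike. Synapses are conductance-based alpha
kernels g(s) = w*(s/tau)*exp(1-s/tau), peaking at exactly w at s = tau.

Presets: a single retinal afferent of 12.5 nS shared by the population, or
the mixed 15-retina / 30-TC divergence-convergence layout (each retinal
cell contacts 4 TC cells, each TC cell receives 2, weights split 9.375 /
3.125 nS). TC->cortex weights follow the optimized trade-off
N x w ~ 210 nS (90 cells: 2.33 nS, 30: 7 nS, 10: 21 nS).

Spikes are detected as upward crossings of -30 mV (debounced below
-45 mV); conduction delays are neglected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from . import cell_models as cm
from .cortical_noise import ConductanceTrace, CorrelationSpec, OUSpec, n_shared
from .stimuli import CurrentSpec, SpikeTrain

__all__ = [
    "SynapseSpec", "CircuitSpec", "SimResult", "alpha_conductance",
    "build_circuit", "attach_ffi", "simulate", "simulate_cortical_cell",
    "jitter_retinal_contacts",
    "RETINAL_W", "RETINAL_W_SPLIT", "TC_W_PRESETS", "tc_weight_for",
]

RETINAL_W = 12.5               # nS, single-afferent retinothalamic weight
RETINAL_W_SPLIT = (9.375, 3.125)   # 75 % / 25 % split for dual innervation
TC_W_PRESETS = {90: 2.33, 30: 7.0, 10: 21.0}
SPIKE_THRESHOLD = K.SPIKE_THR  # mV


def tc_weight_for(n_tc: int) -> float:
    """Optimized thalamocortical weight: presets, else the 210 nS rule."""
    return TC_W_PRESETS.get(n_tc, 210.0 / n_tc)


@dataclass(frozen=True)
class SynapseSpec:
    """Alpha-kernel conductance synapse."""

    w: float                # nS, peak conductance
    e_syn: float = 0.0      # mV
    tau_peak: float = 1.0   # ms
    lag: float = 0.0        # ms (FFI delay after the TC spike)

    def __post_init__(self):
        if self.w < 0 or self.tau_peak <= 0 or self.lag < 0:
            raise ValueError("invalid synapse parameters")


AMPA_CTX = SynapseSpec(w=7.0, e_syn=0.0, tau_peak=1.0)
GABA_FFI = SynapseSpec(w=0.0, e_syn=-75.0, tau_peak=2.0)


def alpha_conductance(w: float, tau_peak: float, s) -> np.ndarray | float:
    """g(s) = w*(s/tau)*exp(1 - s/tau) for s >= 0, 0 before the spike."""
    s = np.asarray(s, dtype=float)
    g = np.where(s >= 0, w * (s / tau_peak) * np.exp(1.0 - s / tau_peak), 0.0)
    return g if g.ndim else float(g)


@dataclass
class CircuitSpec:
    """Topology + per-cell parameters of one convergent circuit."""

    n_ret: int
    n_tc: int
    # (retinal line, tc cell, weight nS) triples
    ret_edges: list = field(default_factory=list)
    w_tc: np.ndarray | None = None     # per-TC-cell thalamocortical weight
    ffi: SynapseSpec | None = None
    tc_params: list = field(default_factory=list)
    ctx_params: cm.MembraneParams | None = None
    tau_ampa: float = 1.0
    e_ampa: float = 0.0

    def in_degree(self, i: int) -> int:
        return sum(1 for (_, tc, _) in self.ret_edges if tc == i)

    def out_degree(self, r: int) -> int:
        return sum(1 for (ret, _, _) in self.ret_edges if ret == r)


def build_circuit(preset: str = "single", n_tc: int = 30,
                  w_tc: float | None = None,
                  heterogeneity: float = 0.0,
                  rng: np.random.Generator | None = None) -> CircuitSpec:
    """Assemble a circuit preset.

    "single": one retinal line contacting every TC cell at 12.5 nS.
    "mixed": 15 retinal lines, 30 TC cells, out-degree 4 / in-degree 2,
    per-cell weights 9.375 + 3.125 nS (sum 12.5 nS).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if preset == "single":
        n_ret = 1
        edges = [(0, i, RETINAL_W) for i in range(n_tc)]
    elif preset == "mixed":
        n_ret, n_tc_req = 15, 30
        if n_tc != n_tc_req:
            raise ValueError("mixed preset is defined for 30 TC cells")
        if 4 * n_ret != 2 * n_tc:
            raise ValueError("inconsistent divergence/convergence degrees")
        edges = []
        w1, w2 = RETINAL_W_SPLIT
        for i in range(n_tc):
            r1 = i % n_ret
            r2 = (r1 + 1 + i // n_ret) % n_ret
            edges.append((r1, i, w1))
            edges.append((r2, i, w2))
    else:
        raise ValueError(f"unknown preset {preset!r}")

    base = cm.tc_default()
    if heterogeneity > 0:
        tc_params = [cm.randomize_cell(base, heterogeneity, rng)
                     for _ in range(n_tc)]
    else:
        tc_params = [base.copy() for _ in range(n_tc)]
    w = tc_weight_for(n_tc) if w_tc is None else w_tc
    return CircuitSpec(
        n_ret=n_ret, n_tc=n_tc, ret_edges=edges,
        w_tc=np.full(n_tc, w), ffi=None,
        tc_params=tc_params, ctx_params=cm.ctx_default())


def attach_ffi(circuit: CircuitSpec, w_gaba: float, lag: float) -> CircuitSpec:
    """Couple a lagged GABA_A event on the cortical cell to every TC spike."""
    if not 0.0 <= w_gaba <= 10.0 or not 0.0 <= lag <= 10.0:
        raise ValueError("FFI weight/lag outside the modeled range")
    out = replace(circuit)
    out.ffi = SynapseSpec(w=w_gaba, e_syn=-75.0, tau_peak=2.0, lag=lag)
    return out


def jitter_retinal_contacts(circuit: CircuitSpec, trains: list,
                            j_mean: float, rng: np.random.Generator
                            ) -> tuple[CircuitSpec, list]:
    """Independently jitter the retinal spike copy seen by every contact.

    Each synaptic contact (edge) receives its own exponentially jittered
    copy of its line's train, desynchronizing retinal inputs across TC
    cells even when the lines themselves are fully synchronized. Returns an
    expanded (circuit, trains) pair with one virtual line per contact.
    """
    from .stimuli import jitter_spikes

    new_trains, new_edges = [], []
    for (r, i, w) in circuit.ret_edges:
        new_edges.append((len(new_trains), i, w))
        new_trains.append(jitter_spikes(trains[r], j_mean, rng))
    out = replace(circuit)
    out.ret_edges = new_edges
    out.n_ret = len(new_trains)
    return out, new_trains


@dataclass
class SimResult:
    """Spike trains and (subsampled) membrane traces of one simulation."""

    tc_spikes: list           # list[SpikeTrain]
    ctx_spikes: SpikeTrain
    tc_v: np.ndarray          # (n_tc, n_rec) mV
    ctx_v: np.ndarray         # (n_rec_full,) mV on the dt grid
    rec_dt: float             # ms between recorded TC samples
    dt: float
    duration: float
    meta: dict = field(default_factory=dict)


_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0)


def _ret_events_csr(circuit: CircuitSpec, trains: list[SpikeTrain], dt: float,
                    active_mask: np.ndarray | None):
    """Per-TC-cell retinal event lists in CSR form, sorted by step."""
    per_cell_steps = [[] for _ in range(circuit.n_tc)]
    per_cell_w = [[] for _ in range(circuit.n_tc)]
    for (r, i, w) in circuit.ret_edges:
        if active_mask is not None and not active_mask[i]:
            continue
        steps = np.floor(trains[r].times / dt).astype(np.int64)
        per_cell_steps[i].append(steps)
        per_cell_w[i].append(np.full(steps.size, w))
    ev_step, ev_w, indptr = [], [], [0]
    for i in range(circuit.n_tc):
        if per_cell_steps[i]:
            s = np.concatenate(per_cell_steps[i])
            w = np.concatenate(per_cell_w[i])
            order = np.argsort(s, kind="stable")
            ev_step.append(s[order])
            ev_w.append(w[order])
            indptr.append(indptr[-1] + s.size)
        else:
            indptr.append(indptr[-1])
    if ev_step:
        return (np.concatenate(ev_step), np.concatenate(ev_w),
                np.asarray(indptr, dtype=np.int64))
    return _EMPTY_I, _EMPTY_F, np.asarray(indptr, dtype=np.int64)


def simulate(circuit: CircuitSpec, retinal_trains: list[SpikeTrain],
             noise: OUSpec | None = None,
             corr: CorrelationSpec | None = None,
             currents: CurrentSpec | list[CurrentSpec] | None = None,
             duration: float = 100_000.0, dt: float = 0.025,
             seed: int = 0, thalamic_jitter: float = 0.0,
             rec_stride: int = 20,
             noise_traces: list[ConductanceTrace] | None = None,
             active_mask: np.ndarray | None = None,
             ctx_noise: ConductanceTrace | None = None) -> SimResult:
    """Integrate the full circuit and return spikes + membrane traces.

    Bombardment is either generated in-stream from `noise`/`corr` (seeded,
    reproducible) or supplied explicitly per cell via `noise_traces`. TC
    spikes drive the cortical synapses with zero conduction delay; an
    optional exponential thalamic jitter delays each TC spike before
    cortical delivery. Cells excluded by `active_mask` keep their
    bombardment but lose retinal input (impaired-layer experiments).

    Raises RuntimeError on numerical blow-up (|V| > 200 mV).
    """
    if len(retinal_trains) != circuit.n_ret:
        raise ValueError(f"expected {circuit.n_ret} retinal trains")
    n_steps = int(round(duration / dt))
    n_tc = circuit.n_tc
    rng = np.random.default_rng(seed)
    kseed = int(rng.integers(0, 2**31 - 1))

    params = np.stack([cm.params_to_vector(p) for p in circuit.tc_params])
    ev_step, ev_w, indptr = _ret_events_csr(circuit, retinal_trains, dt,
                                            active_mask)

    if noise is None:
        noise = OUSpec()          # amplitude 0: no bombardment
    if corr is None:
        corr = CorrelationSpec()
    if isinstance(currents, CurrentSpec) or currents is None:
        cur = currents or CurrentSpec()
        i_const = np.full(n_tc, cur.i_const)
        sine_amp = np.full(n_tc, cur.sine_amp)
        sine_f = cur.sine_freq
        sine_phase = np.full(n_tc, cur.phase)
    else:
        if len(currents) != n_tc:
            raise ValueError("need one CurrentSpec per TC cell")
        i_const = np.array([c.i_const for c in currents])
        sine_amp = np.array([c.sine_amp for c in currents])
        freqs = {c.sine_freq for c in currents}
        if len(freqs) != 1:
            raise ValueError("per-cell sine currents must share one frequency")
        sine_f = freqs.pop()
        sine_phase = np.array([c.phase for c in currents])

    if noise_traces is not None:
        if len(noise_traces) != n_tc:
            raise ValueError("need one ConductanceTrace per TC cell")
        arrs = np.empty((n_tc, 2, n_steps))
        for i, tr in enumerate(noise_traces):
            if tr.g_exc.size < n_steps:
                raise ValueError("noise trace shorter than the simulation")
            arrs[i, 0] = tr.g_exc[:n_steps]
            arrs[i, 1] = tr.g_inh[:n_steps]
        use_arrays = True
    else:
        arrs = np.empty((1, 2, 0))
        use_arrays = False

    schema_id = 0 if corr.schema == "homogeneous" else 1
    m_shared = n_shared(corr.c_pop, n_tc)
    lag_steps = int(round(corr.lag_ei / dt))
    max_sp = int(duration * 0.3) + 64

    spike_t, spike_c, v_rec, blow = K.tc_population_kernel(
        params, dt, n_steps,
        ev_step, ev_w, indptr,
        circuit.tau_ampa, circuit.e_ampa,
        noise.g0_exc, noise.sigma_exc, noise.tau_exc, noise.e_exc,
        noise.g0_inh, noise.sigma_inh, noise.tau_inh, noise.e_inh,
        corr.c_ei, lag_steps,
        schema_id, corr.c_pop, m_shared,
        i_const, sine_amp, sine_f, sine_phase,
        kseed, rec_stride, max_sp,
        arrs, use_arrays)
    if blow:
        raise RuntimeError("numerical blow-up in the TC population (|V|>200 mV)")

    tc_spikes = []
    for i in range(n_tc):
        t = spike_t[i, :spike_c[i]].copy()
        if thalamic_jitter > 0 and t.size:
            t = np.sort(t + rng.exponential(thalamic_jitter, t.size))
        tc_spikes.append(SpikeTrain(_dedup(t), max(duration, t[-1] + 1e-9)
                                    if t.size else duration, f"tc{i}"))

    ctx_v, ctx_spikes = simulate_cortical_cell(
        circuit, tc_spikes, duration, dt, ctx_noise)

    return SimResult(
        tc_spikes=tc_spikes, ctx_spikes=ctx_spikes,
        tc_v=v_rec, ctx_v=ctx_v, rec_dt=dt * rec_stride, dt=dt,
        duration=duration,
        meta=dict(seed=seed, kernel_seed=kseed, noise=noise, corr=corr,
                  thalamic_jitter=thalamic_jitter))


def _dedup(t: np.ndarray) -> np.ndarray:
    """Strictly increasing times (jitter can create exact ties)."""
    if t.size < 2:
        return t
    for i in range(1, t.size):
        if t[i] <= t[i - 1]:
            t[i] = np.nextafter(t[i - 1], np.inf)
    return t


def simulate_cortical_cell(circuit: CircuitSpec, tc_spikes: list[SpikeTrain],
                           duration: float, dt: float = 0.025,
                           ctx_noise: ConductanceTrace | None = None
                           ) -> tuple[np.ndarray, SpikeTrain]:
    """Drive the cortical cell from thalamic spike trains (replay path).

    This is the same integration the full simulation uses, exposed
    separately so that hybrid layers of replayed traces are
    output-equivalent to direct simulation.
    """
    exc_steps, exc_w = [], []
    for i, tr in enumerate(tc_spikes):
        steps = np.floor(tr.times / dt).astype(np.int64)
        exc_steps.append(steps)
        exc_w.append(np.full(steps.size, circuit.w_tc[i]
                             if circuit.w_tc is not None else 0.0))
    if exc_steps:
        s = np.concatenate(exc_steps)
        w = np.concatenate(exc_w)
        order = np.argsort(s, kind="stable")
        s, w = s[order], w[order]
    else:
        s, w = _EMPTY_I, _EMPTY_F

    if circuit.ffi is not None and circuit.ffi.w > 0 and s.size:
        lag_steps = int(round(circuit.ffi.lag / dt))
        gs = s + lag_steps
        gw = np.full(gs.size, circuit.ffi.w)
        tau_g, e_g = circuit.ffi.tau_peak, circuit.ffi.e_syn
    else:
        gs, gw = _EMPTY_I, _EMPTY_F
        tau_g, e_g = 2.0, -75.0

    n_steps = int(round(duration / dt))
    parc = cm.params_to_vector(circuit.ctx_params or cm.ctx_default())
    if ctx_noise is not None:
        ge, gi = ctx_noise.g_exc[:n_steps], ctx_noise.g_inh[:n_steps]
    else:
        ge, gi = _EMPTY_F, _EMPTY_F
    v0 = -70.93  # relaxed cortical rest
    max_sp = int(duration * 0.3) + 64
    ctx_v, sp, nsp = K.simulate_cell(
        parc, dt, n_steps, v0,
        s, w, circuit.tau_ampa, circuit.e_ampa,
        gs, gw, tau_g, e_g,
        ge, gi, 0.0, -75.0,
        0.0, 0.0, 0.0, 0.0, max_sp)
    if nsp < 0:
        raise RuntimeError("numerical blow-up in the cortical cell")
    return ctx_v, SpikeTrain(sp[:nsp], duration, "ctx")
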