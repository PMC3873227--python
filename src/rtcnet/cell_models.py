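"""Single-compartment Hodgkin-Huxley-type neuron models.

Two cells are provided: a thalamocortical (TC) relay cell of the dLGN
carrying I_Na, I_K (Traub-Miles action-potential currents), the
low-threshold calcium current I_T (with a first-order intracellular Ca
pool and Nernst reversal) and the hyperpolarization-activated cation
current I_h; and a layer-4 cortical cell carrying I_Na, I_K and the slow
non-inactivating potassium current I_M.

All conductances are somatic point values in nS. Passive parameters follow
the reference circuit (TC: gL 9.12 nS, EL -76.5 mV, Cm 0.21 nF; cortical:
gL 29.0 nS, EL -70.0 mV, Cm 0.29 nF). The maximal conductances of the
borrowed channel schemes and the Na/K voltage offset are calibration
parameters; the shipped presets are calibrated so that the relaxed resting
point and input conductance reproduce the published operating points
(-74.3 mV / 8.34 nS for the TC cell, -70.6 mV / 33.4 nS for the cortical
cell), the TC cell fires a rebound burst on release from hyperpolarization,
and the cortical cell's single-event AMPA spike threshold is ~80 nS.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K

__all__ = [
    "MembraneParams", "NeuronState", "tc_default", "ctx_default",
    "gate_rates", "membrane_derivative", "randomize_cell",
    "rest_properties", "relax", "params_to_vector", "load_params",
    "dump_params", "PRESETS",
]

#: gate names accepted by :func:`gate_rates`, mapped to (channel, gate).
GATES = ("na_m", "na_h", "k_n", "t_m", "t_h", "h_m", "m_n")


@dataclass
class MembraneParams:
    """Passive and active membrane parameters for one model cell."""

    cell_type: str          # "tc" or "ctx"
    cm: float               # nF
    gl: float               # nS
    el: float               # mV
    g_na: float             # nS
    g_k: float              # nS
    g_t: float = 0.0        # nS, TC only
    g_h: float = 0.0        # nS, TC only
    g_m: float = 0.0        # nS, cortical only
    vt: float = -55.0       # mV, Traub rate-function offset
    e_na: float = 50.0      # mV
    e_k: float = -90.0      # mV
    e_h: float = -43.0      # mV

    def __post_init__(self) -> None:
        if self.cell_type not in ("tc", "ctx"):
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.cm <= 0 or self.gl <= 0:
            raise ValueError("Cm and gL must be positive")
        for name in ("g_na", "g_k", "g_t", "g_h", "g_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def copy(self) -> "MembraneParams":
        return dataclasses.replace(self)


@dataclass
class NeuronState:
    """Membrane potential, gate variables and Ca concentration at time t."""

    v: float
    gates: dict = field(default_factory=dict)
    ca: float = K.CA_INF
    t: float = 0.0


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def tc_default() -> MembraneParams:
    """Calibrated thalamocortical relay cell preset."""
    return MembraneParams(
        cell_type="tc", cm=0.21, gl=9.12, el=-76.5,
        g_na=18900.0, g_k=2100.0,
        g_t=140.99, g_h=0.208,
        vt=-47.5,
    )


def ctx_default() -> MembraneParams:
    """Calibrated layer-4 cortical cell preset."""
    return MembraneParams(
        cell_type="ctx", cm=0.29, gl=29.0, el=-70.0,
        g_na=14500.0, g_k=2900.0,
        g_m=135.64,
        vt=-50.0,
    )


PRESETS = {"tc_default": tc_default, "ctx_default": ctx_default}


def params_to_vector(p: MembraneParams) -> np.ndarray:
    """Pack parameters into the flat layout the kernels consume."""
    v = np.zeros(K.NPAR)
    v[K.P_CM] = p.cm
    v[K.P_GL] = p.gl
    v[K.P_EL] = p.el
    v[K.P_GNA] = p.g_na
    v[K.P_GK] = p.g_k
    v[K.P_VT] = p.vt
    v[K.P_ENA] = p.e_na
    v[K.P_EK] = p.e_k
    if p.cell_type == "tc":
        v[K.P_G3] = p.g_t
        v[K.P_G4] = p.g_h
        v[K.P_E3] = p.e_h
        v[K.P_TYPE] = K.TC_CELL
    else:
        v[K.P_G3] = p.g_m
        v[K.P_E3] = p.e_k
        v[K.P_TYPE] = K.CTX_CELL
    return v


def dump_params(p: MembraneParams, path) -> None:
    """Serialize a parameter set to JSON (YAML-compatible subset)."""
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(p), fh, indent=2)


def load_params(path) -> MembraneParams:
    with open(path) as fh:
        return MembraneParams(**json.load(fh))


# ---------------------------------------------------------------------------
# gate kinetics
# ---------------------------------------------------------------------------

def gate_rates(gate: str, v: float, vt: float = -55.0) -> tuple[float, float]:
    """Forward/backward rate constants (1/ms) for one gating variable.

    Channels defined through steady state and time constant are converted
    via alpha = x_inf/tau, beta = (1-x_inf)/tau. Raises ``ValueError`` for
    an unknown gate name.
    """
    if gate == "na_m":
        return K.na_m_rates(v, vt)
    if gate == "na_h":
        return K.na_h_rates(v, vt)
    if gate == "k_n":
        return K.k_n_rates(v, vt)
    if gate == "t_m":
        inf, tau = K.it_m_ss_tau(v)
        return inf / tau, (1.0 - inf) / tau
    if gate == "t_h":
        inf, tau = K.it_h_ss_tau(v)
        return inf / tau, (1.0 - inf) / tau
    if gate == "h_m":
        inf, tau = K.ih_m_ss_tau(v)
        return inf / tau, (1.0 - inf) / tau
    if gate == "m_n":
        return K.im_n_rates(v)
    raise ValueError(f"unknown gate {gate!r}; expected one of {GATES}")


def membrane_derivative(params: MembraneParams, state: np.ndarray,
                        i_syn: float = 0.0, i_fluct: float = 0.0,
                        i_inj: float = 0.0) -> float:
    """dV/dt (mV/ms) for a packed kernel state vector.

    Cm dV/dt = -gL(V-EL) - sum I_ch + I_syn + I_fluct + I_inj, with positive
    currents depolarizing.
    """
    par = params_to_vector(params)
    v = state[K.S_V]
    i_int = K.intrinsic_current(par, state)
    return (-par[K.P_GL] * (v - par[K.P_EL]) * 1e-3
            - i_int + i_syn + i_fluct + i_inj) / par[K.P_CM]


def steady_state(params: MembraneParams, v0: float) -> np.ndarray:
    """Kernel state vector with all gates relaxed at voltage v0."""
    return K.init_state(params_to_vector(params), v0)


# ---------------------------------------------------------------------------
# heterogeneity randomization
# ---------------------------------------------------------------------------

#: parameters subject to cellular-heterogeneity randomization (TC cells):
#: channel maximal conductances, leak conductance and capacitance.
RANDOMIZED_FIELDS = ("g_t", "g_h", "g_na", "g_k", "gl", "cm")


def randomize_cell(params: MembraneParams, h: float,
                   rng: np.random.Generator) -> MembraneParams:
    """Perturb intrinsic parameters by up to +/- h * 100 %.

    Each randomized parameter p0 is replaced by p0*(1 + h*(2u-1)) with an
    independent uniform u per parameter; h is the cellular heterogeneity
    index in [0, 1].
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"heterogeneity index must be in [0, 1], got {h}")
    out = params.copy()
    for name in RANDOMIZED_FIELDS:
        p0 = getattr(out, name)
        setattr(out, name, p0 * (1.0 + h * (2.0 * rng.uniform() - 1.0)))
    return out


# ---------------------------------------------------------------------------
# resting properties
# ---------------------------------------------------------------------------

_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0)


def relax(params: MembraneParams, duration: float = 3000.0,
          dt: float = 0.025, i_const: float = 0.0,
          v0: float | None = None) -> np.ndarray:
    """Voltage trace of the unstimulated (or current-clamped) cell."""
    par = params_to_vector(params)
    n = int(round(duration / dt))
    v_init = params.el if v0 is None else v0
    v, _, _ = K.simulate_cell(
        par, dt, n, v_init,
        _EMPTY_I, _EMPTY_F, 1.0, 0.0,
        _EMPTY_I, _EMPTY_F, 2.0, -75.0,
        _EMPTY_F, _EMPTY_F, 0.0, -75.0,
        i_const, 0.0, 0.0, 0.0, 64)
    return v


def rest_properties(params: MembraneParams, dt: float = 0.025,
                    settle: float = 3000.0, step_i: float = 0.01,
                    step_dur: float = 2000.0) -> tuple[float, float]:
    """Resting potential (mV) and input conductance (nS).

    The cell is relaxed without input; g_in is measured from the steady
    depolarization under small +/- current steps (g = dI/dV). Raises
    ``RuntimeError`` if the relaxed state is oscillatory or spiking.
    """
    v = relax(params, settle, dt)
    tail = v[-int(200.0 / dt):]
    if np.ptp(tail) > 0.5 or not np.all(np.isfinite(tail)):
        raise RuntimeError("cell does not reach a stable resting state")
    v_rest = float(tail[-1])

    dvs = []
    for sign in (+1.0, -1.0):  # symmetric steps cancel rectification
        # apply the step starting from the relaxed state
        vs = relax(params, step_dur, dt, i_const=sign * step_i, v0=v_rest)
        dvs.append(float(vs[-1]) - v_rest)
    dv = (dvs[0] - dvs[1]) / 2.0
    g_in = 1000.0 * step_i / dv  # nA/mV -> uS -> nS
    return v_rest, g_in


def rebound_response(params: MembraneParams, i_hyp: float = -0.15,
                     hyp_dur: float = 500.0, post_dur: float = 300.0,
                     dt: float = 0.025) -> np.ndarray:
    """Spike times (ms, relative to release) after a hyperpolarizing step.

    The cell is settled for 2 s, hyperpolarized by ``i_hyp`` nA for
    ``hyp_dur`` ms and released; the low-threshold calcium current of the
    TC cell produces a rebound burst after the passive recovery.
    """
    par = params_to_vector(params)
    settle = 2000.0
    n = int(round((settle + hyp_dur + post_dur) / dt))
    on = int(round(settle / dt))
    off = int(round((settle + hyp_dur) / dt))
    _, spikes, n_sp = K.simulate_cell(
        par, dt, n, params.el,
        _EMPTY_I, _EMPTY_F, 1.0, 0.0,
        _EMPTY_I, _EMPTY_F, 2.0, -75.0,
        _EMPTY_F, _EMPTY_F, 0.0, -75.0,
        0.0, 0.0, 0.0, 0.0, 256,
        i_hyp, on, off)
    release = settle + hyp_dur
    sp = spikes[:n_sp]
    return sp[sp >= release] - release
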