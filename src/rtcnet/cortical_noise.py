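"""Stochastic corticothalamic conductance bombardment.

The bombardment seen by each TC cell is a pair of Ornstein-Uhlenbeck
conductance processes (excitatory: tau 2.7 ms, E 0 mV; inhibitory: tau
10.5 ms, E -75 mV), the effective description of thousands of stochastically
releasing cortical synapses. Means are specified as "conductance
amplitudes" a = g0/g_in0 (normalized to the cell's rest input conductance,
8.34 nS for the TC cell) and SDs as "variation ratios" v = sigma/g0, so
amplitude 0 also nullifies the fluctuations.

Cross-cell correlation comes in two schemas sharing one correlation
strength c in [0, 1]:

* homogeneous -- every cell mixes its private realization with one shared
  realization using sqrt(1-c)/sqrt(c) weights, which preserves the per-cell
  mean and variance exactly (the first-order invariance every cell sees);
* heterogeneous -- M = 1 + round(c*(N-1)) cells receive the identical
  shared realization and the rest stay independent, c = (M-1)/(N-1).

Within a cell, the exc and inh innovations can be correlated with strength
c_ei and a lag (inhibition lagging excitation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "OUSpec", "CorrelationSpec", "ConductanceTrace", "G_IN0_TC",
    "ou_generate", "normalize", "total_conductance", "correlate_exc_inh",
    "population_field", "fluct_current", "ou_params",
]

#: reference TC rest input conductance used for normalization (nS)
G_IN0_TC = 8.34

E_EXC = 0.0      # mV
E_INH = -75.0    # mV
TAU_EXC = 2.7    # ms
TAU_INH = 10.5   # ms


def normalize(a_x: float, v_x: float, g_in0: float = G_IN0_TC) -> tuple[float, float]:
    """(mean g0, SD sigma) in nS from amplitude a and variation ratio v."""
    if a_x < 0 or v_x < 0:
        raise ValueError("amplitude and variation ratio must be nonnegative")
    g0 = a_x * g_in0
    return g0, v_x * g0


def total_conductance(g0_exc: float, g0_inh: float,
                      g_in0: float = G_IN0_TC) -> tuple[float, float]:
    """Total mean bombardment conductance (nS) and its normalized value."""
    g_total = g0_exc + g0_inh
    return g_total, g_total / g_in0


@dataclass(frozen=True)
class OUSpec:
    """Dual-OU bombardment statistics for one cell."""

    a_exc: float = 0.0        # conductance amplitude, exc
    a_inh: float = 0.0        # conductance amplitude, inh
    v_exc: float = 0.0        # variation ratio, exc
    v_inh: float = 0.0        # variation ratio, inh
    g_in0: float = G_IN0_TC   # normalization reference (nS)
    tau_exc: float = TAU_EXC  # ms
    tau_inh: float = TAU_INH  # ms
    e_exc: float = E_EXC      # mV
    e_inh: float = E_INH      # mV

    @property
    def g0_exc(self) -> float:
        return self.a_exc * self.g_in0

    @property
    def g0_inh(self) -> float:
        return self.a_inh * self.g_in0

    @property
    def sigma_exc(self) -> float:
        return self.v_exc * self.g0_exc

    @property
    def sigma_inh(self) -> float:
        return self.v_inh * self.g0_inh

    def with_amplitudes(self, a_exc, a_inh) -> "OUSpec":
        return replace(self, a_exc=a_exc, a_inh=a_inh)


#: the optimal low-conductance (LC) operating point: a_e=1.5, a_i=1.0, v=0.2
def lc_optimal() -> OUSpec:
    return OUSpec(a_exc=1.5, a_inh=1.0, v_exc=0.2, v_inh=0.2)


#: the optimal high-conductance (HC) operating point: a_e=a_i=2.0, v=0.2
def hc_optimal() -> OUSpec:
    return OUSpec(a_exc=2.0, a_inh=2.0, v_exc=0.2, v_inh=0.2)


@dataclass(frozen=True)
class CorrelationSpec:
    """Exc-inh and cross-population correlation settings."""

    c_ei: float = 0.0         # exc-inh correlation within a cell
    lag_ei: float = 0.0       # ms, inhibition lags excitation
    c_pop: float = 0.0        # cross-cell correlation strength
    schema: str = "homogeneous"  # or "heterogeneous"

    def __post_init__(self):
        for name in ("c_ei", "c_pop"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lag_ei < 0:
            raise ValueError("lag must be nonnegative")
        if self.schema not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown correlation schema {self.schema!r}")


@dataclass
class ConductanceTrace:
    """Sampled g_exc(t), g_inh(t) for one cell (nS, grid step dt ms)."""

    dt: float
    g_exc: np.ndarray
    g_inh: np.ndarray


def _ou_path(g0: float, sigma: float, tau: float, n: int, dt: float,
             xi: np.ndarray) -> np.ndarray:
    """Exact-discretization OU path driven by standard-normal innovations.

    The AR(1) recursion x_k = ef*x_{k-1} + amp*xi_k (deviation from g0,
    started at 0) is evaluated with a linear filter.
    """
    from scipy.signal import lfilter

    ef = np.exp(-dt / tau)
    amp = sigma * np.sqrt(1.0 - ef * ef)
    dev = lfilter([amp], [1.0, -ef], xi)
    return g0 + dev


def ou_generate(spec: OUSpec, duration: float, dt: float,
                rng: np.random.Generator,
                c_ei: float = 0.0, lag_ei: float = 0.0) -> ConductanceTrace:
    """One dual-OU realization: g(t+dt) = g0 + (g-g0)e^(-dt/tau) + sigma
    sqrt(1-e^(-2dt/tau)) xi, started at g0.

    Refuses dt >= tau (the discretization assumes dt << tau).
    """
    if dt >= min(spec.tau_exc, spec.tau_inh):
        raise ValueError("dt must be smaller than the OU correlation times")
    n = int(round(duration / dt))
    xi_e = rng.standard_normal(n)
    xi_i = correlate_exc_inh(c_ei, lag_ei, xi_e, rng, dt)
    g_e = _ou_path(spec.g0_exc, spec.sigma_exc, spec.tau_exc, n, dt, xi_e)
    g_i = _ou_path(spec.g0_inh, spec.sigma_inh, spec.tau_inh, n, dt, xi_i)
    return ConductanceTrace(dt, g_e, g_i)


def correlate_exc_inh(c_ei: float, lag_ei: float, xi_exc: np.ndarray,
                      rng: np.random.Generator, dt: float = 1.0) -> np.ndarray:
    """Inhibitory innovations correlated with (lagged) excitatory ones.

    xi_inh(t) = sqrt(1-c) zeta(t) + sqrt(c) xi_exc(t - lag); unit variance
    is preserved. A lag that is not a multiple of dt is rounded to the grid.
    """
    if not 0.0 <= c_ei <= 1.0:
        raise ValueError("c_ei must be in [0, 1]")
    lag_steps = int(round(lag_ei / dt))
    if abs(lag_steps * dt - lag_ei) > 1e-9 * max(1.0, lag_ei):
        import warnings
        warnings.warn(f"exc-inh lag rounded to {lag_steps * dt} ms (grid dt={dt})")
    zeta = rng.standard_normal(xi_exc.size)
    lagged = np.empty_like(xi_exc)
    if lag_steps == 0:
        lagged[:] = xi_exc
    else:
        # before any lagged excitation exists, use fresh independent noise
        lagged[:lag_steps] = rng.standard_normal(lag_steps)
        lagged[lag_steps:] = xi_exc[:-lag_steps]
    return np.sqrt(1.0 - c_ei) * zeta + np.sqrt(c_ei) * lagged


def population_field(corr: CorrelationSpec, spec: OUSpec, n_cells: int,
                     duration: float, dt: float,
                     rng: np.random.Generator) -> list[ConductanceTrace]:
    """Per-cell bombardment traces under one of the correlation schemas.

    Homogeneous: g_i = g0 + sqrt(1-c)(g_ind,i - g0) + sqrt(c)(g_com - g0);
    heterogeneous: the first M = 1 + round(c*(N-1)) cells share g_com, the
    rest get independent realizations.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    common = ou_generate(spec, duration, dt, rng, corr.c_ei, corr.lag_ei)
    indep = [ou_generate(spec, duration, dt, rng, corr.c_ei, corr.lag_ei)
             for _ in range(n_cells)]
    out = []
    if corr.schema == "homogeneous":
        wi = np.sqrt(1.0 - corr.c_pop)
        wc = np.sqrt(corr.c_pop)
        for tr in indep:
            ge = spec.g0_exc + wi * (tr.g_exc - spec.g0_exc) + wc * (common.g_exc - spec.g0_exc)
            gi = spec.g0_inh + wi * (tr.g_inh - spec.g0_inh) + wc * (common.g_inh - spec.g0_inh)
            out.append(ConductanceTrace(dt, ge, gi))
    else:
        m = n_shared(corr.c_pop, n_cells)
        for i in range(n_cells):
            if i < m:
                out.append(ConductanceTrace(dt, common.g_exc.copy(),
                                            common.g_inh.copy()))
            else:
                out.append(indep[i])
    return out


def n_shared(c_pop: float, n_cells: int) -> int:
    """M = 1 + round(c*(N-1)), round-half-up."""
    if n_cells == 1:
        return 1
    return 1 + int(np.floor(c_pop * (n_cells - 1) + 0.5))


def fluct_current(g_exc, g_inh, v, e_exc: float = E_EXC,
                  e_inh: float = E_INH):
    """Bombardment current I = g_exc(E_exc - V) + g_inh(E_inh - V), nA.

    Negative conductance excursions are clipped to zero at the point of
    current evaluation only (the OU state itself is never clipped).
    """
    ge = np.maximum(np.asarray(g_exc, dtype=float), 0.0)
    gi = np.maximum(np.asarray(g_inh, dtype=float), 0.0)
    return (ge * (e_exc - np.asarray(v)) + gi * (e_inh - np.asarray(v))) * 1e-3


def ou_params(spec: OUSpec) -> tuple[float, float, float, float, float, float, float, float]:
    """Flat (ge0, sige, taue, Ee, gi0, sigi, taui, Ei) tuple for the kernels."""
    return (spec.g0_exc, spec.sigma_exc, spec.tau_exc, spec.e_exc,
            spec.g0_inh, spec.sigma_inh, spec.tau_inh, spec.e_inh)
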