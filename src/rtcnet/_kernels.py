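"""Numba-compiled integration kernels.

Units throughout: time ms, voltage mV, conductance nS, capacitance nF,
current nA (nS*mV = pA, hence the 1e-3 factors). Intrinsic currents are
written I_ch = g*m^a*h^b*(V-E_ch) and enter the membrane equation with a
minus sign, so inward (depolarizing) currents are negative as written.

Gates use exponential-Euler updates; the voltage uses a forward update.
Rate functions with removable singularities go through `_vtrap`.
"""

import numpy as np
from numba import njit

# spike detection: upward crossing of SPIKE_THR, re-armed below SPIKE_REARM
SPIKE_THR = -30.0
SPIKE_REARM = -45.0

# calcium pool (TC cell): Destexhe-style first-order buffering
CA_INF = 2.4e-4  # mM
CA_TAU = 5.0     # ms
CA_OUT = 2.0     # mM
RT2F = 13.32     # RT/2F at ~36 C, mV

# temperature adjustment factors (kinetics fitted at 23-24 C, run at 36 C)
PHI_T = 3.737    # 3.0**1.2, I_T gates
TADJ_M = 2.95    # 2.3**1.3, I_M gate

# cell type tags
TC_CELL = 0
CTX_CELL = 1

# parameter-vector layout (one float64[12] per cell)
P_CM, P_GL, P_EL, P_GNA, P_GK, P_G3, P_G4, P_VT, P_ENA, P_EK, P_E3, P_TYPE = range(12)
NPAR = 12

# state-vector layout
S_V, S_M, S_H, S_N, S_TM, S_TH, S_HM, S_CA = range(8)
NSTATE = 8


@njit(cache=True)
def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the series limit at x -> 0."""
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (np.exp(x / y) - 1.0)


@njit(cache=True)
def na_m_rates(v, vt):
    u = v - vt
    am = 0.32 * _vtrap(13.0 - u, 4.0)
    bm = 0.28 * _vtrap(u - 40.0, 5.0)
    return am, bm


@njit(cache=True)
def na_h_rates(v, vt):
    u = v - vt
    ah = 0.128 * np.exp((17.0 - u) / 18.0)
    bh = 4.0 / (1.0 + np.exp((40.0 - u) / 5.0))
    return ah, bh


@njit(cache=True)
def k_n_rates(v, vt):
    u = v - vt
    an = 0.032 * _vtrap(15.0 - u, 5.0)
    bn = 0.5 * np.exp((10.0 - u) / 40.0)
    return an, bn


@njit(cache=True)
def it_m_ss_tau(v):
    vs = v + 2.0
    minf = 1.0 / (1.0 + np.exp(-(vs + 57.0) / 6.2))
    taum = (0.612 + 1.0 / (np.exp(-(vs + 132.0) / 16.7)
                           + np.exp((vs + 16.8) / 18.2))) / PHI_T
    return minf, taum


@njit(cache=True)
def it_h_ss_tau(v):
    vs = v + 2.0
    hinf = 1.0 / (1.0 + np.exp((vs + 81.0) / 4.0))
    if vs < -80.0:
        tauh = np.exp((vs + 467.0) / 66.6) / PHI_T
    else:
        tauh = (28.0 + np.exp(-(vs + 22.0) / 10.5)) / PHI_T
    return hinf, tauh


@njit(cache=True)
def ih_m_ss_tau(v):
    minf = 1.0 / (1.0 + np.exp((v + 75.0) / 5.5))
    tau = 1.0 / (np.exp(-14.59 - 0.086 * v) + np.exp(-1.87 + 0.0701 * v))
    return minf, tau


@njit(cache=True)
def im_n_rates(v):
    a = 1e-4 * _vtrap(-(v + 30.0), 9.0) * TADJ_M
    b = 1e-4 * _vtrap(v + 30.0, 9.0) * TADJ_M
    return a, b


@njit(cache=True)
def init_state(par, v0):
    """Gate variables at steady state for voltage v0."""
    s = np.zeros(NSTATE)
    s[S_V] = v0
    vt = par[P_VT]
    am, bm = na_m_rates(v0, vt)
    ah, bh = na_h_rates(v0, vt)
    an, bn = k_n_rates(v0, vt)
    s[S_M] = am / (am + bm)
    s[S_H] = ah / (ah + bh)
    s[S_N] = an / (an + bn)
    if par[P_TYPE] == TC_CELL:
        s[S_TM] = it_m_ss_tau(v0)[0]
        s[S_TH] = it_h_ss_tau(v0)[0]
        s[S_HM] = ih_m_ss_tau(v0)[0]
        s[S_CA] = CA_INF
    else:
        a, b = im_n_rates(v0)
        s[S_HM] = a / (a + b)
        s[S_CA] = CA_INF
    return s


@njit(cache=True)
def intrinsic_split(par, s):
    """Intrinsic currents as (total conductance nS, conductance-weighted
    reversal sum nS*mV), so that I_int = g_sum*V - ge_sum in pA."""
    g_na = par[P_GNA] * s[S_M] ** 3 * s[S_H]
    g_k = par[P_GK] * s[S_N] ** 4
    g_sum = g_na + g_k
    ge_sum = g_na * par[P_ENA] + g_k * par[P_EK]
    if par[P_TYPE] == TC_CELL:
        eca = RT2F * np.log(CA_OUT / s[S_CA])
        g_t = par[P_G3] * s[S_TM] ** 2 * s[S_TH]
        g_h = par[P_G4] * s[S_HM]
        g_sum += g_t + g_h
        ge_sum += g_t * eca + g_h * par[P_E3]
    else:
        g_m = par[P_G3] * s[S_HM]
        g_sum += g_m
        ge_sum += g_m * par[P_EK]
    return g_sum, ge_sum


@njit(cache=True)
def intrinsic_current(par, s):
    """Sum of intrinsic currents I_ch = g*m^a*h^b*(V-E), in nA."""
    g_sum, ge_sum = intrinsic_split(par, s)
    return (g_sum * s[S_V] - ge_sum) * 1e-3


@njit(cache=True)
def membrane_update(par, s, dt, g_extra, ge_extra, i_inj):
    """Exponential-Euler voltage update (unconditionally stable).

    Conductances are frozen over the step: V relaxes toward
    V_inf = (gL*EL + sum g*E + 1000*I_inj) / G_tot with time constant
    Cm/G_tot. `g_extra`/`ge_extra` carry synaptic and fluctuating
    conductances (nS and nS*mV); `i_inj` is in nA.
    """
    g_int, ge_int = intrinsic_split(par, s)
    g_tot = par[P_GL] + g_int + g_extra
    ge_tot = par[P_GL] * par[P_EL] + ge_int + ge_extra + 1000.0 * i_inj
    v_inf = ge_tot / g_tot
    tau = 1000.0 * par[P_CM] / g_tot   # ms
    v_new = v_inf + (s[S_V] - v_inf) * np.exp(-dt / tau)
    s[S_V] = v_new
    return v_new


@njit(cache=True)
def step_gates(par, s, dt):
    """Exponential-Euler gate update in place; returns I_T (nA) for Ca."""
    v = s[S_V]
    vt = par[P_VT]
    am, bm = na_m_rates(v, vt)
    ah, bh = na_h_rates(v, vt)
    an, bn = k_n_rates(v, vt)
    s[S_M] = am / (am + bm) + (s[S_M] - am / (am + bm)) * np.exp(-dt * (am + bm))
    s[S_H] = ah / (ah + bh) + (s[S_H] - ah / (ah + bh)) * np.exp(-dt * (ah + bh))
    s[S_N] = an / (an + bn) + (s[S_N] - an / (an + bn)) * np.exp(-dt * (an + bn))
    i_t = 0.0
    if par[P_TYPE] == TC_CELL:
        minf, taum = it_m_ss_tau(v)
        hinf, tauh = it_h_ss_tau(v)
        s[S_TM] = minf + (s[S_TM] - minf) * np.exp(-dt / taum)
        s[S_TH] = hinf + (s[S_TH] - hinf) * np.exp(-dt / tauh)
        hminf, htau = ih_m_ss_tau(v)
        s[S_HM] = hminf + (s[S_HM] - hminf) * np.exp(-dt / htau)
        eca = RT2F * np.log(CA_OUT / s[S_CA])
        i_t = par[P_G3] * s[S_TM] ** 2 * s[S_TH] * (v - eca) * 1e-3
        # calcium pool: influx from I_T plus first-order decay
        cm = par[P_CM]
        drive = -i_t * 5.1822e-5 / cm  # mM/ms per nA, depth 1 um
        if drive < 0.0:
            drive = 0.0
        s[S_CA] += dt * (drive + (CA_INF - s[S_CA]) / CA_TAU)
        if s[S_CA] < 1e-8:
            s[S_CA] = 1e-8
    else:
        a, b = im_n_rates(v)
        ninf = a / (a + b)
        s[S_HM] = ninf + (s[S_HM] - ninf) * np.exp(-dt * (a + b))
    return i_t


@njit(cache=True)
def simulate_cell(par, dt, n_steps, v0,
                  exc_step, exc_w, tau_exc, e_exc,
                  inh_step, inh_w, tau_inh, e_inh,
                  ge_arr, gi_arr, e_ge, e_gi,
                  i_const, sine_amp, sine_f, sine_phase,
                  max_spikes,
                  i_step=0.0, step_on=-1, step_off=-1,
                  i_arr=np.empty(0)):
    """Integrate one cell driven by alpha-synapse events, fluctuating
    conductance arrays (may be empty), and constant/sine current.

    Event arrays hold (step index, weight) pairs sorted by step; each event
    starts one alpha kernel g(s) = w*(s/tau)*exp(1-s/tau), implemented with
    the exact two-variable update g <- exp(-dt/tau)*(g + dt*a), a <- exp(-dt/tau)*a.

    Returns (v_trace, spike_times, n_spikes).
    """
    s = init_state(par, v0)
    cm = par[P_CM]
    gl = par[P_GL]
    el = par[P_EL]
    v_trace = np.empty(n_steps + 1)
    v_trace[0] = s[S_V]
    spikes = np.empty(max_spikes)
    n_sp = 0
    armed = True

    g_e = 0.0
    a_e = 0.0
    g_i = 0.0
    a_i = 0.0
    dec_e = np.exp(-dt / tau_exc)
    dec_i = np.exp(-dt / tau_inh)
    kick_e = np.e / tau_exc
    kick_i = np.e / tau_inh
    ie = 0
    ii = 0
    n_exc = exc_step.shape[0]
    n_inh = inh_step.shape[0]
    has_ou = ge_arr.shape[0] > 0
    two_pi = 2.0 * np.pi

    for k in range(n_steps):
        while ie < n_exc and exc_step[ie] == k:
            a_e += exc_w[ie] * kick_e
            ie += 1
        while ii < n_inh and inh_step[ii] == k:
            a_i += inh_w[ii] * kick_i
            ii += 1

        v = s[S_V]
        g_extra = g_e + g_i
        ge_extra = g_e * e_exc + g_i * e_inh
        if has_ou:
            ge = ge_arr[k]
            gi = gi_arr[k]
            if ge < 0.0:
                ge = 0.0
            if gi < 0.0:
                gi = 0.0
            g_extra += ge + gi
            ge_extra += ge * e_ge + gi * e_gi
        t = k * dt
        i_inj = i_const + sine_amp * np.sin(two_pi * sine_f * t * 1e-3 + sine_phase)
        if step_on <= k < step_off:
            i_inj += i_step
        if i_arr.shape[0] > 0:
            i_inj += i_arr[k]

        v_new = membrane_update(par, s, dt, g_extra, ge_extra, i_inj)
        step_gates(par, s, dt)

        # alpha synapse state decay
        g_e = dec_e * (g_e + dt * a_e)
        a_e = dec_e * a_e
        g_i = dec_i * (g_i + dt * a_i)
        a_i = dec_i * a_i

        v_trace[k + 1] = v_new
        if armed:
            if v <= SPIKE_THR and v_new > SPIKE_THR and n_sp < max_spikes:
                spikes[n_sp] = (k + 1) * dt
                n_sp += 1
                armed = False
        elif v_new < SPIKE_REARM:
            armed = True
        if abs(v_new) > 200.0:
            # numerical blow-up: signal with NaN tail
            v_trace[k + 1:] = np.nan
            return v_trace, spikes[:n_sp], -1
    return v_trace, spikes[:n_sp], n_sp


@njit(cache=True)
def tc_population_kernel(params, dt, n_steps,
                         ev_step, ev_w, ev_indptr,
                         tau_ampa, e_ampa,
                         ge0, sige, taue, e_ge,
                         gi0, sigi, taui, e_gi,
                         c_ei, lag_steps,
                         schema, c_pop, m_shared,
                         i_const, sine_amp, sine_f, sine_phase,
                         seed, rec_stride, max_spikes,
                         noise_arrays, use_arrays):
    """Integrate a TC population under stochastic conductance bombardment.

    Retinal drive per cell is given in CSR form (ev_indptr slices ev_step /
    ev_w). Bombardment is a dual OU process generated in-stream (exact
    discretization) unless `use_arrays` is set, in which case
    `noise_arrays[cell, 0/1, step]` supplies g_exc/g_inh directly.

    Population correlation: schema 0 ("homogeneous") mixes every cell's
    independent realization with one shared realization using sqrt weights,
    preserving per-cell mean and variance; schema 1 ("heterogeneous") gives
    the first `m_shared` cells the shared realization verbatim and the rest
    independent ones. Exc-inh correlation c_ei mixes the inhibitory
    innovations with the (lagged) excitatory innovations of the same stream.

    Returns (spike_times (n,max_spikes), spike_counts, v_rec, blowup_flag).
    """
    n = params.shape[0]
    np.random.seed(seed)

    states = np.empty((n, NSTATE))
    for i in range(n):
        states[i] = init_state(params[i], params[i, P_EL])

    # alpha synapse state per cell (retinal AMPA)
    g_e = np.zeros(n)
    a_e = np.zeros(n)
    dec_e = np.exp(-dt / tau_ampa)
    kick_e = np.e / tau_ampa
    ev_pos = ev_indptr[:-1].copy()

    # OU state: independent per cell + one shared stream (index n)
    oug_e = np.full(n + 1, ge0)
    oug_i = np.full(n + 1, gi0)
    ef_e = np.exp(-dt / taue)
    ef_i = np.exp(-dt / taui)
    amp_e = sige * np.sqrt(1.0 - ef_e * ef_e)
    amp_i = sigi * np.sqrt(1.0 - ef_i * ef_i)
    nbuf = max(1, lag_steps)
    xibuf = np.zeros((n + 1, nbuf))  # ring buffer of exc innovations
    bufpos = 0
    w_ind = np.sqrt(1.0 - c_pop)
    w_com = np.sqrt(c_pop)
    sq_ei = np.sqrt(c_ei)
    sq_nei = np.sqrt(1.0 - c_ei)

    n_rec = n_steps // rec_stride + 1
    v_rec = np.empty((n, n_rec))
    for i in range(n):
        v_rec[i, 0] = states[i, S_V]
    spike_t = np.zeros((n, max_spikes))
    spike_c = np.zeros(n, dtype=np.int64)
    armed = np.ones(n, dtype=np.bool_)
    two_pi = 2.0 * np.pi
    blow = 0

    for k in range(n_steps):
        # --- advance OU streams ---
        if not use_arrays:
            lagpos = (bufpos + 1) % nbuf  # oldest entry = lagged innovation
            for j in range(n + 1):
                xi_e = np.random.normal()
                zeta = np.random.normal()
                if lag_steps > 0:
                    xi_lag = xibuf[j, lagpos]
                else:
                    xi_lag = xi_e
                xi_i = sq_nei * zeta + sq_ei * xi_lag
                xibuf[j, bufpos] = xi_e
                oug_e[j] = ge0 + (oug_e[j] - ge0) * ef_e + amp_e * xi_e
                oug_i[j] = gi0 + (oug_i[j] - gi0) * ef_i + amp_i * xi_i
            bufpos = (bufpos + 1) % nbuf

        t = k * dt
        for i in range(n):
            # deliver retinal events
            p = ev_pos[i]
            while p < ev_indptr[i + 1] and ev_step[p] == k:
                a_e[i] += ev_w[p] * kick_e
                p += 1
            ev_pos[i] = p

            # bombardment conductances for this cell
            if use_arrays:
                gec = noise_arrays[i, 0, k]
                gic = noise_arrays[i, 1, k]
            elif schema == 0:
                gec = ge0 + w_ind * (oug_e[i] - ge0) + w_com * (oug_e[n] - ge0)
                gic = gi0 + w_ind * (oug_i[i] - gi0) + w_com * (oug_i[n] - gi0)
            else:
                if i < m_shared:
                    gec = oug_e[n]
                    gic = oug_i[n]
                else:
                    gec = oug_e[i]
                    gic = oug_i[i]
            if gec < 0.0:
                gec = 0.0
            if gic < 0.0:
                gic = 0.0

            v = states[i, S_V]
            g_extra = g_e[i] + gec + gic
            ge_extra = g_e[i] * e_ampa + gec * e_ge + gic * e_gi
            i_inj = i_const[i] + sine_amp[i] * np.sin(
                two_pi * sine_f * t * 1e-3 + sine_phase[i])

            par = params[i]
            v_new = membrane_update(par, states[i], dt, g_extra, ge_extra,
                                    i_inj)
            step_gates(par, states[i], dt)

            g_e[i] = dec_e * (g_e[i] + dt * a_e[i])
            a_e[i] = dec_e * a_e[i]

            if armed[i]:
                if v <= SPIKE_THR and v_new > SPIKE_THR and spike_c[i] < max_spikes:
                    spike_t[i, spike_c[i]] = (k + 1) * dt
                    spike_c[i] += 1
                    armed[i] = False
            elif v_new < SPIKE_REARM:
                armed[i] = True
            if abs(v_new) > 200.0:
                blow = 1

        if (k + 1) % rec_stride == 0:
            kk = (k + 1) // rec_stride
            for i in range(n):
                v_rec[i, kk] = states[i, S_V]
        if blow:
            return spike_t, spike_c, v_rec, 1
    return spike_t, spike_c, v_rec, 0
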