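"""Topology construction, synapse kernels and the network integrator."""

import numpy as np
import pytest

from rtcnet import cell_models as cm
from rtcnet import circuit_sim as cs
from rtcnet import cortical_noise as cn
from rtcnet import info_metrics as im
from rtcnet import stimuli as st
from rtcnet.stimuli import SpikeTrain


def test_alpha_kernel_shape():
    s = np.linspace(-2.0, 20.0, 2001)
    g = cs.alpha_conductance(5.0, 1.0, s)
    assert np.all(g[s < 0] == 0.0)
    assert cs.alpha_conductance(5.0, 1.0, 1.0) == pytest.approx(5.0)
    assert cs.alpha_conductance(5.0, 1.0, 0.0) == 0.0
    assert cs.alpha_conductance(5.0, 1.0, 200.0) < 1e-12
    # numeric argmax sits at tau_peak
    fine = np.linspace(0.0, 5.0, 50_001)
    assert fine[np.argmax(cs.alpha_conductance(5.0, 2.0, fine))] == \
        pytest.approx(2.0, abs=1e-3)


def test_alpha_kernel_linearity():
    """Kernels from two presynaptic events superpose exactly."""
    t = np.linspace(0.0, 30.0, 3001)
    both = (cs.alpha_conductance(4.0, 1.0, t - 5.0)
            + cs.alpha_conductance(4.0, 1.0, t - 9.0))
    single_a = cs.alpha_conductance(4.0, 1.0, t - 5.0)
    single_b = cs.alpha_conductance(4.0, 1.0, t - 9.0)
    np.testing.assert_allclose(both, single_a + single_b)


def test_build_single_preset():
    circ = cs.build_circuit("single", 30)
    assert circ.n_ret == 1 and len(circ.ret_edges) == 30
    assert all(w == 12.5 for (_, _, w) in circ.ret_edges)
    assert np.all(circ.w_tc == 7.0)
    assert circ.w_tc.sum() == pytest.approx(210.0)


def test_build_mixed_preset_degrees():
    circ = cs.build_circuit("mixed", 30)
    assert circ.n_ret == 15
    for i in range(30):
        assert circ.in_degree(i) == 2
    for r in range(15):
        assert circ.out_degree(r) == 4
    # per-cell weight split 9.375/3.125 summing to the single-line 12.5
    for i in range(30):
        ws = sorted(w for (_, tc, w) in circ.ret_edges if tc == i)
        assert ws == [3.125, 9.375]


def test_tc_weight_presets():
    assert cs.tc_weight_for(90) == 2.33
    assert cs.tc_weight_for(30) == 7.0
    assert cs.tc_weight_for(10) == 21.0
    assert cs.tc_weight_for(60) == pytest.approx(3.5)
    with pytest.raises(ValueError):
        cs.build_circuit("mixed", 20)
    with pytest.raises(ValueError):
        cs.build_circuit("lattice", 30)


def test_silent_without_input():
    circ = cs.build_circuit("single", 3)
    ret = SpikeTrain(np.array([]), 2000.0)
    res = cs.simulate(circ, [ret], duration=2000.0, seed=0)
    assert all(len(t) == 0 for t in res.tc_spikes)
    assert len(res.ctx_spikes) == 0


def test_cortical_event_threshold_bracket():
    """~80 nS single AMPA event fires the resting cortical cell; 40 nS
    does not."""
    def n_spikes(w):
        circ = cs.CircuitSpec(n_ret=0, n_tc=1, w_tc=np.array([w]),
                              tc_params=[], ctx_params=cm.ctx_default())
        _, sp = cs.simulate_cortical_cell(
            circ, [SpikeTrain(np.array([50.0]), 300.0)], 300.0)
        return len(sp)

    assert n_spikes(85.0) == 1
    assert n_spikes(40.0) == 0


def test_determinism_bit_identical():
    rng = np.random.default_rng(0)
    ret = st.gamma_spike_train(st.RetinalGenSpec(duration=5000.0), rng)
    circ = cs.build_circuit("single", 5)
    kw = dict(noise=cn.lc_optimal(), corr=cn.CorrelationSpec(),
              duration=5000.0, seed=123)
    a = cs.simulate(circ, [ret], **kw)
    b = cs.simulate(circ, [ret], **kw)
    for ta, tb in zip(a.tc_spikes, b.tc_spikes):
        np.testing.assert_array_equal(ta.times, tb.times)
    np.testing.assert_array_equal(a.ctx_spikes.times, b.ctx_spikes.times)
    np.testing.assert_array_equal(a.tc_v, b.tc_v)


def test_identical_noise_traces_synchronize_population():
    """Explicit identical conductance traces + identical cells + common
    retinal input give bit-identical TC responses (c_pop = 1 limit)."""
    rng = np.random.default_rng(1)
    ret = st.gamma_spike_train(st.RetinalGenSpec(duration=4000.0), rng)
    circ = cs.build_circuit("single", 4)
    trace = cn.ou_generate(cn.lc_optimal(), 4000.0, 0.025,
                           np.random.default_rng(2))
    res = cs.simulate(circ, [ret], duration=4000.0, seed=3,
                      noise_traces=[trace] * 4)
    for t in res.tc_spikes[1:]:
        np.testing.assert_array_equal(t.times, res.tc_spikes[0].times)


def test_ffi_zero_weight_is_inert():
    rng = np.random.default_rng(4)
    ret = st.gamma_spike_train(st.RetinalGenSpec(duration=4000.0), rng)
    base = cs.build_circuit("single", 5)
    with_ffi = cs.attach_ffi(cs.build_circuit("single", 5), 0.0, 1.0)
    kw = dict(noise=cn.lc_optimal(), corr=cn.CorrelationSpec(),
              duration=4000.0, seed=5)
    a = cs.simulate(base, [ret], **kw)
    b = cs.simulate(with_ffi, [ret], **kw)
    np.testing.assert_array_equal(a.ctx_spikes.times, b.ctx_spikes.times)
    with pytest.raises(ValueError):
        cs.attach_ffi(base, 20.0, 1.0)


def test_ffi_inhibits_cortical_firing():
    rng = np.random.default_rng(6)
    ret = st.gamma_spike_train(st.RetinalGenSpec(duration=10_000.0), rng)
    kw = dict(noise=cn.lc_optimal(), corr=cn.CorrelationSpec(),
              duration=10_000.0, seed=7)
    base = cs.simulate(cs.build_circuit("single", 30), [ret], **kw)
    strong = cs.simulate(
        cs.attach_ffi(cs.build_circuit("single", 30), 8.0, 1.0), [ret], **kw)
    assert len(strong.ctx_spikes) < len(base.ctx_spikes)


def test_impaired_cells_lose_retinal_input_only():
    rng = np.random.default_rng(8)
    ret = st.gamma_spike_train(st.RetinalGenSpec(duration=8000.0), rng)
    circ = cs.build_circuit("single", 6)
    mask = np.array([True, True, True, False, False, False])
    res = cs.simulate(circ, [ret], noise=cn.lc_optimal(),
                      corr=cn.CorrelationSpec(), duration=8000.0, seed=9,
                      active_mask=mask)
    active = np.mean([res.tc_spikes[i].rate for i in range(3)])
    inactive = np.mean([res.tc_spikes[i].rate for i in range(3, 6)])
    # impaired cells still fire from bombardment, but less
    assert 0.0 < inactive < active


def test_sta_peaks_before_cortical_spikes(lc_run):
    """Cortical spikes are preceded by a thalamic synchrony peak in the
    last few ms (LC-optimal uncorrelated regime)."""
    _, res = lc_run
    lags, mean, _ = im.spike_triggered_average(res.ctx_spikes, res.tc_spikes)
    peak_lag = lags[np.argmax(mean)]
    assert peak_lag <= 5.0


def test_thalamic_jitter_preserves_counts():
    rng = np.random.default_rng(10)
    ret = st.gamma_spike_train(st.RetinalGenSpec(duration=5000.0), rng)
    circ = cs.build_circuit("single", 5)
    kw = dict(noise=cn.lc_optimal(), corr=cn.CorrelationSpec(),
              duration=5000.0, seed=11)
    a = cs.simulate(circ, [ret], **kw)
    b = cs.simulate(circ, [ret], thalamic_jitter=2.0, **kw)
    for ta, tb in zip(a.tc_spikes, b.tc_spikes):
        assert len(ta) == len(tb)
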