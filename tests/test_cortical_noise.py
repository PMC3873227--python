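"""OU bombardment statistics, normalization and correlation schemas."""

import numpy as np
import pytest

from rtcnet import cortical_noise as cn


def test_normalization_convention():
    assert cn.normalize(3.0, 0.0) == (pytest.approx(25.02), 0.0)
    g0, sig = cn.normalize(1.5, 1.0)
    assert sig == pytest.approx(12.51)
    # amplitude 0 nullifies the fluctuations regardless of v
    assert cn.normalize(0.0, 1.0) == (0.0, 0.0)
    with pytest.raises(ValueError):
        cn.normalize(-1.0, 0.2)


def test_total_conductance_operating_points():
    lc = cn.lc_optimal()
    g_tot, g_norm = cn.total_conductance(lc.g0_exc, lc.g0_inh)
    assert g_tot == pytest.approx(20.85)
    assert g_norm == pytest.approx(2.5)
    hc = cn.hc_optimal()
    g_tot, g_norm = cn.total_conductance(hc.g0_exc, hc.g0_inh)
    assert g_tot == pytest.approx(33.36)
    assert g_norm == pytest.approx(4.0)
    assert cn.total_conductance(0.0, 0.0) == (0.0, 0.0)


def test_ou_zero_sigma_is_constant():
    spec = cn.OUSpec(a_exc=1.5, a_inh=1.0)  # v = 0
    tr = cn.ou_generate(spec, 100.0, 0.05, np.random.default_rng(0))
    assert np.all(tr.g_exc == spec.g0_exc)
    assert np.all(tr.g_inh == spec.g0_inh)


def test_ou_stationary_moments():
    """100 s path: mean within 2% of g0, SD within 3% of sigma."""
    spec = cn.lc_optimal()
    tr = cn.ou_generate(spec, 100_000.0, 0.1, np.random.default_rng(1))
    half = tr.g_exc.size // 10   # skip transient
    for g, g0, sig in ((tr.g_exc, spec.g0_exc, spec.sigma_exc),
                       (tr.g_inh, spec.g0_inh, spec.sigma_inh)):
        assert g[half:].mean() == pytest.approx(g0, rel=0.02)
        assert g[half:].std() == pytest.approx(sig, rel=0.03)


def test_ou_autocorrelation_time():
    """Autocorrelation at lag tau is ~ e^-1."""
    spec = cn.OUSpec(a_exc=1.0, a_inh=1.0, v_exc=0.3, v_inh=0.3)
    tr = cn.ou_generate(spec, 200_000.0, 0.1, np.random.default_rng(2))
    for g, tau in ((tr.g_exc, spec.tau_exc), (tr.g_inh, spec.tau_inh)):
        x = g - g.mean()
        k = int(round(tau / 0.1))
        rho = np.dot(x[:-k], x[k:]) / np.dot(x, x)
        assert rho == pytest.approx(np.exp(-1.0), abs=0.02)


def test_ou_rejects_coarse_dt():
    with pytest.raises(ValueError):
        cn.ou_generate(cn.lc_optimal(), 100.0, 5.0, np.random.default_rng(0))


def test_correlate_exc_inh_limits():
    rng = np.random.default_rng(3)
    xi = rng.standard_normal(200_000)
    xi0 = cn.correlate_exc_inh(0.0, 0.0, xi, rng)
    assert abs(np.corrcoef(xi, xi0)[0, 1]) < 0.01
    np.testing.assert_array_equal(cn.correlate_exc_inh(1.0, 0.0, xi, rng), xi)


def test_correlate_exc_inh_mixing_law():
    """c = 0.5 with a lag: correlation sqrt(0.5) at the lag, ~0 elsewhere;
    unit variance preserved."""
    rng = np.random.default_rng(4)
    xi = rng.standard_normal(400_000)
    lag = 20
    out = cn.correlate_exc_inh(0.5, float(lag), xi, rng, dt=1.0)
    assert out.std() == pytest.approx(1.0, rel=0.01)
    rho_lag = np.corrcoef(xi[:-lag], out[lag:])[0, 1]
    assert rho_lag == pytest.approx(np.sqrt(0.5), abs=0.01)
    assert abs(np.corrcoef(xi, out)[0, 1]) < 0.01


def test_population_field_extremes():
    spec = cn.OUSpec(a_exc=1.0, a_inh=1.0, v_exc=0.3, v_inh=0.3)
    for schema in ("homogeneous", "heterogeneous"):
        rng = np.random.default_rng(5)
        full = cn.population_field(
            cn.CorrelationSpec(c_pop=1.0, schema=schema), spec, 5,
            2000.0, 0.1, rng)
        for tr in full[1:]:
            np.testing.assert_allclose(tr.g_exc, full[0].g_exc)
        rng = np.random.default_rng(6)
        indep = cn.population_field(
            cn.CorrelationSpec(c_pop=0.0, schema=schema), spec, 5,
            20_000.0, 0.1, rng)
        for i in range(1, 5):
            rho = np.corrcoef(indep[0].g_exc, indep[i].g_exc)[0, 1]
            assert abs(rho) < 0.05


def test_population_field_correlation_structure():
    """Homogeneous c=0.8: pair correlations unimodal near 0.8;
    heterogeneous: bimodal (~1 in the shared subset, ~0 outside)."""
    spec = cn.OUSpec(a_exc=1.0, a_inh=1.0, v_exc=0.3, v_inh=0.3)
    n = 10
    rng = np.random.default_rng(7)
    hom = cn.population_field(
        cn.CorrelationSpec(c_pop=0.8, schema="homogeneous"), spec, n,
        60_000.0, 0.2, rng)
    rhos = [np.corrcoef(hom[i].g_exc, hom[j].g_exc)[0, 1]
            for i in range(n) for j in range(i + 1, n)]
    assert np.mean(rhos) == pytest.approx(0.8, abs=0.05)
    assert np.std(rhos) < 0.1

    het = cn.population_field(
        cn.CorrelationSpec(c_pop=0.8, schema="heterogeneous"), spec, n,
        60_000.0, 0.2, np.random.default_rng(8))
    m = cn.n_shared(0.8, n)
    assert m == 1 + round(0.8 * (n - 1))
    in_rho = [np.corrcoef(het[i].g_exc, het[j].g_exc)[0, 1]
              for i in range(m) for j in range(i + 1, m)]
    out_rho = [np.corrcoef(het[i].g_exc, het[j].g_exc)[0, 1]
               for i in range(m) for j in range(m, n)]
    assert min(in_rho) > 0.99
    assert max(np.abs(out_rho)) < 0.1


def test_first_order_invariance():
    """Per-cell mean/variance are invariant to c_pop and schema."""
    spec = cn.OUSpec(a_exc=1.5, a_inh=1.0, v_exc=0.2, v_inh=0.2)
    stats = []
    for schema in ("homogeneous", "heterogeneous"):
        for c in (0.0, 0.5, 1.0):
            rng = np.random.default_rng(9)
            field = cn.population_field(
                cn.CorrelationSpec(c_pop=c, schema=schema), spec, 4,
                100_000.0, 0.1, rng)
            g = field[0].g_exc[10_000:]
            stats.append((g.mean(), g.std()))
    means = np.array([s[0] for s in stats])
    sds = np.array([s[1] for s in stats])
    assert np.ptp(means) / spec.g0_exc < 0.02
    assert np.ptp(sds) / spec.sigma_exc < 0.08


def test_pair_correlation_monotone_in_cpop():
    spec = cn.OUSpec(a_exc=1.0, a_inh=1.0, v_exc=0.3, v_inh=0.3)
    for schema in ("homogeneous", "heterogeneous"):
        means = []
        for c in (0.0, 0.3, 0.6, 1.0):
            field = cn.population_field(
                cn.CorrelationSpec(c_pop=c, schema=schema), spec, 6,
                30_000.0, 0.2, np.random.default_rng(10))
            rhos = [np.corrcoef(field[i].g_exc, field[j].g_exc)[0, 1]
                    for i in range(6) for j in range(i + 1, 6)]
            means.append(np.mean(rhos))
        assert all(b >= a - 0.03 for a, b in zip(means, means[1:]))


def test_homogeneous_mixing_preserves_autocorrelation():
    spec = cn.OUSpec(a_exc=1.0, a_inh=1.0, v_exc=0.3, v_inh=0.3)
    field = cn.population_field(
        cn.CorrelationSpec(c_pop=0.5, schema="homogeneous"), spec, 2,
        200_000.0, 0.1, np.random.default_rng(11))
    x = field[0].g_exc - field[0].g_exc.mean()
    k = int(round(spec.tau_exc / 0.1))
    rho = np.dot(x[:-k], x[k:]) / np.dot(x, x)
    assert rho == pytest.approx(np.exp(-1.0), abs=0.02)


def test_fluct_current():
    assert cn.fluct_current(10.0, 5.0, 0.0) == pytest.approx(
        5.0 * -75.0 * 1e-3)   # exc term vanishes at E_exc
    assert cn.fluct_current(0.0, 5.0, -75.0) == pytest.approx(0.0)
    assert cn.fluct_current(10.0, 0.0, -70.0) == pytest.approx(0.7)
    # negative excursions are clipped at evaluation
    assert cn.fluct_current(-4.0, 0.0, -70.0) == 0.0
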