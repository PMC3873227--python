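"""Windowed MI / transfer-efficiency estimator and auxiliary measures."""

import numpy as np
import pytest

from rtcnet import info_metrics as im
from rtcnet.stimuli import SpikeTrain


def _train_from_bits(bits, bin_size=1.0):
    times = (np.flatnonzero(bits) + 0.5) * bin_size
    return SpikeTrain(times, len(bits) * bin_size)


def _poisson_train(rate_hz, duration, rng):
    n = rng.poisson(rate_hz * duration / 1000.0)
    return SpikeTrain(np.sort(rng.uniform(0, duration, n)), duration)


def test_binarize_basics():
    assert np.all(im.binarize(SpikeTrain(np.array([]), 100.0), 1.0, 100.0) == 0)
    tr = SpikeTrain(np.array([10.2, 10.7]), 100.0)
    b = im.binarize(tr, 1.0, 100.0)
    assert b.sum() == 1 and b[10] == 1   # two spikes in one bin -> single 1


def test_binarize_edge_convention():
    """Right-open bins: a spike exactly on an edge joins the later bin.
    Verified against a brute-force per-bin count."""
    times = np.array([0.0, 3.0, 4.5, 9.999])
    tr = SpikeTrain(times, 12.0)
    b = im.binarize(tr, 3.0, 12.0)
    brute = np.array([np.any((times >= i * 3.0) & (times < (i + 1) * 3.0))
                      for i in range(4)], dtype=int)
    np.testing.assert_array_equal(b, brute)
    assert b[1] == 1   # t = 3.0 falls in [3, 6)


@pytest.mark.parametrize("p_flip", [0.05, 0.1, 0.3])
def test_binary_symmetric_channel_closed_form(p_flip):
    """S iid Bernoulli(0.5), R = S flipped w.p. p: MI = 1 - H2(p)."""
    rng = np.random.default_rng(17)
    # window count chosen so the estimator's own SD is well below the 2%
    # band (the MI shrinks with p, so flatter channels need more data)
    n = 50_000 if p_flip < 0.2 else 250_000
    s = rng.integers(0, 2, n)
    r = s ^ (rng.random(n) < p_flip)
    settings = im.MISettings(window=1.0, bin_size=1.0, lag=0.0,
                             min_windows=10)
    res = im.mutual_information(_train_from_bits(s), _train_from_bits(r),
                                settings, np.random.default_rng(0))
    h2 = -p_flip * np.log2(p_flip) - (1 - p_flip) * np.log2(1 - p_flip)
    assert res.mi == pytest.approx(1.0 - h2, rel=0.02)


def test_independent_streams_give_zero_mi():
    rng = np.random.default_rng(3)
    s = _poisson_train(30.0, 60_000.0, rng)
    r = _poisson_train(30.0, 60_000.0, rng)
    res = im.mutual_information(s, r, rng=np.random.default_rng(1))
    # corrected MI ~ 0 (well below the shuffle bias scale)
    assert res.mi < 0.05
    assert res.te < 2.0


def test_bias_corrected_mi_unbiased_on_independence():
    """Mean corrected MI over seeded repeats is ~0 (|mean| < 2 SE)."""
    vals = []
    settings = im.MISettings(min_windows=10)
    for k in range(60):
        rng = np.random.default_rng(100 + k)
        s = _poisson_train(30.0, 9000.0, rng)
        r = _poisson_train(30.0, 9000.0, rng)
        res = im.mutual_information(s, r, settings, np.random.default_rng(k))
        vals.append(res.mi_raw - res.bias)   # before clipping
    vals = np.asarray(vals)
    assert abs(vals.mean()) < 2.0 * vals.std() / np.sqrt(vals.size)


def test_identity_channel_recovers_word_entropy():
    # sparse trains keep the word dictionary small, so the shuffle bias is
    # tiny and the corrected MI lands on the word entropy
    rng = np.random.default_rng(5)
    s = _poisson_train(10.0, 100_000.0, rng)
    settings = im.MISettings(lag=0.0)
    res = im.mutual_information(s, s, settings, np.random.default_rng(2))
    words = im.words(im.binarize(s, 1.0, s.duration), 30)
    _, counts = np.unique(words, return_counts=True)
    p = counts / counts.sum()
    h = -(p * np.log2(p)).sum()
    assert res.mi_raw == pytest.approx(h, rel=1e-9)
    assert res.mi == pytest.approx(h, rel=0.2)  # shuffle bias is subtracted


def test_zero_entropy_stimulus_flagged():
    s = SpikeTrain(np.array([]), 60_000.0)
    r = _poisson_train(30.0, 60_000.0, np.random.default_rng(0))
    res = im.mutual_information(s, r)
    assert res.zero_entropy and res.te == 0.0


def test_te_invariant_to_global_shift():
    rng = np.random.default_rng(6)
    s = _poisson_train(40.0, 60_000.0, rng)
    # response: s delayed by 6 ms with 20% deletion
    keep = rng.random(len(s)) > 0.2
    r = SpikeTrain(s.times[keep] + 6.0, s.duration + 10.0)
    res = im.mutual_information(s, r, rng=np.random.default_rng(3))
    shift = 500.0
    s2 = SpikeTrain(s.times + shift, s.duration + shift)
    r2 = SpikeTrain(r.times + shift, r.duration + shift)
    res2 = im.mutual_information(s2, r2, rng=np.random.default_rng(3))
    assert res2.te == pytest.approx(res.te, rel=0.05)


def test_lag_maximizes_te_at_true_delay():
    rng = np.random.default_rng(7)
    s = _poisson_train(40.0, 100_000.0, rng)
    keep = rng.random(len(s)) > 0.2
    r = SpikeTrain(s.times[keep] + 6.0, s.duration + 10.0)
    tes = {lag: im.mutual_information(
        s, r, im.MISettings(lag=lag), np.random.default_rng(4)).te
        for lag in (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)}
    assert max(tes, key=tes.get) == 6.0


def test_finite_size_check_flags_undersampling():
    rng = np.random.default_rng(8)
    n = 60_000
    s_bits = rng.integers(0, 2, n)
    r_bits = s_bits ^ (rng.random(n) < 0.1)
    settings = im.MISettings(window=1.0, bin_size=1.0, lag=0.0,
                             min_windows=10)
    long_frac = im.finite_size_check(
        _train_from_bits(s_bits), _train_from_bits(r_bits), settings,
        rng=np.random.default_rng(5))
    short_frac = im.finite_size_check(
        _train_from_bits(s_bits[:100]), _train_from_bits(r_bits[:100]),
        settings, rng=np.random.default_rng(5))
    assert long_frac < 0.01
    assert short_frac > 0.01


def test_extrapolated_estimator_reduces_bias():
    """On a well-specified channel the extrapolated estimate is closer to
    the closed-form MI than the plain corrected estimate at small n."""
    rng = np.random.default_rng(9)
    n = 1500
    p = 0.1
    h2 = -p * np.log2(p) - (1 - p) * np.log2(1 - p)
    true_mi = 1.0 - h2
    # 3-bin words to create mild undersampling
    s_bits = rng.integers(0, 2, 3 * n)
    r_bits = s_bits ^ (rng.random(3 * n) < p)
    settings = im.MISettings(window=3.0, bin_size=1.0, lag=0.0,
                             min_windows=10)
    plain = im.mutual_information(
        _train_from_bits(s_bits), _train_from_bits(r_bits), settings,
        np.random.default_rng(6))
    extra = im.mutual_information(
        _train_from_bits(s_bits), _train_from_bits(r_bits), settings,
        np.random.default_rng(6), extrapolate=True)
    assert abs(extra.mi - 3 * true_mi) <= abs(plain.mi - 3 * true_mi) + 0.01


def test_partial_te_deterministic_relay():
    """A noiseless relay whose legs realize exactly the nominal 4/2/6 ms
    delays yields three identical partial transfer values."""
    rng = np.random.default_rng(10)
    s = _poisson_train(30.0, 60_000.0, rng)
    thal = SpikeTrain(s.times + 4.0, s.duration + 10.0)
    ctx = SpikeTrain(s.times + 6.0, s.duration + 10.0)
    rt, tc, rc = im.partial_te(s, thal, ctx, rng=np.random.default_rng(7))
    # the three legs see the same channel up to window-boundary effects
    assert rt.mi_raw == pytest.approx(tc.mi_raw, rel=0.02)
    assert rt.mi_raw == pytest.approx(rc.mi_raw, rel=0.02)
    assert rt.te == pytest.approx(tc.te, rel=0.1)
    assert rt.te == pytest.approx(rc.te, rel=0.1)


def test_efficacy_and_contribution():
    rng = np.random.default_rng(11)
    s = _poisson_train(30.0, 60_000.0, rng)
    eff, con = im.efficacy_contribution(s, s)
    assert eff == 1.0 and con == 1.0
    eff0, con0 = im.efficacy_contribution(s, SpikeTrain(np.array([]), s.duration))
    assert eff0 == 0.0 and con0 is None
    # Poisson cortex independent of retina: efficacy ~ 1 - exp(-rate*T)
    r = _poisson_train(20.0, 60_000.0, rng)
    eff_p, _ = im.efficacy_contribution(s, r)
    assert eff_p == pytest.approx(1.0 - np.exp(-20.0 * 0.03), abs=0.03)


def test_pairwise_correlation():
    rng = np.random.default_rng(12)
    x = _poisson_train(30.0, 120_000.0, rng)
    assert im.pairwise_correlation(x, x) == pytest.approx(1.0)
    y = _poisson_train(30.0, 120_000.0, rng)
    n_bins = 120_000
    assert abs(im.pairwise_correlation(x, y)) < 3.0 / np.sqrt(n_bins)
    silent = SpikeTrain(np.array([]), x.duration)
    assert np.isnan(im.pairwise_correlation(x, silent))


def test_sta_delta_reconstruction():
    """Thalamic spikes exactly 5 ms before every cortical spike produce a
    delta STA at the 5 ms bin."""
    ctx = SpikeTrain(np.arange(100.0, 50_000.0, 100.0), 50_000.0)
    th = SpikeTrain(ctx.times - 5.0, 50_000.0)
    lags, mean, sd = im.spike_triggered_average(ctx, [th])
    assert mean.sum() == pytest.approx(1.0)
    peak = lags[np.argmax(mean)]
    assert 4.0 <= peak <= 6.0
    assert sd[np.argmax(mean)] == pytest.approx(0.0)


def test_sta_flat_for_independent_thalamus():
    rng = np.random.default_rng(13)
    n_cells, rate = 8, 25.0
    th = [_poisson_train(rate, 200_000.0, rng) for _ in range(n_cells)]
    ctx = _poisson_train(10.0, 200_000.0, rng)
    _, mean, _ = im.spike_triggered_average(ctx, th)
    expected = n_cells * rate * 1e-3   # counts per 1 ms bin
    assert mean.mean() == pytest.approx(expected, rel=0.05)
    assert np.ptp(mean) < 0.5 * expected


def test_sta_empty_without_cortical_spikes():
    lags, mean, sd = im.spike_triggered_average(
        SpikeTrain(np.array([]), 1000.0), [])
    assert lags.size == 0 and mean.size == 0


def test_rate_and_cv():
    periodic = SpikeTrain(np.arange(10.0, 100_000.0, 33.0), 100_000.0)
    rate, cv = im.rate_and_cv(periodic)
    assert cv == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(14)
    isi = rng.gamma(3.0, 1000.0 / 30.0 / 3.0, 20_000)
    tr = SpikeTrain(np.cumsum(isi), float(np.sum(isi) + 1))
    rate, cv = im.rate_and_cv(tr)
    assert rate == pytest.approx(30.0, rel=0.03)
    assert cv == pytest.approx(1.0 / np.sqrt(3.0), rel=0.03)
    _, cv_none = im.rate_and_cv(SpikeTrain(np.array([1.0]), 1000.0))
    assert cv_none is None


def test_spike_count_mi_bounded_by_word_mi():
    rng = np.random.default_rng(15)
    s = _poisson_train(40.0, 100_000.0, rng)
    keep = rng.random(len(s)) > 0.3
    r = SpikeTrain(s.times[keep] + 2.0, s.duration + 5.0)
    settings = im.MISettings(lag=2.0)
    word = im.mutual_information(s, r, settings, np.random.default_rng(8))
    count = im.spike_count_mi(s, r, settings, np.random.default_rng(8))
    assert count.mi_raw <= word.mi_raw + 1e-9
    assert count.mi <= word.mi + 0.05


def test_cross_correlation_identity_peak():
    rng = np.random.default_rng(16)
    s = _poisson_train(30.0, 60_000.0, rng)
    lags, cc = im.cross_correlation(s, s)
    assert cc[lags == 0.0] == pytest.approx(1.0)
    assert np.all(cc <= 1.0 + 1e-12)


def test_membrane_sd_excision():
    dt = 0.5
    v = np.full(4000, -70.0)
    v[1004:1010] = 0.0    # a "spike" deflection peaking at t = 502 ms
    sd_with = np.std(v)
    # excising [-1, +4] ms around the spike removes the whole deflection
    sd_excised = im.membrane_sd(v, dt, np.array([502.0]))
    assert sd_excised == pytest.approx(0.0, abs=1e-12)
    assert sd_with > 1.0
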