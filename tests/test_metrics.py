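"""Chaos-metric battery on known-dynamics fixtures and simulated traces."""

import numpy as np
import pytest

from chaostrench.io import make_fixture, make_surrogate
from chaostrench.metrics import (
    acf_with_peaks,
    classify_alive,
    correlation_dimension,
    cross_correlation,
    determinism_test,
    difference_signal,
    lyapunov_exponent,
    mean_acf,
    permutation_entropy,
    preprocess_trace,
    stationarity_test,
)
from chaostrench.model_core import Trace


# --- preprocessing -------------------------------------------------------


def test_preprocess_crop_and_identity():
    tr = make_fixture("white_noise", 500, seed=0)
    out = preprocess_trace(tr, window=1, passes=2, t_start=100.0)
    assert out.t[0] >= 100.0
    np.testing.assert_array_equal(out.y, tr.y[tr.t >= 100.0])


def test_preprocess_constant_unchanged():
    tr = make_fixture("constant", 100, value=3.0)
    out = preprocess_trace(tr, window=3, passes=2)
    np.testing.assert_allclose(out.y, 3.0)


def test_preprocess_smooths_variance():
    tr = make_fixture("white_noise", 2000, seed=1)
    out = preprocess_trace(tr, window=3, passes=2)
    assert out.y.std() < 0.6 * tr.y.std()
    assert len(out) == len(tr)  # shrinking edge windows keep the length


def test_preprocess_zero_passes_supported():
    tr = make_fixture("white_noise", 200, seed=2)
    out = preprocess_trace(tr, window=3, passes=0)
    np.testing.assert_array_equal(out.y, tr.y)


def test_preprocess_too_short_rejected():
    with pytest.raises(ValueError):
        preprocess_trace(make_fixture("constant", 50), window=3, t_start=49.0)


def test_difference_signal():
    tr = Trace(np.arange(5.0), np.array([1.0, 1.0, 1.0, 1.0, 1.0]))
    np.testing.assert_array_equal(difference_signal(tr).y, np.zeros(4))
    ramp = Trace(np.arange(6.0), 2.5 * np.arange(6.0))
    np.testing.assert_allclose(difference_signal(ramp).y, 2.5)
    sine = make_fixture("sine", 600, period=60)
    d = difference_signal(sine)
    _, _, period = acf_with_peaks(d, max_lag=200)
    assert period == pytest.approx(60.0, abs=1.0)  # differencing keeps the period
    with pytest.raises(ValueError):
        difference_signal(Trace(np.array([0.0]), np.array([1.0])))


# --- autocorrelation -----------------------------------------------------


def test_acf_sine_peak_at_period():
    tr = make_fixture("sine", 3000, period=60)
    vals, peaks, period = acf_with_peaks(tr, max_lag=500)
    assert vals[0] == pytest.approx(1.0)
    assert abs(peaks[0] - 60) <= 1
    assert period == pytest.approx(60.0, abs=1.0)


def test_acf_white_noise_no_prominent_peak():
    hits = 0
    for s in range(10):
        tr = make_fixture("white_noise", 2000, seed=100 + s)
        _, peaks, _ = acf_with_peaks(tr, max_lag=500)
        hits += peaks.size == 0
    assert hits >= 9  # no prominence-0.2 peak in at least 95% of draws


def test_acf_zero_variance_rejected():
    with pytest.raises(ValueError):
        acf_with_peaks(make_fixture("constant", 100))


def test_mean_acf_sharpens_common_period():
    traces = [
        make_fixture("sine", 1500, period=60, phase=0.1 * k) for k in range(4)
    ]
    curve, peaks = mean_acf(traces, max_lag=300)
    assert abs(peaks[0] - 60) <= 1


def test_simulated_periodic_regime_acf(run_no_growth):
    """With growth uncoupled the response is division-locked: regular ACF
    peaks whose period equals the (unstressed) interdivision time."""
    res = run_no_growth
    d = difference_signal(res.mother_steady_trace("grxA"))
    _, peaks, period = acf_with_peaks(d, max_lag=400)
    idt = res.mother_interdivision_times(t_min=750).mean()
    assert peaks.size >= 5
    assert abs(period - idt) <= 1.0  # within one lag step
    # sanity: idt at constant g0 equals the adder doubling time
    assert idt == pytest.approx(np.log(2) / np.log(1 + 0.042), abs=1.0)


# --- Lyapunov ------------------------------------------------------------


def test_lyapunov_logistic_map_ln2():
    """Fully chaotic logistic map: the exact exponent is ln 2 per iterate."""
    tr = make_fixture("logistic_map", 5000, seed=3)
    lam = lyapunov_exponent(tr)
    assert lam == pytest.approx(np.log(2.0), rel=0.15)


def test_lyapunov_sine_not_positive():
    tr = make_fixture("sine", 5000, period=60)
    assert lyapunov_exponent(tr) <= 1e-6


def test_lyapunov_error_paths():
    with pytest.raises(ValueError):
        lyapunov_exponent(make_fixture("sine", 100, period=10))
    with pytest.raises(ValueError):
        lyapunov_exponent(make_fixture("constant", 1000))


# --- correlation dimension ----------------------------------------------


def test_corrdim_white_noise_tracks_embedding_dimension():
    """A stochastic series has D_corr ~ E (within 20% for E <= 5)."""
    tr = make_fixture("white_noise", 3000, seed=2)
    cd = correlation_dimension(tr)
    for e, d in zip(cd.embedding_dims, cd.d_corr):
        if e <= 5:
            assert d == pytest.approx(e, rel=0.20)
    assert not cd.saturated


def test_corrdim_sine_saturates_near_one():
    """A limit cycle is a 1-manifold: D_corr plateaus at ~1."""
    tr = make_fixture("sine", 3000, period=60.37)  # incommensurate sampling
    cd = correlation_dimension(tr)
    assert cd.saturated
    assert cd.saturation == pytest.approx(1.0, rel=0.2)


def test_corrdim_shuffle_control(run_fluctuating_100):
    """Deterministic model trace saturates; its shuffle does not."""
    tr = run_fluctuating_100.mother_steady_trace("grxA")
    cd = correlation_dimension(tr)
    assert cd.saturated
    assert cd.saturation < 3.0
    sh = correlation_dimension(make_surrogate(tr, seed=1))
    assert not sh.saturated
    assert sh.d_corr[-1] > cd.d_corr[-1] + 2.0


def test_corrdim_error_paths():
    with pytest.raises(ValueError):
        correlation_dimension(make_fixture("constant", 500))
    with pytest.raises(ValueError):
        correlation_dimension(make_fixture("white_noise", 50, seed=1))


# --- determinism / stationarity -----------------------------------------


def test_permutation_entropy_limits():
    assert permutation_entropy(np.arange(300.0)) == 0.0  # single pattern
    rng = np.random.default_rng(0)
    h = permutation_entropy(rng.normal(size=20000), order=3)
    assert h > 0.99  # all patterns equally likely in the iid limit


def test_determinism_classifications():
    det, stat = determinism_test(make_fixture("logistic_map", 1000, seed=5), seed=1)
    assert det == "deterministic"
    det, stat = determinism_test(np.arange(200.0), seed=3)
    assert det == "deterministic"
    assert stat == "non-stationary"  # a ramp drifts
    hits = sum(
        determinism_test(make_fixture("white_noise", 1000, seed=200 + s), seed=s)[0]
        == "stochastic"
        for s in range(10)
    )
    assert hits >= 9


def test_shuffling_flips_determinism():
    tr = make_fixture("logistic_map", 1000, seed=6)
    sh = make_surrogate(tr, seed=7)
    assert determinism_test(tr, seed=1)[0] == "deterministic"
    assert determinism_test(sh, seed=1)[0] == "stochastic"
    # the surrogate's entropy exceeds the original's
    assert permutation_entropy(sh.y) > permutation_entropy(tr.y)


def test_determinism_insufficient_data():
    with pytest.raises(ValueError, match="insufficient"):
        determinism_test(make_fixture("white_noise", 50, seed=1))
    with pytest.raises(ValueError):
        determinism_test(make_fixture("constant", 200))


def test_stationarity_windowed_drift():
    rng = np.random.default_rng(2)
    flat = rng.normal(size=1000)
    assert stationarity_test(flat)
    drifting = flat + np.linspace(0.0, 10.0, 1000)
    assert not stationarity_test(drifting)


# --- alive / cross-correlation ------------------------------------------


@pytest.mark.parametrize(
    "rate,alive", [(0.0, False), (0.042, True), (0.0024, True), (0.00239, False)]
)
def test_classify_alive_threshold(rate, alive):
    tr = Trace(np.arange(100.0), np.full(100, rate))
    assert classify_alive(tr) is alive


def test_cross_correlation_identities():
    tr = make_fixture("white_noise", 1000, seed=4)
    lags, cc = cross_correlation(tr, tr, max_lag=20)
    assert cc[lags == 0][0] == pytest.approx(1.0)
    neg = Trace(tr.t, -tr.y)
    _, cc2 = cross_correlation(tr, neg, max_lag=20)
    assert cc2[lags == 0][0] == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        cross_correlation(tr, make_fixture("constant", 1000), max_lag=5)


def test_grxa_anticorrelates_with_barrier_count(run_fluctuating_100):
    """More barrier cells -> more shielding -> lower mother GrxA."""
    res = run_fluctuating_100
    tr = res.mother_steady_trace("grxA")
    counts = res.cell_count_trace().crop(*res.steady_window_times())
    # smooth to cell-cycle scale, as in the reporter-trace pipeline
    trs = preprocess_trace(tr, window=9, passes=2)
    ncs = preprocess_trace(counts, window=9, passes=2)
    lags, cc = cross_correlation(trs, ncs, max_lag=30)
    short_pos = cc[(lags >= 0) & (lags <= 15)]
    assert short_pos.min() < -0.1  # count changes drive GrxA down within ~min
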