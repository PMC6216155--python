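"""Conditioning-chain tests, including an independently coded filter oracle.

The oracle designs the 2nd-order Butterworth sections by hand (analog
prototype + bilinear transform) and applies the forward-backward difference
equation directly, so it shares no code with the scipy-based implementation.
Zero-phase edge handling differs between the two (the implementation pads,
the oracle does not), so cascade comparisons are made away from the edges.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synergia import (CycleTimes, EnvelopeMatrix, ValidationError,
                      make_envelope, make_envelopes, normalize_amplitude,
                      time_normalize)

# ---------------------------------------------------------------------------
# independent oracle


def _butter2_coeffs(fc, fs, kind):
    """2nd-order Butterworth coefficients via the bilinear transform.

    Analog prototype H(s) = 1 / (s^2 + sqrt(2) s + 1); s is replaced by
    (1/K)(1-z^-1)/(1+z^-1) for low-pass and by K(1+z^-1)/(1-z^-1) for
    high-pass, with K = tan(pi fc / fs).
    """
    K = np.tan(np.pi * fc / fs)
    K2 = K * K
    den = 1 + np.sqrt(2) * K + K2
    a = np.array([1.0, 2 * (K2 - 1) / den, (1 - np.sqrt(2) * K + K2) / den])
    if kind == "low":
        b = np.array([K2, 2 * K2, K2]) / den
    else:
        b = np.array([1.0, -2.0, 1.0]) / den
    return b, a


def _df1(b, a, x):
    """Direct-form-I difference equation, zero initial conditions."""
    y = np.zeros_like(x)
    for n in range(len(x)):
        acc = b[0] * x[n]
        if n >= 1:
            acc += b[1] * x[n - 1] - a[1] * y[n - 1]
        if n >= 2:
            acc += b[2] * x[n - 2] - a[2] * y[n - 2]
        y[n] = acc
    return y


def _zero_phase(b, a, x):
    return _df1(b, a, _df1(b, a, x)[::-1])[::-1]


def oracle_envelope(x, fs=1000.0, hp=50.0, lp=20.0):
    """Reference enactment of the conditioning cascade."""
    bh, ah = _butter2_coeffs(hp, fs, "high")
    bl, al = _butter2_coeffs(lp, fs, "low")
    y = _zero_phase(bh, ah, x)
    y = np.abs(y)
    y = _zero_phase(bl, al, y)
    y = np.where(y < 0, 0.0, y)
    nz = y[y > 0]
    if nz.size:
        y[y == 0] = nz.min()
    return y


# ---------------------------------------------------------------------------
# make_envelope


def test_sine_matches_independent_filter_oracle():
    """10 Hz unit sine, 2 s: cascade agrees with the reference away from edges."""
    t = np.arange(2000) / 1000.0
    x = np.sin(2 * np.pi * 10 * t)
    mine = make_envelope(x)
    ref = oracle_envelope(x)
    mid = slice(500, 1500)
    rms = np.sqrt(np.mean((mine[mid] - ref[mid]) ** 2))
    assert rms < 1e-6


def test_constant_input_reduces_to_tiny_positive_floor():
    y = make_envelope(np.full(2000, 5.0))
    assert np.all(y > 0)
    assert y.max() < 1e-6  # high-pass removes DC entirely

def test_output_strictly_positive_and_same_length(synthetic_trial):
    trial, _, _ = synthetic_trial
    x = trial.channel_matrix()[0]
    y = make_envelope(x)
    assert y.shape == x.shape
    assert np.all(y > 0)


def test_rectified_lowpassed_carrier_approximates_envelope(clean_carrier_trial):
    """The conditioning chain tracks the true envelope up to a known scale.

    For a unit-RMS Gaussian carrier the rectified mean is sqrt(2/pi), so the
    envelope estimate of a noise-free trial, rescaled by that factor, should
    sit close to the generating envelope where it is appreciably non-zero.
    """
    gt, (trial, ct, env) = clean_carrier_trial
    i = 3
    y = make_envelope(trial.channel_matrix()[i]) / np.sqrt(2 / np.pi)
    mask = env[i] > 0.1 * env[i].max()
    rel = np.sqrt(np.mean((y[mask] - env[i][mask]) ** 2)) / env[i][mask].max()
    assert rel < 0.25  # per-sample carrier fluctuation dominates


@pytest.mark.parametrize("bad", [np.zeros(50), np.r_[np.ones(500), np.nan]])
def test_short_or_nan_series_rejected(bad):
    with pytest.raises(ValueError):
        make_envelope(bad)


# ---------------------------------------------------------------------------
# normalize_amplitude


def test_maximum_is_taken_across_both_trials(rng):
    a = rng.uniform(0.0, 2.0, (13, 100))
    b = rng.uniform(0.0, 4.0, (13, 120))
    na, nb = normalize_amplitude([a, b])
    for i in range(13):
        m = max(a[i].max(), b[i].max())
        np.testing.assert_allclose(na[i], a[i] / m)
        np.testing.assert_allclose(nb[i], b[i] / m)
        assert max(na[i].max(), nb[i].max()) == pytest.approx(1.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_normalization_is_idempotent_with_unit_global_max(seed):
    rng = np.random.default_rng(seed)
    trials = [rng.uniform(0.0, rng.uniform(0.5, 5.0), (4, 50)) for _ in range(2)]
    once = normalize_amplitude(trials)
    twice = normalize_amplitude(once)
    glob = np.max([t.max(axis=1) for t in once], axis=0)
    np.testing.assert_allclose(glob, 1.0)
    for t1, t2 in zip(once, twice):
        np.testing.assert_allclose(t1, t2)


def test_flat_channel_warns_and_stays_at_most_one():
    a = np.vstack([np.zeros(100), np.ones(100)])
    b = np.vstack([np.zeros(100), 2 * np.ones(100)])
    with pytest.warns(RuntimeWarning):
        na, nb = normalize_amplitude([a, b])
    assert na[0].max() <= 1.0


# ---------------------------------------------------------------------------
# time_normalize


def _uniform_ct(n, contact=0.3, cycle=0.75):
    # n+1 rows define n complete cycles
    td = np.arange(n + 1) * cycle
    return CycleTimes(td, np.full(n + 1, contact))


def test_thirty_cycles_give_6000_columns(rng):
    ct = _uniform_ct(30)
    env = rng.uniform(0.1, 1.0, (13, int(ct.touchdown[-1] * 1000) + 100))
    V = time_normalize(env, ct, n_cycles=30)
    assert V.values.shape == (13, 6000)
    assert V.cycles == 30


def test_constant_stance_resamples_to_constant():
    # stance of exactly 100 samples, constant value c
    ct = CycleTimes([0.0, 0.2], [0.099, 0.099])
    env = np.full((1, 220), 3.5)
    V = time_normalize(env, ct, n_cycles=1)
    np.testing.assert_allclose(V.values[0, :100], 3.5)


def test_linear_ramp_matches_closed_form_interpolant():
    fs = 1000.0
    ct = CycleTimes([0.0, 0.75], [0.3, 0.3])
    T = 800
    t = np.arange(T) / fs
    env = (t / 0.3)[None, :]  # ramp 0 -> 1 over the stance
    V = time_normalize(env, ct, fs=fs, n_cycles=1)
    grid = np.linspace(0.0, 0.3, 100)
    np.testing.assert_allclose(V.values[0, :100], grid / 0.3, atol=1e-9)


def test_insufficient_cycles_error_reports_count():
    ct = _uniform_ct(4)  # 5 rows -> 4 complete cycles
    env = np.ones((2, 5000))
    with pytest.raises(ValidationError, match="only 4"):
        time_normalize(env, ct, n_cycles=5)


def test_monotone_segment_preserves_min_max(rng):
    ct = CycleTimes([0.0, 0.75], [0.3, 0.3])
    T = 800
    env = np.cumsum(rng.uniform(0, 1, (1, T)), axis=1)  # monotone increasing
    V = time_normalize(env, ct, n_cycles=1)
    assert V.values[0].min() >= env[0].min() - 1e-9
    assert V.values[0].max() <= env[0].max() + 1e-9


def test_full_chain_recovers_generating_envelope(clean_carrier_trial):
    """Noise-free pipeline: the cycle-averaged V matches the generator envelope.

    Per-sample carrier fluctuation averages out over the 30 normalized
    cycles; each muscle's cycle-averaged conditioned activation should match
    the cycle-averaged true envelope (both peak-normalized) to < 5 % relative
    RMS away from the cycle boundaries.
    """
    from synergia import mean_cycle

    gt, (trial, ct, env) = clean_carrier_trial
    raw_env = make_envelopes(trial.channel_matrix())
    V = time_normalize(raw_env, ct, n_cycles=30)
    ref = time_normalize(env, ct, n_cycles=30)
    keep = np.ones(200, dtype=bool)
    keep[:5] = keep[95:105] = keep[195:] = False
    for i in range(13):
        est = mean_cycle(V.values[i])
        tru = mean_cycle(ref.values[i])
        est, tru = est / est.max(), tru / tru.max()
        rel = np.sqrt(np.mean((est[keep] - tru[keep]) ** 2)) / tru[keep].max()
        assert rel < 0.05
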