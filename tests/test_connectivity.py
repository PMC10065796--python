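"""Windowed lagged coherence / PLI and baseline normalization."""

import numpy as np
import pytest

from ictalnet.connectivity import (
    ConnectivitySeries,
    baseline_normalize,
    compute_baseline,
    compute_connectivity_series,
    lagged_coherence_matrix,
    pli_matrix,
    sliding_windows,
)
from ictalnet.recording import ChannelInfo, Recording


def test_window_counts_match_hand_enumeration():
    """2.5 s windows: 80% overlap -> 0.5 s hop, 90% -> 0.25 s hop."""
    fs = 1000.0
    starts, win = sliding_windows(int(10 * fs), fs, 2.5, 0.8)
    assert win == 2500
    assert len(starts) == 16  # floor((10 - 2.5)/0.5) + 1
    assert starts[1] - starts[0] == 500
    starts, _ = sliding_windows(int(60 * fs), fs, 2.5, 0.8)
    assert len(starts) == 116  # floor((60 - 2.5)/0.5) + 1
    starts, _ = sliding_windows(int(10 * fs), fs, 2.5, 0.9)
    assert len(starts) == 31  # floor((10 - 2.5)/0.25) + 1


def test_window_validation():
    with pytest.raises(ValueError, match="shorter"):
        sliding_windows(100, 100.0, 2.5, 0.8)
    with pytest.raises(ValueError, match="overlap"):
        sliding_windows(1000, 100.0, 2.5, 1.0)


def _two_channel_mix(lag_samples: int, fs=500.0, seconds=2.5, seed=0, band=(80.0, 140.0)):
    """Shared band-limited source received by ch2 with a pure delay."""
    from scipy import signal

    rng = np.random.default_rng(seed)
    n = int(seconds * fs)
    pad = 200
    taps = signal.firwin(301, band, pass_zero=False, fs=fs)
    src = signal.oaconvolve(rng.standard_normal(n + pad), taps, mode="same")
    noise = 0.3 * rng.standard_normal((2, n + pad))
    x = np.stack([src, np.roll(src, lag_samples)])[:, pad // 2 : pad // 2 + n]
    return x + noise[:, pad // 2 : pad // 2 + n]


def test_lagged_coherence_ignores_zero_lag_coupling():
    """A common source at zero lag (volume conduction) yields ~0; the same
    source received with a small delay yields strong lagged coherence."""
    fs, band = 500.0, (80.0, 140.0)
    zero_lag = [lagged_coherence_matrix(_two_channel_mix(0, seed=s), band, fs)[0, 1] for s in range(5)]
    lagged = [lagged_coherence_matrix(_two_channel_mix(2, seed=s), band, fs)[0, 1] for s in range(5)]
    # finite-sample floor: fully independent channels
    rng = np.random.default_rng(99)
    indep = [
        lagged_coherence_matrix(rng.standard_normal((2, 1250)), band, fs)[0, 1]
        for _ in range(5)
    ]
    floor = np.mean(indep)
    # zero-lag coupling is indistinguishable from independence ...
    assert np.mean(zero_lag) < floor + 0.05
    # ... while a 4 ms lag produces strong lagged coherence
    assert np.mean(lagged) > floor + 0.25
    assert np.mean(lagged) > 4 * np.mean(zero_lag)


def test_lagged_coherence_matrix_properties():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((4, 1250))
    m = lagged_coherence_matrix(x, (80.0, 140.0), 500.0)
    assert np.allclose(m, m.T)
    assert np.all(np.diag(m) == 0)
    assert np.all((m >= 0) & (m <= 1))


def test_lagged_coherence_zero_variance_channel_warns():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((3, 1250))
    x[2] = 0.0
    with pytest.warns(UserWarning, match="zero-variance"):
        m = lagged_coherence_matrix(x, (80.0, 140.0), 500.0)
    assert np.all(m[2] == 0) and np.all(m[:, 2] == 0)


def test_pli_constant_phase_lag_is_one_zero_lag_is_zero():
    fs = 500.0
    t = np.arange(int(4 * fs)) / fs
    x = np.sin(2 * np.pi * 6.0 * t)
    y_lag = np.sin(2 * np.pi * 6.0 * t - np.pi / 3)
    m = pli_matrix(np.stack([x, y_lag]))
    assert m[0, 1] > 0.97
    # identical signals: the imaginary cross term is exactly zero -> PLI 0
    m0 = pli_matrix(np.stack([x, x.copy()]))
    assert m0[0, 1] == 0.0


def test_pli_sign_count_oracle():
    """Phase difference positive for 3/4 of the window -> PLI = |0.75 - 0.25| = 0.5."""
    fs, f = 100.0, 10.0
    n = 1000
    t = np.arange(n) / fs
    x = np.cos(2 * np.pi * f * t)
    y = np.concatenate([
        np.cos(2 * np.pi * f * t[: 3 * n // 4] - 0.4),  # x leads: sign +
        np.cos(2 * np.pi * f * t[3 * n // 4 :] + 0.4),  # x lags: sign -
    ])
    m = pli_matrix(np.stack([x, y]))
    assert abs(m[0, 1] - 0.5) < 0.05


def test_series_hop_and_sampling_rate():
    vals = np.zeros((3, 3, 4))
    s = ConnectivitySeries(vals, (80.0, 140.0), 2.5, 0.8, np.arange(4.0))
    assert s.hop_s == pytest.approx(0.5)
    assert s.samples_per_s == pytest.approx(2.0)
    s_lf = ConnectivitySeries(vals, (3.0, 50.0), 2.5, 0.9, np.arange(4.0))
    assert s_lf.samples_per_s == pytest.approx(4.0)


def test_compute_series_window_centers():
    fs = 500.0
    rng = np.random.default_rng(0)
    rec = Recording(
        rng.standard_normal((2, int(10 * fs))), fs,
        [ChannelInfo("A1", "A", 0), ChannelInfo("A2", "A", 1)],
    )
    series = compute_connectivity_series(rec, (80.0, 140.0))
    assert series.n_layers == 16
    assert series.t0[0] == pytest.approx(1.25)
    assert series.t0[1] == pytest.approx(1.75)
    assert not series.normalized


def test_baseline_floor_and_warnings():
    vals = np.zeros((2, 2, 3))
    vals[0, 1, :] = vals[1, 0, :] = 0.4  # constant edge -> zero std, floored
    s = ConnectivitySeries(vals, (80.0, 140.0), 2.5, 0.8, np.arange(3.0))
    with pytest.warns(UserWarning, match="only"):
        base = compute_baseline(s)
    assert base.std[0, 1] == 1e-6
    assert base.floored[0, 1]
    one = s.select_layers(np.array([True, False, False]))
    with pytest.raises(ValueError, match="at least 2"):
        compute_baseline(one)


def test_baseline_normalization_maps_mean_to_half():
    rng = np.random.default_rng(2)
    raw = rng.uniform(0.1, 0.9, size=(4, 4, 30))
    raw = (raw + raw.transpose(1, 0, 2)) / 2
    idx = np.arange(4)
    raw[idx, idx, :] = 0
    s = ConnectivitySeries(raw, (80.0, 140.0), 2.5, 0.8, np.arange(30.0))
    base = compute_baseline(s)
    # a layer exactly at the baseline mean maps to logistic(0) = 0.5
    at_mean = ConnectivitySeries(
        np.repeat(base.mean[:, :, None], 2, axis=2), s.band, 2.5, 0.8, np.arange(2.0)
    )
    norm = baseline_normalize(at_mean, base)
    off = ~np.eye(4, dtype=bool)
    assert np.allclose(norm.values[off, :], 0.5)
    # generic layers stay inside (0, 1), symmetric, zero diagonal
    norm_all = baseline_normalize(s, base)
    assert np.all((norm_all.values >= 0) & (norm_all.values <= 1))
    assert np.allclose(norm_all.values, norm_all.values.transpose(1, 0, 2))
    assert np.all(norm_all.values[idx, idx, :] == 0)
    assert norm_all.normalized


def test_normalization_is_monotone_in_raw_value():
    base_mean = np.full((2, 2), 0.3)
    base_std = np.full((2, 2), 0.1)
    from ictalnet.connectivity import BaselineStats

    base = BaselineStats(base_mean, base_std, 10)
    lo = ConnectivitySeries(np.full((2, 2, 1), 0.2), (80.0, 140.0), 2.5, 0.8, [0.0])
    hi = ConnectivitySeries(np.full((2, 2, 1), 0.6), (80.0, 140.0), 2.5, 0.8, [0.0])
    v_lo = baseline_normalize(lo, base).values[0, 1, 0]
    v_hi = baseline_normalize(hi, base).values[0, 1, 0]
    assert v_lo < 0.5 < v_hi
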