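"""Demodulation, synchronization, alignment and response quantification."""

import numpy as np
import pytest

from noex import photometry as ph
from noex.synthetic import (make_transient_log, simulate_fm_photometry,
                            simulate_lifetime_trace)


# ---------------------------------------------------------------------------
# rolling z-score
# ---------------------------------------------------------------------------

def test_rolling_zscore_constant_series_is_zero():
    assert np.all(ph.rolling_zscore(np.full(500, 3.7), 100) == 0.0)


def test_rolling_zscore_standardizes_white_noise():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, size=100_000)
    z = ph.rolling_zscore(x, 5000)
    assert abs(z.mean()) < 0.05
    assert abs(z.std() - 1.0) < 0.05


def test_rolling_zscore_equals_brute_force_definition():
    rng = np.random.default_rng(1)
    t = np.arange(400)
    x = np.exp(-t / 150) + 0.05 * rng.normal(size=400)
    x[200:210] += 0.3  # embedded transient
    window = 50
    z = ph.rolling_zscore(x, window)
    half_lo = window // 2
    half_hi = (window - 1) // 2
    for i in range(0, 400, 7):
        seg = x[max(0, i - half_lo):min(400, i + half_hi + 1)]
        sd = seg.std(ddof=1)
        expected = 0.0 if sd == 0 else (x[i] - seg.mean()) / sd
        assert z[i] == pytest.approx(expected, abs=1e-10)


def test_rolling_zscore_rejects_window_longer_than_series():
    with pytest.raises(ValueError):
        ph.rolling_zscore(np.zeros(10), 11)


# ---------------------------------------------------------------------------
# demodulation
# ---------------------------------------------------------------------------

def test_demodulated_power_scales_quadratically_with_amplitude():
    fs, dur = 4000.0, 8.0
    t = np.arange(int(fs * dur)) / fs
    sync = np.zeros(t.size)
    powers = []
    for amp in (1.0, 2.0):
        raw = ph.RawPhotometry(signal=amp * np.sin(2 * np.pi * 200 * t),
                               sync=sync, fs=fs, carriers={"signal": 200.0})
        d = ph.demodulate_fm(raw)
        powers.append(np.median(d.channels["signal"]))
    assert powers[1] / powers[0] == pytest.approx(4.0, rel=1e-3)


def test_output_sampling_period_is_27ms_at_defaults():
    raw = simulate_fm_photometry(duration=5.0)
    d = ph.demodulate_fm(raw)
    assert d.dt == pytest.approx(0.027)
    assert np.allclose(np.diff(d.times), 0.027)


@pytest.mark.parametrize("n", [216, 300, 432, 1000, 12345])
def test_output_length_formula(n):
    raw = ph.RawPhotometry(signal=np.random.default_rng(2).normal(size=n),
                           sync=np.zeros(n), fs=4000.0)
    d = ph.demodulate_fm(raw)
    assert len(d) == (n - 216) // 108 + 1


def test_step_in_one_carrier_leaves_other_channel_unaffected():
    fs, dur = 4000.0, 20.0
    t = np.arange(int(fs * dur)) / fs
    depth = np.where(t < 10.0, 1.0, 2.0)
    x = depth * np.sin(2 * np.pi * 200 * t) + np.sin(2 * np.pi * 250 * t)
    raw = ph.RawPhotometry(signal=x, sync=np.zeros(t.size), fs=fs)
    d = ph.demodulate_fm(raw)
    pre, post = slice(50, 300), slice(450, 700)
    step_sig = d.channels["signal"][post].mean() - d.channels["signal"][pre].mean()
    step_ref = d.channels["reference"][post].mean() - d.channels["reference"][pre].mean()
    assert abs(step_ref) / abs(step_sig) < 0.01
    # step localized within one output sample of t = 10 s
    mid = 0.5 * (d.channels["signal"][pre].mean()
                 + d.channels["signal"][post].mean())
    crossing = d.times[np.argmax(d.channels["signal"] > mid)]
    assert abs(crossing - 10.0) <= d.dt


def test_carrier_above_nyquist_rejected():
    raw = simulate_fm_photometry(duration=1.0)
    raw.carriers["signal"] = 2500.0
    with pytest.raises(ValueError):
        ph.demodulate_fm(raw)


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------

def test_two_frames_map_to_pulse_samples():
    raw = simulate_fm_photometry(duration=10.0)
    d = ph.demodulate_fm(raw)
    idx = ph.build_sync_map(raw.sync, raw.fs, 2, d.times)
    pulses = ph.detect_sync_pulses(raw.sync, raw.fs)
    assert abs(d.times[idx[0]] - pulses[0]) <= d.dt / 2 + 1e-9
    assert abs(d.times[idx[1]] - pulses[1]) <= d.dt / 2 + 1e-9


def test_uniform_frames_map_within_one_output_sample():
    raw = simulate_fm_photometry(duration=20.0)
    d = ph.demodulate_fm(raw)
    n_frames = 500
    idx = ph.build_sync_map(raw.sync, raw.fs, n_frames, d.times)
    pulses = ph.detect_sync_pulses(raw.sync, raw.fs)
    analytic = np.linspace(pulses[0], pulses[1], n_frames)
    assert np.max(np.abs(d.times[idx] - analytic)) < d.dt
    assert np.all(np.diff(idx) >= 0)


def test_missing_pulse_rejected():
    raw = simulate_fm_photometry(duration=5.0)
    with pytest.raises(ValueError, match="sync"):
        ph.build_sync_map(np.zeros_like(raw.sync), raw.fs, 10,
                          np.arange(100) * 0.027)


# ---------------------------------------------------------------------------
# alignment and responses
# ---------------------------------------------------------------------------

def test_constant_signal_aligns_to_constant_rows():
    aligned = ph.align_to_events(np.full(1000, 2.5), 0.01, [300, 600],
                                 window=1.0)
    assert aligned.n_trials == 2
    assert np.all(aligned.data == 2.5)


def test_event_at_edge_dropped_and_counted():
    aligned = ph.align_to_events(np.arange(100.0), 0.1, [50, 99], window=1.0)
    assert aligned.n_trials == 1
    assert aligned.n_dropped == 1


def test_transients_at_events_average_peaks_at_lag_zero():
    log = make_transient_log([10.0, 20.0, 30.0], [0.5] * 3, [0.15] * 3)
    raw = simulate_fm_photometry(40.0, transients=log, noise_sd=0.01, seed=3)
    d = ph.demodulate_fm(raw, zscore=True)
    ev = np.searchsorted(d.times, [10.0, 20.0, 30.0])
    aligned = ph.align_to_events(d.channels["signal"], d.dt, ev, window=2.0)
    mean_trace = aligned.data.mean(axis=0)
    assert abs(aligned.lags[np.argmax(mean_trace)]) <= d.dt + 1e-9


def test_window_response_constant_trial_is_zero():
    aligned = ph.EventAlignedMatrix(
        data=np.full((3, 61), 4.2), lags=np.linspace(-3, 3, 61))
    assert np.allclose(ph.window_response(aligned), 0.0)


def test_window_response_triangular_transient_half_height():
    # symmetric triangle, peak h at lag 0, half-width 1 s, zero baseline
    h = 0.8
    lags = np.linspace(-3, 3, 601)
    tri = h * np.clip(1 - np.abs(lags), 0, None)
    aligned = ph.EventAlignedMatrix(data=tri[None, :], lags=lags)
    resp = ph.window_response(aligned, -1.0, 1.0, baseline=None)
    assert resp[0] == pytest.approx(h / 2, rel=2e-2)


def test_lifetime_transient_amplitude_recovered_within_10pct():
    amp = 0.05  # ns
    log = make_transient_log([10.0, 20.0, 30.0], [amp] * 3, [0.4] * 3)
    trace = simulate_lifetime_trace(40.0, fs=200.0, transients=log,
                                    noise_sd=0.01, seed=4)
    down = ph.downsample_moving_average(trace, 10.0)
    ev = np.searchsorted(down.times, [10.0, 20.0, 30.0])
    aligned = ph.align_to_events(down.values, 1 / down.rate, ev, window=3.0)
    resp = ph.window_response(aligned, -1.0, 1.0, baseline=(-3.0, -2.0),
                              mode="peak")
    assert np.mean(resp) == pytest.approx(amp, rel=0.10)


# ---------------------------------------------------------------------------
# strata and downsampling
# ---------------------------------------------------------------------------

def test_strata_partition_25_trials():
    means, sizes = ph.strata_means(np.arange(25.0), 10)
    assert list(sizes) == [10, 10, 5]
    assert means[0] == pytest.approx(np.mean(np.arange(10.0)))


def test_strata_constant_trials():
    means, _ = ph.strata_means(np.full(30, 7.0), 10)
    assert np.all(means == 7.0)


def test_strata_of_decaying_amplitudes_strictly_decrease():
    per_trial = 2.0 * 0.9 ** np.arange(40)
    means, _ = ph.strata_means(per_trial, 10)
    assert np.all(np.diff(means) < 0)


def test_downsample_constant_and_identity():
    const = ph.LifetimeSignal(np.full(1000, 2.6), rate=100.0)
    down = ph.downsample_moving_average(const, 10.0)
    assert np.allclose(down.values, 2.6) and down.rate == 10.0
    same = ph.downsample_moving_average(const, 100.0)
    assert np.array_equal(same.values, const.values)


def test_downsample_sine_attenuation_matches_block_average_factor():
    fs, f, dur = 1000.0, 1.0, 10.0
    t = np.arange(int(fs * dur)) / fs
    sig = ph.LifetimeSignal(np.sin(2 * np.pi * f * t), rate=fs)
    down = ph.downsample_moving_average(sig, 10.0)
    measured = np.sqrt(2) * down.values.std()
    expected = np.sinc(f * 0.1)  # block-average attenuation of a 1 Hz tone
    assert measured == pytest.approx(expected, rel=0.01)


def test_downsample_non_integer_ratio_warns():
    sig = ph.LifetimeSignal(np.zeros(100), rate=30.0)
    with pytest.warns(UserWarning):
        ph.downsample_moving_average(sig, 7.0)


# ---------------------------------------------------------------------------
# group averaging
# ---------------------------------------------------------------------------

def test_group_average_single_animal_sem_flagged():
    g = ph.group_average([np.array([[1.0, 2.0], [3.0, 4.0]])])
    assert np.allclose(g.mean, [2.0, 3.0])
    assert not g.sem_defined and np.all(g.sem == 0)


def test_group_average_weights_animals_equally():
    a1 = np.array([[1.0, 1.0]] * 9)            # 9 trials
    a2 = np.array([[3.0, 3.0]])                # 1 trial
    g = ph.group_average([a1, a2])
    assert np.allclose(g.mean, 2.0)            # not the pooled-trials mean


def test_group_average_two_stage_arithmetic():
    a1 = np.array([[1.0, 3.0], [3.0, 5.0]])    # animal mean (2, 4)
    a2 = np.array([[4.0, 8.0]])                # animal mean (4, 8)
    g = ph.group_average([a1, a2])
    assert np.allclose(g.mean, [3.0, 6.0])
    expected_sem = np.std([[2.0, 4.0], [4.0, 8.0]], axis=0, ddof=1) / np.sqrt(2)
    assert np.allclose(g.sem, expected_sem)
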