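import numpy as np
import pytest

from conftest import make_bipolar, make_events
from motormap import broadband_timecourse, event_locked_average, latency
from motormap.dynamics import condition_emg_series


def test_stationary_noise_centers_near_zero():
    """The conditioned series sits at 0 for stationary input: the z-scored
    log has median 0, so the exponentiated series has median 1 and the
    final subtraction centers it. (The mean retains the positive skew of
    the exponential, so the median is the right location statistic.)"""
    fs = 1200.0
    x = np.random.default_rng(0).normal(size=(1, int(30 * fs)))
    tc = broadband_timecourse(make_bipolar(x, fs))
    assert abs(np.median(tc.data)) < 0.1
    assert abs(tc.data.mean()) < 0.3


def test_gain_invariance():
    fs = 1200.0
    x = np.random.default_rng(1).normal(size=(1, int(10 * fs)))
    a = broadband_timecourse(make_bipolar(x, fs)).data
    b = broadband_timecourse(make_bipolar(1000.0 * x, fs)).data
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_am_tone_envelope_tracking():
    """A square-wave-modulated 90 Hz tone yields an output that tracks the
    envelope, with transition width set by the smoothing kernel."""
    fs = 1200.0
    t = np.arange(int(20 * fs)) / fs
    env = (np.floor(t / 2.0) % 2 == 1).astype(float)  # 2 s off / 2 s on
    x = (1.0 + 4.0 * env) * np.sin(2 * np.pi * 90 * t)
    tc = broadband_timecourse(make_bipolar(x[None], fs), smooth_sd_s=0.05)
    y = tc.data[0]
    on = y[(env == 1) & (np.abs((t % 2.0) - 1.0) < 0.8)]
    off = y[(env == 0) & (np.abs((t % 2.0) - 1.0) < 0.8)]
    assert on.min() > off.max()  # clean separation away from the edges
    # the rise completes within ~3 smoothing sd of the step
    rise = y[(t > 2.0 + 0.15) & (t < 4.0 - 0.15)]
    assert rise.min() > 0.8 * np.median(on)


def test_low_sampling_rate_rejected():
    x = np.zeros((1, 1000))
    with pytest.raises(ValueError, match="too low"):
        broadband_timecourse(make_bipolar(x, 200.0))


class TestConditionEmg:
    def test_notch_attenuates_mains(self):
        fs = 1200.0
        t = np.arange(int(10 * fs)) / fs
        rng = np.random.default_rng(2)
        base = rng.normal(size=len(t))
        from scipy.signal import periodogram, butter, sosfiltfilt, filtfilt, iirnotch

        # oracle on the linear filter chain itself: 60 Hz tone in vs out
        tone = np.sin(2 * np.pi * 60 * t)
        sos = butter(3, [25, 400], btype="bandpass", fs=fs, output="sos")
        y = sosfiltfilt(sos, tone)
        for f0 in (60.0, 120.0, 180.0):
            b, a = iirnotch(f0, Q=30.0, fs=fs)
            y = filtfilt(b, a, y)
        att = 10 * np.log10(np.mean(tone ** 2) / max(np.mean(y ** 2), 1e-300))
        assert att >= 20

    def test_burst_contrast_preserved(self):
        fs = 1200.0
        rng = np.random.default_rng(3)
        n = int(12 * fs)
        x = rng.normal(0, 1.0, n)
        burst = slice(int(4 * fs), int(8 * fs))
        x[burst] += rng.normal(0, 20.0, burst.stop - burst.start)
        env = condition_emg_series(x, fs)
        assert env[burst].mean() / np.r_[env[:burst.start], env[burst.stop:]].mean() >= 5

    def test_all_zero_signal_constant_no_nan(self):
        env = condition_emg_series(np.zeros(12000), 1200.0)
        assert np.isfinite(env).all()
        assert np.ptp(env) == 0.0

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            condition_emg_series(np.zeros(1000), 700.0)


class TestLatency:
    def test_identical_series_peak_at_zero(self):
        x = np.random.default_rng(4).normal(size=6000)
        prof = latency(x, x, fs=1200.0)
        assert prof.peak_lag_s == 0.0
        assert not prof.at_boundary

    @pytest.mark.parametrize("k", [-2400, -377, -1, 0, 1, 500, 2400])
    def test_shifted_copy_identity_exact(self, k):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12000)
        e = np.roll(x, k)  # emg delayed by k samples -> brain leads by k
        prof = latency(x, e, fs=1200.0)
        assert prof.peak_lag_s * 1200.0 == pytest.approx(k, abs=0)

    def test_boundary_peak_flagged(self):
        t = np.arange(12000) / 1200.0
        x = np.sin(2 * np.pi * 0.05 * t)  # slow, strongly autocorrelated
        e = np.roll(x, 3000)  # true lag (2.5 s) beyond the +-2 s window
        prof = latency(x, e, fs=1200.0, max_lag_s=2.0)
        assert prof.at_boundary

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            latency(np.zeros(10), np.zeros(11), fs=100.0)

    def test_windowed_mode_recovers_shift_exactly(self):
        fs = 1200.0
        rng = np.random.default_rng(8)
        n = int(30 * fs)
        x = rng.normal(size=n)
        windows = [(6.0, 9.0), (14.0, 17.0), (22.0, 25.0)]
        for k in (-600, -5, 0, 11, 600):
            prof = latency(x, np.roll(x, k), fs, max_lag_s=1.0, windows=windows)
            assert prof.peak_lag_s * fs == pytest.approx(k, abs=0)

    def test_windowed_mode_requires_usable_windows(self):
        with pytest.raises(ValueError, match="windows"):
            latency(np.zeros(1000), np.zeros(1000), 1200.0, windows=[(0.0, 0.2)])


class TestEventLockedAverage:
    def fixture(self):
        fs = 100.0
        rng = np.random.default_rng(7)
        data = rng.normal(size=(2, int(40 * fs)))
        from motormap.dynamics import BroadbandTimecourse

        tc = BroadbandTimecourse(data=data, fs=fs, channel_names=["P00", "P01"])
        ev = make_events([(5.0, 3.0, "hand", "cue"), (15.0, 3.0, "hand", "cue"),
                          (25.0, 3.0, "tongue", "cue")])
        return tc, ev

    def test_traces_start_at_zero_and_single_epoch_identity(self):
        tc, ev = self.fixture()
        out = event_locked_average(tc, ev, {"tongue": ["P00"]}, window=(-0.5, 2.0))
        tr = out[out["movement"] == "tongue"]["value"].to_numpy()
        assert tr[0] == 0.0
        i0 = int((25.0 - 0.5) * tc.fs)
        expected = tc.data[0, i0:i0 + len(tr)]
        np.testing.assert_allclose(tr, expected - expected[0], atol=1e-12)

    def test_averaging_is_linear(self):
        tc, ev = self.fixture()
        from motormap.dynamics import BroadbandTimecourse

        tc2 = BroadbandTimecourse(data=2.0 * tc.data + 1.0, fs=tc.fs,
                                  channel_names=tc.channel_names)
        a = event_locked_average(tc, ev, {"hand": ["P00"]})["value"].to_numpy()
        b = event_locked_average(tc2, ev, {"hand": ["P00"]})["value"].to_numpy()
        np.testing.assert_allclose(b, 2.0 * a, atol=1e-12)  # shift removes the offset

    def test_out_of_range_epoch_dropped(self):
        tc, ev = self.fixture()
        ev2 = make_events([(0.1, 3.0, "hand", "cue"), (15.0, 3.0, "hand", "cue")])
        out = event_locked_average(tc, ev2, {"hand": ["P00"]}, window=(-0.5, 2.0))
        tr = out["value"].to_numpy()
        i0 = int((15.0 - 0.5) * tc.fs)
        expected = tc.data[0, i0:i0 + len(tr)]
        np.testing.assert_allclose(tr, expected - expected[0], atol=1e-12)


def test_rma_channels_increase_for_all_movements(sim_default, bp_default,
                                                 emg_events_default):
    """Event-locked broadband of RMA channels rises during every movement."""
    _, _, _, truth = sim_default
    tc = broadband_timecourse(bp_default)
    rma = list(truth.channels[truth.channels["label"] == "rma"]["name"])
    hand = list(truth.channels[truth.channels["label"] == "somatotopic_hand"]["name"])
    out = event_locked_average(tc, emg_events_default, {"rma": rma, "hand": hand})
    for mv in ("hand", "tongue", "foot"):
        tr = out[(out["group"] == "rma") & (out["movement"] == mv)]
        mid = tr[(tr["time_s"] > 0.5) & (tr["time_s"] < 2.5)]["value"]
        assert mid.mean() > 0.2, mv
    # somatotopic hand trace peaks during movement and returns toward zero
    tr = out[(out["group"] == "hand") & (out["movement"] == "hand")]
    mid = tr[(tr["time_s"] > 0.5) & (tr["time_s"] < 2.5)]["value"].mean()
    tail = tr[tr["time_s"] > 3.7]["value"].mean()
    assert mid > 0.3 and tail < 0.5 * mid
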