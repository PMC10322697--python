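"""Broadband and EMG timecourses and brain-EMG latency.

The broadband power timecourse of a channel is built by band-passing the
voltage in five 10 Hz bands spanning 65-115 Hz (third-order Butterworth),
squaring the magnitude of the analytic (Hilbert) signal in each band, and
summing the five series. Splitting into narrow bands before the Hilbert
transform keeps the 1/f spectral slope from letting the lowest
frequencies dominate the envelope. The summed series is then logged,
z-scored, smoothed with a Gaussian kernel, exponentiated and centered at
zero (subtract 1), so rest sits near 0 and the scale is per-channel
normalized.

EMG is band-passed 25-400 Hz, notch-filtered at 60/120/180 Hz, rectified
(absolute value), enveloped (smoothed) and then put through the same
log / z-score / smooth / exponentiate chain.

Latency between brain and muscle is the lag of the peak of a sliding dot
product between the two conditioned series over -2..+2 s in one-sample
steps; positive lag means brain leads EMG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .io import MOVEMENTS, TaskEvents
from .preprocess import BipolarRecording

BB_BANDS = tuple((lo, lo + 10.0) for lo in range(65, 115, 10))
SMOOTH_SD_S = 0.050
LATENCY_RANGE_S = 2.0


@dataclass
class BroadbandTimecourse:
    """Per-channel normalized broadband power series at the recording rate."""

    data: np.ndarray  # channels x samples, centered near 0 at rest
    fs: float
    channel_names: list[str]
    bands: tuple = BB_BANDS
    smooth_sd_s: float = SMOOTH_SD_S


def _log_z_smooth_exp(x: np.ndarray, fs: float, smooth_sd_s: float) -> np.ndarray:
    """log -> z-score over the run -> Gaussian smooth -> exp.

    Zeros are floored at the 1st percentile of the positive values before
    the log so silent stretches cannot produce -inf.
    """
    pos = x[x > 0]
    floor = np.percentile(pos, 1) if len(pos) else 1.0
    lx = np.log(np.maximum(x, floor))
    sd = lx.std()
    if sd == 0:  # constant input (e.g. an all-zero channel) -> constant output
        return np.ones_like(lx)
    lx = (lx - lx.mean()) / sd
    lx = ndimage.gaussian_filter1d(lx, smooth_sd_s * fs)
    return np.exp(lx)


def broadband_timecourse(bipolar: BipolarRecording,
                         smooth_sd_s: float = SMOOTH_SD_S,
                         bands: tuple = BB_BANDS,
                         notch_hz: tuple = (60.0, 120.0, 180.0)) -> BroadbandTimecourse:
    """Summed 10 Hz-band Hilbert power, conditioned and centered at zero.

    Mains noise and its harmonics are notched out first: the band grid is
    chosen to avoid 60 and 120 Hz, but third-order Butterworth edges are
    gentle enough that a strong line at 60 Hz still leaks into the 65-75 Hz
    band and contaminates the envelope, so the exclusion is enforced with
    zero-phase notches (as in the EMG chain).
    """
    fs = bipolar.fs
    if fs < 2 * max(hi for _, hi in bands):
        raise ValueError(f"fs={fs} too low for a {max(hi for _, hi in bands)} Hz band")
    x = bipolar.pair_data()
    for f0 in notch_hz:
        b, a = signal.iirnotch(f0, Q=30.0, fs=fs)
        x = signal.filtfilt(b, a, x, axis=1)
    power = np.zeros_like(x)
    for lo, hi in bands:
        sos = signal.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
        bp = signal.sosfiltfilt(sos, x, axis=1)
        power += np.abs(signal.hilbert(bp, axis=1)) ** 2
    out = np.empty_like(power)
    for i in range(power.shape[0]):
        out[i] = _log_z_smooth_exp(power[i], fs, smooth_sd_s) - 1.0
    return BroadbandTimecourse(data=out, fs=fs,
                               channel_names=list(bipolar.pair_table["name"]),
                               bands=bands, smooth_sd_s=smooth_sd_s)


def condition_emg_series(x: np.ndarray, fs: float,
                         smooth_sd_s: float = SMOOTH_SD_S,
                         envelope_sd_s: float = 0.025) -> np.ndarray:
    """Condition one raw EMG trace into a non-negative activity envelope."""
    if fs <= 800:
        raise ValueError("EMG conditioning needs fs > 800 Hz for the 400 Hz band")
    sos = signal.butter(3, [25.0, 400.0], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    for f0 in (60.0, 120.0, 180.0):
        b, a = signal.iirnotch(f0, Q=30.0, fs=fs)
        y = signal.filtfilt(b, a, y)
    env = ndimage.gaussian_filter1d(np.abs(y), envelope_sd_s * fs)
    return _log_z_smooth_exp(env, fs, smooth_sd_s)


def condition_emg(bipolar: BipolarRecording,
                  smooth_sd_s: float = SMOOTH_SD_S) -> dict[str, np.ndarray]:
    """Conditioned envelope per EMG channel name."""
    out = {}
    for i, name in enumerate(bipolar.emg_table["name"]):
        out[name] = condition_emg_series(bipolar.emg_data()[i], bipolar.fs,
                                         smooth_sd_s=smooth_sd_s)
    if not out:
        raise ValueError("recording has no EMG channels")
    return out


def event_locked_average(tc: BroadbandTimecourse, events: TaskEvents,
                         channel_sets: dict[str, list[str]],
                         window: tuple[float, float] = (-0.5, 4.0)) -> pd.DataFrame:
    """Average broadband traces around movement onsets.

    ``channel_sets`` maps a group name to channel names; somatotopic
    groups named after a movement are averaged over that movement's
    epochs only, any other group (e.g. ``rma``) over all movements. Each
    trace is shifted to start at zero. Returns a long DataFrame with
    columns group, movement, time_s, value.
    """
    fs = tc.fs
    i_pre, i_post = int(round(window[0] * fs)), int(round(window[1] * fs))
    rel_t = np.arange(i_pre, i_post) / fs
    name_to_row = {n: i for i, n in enumerate(tc.channel_names)}
    rows = []
    moves = events.movement_epochs()
    for group, names in channel_sets.items():
        idx = [name_to_row[n] for n in names if n in name_to_row]
        if not idx:
            continue
        movements = [group] if group in MOVEMENTS else list(MOVEMENTS)
        for mv in movements:
            traces = []
            for onset in moves[moves["trial_type"] == mv]["onset"]:
                c = int(round(onset * fs))
                if c + i_pre < 0 or c + i_post > tc.data.shape[1]:
                    continue  # epoch window exceeds the recording
                traces.append(tc.data[idx, c + i_pre:c + i_post].mean(axis=0))
            if not traces:
                continue
            tr = np.mean(traces, axis=0)
            tr = tr - tr[0]  # shift to start at 0
            rows.extend({"group": group, "movement": mv, "time_s": ti, "value": vi}
                        for ti, vi in zip(rel_t, tr))
    return pd.DataFrame(rows)


@dataclass
class LatencyProfile:
    """Correlation-vs-lag profile between one brain channel and one EMG."""

    lags_s: np.ndarray
    profile: np.ndarray
    peak_lag_s: float
    at_boundary: bool

    @property
    def peak_lag_ms(self) -> float:
        return 1000.0 * self.peak_lag_s


def latency(brain: np.ndarray, emg: np.ndarray, fs: float,
            max_lag_s: float = LATENCY_RANGE_S,
            windows: list[tuple[float, float]] | None = None) -> LatencyProfile:
    """Sliding dot product between conditioned brain and EMG series.

    Both series are mean-subtracted first (otherwise the DC offset
    dominates every lag). The profile is sum_t brain(t) * emg(t + lag)
    on a one-sample lag grid; a positive peak lag means the brain series
    leads the EMG. A peak on the +-2 s boundary is flagged unreliable.

    With ``windows`` (movement epochs in seconds, typically that
    effector's EMG-timed trials) the dot product is restricted to those
    stretches and summed across them. The windowed profile is free of
    cross-trial and baseline contributions, which skew the whole-run
    peak by tens of milliseconds; when epochs are known it is the more
    accurate estimator, and the pipeline uses it.
    """
    if len(brain) != len(emg):
        raise ValueError("series must have equal length")
    max_lag = int(round(max_lag_s * fs))
    if windows is None:
        b = np.asarray(brain, float) - np.mean(brain)
        e = np.asarray(emg, float) - np.mean(emg)
        # full cross-correlation: z[k] corresponds to lag = k - (len(b) - 1)
        z = signal.correlate(e, b, mode="full", method="fft")
        lags = np.arange(-(len(b) - 1), len(e))
        sel = (lags >= -max_lag) & (lags <= max_lag)
        lags, z = lags[sel], z[sel]
    else:
        lags = np.arange(-max_lag, max_lag + 1)
        z = np.zeros(len(lags))
        used = 0
        for start, stop in windows:
            i0, i1 = int(round((start - 0.5) * fs)), int(round((stop + 0.5) * fs))
            if i0 - max_lag < 0 or i1 + max_lag > len(brain):
                continue
            bw = brain[i0:i1] - np.mean(brain[i0:i1])
            ew = emg[i0 - max_lag:i1 + max_lag]
            ew = ew - np.mean(ew)
            z += signal.correlate(ew, bw, mode="valid", method="fft")
            used += 1
        if used == 0:
            raise ValueError("no usable windows inside the recording")
    k = int(np.argmax(z))
    return LatencyProfile(lags_s=lags / fs, profile=z,
                          peak_lag_s=lags[k] / fs,
                          at_boundary=(k == 0 or k == len(z) - 1))


def latency_table(tc: BroadbandTimecourse, emg_envelopes: dict[str, np.ndarray],
                  channels: list[str] | None = None,
                  pairs: list[tuple[str, str]] | None = None,
                  windows_by_emg: dict[str, list[tuple[float, float]]] | None = None
                  ) -> pd.DataFrame:
    """Peak lag (ms) per (channel, EMG) pair.

    With ``pairs`` only those combinations are computed (the matched-pair
    analysis: a somatotopic channel against its own effector's EMG, a
    shared-representation channel against each); otherwise every channel
    in ``channels`` (default all) is paired with every EMG envelope.
    ``windows_by_emg`` maps an EMG channel name to that effector's
    movement epochs, enabling the windowed estimator (see :func:`latency`).
    """
    rows = []
    name_to_row = {n: i for i, n in enumerate(tc.channel_names)}
    if pairs is None:
        names = channels if channels is not None else tc.channel_names
        pairs = [(ch, emg) for ch in names for emg in emg_envelopes]
    for ch, emg_name in pairs:
        win = windows_by_emg.get(emg_name) if windows_by_emg else None
        prof = latency(tc.data[name_to_row[ch]], emg_envelopes[emg_name], tc.fs,
                       windows=win)
        rows.append({"channel": ch, "emg": emg_name,
                     "peak_lag_ms": prof.peak_lag_ms,
                     "at_boundary": prof.at_boundary})
    return pd.DataFrame(rows)
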