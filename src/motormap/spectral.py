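"""Trial spectra and the signed r-squared movement statistic.

Each movement or rest epoch gets a Welch PSD (1 s Hann windows, 0.5 s
overlap, 1-300 Hz at 1 Hz steps). Because field potentials follow a 1/f
power law, every trial PSD is divided bin-wise by the channel's global
mean PSD across all trials before band power is computed. Broadband
power is the mean normalized power in 65-115 Hz — above the range of
most oscillations, clear of 60/120 Hz line noise.

The signed r-squared statistic compares movement-trial band power ``m``
against the rest trials that *followed* that same movement type ``r``
(pairing that avoids contamination by the post-movement beta rebound)::

    r2 = sign(mean(m) - mean(r)) * (mean(m) - mean(r))^2 * Nm * Nr
         / (var(m u r) * (Nm + Nr)^2)

with the population (divide-by-N) variance of the pooled samples. This
is the fraction of pooled variance explained by the group split, signed
by direction, and is identical to the squared point-biserial correlation
between samples and group labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .io import MOVEMENTS, TaskEvents
from .preprocess import BipolarRecording

FREQS = np.arange(1, 301)  # Hz
BROADBAND = (65.0, 115.0)
BETA = (8.0, 32.0)


@dataclass
class TrialPSD:
    """Per-trial normalized PSDs for every bipolar channel.

    ``psd``: trials x channels x frequency bins (normalized to the global
    mean across trials, per channel and bin); ``norm``: the global mean
    PSD that was divided out; ``trial_info``: one row per trial (onset,
    duration, trial_type, following).
    """

    psd: np.ndarray
    norm: np.ndarray
    freqs: np.ndarray
    trial_info: pd.DataFrame
    channel_names: list[str]

    def band_power(self, band: tuple[float, float] = BROADBAND) -> np.ndarray:
        """Mean normalized power in ``band`` (inclusive): trials x channels."""
        sel = (self.freqs >= band[0]) & (self.freqs <= band[1])
        return self.psd[:, :, sel].mean(axis=2)


@dataclass
class ChannelStats:
    """Signed r2 and move-vs-rest t-test per channel and movement.

    ``table`` columns: channel, movement, r2, p, n_move, n_rest.
    ``bb``: trials x channels broadband power, aligned with
    ``trial_info`` — kept so downstream decoding can reuse the samples.
    """

    table: pd.DataFrame
    bb: np.ndarray
    trial_info: pd.DataFrame
    channel_names: list[str]
    band: tuple[float, float] = BROADBAND

    def r2_matrix(self, movements=MOVEMENTS) -> pd.DataFrame:
        """Channels x movements pivot of signed r2."""
        piv = self.table.pivot(index="channel", columns="movement", values="r2")
        return piv.reindex(index=self.channel_names, columns=list(movements))

    def p_matrix(self, movements=MOVEMENTS) -> pd.DataFrame:
        piv = self.table.pivot(index="channel", columns="movement", values="p")
        return piv.reindex(index=self.channel_names, columns=list(movements))


def trial_psd(bipolar: BipolarRecording, events: TaskEvents,
              fmax: int = 300, window_s: float = 1.0) -> TrialPSD:
    """Welch PSD per epoch per sEEG pair, normalized to the global mean.

    Epochs shorter than one window are skipped with a warning. Rest
    epochs shorter than 1 s (truncated followers at run end) are dropped.
    """
    fs = bipolar.fs
    nper = int(round(window_s * fs))
    data = bipolar.pair_data()
    rows = []
    psds = []
    for _, ev in events.table.iterrows():
        i0 = int(round(ev["onset"] * fs))
        i1 = int(round((ev["onset"] + ev["duration"]) * fs))
        i1 = min(i1, data.shape[1])
        if i1 - i0 < nper:
            warnings.warn(f"epoch at {ev['onset']:.2f}s shorter than the "
                          f"{window_s:.1f}s Welch window; skipped")
            continue
        f, pxx = signal.welch(data[:, i0:i1], fs=fs, window="hann",
                              nperseg=nper, noverlap=nper // 2, detrend="constant")
        sel = (f >= 1) & (f <= fmax)
        psds.append(pxx[:, sel])
        rows.append({"onset": ev["onset"], "duration": ev["duration"],
                     "trial_type": ev["trial_type"], "following": ev["following"]})
    psd = np.stack(psds)  # trials x channels x freqs
    norm = psd.mean(axis=0, keepdims=True)
    psd = psd / norm
    return TrialPSD(psd=psd, norm=norm[0], freqs=f[sel],
                    trial_info=pd.DataFrame(rows),
                    channel_names=list(bipolar.pair_table["name"]))


def broadband_power(psds: TrialPSD, band: tuple[float, float] = BROADBAND) -> np.ndarray:
    """Per-trial mean normalized power in the broadband window (trials x channels)."""
    return psds.band_power(band)


def signed_r2(m: np.ndarray, r: np.ndarray) -> float:
    """Signed cross-correlation r2 between two sample groups.

    Bounded by [-1, 1]; zero when the group means are equal (the 0/0
    limit) or when the pooled samples are constant.
    """
    m = np.asarray(m, dtype=float)
    r = np.asarray(r, dtype=float)
    nm, nr = len(m), len(r)
    if nm < 2 or nr < 2:
        raise ValueError("need at least two samples per group")
    d = m.mean() - r.mean()
    pooled = np.concatenate([m, r])
    var = pooled.var()  # population variance
    if d == 0 or var == 0:
        return 0.0
    n = nm + nr
    return float(np.sign(d) * d * d * nm * nr / (var * n * n))


def movement_stats(psds: TrialPSD, band: tuple[float, float] = BROADBAND) -> ChannelStats:
    """Signed r2 + unpaired t-test per channel per movement.

    Movement trials are compared only against rest trials that followed
    that same movement type. Movements with fewer than two rest
    followers are flagged with NaN statistics.
    """
    bb = psds.band_power(band)
    info = psds.trial_info
    rows = []
    for ci, ch in enumerate(psds.channel_names):
        for mv in MOVEMENTS:
            mi = np.flatnonzero((info["trial_type"] == mv).to_numpy())
            ri = np.flatnonzero(((info["trial_type"] == "rest")
                                 & (info["following"] == mv)).to_numpy())
            if len(mi) < 2 or len(ri) < 2:
                rows.append({"channel": ch, "movement": mv, "r2": np.nan,
                             "p": np.nan, "n_move": len(mi), "n_rest": len(ri)})
                continue
            m, r = bb[mi, ci], bb[ri, ci]
            t = stats.ttest_ind(m, r)
            rows.append({"channel": ch, "movement": mv,
                         "r2": signed_r2(m, r), "p": float(t.pvalue),
                         "n_move": len(mi), "n_rest": len(ri)})
    return ChannelStats(table=pd.DataFrame(rows), bb=bb, trial_info=info,
                        channel_names=psds.channel_names, band=band)
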