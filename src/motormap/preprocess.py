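"""Bipolar rereferencing and EMG-defined movement epoching.

Depth-electrode voltages are recorded against a distant clinical
reference; subtracting adjacent contacts on the same lead segment yields
locally referenced channels and cancels signal common to the lead.
Movement epochs are re-timed from the visual cue to the actual EMG burst,
since reaction times jitter from trial to trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MOVEMENTS, Recording, SessionFormatError, TaskEvents

log = logging.getLogger(__name__)


@dataclass
class BipolarRecording:
    """Adjacent-contact difference channels plus untouched EMG channels.

    ``data`` rows follow ``pair_table`` (sEEG pairs) then ``emg_table``
    (original EMG channels). Pair polarity is proximal minus distal:
    ``pair = contact_i - contact_{i+1}`` in contact-index order, and the
    pair position is the midpoint of the two contacts.
    """

    data: np.ndarray
    fs: float
    pair_table: pd.DataFrame
    emg_table: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return len(self.pair_table)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def pair_data(self) -> np.ndarray:
        return self.data[: self.n_pairs]

    def emg_data(self) -> np.ndarray:
        return self.data[self.n_pairs:]

    def emg_channel(self, effector: str) -> np.ndarray | None:
        """EMG trace for one effector, matched by channel-name suffix."""
        names = self.emg_table["name"].str.lower()
        hit = np.flatnonzero(names.str.contains(effector.lower()))
        if len(hit) == 0:
            return None
        return self.emg_data()[hit[0]]


def bipolar_rereference(recording: Recording) -> BipolarRecording:
    """Difference all adjacent contact pairs within each lead segment.

    Contacts in different segments (or leads) are never paired. EMG
    channels pass through untouched. Raises when no valid pair exists.
    """
    ct = recording.channel_table
    seeg = ct[ct["kind"] == "seeg"]
    pair_rows = []
    pair_sigs = []
    for (lead, seg), grp in seeg.groupby(["lead_id", "segment_id"], sort=False):
        grp = grp.sort_values("contact_index")
        idx = grp.index.to_numpy()
        cidx = grp["contact_index"].to_numpy()
        for a, b in zip(range(len(grp) - 1), range(1, len(grp))):
            if cidx[b] - cidx[a] != 1:  # non-adjacent contacts (gap in the lead)
                continue
            ra, rb = grp.iloc[a], grp.iloc[b]
            pair_sigs.append(recording.data[idx[a]].astype(np.float64)
                             - recording.data[idx[b]].astype(np.float64))
            pair_rows.append({
                "name": f"{ra['name']}-{rb['name']}",
                "name_a": ra["name"], "name_b": rb["name"],
                "lead_id": lead, "segment_id": seg,
                "x": (ra["x"] + rb["x"]) / 2.0,
                "y": (ra["y"] + rb["y"]) / 2.0,
                "z": (ra["z"] + rb["z"]) / 2.0,
            })
    if not pair_rows:
        raise SessionFormatError("no valid adjacent contact pairs to rereference")
    emg_idx = recording.channels_of_kind("emg")
    emg_table = ct.iloc[emg_idx].reset_index(drop=True)
    data = np.vstack([np.asarray(pair_sigs),
                      recording.data[emg_idx].astype(np.float64)]) \
        if len(emg_idx) else np.asarray(pair_sigs)
    return BipolarRecording(data=data, fs=recording.fs,
                            pair_table=pd.DataFrame(pair_rows), emg_table=emg_table)


@dataclass
class EmgEpochParams:
    """Automated stand-in for manual EMG annotation.

    A burst is a stretch where the conditioned EMG envelope exceeds the
    rest baseline by ``threshold_sd`` standard deviations for at least
    ``min_duration_s``; the reported onset/offset are then refined to the
    crossings of ``refine_fraction`` of that trial's peak envelope. The
    quarter-peak default marks onset where the burst reaches 25% of its
    amplitude — the same convention as a 5x-baseline criterion on a
    typical burst ~20x baseline — and is far less biased by envelope
    smoothing than the raw sustained-threshold crossing.
    """

    threshold_sd: float = 3.0
    min_duration_s: float = 0.200
    search_pad_s: float = 1.0
    refine_fraction: float = 0.25


def emg_epochs(bipolar: "BipolarRecording", events: TaskEvents,
               params: EmgEpochParams | None = None) -> TaskEvents:
    """Re-time movement epochs to EMG burst onset/offset.

    Rest epochs keep their cue timing and their following-movement tag.
    Effectors lacking an EMG channel fall back to shifting cue times by
    the mean EMG-cue delay of the other effectors (logged).
    """
    from .dynamics import condition_emg

    if params is None:
        params = EmgEpochParams()
    fs = bipolar.fs
    envs = {mv: bipolar.emg_channel(mv) for mv in MOVEMENTS}
    if all(v is None for v in envs.values()):
        raise SessionFormatError("no EMG channels; cannot re-time epochs")
    conditioned = {mv: condition_emg_channel(envs[mv], fs) for mv in envs if envs[mv] is not None}

    table = events.table
    rest_mask = table["trial_type"] == "rest"
    rest_sel = table[rest_mask]
    # rest-baseline stats of each conditioned envelope
    base: dict[str, tuple[float, float]] = {}
    for mv, env in conditioned.items():
        samples = []
        for _, row in rest_sel.iterrows():
            i0 = int(round((row["onset"] + 0.5) * fs))
            i1 = int(round((row["onset"] + row["duration"] - 0.5) * fs))
            samples.append(env[i0:i1])
        allb = np.concatenate(samples)
        base[mv] = (float(allb.mean()), float(allb.std()))

    new_rows = []
    delays = []  # (emg_onset - cue_onset) for effectors with EMG
    fallback: list[int] = []
    for irow, row in table[~rest_mask].iterrows():
        mv = row["trial_type"]
        if mv not in conditioned:
            fallback.append(irow)
            new_rows.append(None)
            continue
        env = conditioned[mv]
        mu, sd = base[mv]
        if sd == 0 or not np.any(env > mu + params.threshold_sd * sd):
            raise SessionFormatError(f"no supra-threshold EMG activity for {mv}")
        i0 = int(round((row["onset"] - 0.25) * fs))
        i1 = int(round((row["onset"] + row["duration"] + params.search_pad_s) * fs))
        seg = env[max(i0, 0):i1]
        on, off = _detect_burst(seg, mu + params.threshold_sd * sd, mu,
                                int(round(params.min_duration_s * fs)),
                                params.refine_fraction)
        if on is None:
            log.warning("no EMG burst found for %s trial at %.1f s; keeping cue timing",
                        mv, row["onset"])
            new_rows.append({"onset": row["onset"], "duration": row["duration"],
                             "trial_type": mv, "source": "cue", "following": "n/a"})
            continue
        onset_s = (max(i0, 0) + on) / fs
        offset_s = (max(i0, 0) + off) / fs
        delays.append(onset_s - row["onset"])
        new_rows.append({"onset": onset_s, "duration": offset_s - onset_s,
                         "trial_type": mv, "source": "emg", "following": "n/a"})

    if fallback:
        if not delays:
            raise SessionFormatError("no effector has usable EMG; cannot re-time epochs")
        shift = float(np.mean(delays))
        moves = table[~rest_mask]
        missing = sorted({table.loc[i, 'trial_type'] for i in fallback})
        log.warning("no EMG for effector(s) %s; shifting cues by mean delay %.3f s",
                    missing, shift)
        for k, irow in enumerate(table[~rest_mask].index):
            if new_rows[k] is None:
                row = moves.loc[irow]
                # timing estimated from the other effectors' EMG delay, so it
                # belongs to the emg-timed stream, not the cue grid
                new_rows[k] = {"onset": row["onset"] + shift, "duration": row["duration"],
                               "trial_type": row["trial_type"], "source": "emg",
                               "following": "n/a"}

    out = pd.DataFrame(new_rows + rest_sel.to_dict("records"))
    out = out.sort_values("onset", kind="stable").reset_index(drop=True)
    return TaskEvents(out)


def condition_emg_channel(x: np.ndarray, fs: float) -> np.ndarray:
    from .dynamics import condition_emg_series

    return condition_emg_series(x, fs)


def _detect_burst(seg: np.ndarray, thresh: float, floor: float,
                  min_len: int, refine_fraction: float):
    """First sustained supra-threshold run, refined to fractional-peak crossings."""
    above = seg > thresh
    # find runs of True
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(seg))
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            peak = seg[s:e].max()
            level = floor + refine_fraction * (peak - floor)
            over = np.flatnonzero(seg[s:e] >= level)
            on = s + over[0]
            while on > 0 and seg[on - 1] > level:
                on -= 1
            off = s + over[-1]
            while off < len(seg) and seg[off] > level:
                off += 1
            return on, off
    return None, None
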