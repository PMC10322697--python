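"""Synthetic sEEG + EMG session generator with known ground truth.

Emulates the statistical structure the mapping analysis relies on:

* contact voltages follow a 1/f power-law spectrum with line noise at
  60/120/180 Hz and a 7 Hz common-mode shared by all contacts of a lead
  (so bipolar rereferencing demonstrably removes it);
* during movement, responsive channels multiply their broadband
  (65 Hz and up) power by ``g_bb`` and suppress 10-30 Hz (beta) power by
  ``g_beta``, with the brain modulation leading EMG onset by ``tau_s``.
  Effect sizes vary across sites and movements the way real motor maps
  do: each (channel, movement) draws a mean-one log-normal multiplier on
  the excess gain ``g_bb - 1`` (sd ``g_bb_log_sd`` in log units), so a
  shared-representation channel responds to all three movements but not
  identically;
* channel classes: somatotopic (respond to exactly one movement in
  broadband), RMA / shared-representation (respond to all three), and
  inactive. Beta suppression is widespread and movement-nonspecific, the
  way pericentral beta desynchronization behaves, for every active
  channel (configurable via ``beta_scope``);
* EMG channels carry 25-400 Hz band-limited bursts per effector, with
  movement onsets jittered around the visual cue.

Band-limited modulation works by partitioning one realization of colored
Gaussian noise in the frequency domain into low / beta / broadband
components (disjoint support, hence independent) and cross-fading the
beta and broadband gains with 100 ms raised-cosine ramps; this avoids the
edge clicks that would otherwise leak broadband power.

A lead segment with P bipolar pairs is emitted as P+1 monopolar contacts
built by cumulative subtraction (contact_{j+1} = contact_j - pair_j), so
adjacent-pair bipolar rereferencing recovers each synthesized pair signal
exactly. Contact voltage variance therefore grows along a segment; this
is a synthetic compromise, not a biophysical claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MOVEMENTS, Recording, TaskEvents, write_session

CLASS_LABELS = ("somatotopic_hand", "somatotopic_tongue", "somatotopic_foot", "rma", "inactive")


@dataclass
class ChannelPlan:
    """Number of ground-truth bipolar channels per response class."""

    somatotopic_hand: int = 10
    somatotopic_tongue: int = 10
    somatotopic_foot: int = 10
    rma: int = 6
    inactive: int = 30

    def labels(self) -> list[str]:
        out: list[str] = []
        for name in CLASS_LABELS:
            out.extend([name] * getattr(self, name))
        return out

    @property
    def total(self) -> int:
        return len(self.labels())


@dataclass
class GeneratorSpec:
    """All knobs of the synthetic session.

    Effect sizes (broadband gain, beta suppression) are free parameters of
    the generator; the defaults are plain-to-detect motor effects at 20
    trials per movement.
    """

    seed: int = 0
    fs: float = 1200.0
    n_trials_per_movement: int = 20
    cue_s: float = 3.0
    rest_s: float = 3.0
    plan: ChannelPlan = field(default_factory=ChannelPlan)
    g_bb: float = 3.0            # move/rest 65-115 Hz power ratio (class mean)
    g_bb_log_sd: float = 0.25    # per-(channel, movement) log-normal gain spread
    g_beta: float = 0.5          # move/rest 10-30 Hz power ratio (< 1: suppression)
    tau_s: float = 0.100         # brain modulation leads EMG onset by this much
    emg_delay_s: float = 0.150   # mean cue -> movement reaction time
    emg_jitter_sd_s: float = 0.050
    line_amps_uv: dict[float, float] = field(default_factory=lambda: {60.0: 5.0, 120.0: 2.0, 180.0: 1.0})
    one_over_f_exponent: float = 2.0
    noise_rms_uv: float = 20.0
    bb_band: tuple[float, float] = (65.0, 200.0)   # modulated broadband support
    beta_band: tuple[float, float] = (10.0, 30.0)
    ramp_s: float = 0.100
    beta_scope: str = "all"       # "all": nonspecific suppression; "responsive": per-class
    common_mode_amp_uv: float = 30.0
    common_mode_freq: float = 7.0
    emg_baseline_uv: float = 1.0
    emg_burst_gain: float = 20.0  # burst amplitude in units of baseline sd
    pairs_per_segment: int = 10
    pad_s: float = 4.0

    def __post_init__(self) -> None:
        if not self.g_bb >= 1:
            raise ValueError("g_bb must be >= 1 (1 disables broadband modulation)")
        if not 0 < self.g_beta <= 1:
            raise ValueError("g_beta must be in (0, 1]")
        if self.tau_s < 0:
            raise ValueError("tau_s must be non-negative")
        if self.beta_scope not in ("all", "responsive"):
            raise ValueError("beta_scope must be 'all' or 'responsive'")

    @classmethod
    def preset(cls, name: str, seed: int = 0, **overrides) -> "GeneratorSpec":
        """Named study conditions: ``default`` or ``beta-only``.

        ``beta-only`` disables the broadband response (g_bb = 1) leaving
        only widespread nonspecific beta suppression, the condition under
        which low-frequency parcellation collapses to active-vs-inactive.
        """
        if name == "default":
            return cls(seed=seed, **overrides)
        if name == "beta-only":
            return cls(seed=seed, g_bb=1.0, beta_scope="all", **overrides)
        raise ValueError(f"unknown preset {name!r}")


@dataclass
class GroundTruth:
    """Per-channel class labels and per-trial true movement timing.

    ``channels``: name (bipolar pair name), label, responsive
    ("hand"/"tongue"/"foot"/"all"/"none"), tau_s.
    ``trials``: trial_type, cue_onset, onset, offset — onset/offset are the
    times the jittered EMG burst envelope crosses 5x the EMG baseline sd.
    """

    channels: pd.DataFrame
    trials: pd.DataFrame

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.channels.to_csv(path / "ground_truth_channels.tsv", sep="\t", index=False)
        self.trials.to_csv(path / "ground_truth_trials.tsv", sep="\t", index=False)


RESPONSIVE = {
    "somatotopic_hand": ("hand",),
    "somatotopic_tongue": ("tongue",),
    "somatotopic_foot": ("foot",),
    "rma": MOVEMENTS,
    "inactive": (),
}


def make_schedule(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> TaskEvents:
    """Shuffled movement cues (n per type), each followed by a tagged rest epoch."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    types = np.repeat(MOVEMENTS, spec.n_trials_per_movement)
    types = types[rng.permutation(len(types))]
    rows = []
    t = spec.pad_s
    for mv in types:
        rows.append({"onset": t, "duration": spec.cue_s, "trial_type": mv,
                     "source": "cue", "following": "n/a"})
        rows.append({"onset": t + spec.cue_s, "duration": spec.rest_s, "trial_type": "rest",
                     "source": "cue", "following": mv})
        t += spec.cue_s + spec.rest_s
    return TaskEvents(pd.DataFrame(rows))


def _raised_cosine_window(t: np.ndarray, start: float, stop: float, ramp: float) -> np.ndarray:
    """0->1->0 window: rising ramp centered at `start`, falling at `stop`."""
    w = np.zeros_like(t)
    r2 = ramp / 2.0
    rise = (t >= start - r2) & (t < start + r2)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - (start - r2)) / ramp))
    flat = (t >= start + r2) & (t < stop - r2)
    w[flat] = 1.0
    fall = (t >= stop - r2) & (t < stop + r2)
    w[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - (stop - r2)) / ramp))
    return w


def _gain_envelope(t: np.ndarray, intervals: np.ndarray, gain: float, ramp: float) -> np.ndarray:
    """Amplitude envelope: 1 at rest, sqrt(gain) inside each interval."""
    a = np.sqrt(gain)
    w = np.zeros_like(t)
    for start, stop in intervals:
        w += _raised_cosine_window(t, start, stop, ramp)
    return 1.0 + (a - 1.0) * w


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0]) & (freqs <= band[1])


def synthesize(spec: GeneratorSpec) -> tuple[Recording, TaskEvents, GroundTruth]:
    """Generate a full session: Recording (contacts + EMG), schedule, truth.

    Deterministic in ``spec`` (including ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    events = make_schedule(spec, rng)
    fs = spec.fs
    moves = events.movement_epochs()
    total_s = float(events.table["onset"].iloc[-1] + events.table["duration"].iloc[-1] + spec.pad_s)
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    # jittered per-trial movement timing; ramp centers m_on/m_off, ground
    # truth = the 5x-baseline crossing of the EMG burst envelope
    jit = np.clip(rng.normal(0.0, spec.emg_jitter_sd_s, size=(len(moves), 2)),
                  -2.5 * spec.emg_jitter_sd_s, 2.5 * spec.emg_jitter_sd_s)
    m_on = moves["onset"].to_numpy() + spec.emg_delay_s + jit[:, 0]
    m_off = moves["onset"].to_numpy() + moves["duration"].to_numpy() + spec.emg_delay_s + jit[:, 1]
    q = 5.0 / spec.emg_burst_gain  # envelope fraction at the 5x-baseline crossing
    u = np.arccos(1 - 2 * q) / np.pi  # position of that crossing within the ramp
    cross = (u - 0.5) * spec.ramp_s
    truth_trials = pd.DataFrame({
        "trial_type": moves["trial_type"].to_numpy(),
        "cue_onset": moves["onset"].to_numpy(),
        "onset": m_on + cross,
        "offset": m_off - cross,
    })

    emg_iv = {mv: np.column_stack([m_on[moves["trial_type"] == mv],
                                   m_off[moves["trial_type"] == mv]])
              for mv in MOVEMENTS}
    brain_iv = {mv: iv - spec.tau_s for mv, iv in emg_iv.items()}
    all_brain = np.vstack([brain_iv[mv] for mv in MOVEMENTS])
    all_brain = all_brain[np.argsort(all_brain[:, 0])]

    # unit 0->1 window sums per movement; per-channel broadband envelopes are
    # assembled from these with channel-specific gains
    w_bb = {mv: sum(_raised_cosine_window(t, a, b, spec.ramp_s) for a, b in brain_iv[mv])
            for mv in MOVEMENTS}
    env_beta_all = _gain_envelope(t, all_brain, spec.g_beta, spec.ramp_s)
    env_beta_mv: dict[str, np.ndarray] = {}
    if spec.beta_scope == "responsive":
        env_beta_mv = {mv: _gain_envelope(t, brain_iv[mv], spec.g_beta, spec.ramp_s)
                       for mv in MOVEMENTS}
        env_beta_mv["all"] = _gain_envelope(t, all_brain, spec.g_beta, spec.ramp_s)

    freqs = np.fft.rfftfreq(n, 1 / fs)
    with np.errstate(divide="ignore"):
        amp = np.where(freqs > 0, freqs ** (-spec.one_over_f_exponent / 2.0), 0.0)
    mask_beta = _band_mask(freqs, spec.beta_band)
    mask_bb = _band_mask(freqs, spec.bb_band)
    mask_low = ~(mask_beta | mask_bb)
    mask_low[0] = False  # no DC

    labels = spec.plan.labels()
    n_pairs = len(labels)
    n_seg = int(np.ceil(n_pairs / spec.pairs_per_segment)) if n_pairs else 0
    rows_ch: list[dict] = []
    rows_gt: list[dict] = []
    contacts: list[np.ndarray] = []

    for seg in range(n_seg):
        lead = f"L{seg + 1:02d}"
        seg_labels = labels[seg * spec.pairs_per_segment:(seg + 1) * spec.pairs_per_segment]
        phase = rng.uniform(0, 2 * np.pi)
        common = spec.common_mode_amp_uv * np.sin(2 * np.pi * spec.common_mode_freq * t + phase)
        entry = rng.normal(0, 25.0, 3)
        direction = rng.normal(0, 1, 3)
        direction /= np.linalg.norm(direction)
        contact = common.copy()
        for j, lab in enumerate([*seg_labels, None]):
            xyz = entry + 3.5 * j * direction
            rows_ch.append({"name": f"{lead}c{j + 1:02d}", "kind": "seeg", "lead_id": lead,
                            "segment_id": 1, "contact_index": j + 1,
                            "x": xyz[0], "y": xyz[1], "z": xyz[2]})
            contacts.append(contact.astype(np.float32))
            if lab is None:
                break
            s, gains = _pair_signal(spec, rng, n, t, amp, mask_low, mask_beta, mask_bb,
                                    lab, w_bb, env_beta_all, env_beta_mv)
            rows_gt.append({"name": f"{lead}c{j + 1:02d}-{lead}c{j + 2:02d}",
                            "label": lab,
                            "responsive": ("all" if lab == "rma" else
                                           "none" if lab == "inactive" else lab.split("_")[1]),
                            "tau_s": spec.tau_s if lab != "inactive" else np.nan,
                            **{f"g_{mv}": gains.get(mv, np.nan) for mv in MOVEMENTS}})
            contact = contact - s

    # EMG channels: near-zero baseline + band-limited bursts per effector
    for k, mv in enumerate(MOVEMENTS):
        base = rng.normal(0, spec.emg_baseline_uv, n)
        z = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
        band = np.fft.irfft(z * _band_mask(freqs, (25.0, 400.0)), n)
        band /= band.std()
        w = np.zeros(n)
        for start, stop in emg_iv[mv]:
            w += _raised_cosine_window(t, start, stop, spec.ramp_s)
        sig = base + spec.emg_burst_gain * spec.emg_baseline_uv * band * w
        rows_ch.append({"name": f"EMG_{mv}", "kind": "emg", "lead_id": "EMG",
                        "segment_id": 1, "contact_index": k + 1,
                        "x": np.nan, "y": np.nan, "z": np.nan})
        contacts.append(sig.astype(np.float32))

    data = np.vstack(contacts) if contacts else np.empty((0, n), dtype=np.float32)
    recording = Recording(data=data, fs=fs, channel_table=pd.DataFrame(rows_ch))
    truth = GroundTruth(channels=pd.DataFrame(rows_gt), trials=truth_trials)
    return recording, events, truth


def _pair_signal(spec, rng, n, t, amp, mask_low, mask_beta, mask_bb,
                 label, w_bb, env_beta_all, env_beta_mv):
    """One ground-truth bipolar channel: colored noise with class-dependent
    band-limited gain modulation, plus line noise. Returns (signal, gains)."""
    z = rng.standard_normal(len(amp)) + 1j * rng.standard_normal(len(amp))
    base = z * amp
    full = np.fft.irfft(base, n)
    sd = full.std()
    gains: dict[str, float] = {}
    if label == "inactive":
        s = full
    else:
        low = np.fft.irfft(base * mask_low, n)
        beta = np.fft.irfft(base * mask_beta, n)
        bb = np.fft.irfft(base * mask_bb, n)
        resp = RESPONSIVE[label]
        # mean-one log-normal multiplier on the *excess* gain per responsive
        # movement, so E[g] = g_bb and g_bb = 1 stays exactly unmodulated
        sig = spec.g_bb_log_sd
        for mv in resp:
            mult = float(np.exp(rng.normal(-sig ** 2 / 2, sig)))
            gains[mv] = 1.0 + (spec.g_bb - 1.0) * mult
        e_bb = np.ones(n)
        for mv in resp:
            e_bb += (np.sqrt(gains[mv]) - 1.0) * w_bb[mv]
        if spec.beta_scope == "all":
            e_beta = env_beta_all
        else:
            e_beta = env_beta_mv["all"] if label == "rma" else env_beta_mv[resp[0]]
        s = low + beta * e_beta + bb * e_bb
    s = s * (spec.noise_rms_uv / sd)
    for f0, a0 in spec.line_amps_uv.items():
        s = s + a0 * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    return s, gains


def simulate_to_dir(spec: GeneratorSpec, out: str | Path) -> Path:
    """Write a full synthetic session plus ground-truth TSVs to ``out``."""
    rec, events, truth = synthesize(spec)
    out = Path(out)
    write_session(rec, events, out)
    truth.write(out)
    return out
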