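"""Somatotopic delineation and shared-representation (RMA) scoring.

Each channel's three movement r2 values (negatives zeroed first) are
placed on unit vectors 120 degrees apart — hand at pi/6, tongue at
5*pi/6, foot at 3*pi/2 — and summed. The phase of the resulting complex
number points at the movement the channel prefers; the magnitude is the
strength of somatotopic selectivity, and a channel equally active for
all three movements cancels to zero.

Shared representation ("overlap") is the geometric mean of the three r2
values, with any movement whose move-vs-rest test is not significant
(p >= 0.05) contributing zero — so one silent movement annihilates the
score. High overlap with low vector magnitude is the RMA signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import ChannelStats

BASIS = {
    "hand": np.exp(1j * np.pi / 6),
    "tongue": np.exp(1j * 5 * np.pi / 6),
    "foot": np.exp(1j * 3 * np.pi / 2),
}

OVERLAP_ALPHA = 0.05


@dataclass
class SomatotopyMap:
    """Per-channel tuning vector and overlap score.

    ``table`` columns: channel, tuning_re, tuning_im, magnitude,
    angle_rad, overlap.
    """

    table: pd.DataFrame

    @property
    def magnitude(self) -> np.ndarray:
        return self.table["magnitude"].to_numpy()

    @property
    def overlap(self) -> np.ndarray:
        return self.table["overlap"].to_numpy()


def somatotopy_vector(r2_hand, r2_tongue, r2_foot) -> np.ndarray:
    """Complex tuning value(s) from per-movement r2; negatives clipped to 0."""
    h = np.clip(np.asarray(r2_hand, dtype=float), 0, None)
    t = np.clip(np.asarray(r2_tongue, dtype=float), 0, None)
    f = np.clip(np.asarray(r2_foot, dtype=float), 0, None)
    return h * BASIS["hand"] + t * BASIS["tongue"] + f * BASIS["foot"]


def shared_overlap(r2_hand, r2_tongue, r2_foot, p_hand=None, p_tongue=None,
                   p_foot=None, alpha: float = OVERLAP_ALPHA) -> np.ndarray:
    """Geometric mean of significant r2 values; zero if any movement is n.s."""
    vals = []
    for r2, p in ((r2_hand, p_hand), (r2_tongue, p_tongue), (r2_foot, p_foot)):
        v = np.clip(np.asarray(r2, dtype=float), 0, None)
        if p is not None:
            v = np.where(np.asarray(p, dtype=float) < alpha, v, 0.0)
        vals.append(v)
    return np.cbrt(vals[0] * vals[1] * vals[2])


def somatotopy_map(stats: ChannelStats, alpha: float = OVERLAP_ALPHA) -> SomatotopyMap:
    """Tuning vector + overlap for every channel in ``stats``."""
    r2 = stats.r2_matrix()
    p = stats.p_matrix()
    tuning = somatotopy_vector(r2["hand"].to_numpy(), r2["tongue"].to_numpy(),
                               r2["foot"].to_numpy())
    ov = shared_overlap(r2["hand"].to_numpy(), r2["tongue"].to_numpy(),
                        r2["foot"].to_numpy(), p["hand"].to_numpy(),
                        p["tongue"].to_numpy(), p["foot"].to_numpy(), alpha=alpha)
    table = pd.DataFrame({
        "channel": r2.index,
        "tuning_re": tuning.real,
        "tuning_im": tuning.imag,
        "magnitude": np.abs(tuning),
        "angle_rad": np.mod(np.angle(tuning), 2 * np.pi),
        "overlap": ov,
    })
    return SomatotopyMap(table=table)


@dataclass
class DisplayMasks:
    """Boolean display inclusion masks over channels (same order as the map)."""

    somatotopy: np.ndarray     # magnitude > 50% of within-session max
    overlap: np.ndarray        # overlap > 50% of within-session max
    per_movement: pd.DataFrame  # r2 above 1% of that movement's max r2


def threshold_maps(smap: SomatotopyMap, stats: ChannelStats,
                   half_max: float = 0.5, single_modality: float = 0.01) -> DisplayMasks:
    """Display cutoffs: half-of-maximum for the aggregate maps, and the
    one-percent-of-maximum single-modality significance cutoff."""
    mag, ov = smap.magnitude, smap.overlap
    mag_mask = mag > half_max * (mag.max() if len(mag) else 0.0)
    ov_mask = ov > half_max * (ov.max() if len(ov) else 0.0)
    r2 = stats.r2_matrix().clip(lower=0)
    per_mv = r2 > single_modality * r2.max(axis=0)
    return DisplayMasks(somatotopy=mag_mask, overlap=ov_mask, per_movement=per_mv)
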