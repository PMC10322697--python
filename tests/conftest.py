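import numpy as np
import pandas as pd
import pytest

from motormap import (GeneratorSpec, bipolar_rereference, emg_epochs,
                      movement_stats, synthesize, trial_psd)
from motormap.io import TaskEvents
from motormap.preprocess import BipolarRecording

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def sim_default():
    """One full default synthetic session shared across the suite."""
    spec = GeneratorSpec(seed=DEFAULT_SEED)
    recording, events, truth = synthesize(spec)
    return spec, recording, events, truth


@pytest.fixture(scope="session")
def bp_default(sim_default):
    _, recording, _, _ = sim_default
    return bipolar_rereference(recording)


@pytest.fixture(scope="session")
def emg_events_default(sim_default, bp_default):
    _, _, events, _ = sim_default
    return emg_epochs(bp_default, events)


@pytest.fixture(scope="session")
def psds_default(bp_default, emg_events_default):
    return trial_psd(bp_default, emg_events_default)


@pytest.fixture(scope="session")
def stats_default(psds_default):
    return movement_stats(psds_default)


def make_bipolar(data: np.ndarray, fs: float, emg: np.ndarray | None = None,
                 emg_names: list[str] | None = None) -> BipolarRecording:
    """Wrap raw arrays as a BipolarRecording for direct unit tests."""
    data = np.atleast_2d(np.asarray(data, float))
    pair_table = pd.DataFrame({
        "name": [f"P{i:02d}" for i in range(len(data))],
        "name_a": [f"c{i}" for i in range(len(data))],
        "name_b": [f"c{i + 1}" for i in range(len(data))],
        "lead_id": "L01", "segment_id": 1,
        "x": 0.0, "y": 0.0, "z": 0.0,
    })
    if emg is not None:
        emg = np.atleast_2d(np.asarray(emg, float))
        names = emg_names or [f"EMG_{i}" for i in range(len(emg))]
        emg_table = pd.DataFrame({"name": names, "kind": "emg", "lead_id": "EMG",
                                  "segment_id": 1,
                                  "contact_index": range(1, len(emg) + 1),
                                  "x": np.nan, "y": np.nan, "z": np.nan})
        full = np.vstack([data, emg])
    else:
        emg_table = pd.DataFrame(columns=["name", "kind", "lead_id", "segment_id",
                                          "contact_index", "x", "y", "z"])
        full = data
    return BipolarRecording(data=full, fs=fs, pair_table=pair_table, emg_table=emg_table)


def make_events(rows: list[tuple]) -> TaskEvents:
    """rows: (onset, duration, trial_type, source[, following])."""
    recs = []
    for r in rows:
        onset, duration, trial_type, source = r[:4]
        following = r[4] if len(r) > 4 else "n/a"
        recs.append({"onset": onset, "duration": duration, "trial_type": trial_type,
                     "source": source, "following": following})
    return TaskEvents(pd.DataFrame(recs))
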