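import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal, stats as sps

from conftest import make_bipolar, make_events
from motormap import broadband_power, movement_stats, signed_r2, trial_psd
from motormap.io import MOVEMENTS


def r2_oracle(m, r):
    """Sign times squared point-biserial correlation of samples vs labels."""
    pooled = np.concatenate([m, r])
    labels = np.r_[np.ones(len(m)), np.zeros(len(r))]
    rho = np.corrcoef(pooled, labels)[0, 1]
    return np.sign(rho) * rho ** 2


class TestSignedR2:
    @pytest.mark.parametrize("m,r,expected", [
        ([2, 2, 2], [1, 1, 1], 1.0),
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 1, 1], [2, 2, 2], -1.0),
        ([1, 1, 1, 1], [1, 1, 1, 1], 0.0),  # constant pooled input
    ])
    def test_known_values(self, m, r, expected):
        assert signed_r2(m, r) == pytest.approx(expected, abs=1e-15)

    def test_matches_point_biserial_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            nm, nr = rng.integers(2, 30, 2)
            m = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), nm)
            r = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), nr)
            assert signed_r2(m, r) == pytest.approx(r2_oracle(m, r), abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=12),
           st.lists(st.floats(-50, 50), min_size=2, max_size=12),
           st.floats(0.01, 100), st.floats(-10, 10))
    def test_antisymmetry_bound_and_affine_invariance(self, m, r, a, b):
        m, r = np.array(m), np.array(r)
        v = signed_r2(m, r)
        assert -1.0 <= v <= 1.0
        assert signed_r2(r, m) == pytest.approx(-v, abs=1e-9)
        assert signed_r2(a * m + b, a * r + b) == pytest.approx(v, abs=1e-6)

    def test_requires_two_samples_per_group(self):
        with pytest.raises(ValueError):
            signed_r2([1.0], [1.0, 2.0])


def sinusoid_session(freq=20.0, fs=1200.0):
    t = np.arange(int(3 * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)[None, :]
    bp = make_bipolar(np.vstack([x, x]), fs)
    ev = make_events([(0.0, 3.0, "hand", "cue")])
    return bp, ev


def test_psd_peaks_at_sinusoid_frequency():
    bp, ev = sinusoid_session(freq=20.0)
    psds = trial_psd(bp, ev)
    assert psds.freqs[np.argmax(psds.norm[0])] == 20


def test_normalization_means_one_per_bin(psds_default):
    np.testing.assert_allclose(psds_default.psd.mean(axis=0), 1.0, atol=1e-10)


def test_white_noise_normalized_psd_flat_within_welch_variability():
    """Single-trial normalized PSD scatter matches the Welch variance
    formula for Hann windows at 50% overlap (overlap-corrected dof)."""
    fs, n_trials = 1200.0, 40
    rng = np.random.default_rng(3)
    x = rng.normal(size=(1, int(3 * fs * n_trials)))
    rows = [(3.0 * i, 3.0, "hand", "cue") for i in range(n_trials)]
    psds = trial_psd(make_bipolar(x, fs), make_events(rows))
    # oracle: relative variance of an L-window Welch mean with overlap rho
    w = signal.get_window("hann", int(fs))
    shift = int(fs) // 2
    rho = (np.sum(w[shift:] * w[:-shift]) / np.sum(w * w)) ** 2
    L = 5  # windows per 3 s trial at 50% overlap
    var_rel = (1 + 2 * (L - 1) / L * rho) / L
    z = (psds.psd[:, 0, :] - 1.0) / np.sqrt(var_rel)
    assert np.mean(np.abs(z) > 3) < 0.01
    assert 0.8 < z.std() < 1.2


def test_broadband_power_of_flat_psd_is_one(psds_default):
    flat = psds_default.psd.copy()
    flat[:] = 1.0
    import dataclasses

    p2 = dataclasses.replace(psds_default, psd=flat)
    np.testing.assert_allclose(broadband_power(p2), 1.0)


def test_line_noise_outside_band_does_not_change_broadband():
    fs = 1200.0
    rng = np.random.default_rng(7)
    t = np.arange(int(12 * fs)) / fs
    base = rng.normal(size=len(t))
    mains = 40 * np.sin(2 * np.pi * 60 * t) + 20 * np.sin(2 * np.pi * 120 * t)
    rows = [(3.0 * i, 3.0, "hand", "cue") for i in range(4)]
    ev = make_events(rows)
    bb_clean = broadband_power(trial_psd(make_bipolar(base[None], fs), ev))
    bb_lines = broadband_power(trial_psd(make_bipolar((base + mains)[None], fs), ev))
    # 65-115 Hz excludes 60/120 Hz: line power enters only via normalization
    np.testing.assert_allclose(bb_lines, bb_clean, rtol=1e-6)


def test_movement_stats_detects_only_responsive_movement(sim_default, stats_default):
    _, _, _, truth = sim_default
    p = stats_default.p_matrix().to_numpy()
    r2 = stats_default.r2_matrix().to_numpy()
    labels = truth.channels["label"].to_numpy()
    hand = labels == "somatotopic_hand"
    assert (p[hand, 0] < 0.05).all()
    assert r2[hand, 0].min() > 0.3
    # non-responsive movements are n.s. for the overwhelming majority
    assert np.mean(p[hand, 1:] >= 0.05) > 0.85


def test_label_permutation_p_values_are_uniform(stats_default):
    """Permuting move/rest labels of broadband samples gives uniform p."""
    rng = np.random.default_rng(0)
    bb = stats_default.bb
    info = stats_default.trial_info
    mi = np.flatnonzero((info["trial_type"] == "hand").to_numpy())
    ri = np.flatnonzero(((info["trial_type"] == "rest")
                         & (info["following"] == "hand")).to_numpy())
    samples = bb[np.r_[mi, ri], 0]  # an inactive-or-not channel, labels destroyed
    ps = []
    for _ in range(200):
        perm = rng.permutation(len(samples))
        ps.append(sps.ttest_ind(samples[perm[:len(mi)]], samples[perm[len(mi):]]).pvalue)
    assert sps.kstest(ps, "uniform").pvalue > 0.05


def test_short_epochs_skipped_with_warning():
    fs = 1200.0
    x = np.random.default_rng(0).normal(size=(1, int(5 * fs)))
    ev = make_events([(0.0, 0.5, "hand", "cue"), (1.0, 3.0, "hand", "cue")])
    with pytest.warns(UserWarning, match="shorter"):
        psds = trial_psd(make_bipolar(x, fs), ev)
    assert len(psds.trial_info) == 1


def test_movement_without_rest_followers_flagged(psds_default):
    import dataclasses

    info = psds_default.trial_info.copy()
    info.loc[(info["trial_type"] == "rest") & (info["following"] == "foot"),
             "following"] = "hand"
    p2 = dataclasses.replace(psds_default, trial_info=info)
    st2 = movement_stats(p2)
    foot = st2.table[st2.table["movement"] == "foot"]
    assert foot["r2"].isna().all() and (foot["n_rest"] == 0).all()
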