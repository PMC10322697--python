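"""End-to-end orchestration: simulate (or load) -> preprocess -> stats ->
map -> dynamics -> cluster -> decode, with a run manifest and QC figures.

Every stage writes plain TSV artifacts into the output directory, and the
manifest records the config snapshot, seeds, package version, input
hashes, per-stage timings and channel/trial drop counts, so a run can be
reproduced bit-exactly from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, decoding, dynamics, mapping, spectral
from .io import read_session, write_session
from .preprocess import bipolar_rereference, emg_epochs
from .synthetic import GeneratorSpec, synthesize

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Key-value run configuration (loadable from TOML via :func:`load_config`)."""

    seed: int = 0
    session: str | None = None      # load this session instead of simulating
    preset: str = "default"         # generator preset when simulating
    band_lo: float = 65.0
    band_hi: float = 115.0
    beta_lo: float = 8.0
    beta_hi: float = 32.0
    alpha: float = 1.5              # clustering penalty exponent
    k_max: int = 20
    restarts: int = 1000
    smooth_sd_s: float = 0.050
    folds: int = 3
    figures: bool = True
    run_dynamics: bool = True

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as f:
            raw = tomllib.load(f)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, out: str | Path) -> dict:
    """Execute the full pipeline; returns the manifest dict (also written
    to ``manifest.json`` under ``out``)."""
    from . import __version__

    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "version": __version__,
                      "stages": {}, "outputs": {}, "counts": {}}
    band = (config.band_lo, config.band_hi)

    def stage(name):
        t0 = time.perf_counter()

        def done(**outputs):
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            for k, v in outputs.items():
                manifest["outputs"][k] = str(v)
        return done

    try:
        done = stage("input")
        if config.session is None:
            spec = GeneratorSpec.preset(config.preset, seed=config.seed)
            recording, events, truth = synthesize(spec)
            sess_dir = out / "session"
            write_session(recording, events, sess_dir)
            truth.write(sess_dir)
            manifest["generator_spec"] = {k: v for k, v in asdict(spec).items()
                                          if not isinstance(v, dict)}
            done(session=sess_dir)
        else:
            recording, events = read_session(config.session)
            manifest["input_hashes"] = {
                p.name: _sha256(p) for p in sorted(Path(config.session).iterdir())
                if p.is_file()}
            done(session=config.session)
        manifest["counts"]["channels_in"] = recording.n_channels

        done = stage("preprocess")
        bipolar = bipolar_rereference(recording)
        ev = emg_epochs(bipolar, events)
        manifest["counts"]["bipolar_pairs"] = bipolar.n_pairs
        done()

        done = stage("stats")
        psds = spectral.trial_psd(bipolar, ev)
        stats = spectral.movement_stats(psds, band=band)
        stats.table.to_csv(out / "stats.tsv", sep="\t", index=False)
        manifest["counts"]["trials_used"] = len(psds.trial_info)
        done(stats=out / "stats.tsv")

        done = stage("map")
        smap = mapping.somatotopy_map(stats)
        masks = mapping.threshold_maps(smap, stats)
        map_table = smap.table.assign(somatotopy_mask=masks.somatotopy,
                                      overlap_mask=masks.overlap)
        map_table.to_csv(out / "map.tsv", sep="\t", index=False)
        done(map=out / "map.tsv")

        lat = None
        if config.run_dynamics:
            done = stage("dynamics")
            tc = dynamics.broadband_timecourse(bipolar, smooth_sd_s=config.smooth_sd_s)
            envs = dynamics.condition_emg(bipolar, smooth_sd_s=config.smooth_sd_s)
            groups = decoding.select_channels(stats)
            pmat = stats.p_matrix()
            emg_of = {mv: next((n for n in envs if mv in n.lower()), None)
                      for mv in ("hand", "tongue", "foot")}
            sets = {"rma": groups["rma"]}
            for mv in ("hand", "tongue", "foot"):
                sets[mv] = [c for c in groups["somatotopic"]
                            if pmat.loc[c, mv] == pmat.loc[c].min()]
            # matched pairs: somatotopic channel vs its own effector's EMG,
            # shared-representation channels vs each effector
            lat_pairs = [(c, emg_of[mv]) for mv in ("hand", "tongue", "foot")
                         for c in sets[mv] if emg_of[mv]]
            lat_pairs += [(c, e) for c in groups["rma"]
                          for e in emg_of.values() if e]
            moves = ev.movement_epochs()
            windows_by_emg = {
                emg_of[mv]: [(r["onset"], r["onset"] + r["duration"])
                             for _, r in moves[moves["trial_type"] == mv].iterrows()]
                for mv in ("hand", "tongue", "foot") if emg_of[mv]}
            lat = dynamics.latency_table(tc, envs, pairs=lat_pairs,
                                         windows_by_emg=windows_by_emg)
            lat.to_csv(out / "latencies.tsv", sep="\t", index=False)
            ela = dynamics.event_locked_average(tc, ev, sets)
            ela.to_csv(out / "event_locked.tsv", sep="\t", index=False)
            done(latencies=out / "latencies.tsv", event_locked=out / "event_locked.tsv")

        done = stage("cluster")
        feats = clustering.build_feature_space(stats)
        sel = clustering.select_cluster_count(feats, alpha=config.alpha,
                                              k_max=config.k_max,
                                              restarts=config.restarts,
                                              seed=config.seed)
        names = clustering.label_clusters(sel)
        pd.DataFrame({"channel": feats.index,
                      "cluster": sel.labels,
                      "cluster_label": [names[c] for c in sel.labels]}) \
            .to_csv(out / "clusters.tsv", sep="\t", index=False)
        pd.DataFrame({"k": sel.k_values, "inertia": sel.inertia,
                      "penalty": sel.penalty, "votes": sel.k_histogram}) \
            .to_csv(out / "penalty_curve.tsv", sep="\t", index=False)
        manifest["counts"]["selected_k"] = sel.selected_k
        done(clusters=out / "clusters.tsv", penalty_curve=out / "penalty_curve.tsv")

        done = stage("decode")
        results = decoding.decode_groups(stats, folds=config.folds, seed=config.seed)
        rows = [{"channel_group": g, "n_channels": len(r.channels),
                 "accuracy_all_trials": r.accuracy_all_trials,
                 "accuracy_movement_trials": r.accuracy_movement_trials}
                for g, r in results.items()]
        pd.DataFrame(rows).to_csv(out / "decoding.tsv", sep="\t", index=False)
        done(decoding=out / "decoding.tsv")

        if config.figures:
            done = stage("figures")
            _qc_figures(out, psds, smap, sel, lat)
            done()
    except Exception as exc:  # tag the failing stage for the caller
        stage_name = next(reversed(manifest["stages"]), "input")
        raise RuntimeError(f"pipeline failed after stage {stage_name!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest


def _qc_figures(out: Path, psds, smap, sel, lat) -> None:
    """PSD pair, map scatter, penalty curve and latency histogram PNGs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    ax = axes[0, 0]
    info = psds.trial_info
    move = psds.psd[(info["trial_type"] != "rest").to_numpy()].mean(axis=(0, 1))
    rest = psds.psd[(info["trial_type"] == "rest").to_numpy()].mean(axis=(0, 1))
    ax.loglog(psds.freqs, move, label="move")
    ax.loglog(psds.freqs, rest, label="rest")
    ax.axvspan(65, 115, alpha=0.2, color="gray")
    ax.set(xlabel="frequency (Hz)", ylabel="normalized power", title="mean trial PSD")
    ax.legend()

    ax = axes[0, 1]
    sc = ax.scatter(smap.table["magnitude"], smap.table["overlap"],
                    c=smap.table["angle_rad"], cmap="hsv", s=12)
    fig.colorbar(sc, ax=ax, label="tuning angle (rad)")
    ax.set(xlabel="somatotopy magnitude", ylabel="overlap", title="map summary")

    ax = axes[1, 0]
    ax.plot(sel.k_values, sel.penalty, "o-")
    ax.axvline(sel.selected_k, color="r", ls="--")
    ax.set(xlabel="k", ylabel=f"N^{sel.alpha} * sum D^2", title="penalty curve")

    ax = axes[1, 1]
    if lat is not None and len(lat):
        ax.hist(lat["peak_lag_ms"], bins=30)
        ax.axvline(0, color="k")
        ax.set(xlabel="brain-EMG lag (ms)", ylabel="count", title="latency histogram")
    fig.tight_layout()
    fig.savefig(out / "qc.png", dpi=110)
    plt.close(fig)
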