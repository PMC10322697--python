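"""Movement decoding from trial broadband power with LDA.

Compares how well shared-representation (RMA) channels and somatotopic
channels distinguish hand / tongue / foot / rest trials. Channel groups
come from the move-vs-rest t-tests: RMA channels have p < 0.05 for every
movement independently; somatotopic channels have p < 0.05/3 (Bonferroni
over the three movements) for exactly one movement. Channels significant
for two movements, or none, are excluded.

Classification is linear discriminant analysis (pooled covariance) with
stratified threefold cross-validation, trained on all movement and rest
trials. Class priors are set uniform (1/4 each) so that accuracy has a
0.25 chance level despite there being more rest trials than trials of
any single movement. Accuracy is reported both over all trials and over
movement trials only — the latter scored from the same fitted four-class
models, never retrained on three classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .io import MOVEMENTS
from .spectral import ChannelStats

log = logging.getLogger(__name__)

RMA_ALPHA = 0.05
SOMATOTOPIC_ALPHA = 0.05 / 3  # 0.01666..., Bonferroni over three movements
CLASSES = ("hand", "tongue", "foot", "rest")


def select_channels(stats: ChannelStats, rma_alpha: float = RMA_ALPHA,
                    somatotopic_alpha: float = SOMATOTOPIC_ALPHA) -> dict[str, list[str]]:
    """Partition channels into decoding groups by per-movement p-values."""
    p = stats.p_matrix()
    groups: dict[str, list[str]] = {"rma": [], "somatotopic": []}
    for ch, row in p.iterrows():
        pv = row.to_numpy(dtype=float)
        if np.isnan(pv).any():
            continue
        if np.all(pv < rma_alpha):
            groups["rma"].append(ch)
        elif int((pv < somatotopic_alpha).sum()) == 1:
            groups["somatotopic"].append(ch)
    return groups


@dataclass
class DecodingResult:
    channel_group: str
    channels: list[str]
    accuracy_all_trials: float
    accuracy_movement_trials: float
    confusion: pd.DataFrame          # rows true, columns predicted
    fold_assignment: np.ndarray      # fold index per trial
    used_shrinkage: bool = False


def _trial_features(stats: ChannelStats, channels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial broadband power features (trials x channels) and labels."""
    cols = [stats.channel_names.index(c) for c in channels]
    X = stats.bb[:, cols]
    y = np.where(stats.trial_info["trial_type"] == "rest", "rest",
                 stats.trial_info["trial_type"]).astype(object)
    return X, np.asarray(y, dtype=object)


def decode(stats: ChannelStats, channels: list[str], group_name: str = "",
           folds: int = 3, seed: int = 0,
           y: np.ndarray | None = None) -> DecodingResult:
    """Stratified k-fold LDA over all movement and rest trials.

    ``y`` overrides the trial labels (used for label-shuffle nulls). A
    singular pooled covariance triggers a Ledoit-Wolf shrinkage refit
    (logged).
    """
    if not channels:
        raise ValueError(f"empty channel group {group_name!r}; decoding skipped")
    X, y_true = _trial_features(stats, channels)
    if y is None:
        y = y_true
    classes = np.array(CLASSES, dtype=object)
    priors = np.full(len(classes), 1.0 / len(classes))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    fold_of = np.empty(len(y), dtype=int)
    used_shrinkage = False
    for fi, (tr, te) in enumerate(skf.split(X, y)):
        lda = LinearDiscriminantAnalysis(solver="lsqr", priors=priors)
        try:
            lda.fit(X[tr], y[tr])
        except np.linalg.LinAlgError:
            log.warning("singular pooled covariance in fold %d; refitting with shrinkage", fi)
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto", priors=priors)
            lda.fit(X[tr], y[tr])
            used_shrinkage = True
        pred[te] = lda.predict(X[te])
        fold_of[te] = fi
    move_mask = y != "rest"
    acc_all = float(np.mean(pred == y))
    acc_move = float(np.mean(pred[move_mask] == y[move_mask]))
    conf = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for yt, yp in zip(y, pred):
        conf.loc[yt, yp] += 1
    return DecodingResult(channel_group=group_name, channels=list(channels),
                          accuracy_all_trials=acc_all,
                          accuracy_movement_trials=acc_move,
                          confusion=conf, fold_assignment=fold_of,
                          used_shrinkage=used_shrinkage)


def decode_groups(stats: ChannelStats, folds: int = 3, seed: int = 0) -> dict[str, DecodingResult]:
    """Decode with both channel groups; empty groups are reported and skipped."""
    groups = select_channels(stats)
    out = {}
    for name, chans in groups.items():
        if not chans:
            log.warning("channel group %r is empty; skipping decoding", name)
            continue
        out[name] = decode(stats, chans, group_name=name, folds=folds, seed=seed)
    return out
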