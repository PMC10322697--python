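"""Naive parcellation of channels by k-means in signed-r2 space.

Channels live in a 3D feature space of signed r2 values — foot, hand and
tongue on the x, y and z axes. Lloyd's k-means (k-means++ seeding) is
refit over many random restarts for every k in 1..k_max, and each
restart selects the k minimizing the penalty ``N**alpha * sum_k D_k^2``
(N = cluster count, D_k = distance of each channel to its assigned
centroid). The exponent trades parcel count against error: at alpha = 1
the error sum shrinks faster than N grows, so ever-larger k is favored
and no global minimum emerges, while large alpha (say 2 and beyond)
collapses toward very few parcels; the middle-ground exponent 3/2 turns
the curve at the natural group count and is the default here. The
selected k is the mode over restarts, and the final labeling is the
minimum-error restart at that k.

Also provides convex-hull depth: the distance from each recording site
to the nearest point on the hull of the cortical surface, used to show
that shared-representation sites sit deeper than somatotopic ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.spatial import ConvexHull

from .spectral import ChannelStats

log = logging.getLogger(__name__)

FEATURE_AXES = ("foot", "hand", "tongue")  # x, y, z


def build_feature_space(stats: ChannelStats) -> pd.DataFrame:
    """Channels x (foot, hand, tongue) signed r2 matrix.

    Negative r2 values are kept signed here (unlike the somatotopy maps,
    which clip them). Channels missing any movement are excluded with a
    warning.
    """
    r2 = stats.r2_matrix(movements=FEATURE_AXES)
    bad = r2.isna().any(axis=1)
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} channel(s) with missing r2")
    return r2[~bad]


@dataclass
class ClusterSelection:
    """Result of penalty-based k selection over k-means restarts."""

    features: pd.DataFrame
    alpha: float
    k_values: np.ndarray
    inertia: np.ndarray        # best-of-restarts sum D^2 per k
    penalty: np.ndarray        # N**alpha * best inertia per k
    k_histogram: np.ndarray    # times each k was selected over restarts
    selected_k: int
    labels: np.ndarray         # labels of the min-error restart at selected_k
    centroids: np.ndarray


def select_cluster_count(features: pd.DataFrame | np.ndarray, alpha: float = 1.5,
                         k_max: int = 20, restarts: int = 1000,
                         seed: int | np.random.Generator = 0,
                         iters: int = 100) -> ClusterSelection:
    """Repeat k-means over k = 1..k_max, pick argmin of N**alpha * sum D^2
    per restart; selected k is the mode over restarts (ties -> smaller k)."""
    feats = features if isinstance(features, pd.DataFrame) else pd.DataFrame(np.asarray(features))
    X = feats.to_numpy(dtype=float)
    n = len(X)
    if n < k_max:
        raise ValueError(f"need at least k_max={k_max} points, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k_values = np.arange(1, k_max + 1)
    if np.allclose(X, X[0]):  # degenerate: every channel identical
        return ClusterSelection(features=feats, alpha=alpha, k_values=k_values,
                                inertia=np.zeros(k_max), penalty=np.zeros(k_max),
                                k_histogram=np.r_[restarts, np.zeros(k_max - 1, int)],
                                selected_k=1, labels=np.zeros(n, int),
                                centroids=X[:1].copy())
    votes = np.zeros(k_max, dtype=int)
    best_inertia = np.full(k_max, np.inf)
    best_fit: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # kmeans2 warns on empty clusters at large k
        for _ in range(restarts):
            inertia_r = np.empty(k_max)
            for ki, k in enumerate(k_values):
                if k == 1:
                    cent = X.mean(axis=0, keepdims=True)
                    lab = np.zeros(n, int)
                else:
                    cent, lab = kmeans2(X, k, iter=iters, minit="++", seed=rng)
                inertia_r[ki] = float(((X - cent[lab]) ** 2).sum())
                if inertia_r[ki] < best_inertia[ki]:
                    best_inertia[ki] = inertia_r[ki]
                    best_fit[k] = (inertia_r[ki], lab.copy(), cent.copy())
            votes[int(np.argmin(k_values ** alpha * inertia_r))] += 1
    selected_k = int(k_values[np.argmax(votes)])  # argmax ties break to smaller k
    if np.any(np.diff(best_inertia) > 1e-9 * max(best_inertia[0], 1.0)):
        log.warning("best-of-restarts inertia not monotone in k; consider more restarts")
    _, labels, centroids = best_fit[selected_k]
    return ClusterSelection(features=feats, alpha=alpha, k_values=k_values,
                            inertia=best_inertia,
                            penalty=k_values ** alpha * best_inertia,
                            k_histogram=votes, selected_k=selected_k,
                            labels=labels, centroids=centroids)


def label_clusters(selection: ClusterSelection, active_threshold: float = 0.1,
                   dominance: float = 0.5) -> dict[int, str]:
    """Name clusters by centroid geometry.

    Near-origin centroids are "inactive"; a single dominant positive axis
    names the effector; balanced high values on all three axes are "rma";
    anything else is "unlabeled". Thresholds refer to broadband r2
    (positive = power increase).
    """
    out = {}
    for ci, cent in enumerate(selection.centroids):
        c = np.clip(np.asarray(cent, float), 0, None)
        mx = c.max()
        if mx < active_threshold:
            out[ci] = "inactive"
        elif c.min() > dominance * mx:
            out[ci] = "rma"
        elif np.sort(c)[-2] < dominance * mx:
            out[ci] = FEATURE_AXES[int(np.argmax(c))]
        else:
            out[ci] = "unlabeled"
    return out


def depth_from_hull(points: np.ndarray, hull_points: np.ndarray) -> np.ndarray:
    """Distance (mm) from each point to the nearest point on the convex
    hull surface of ``hull_points``."""
    hull = ConvexHull(np.asarray(hull_points, float))
    pts = np.atleast_2d(np.asarray(points, float))
    verts = hull.points
    tri = verts[hull.simplices]  # facets x 3 x 3
    d = np.empty(len(pts))
    for i, p in enumerate(pts):
        d[i] = min(_point_triangle_distance(p, t) for t in tri)
    return d


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> float:
    """Euclidean distance from point ``p`` to triangle ``tri`` (3 x 3)."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return float(np.linalg.norm(ap))
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return float(np.linalg.norm(bp))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return float(np.linalg.norm(cp))
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        v = d1 / (d1 - d3)
        return float(np.linalg.norm(p - (a + v * ab)))
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        w = d2 / (d2 - d6)
        return float(np.linalg.norm(p - (a + w * ac)))
    va = d3 * d6 - d5 * d4
    if va <= 0 and d4 - d3 >= 0 and d5 - d6 >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return float(np.linalg.norm(p - (b + w * (c - b))))
    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    return float(np.linalg.norm(p - (a + v * ab + w * ac)))
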