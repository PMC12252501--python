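"""Ripening-pattern classification of Py time series.

Pipeline: per-sample Min-Max normalisation of the Py series, first-order
differencing (so only the *shape* of the trajectory matters, not its level
or span), a pairwise distance matrix — Dynamic Time Warping by default, so
fruit that ripen on shifted schedules still compare — then a 2-D principal
component embedding of the distance-matrix rows and a Gaussian Mixture
Model with k = 3 components.  The clusters map onto the three ripening
archetypes: C the large homogeneous majority, A the flat-Py minority, B the
small fast-ripening group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray
    embedding: np.ndarray
    distance_matrix: np.ndarray
    k: int
    seed: int
    type_map: dict[int, str] | None = None


def preprocess_series(py_matrix: np.ndarray) -> np.ndarray:
    """Min-Max normalise each row, then take first differences.

    Output has one column fewer than the input.  A constant row (max = min)
    maps to all-zero differences by convention.  Affine-invariant: a·x + b
    (a > 0) preprocesses identically to x.
    """
    m = np.asarray(py_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 3:
        raise ValueError("need a samples x days matrix with at least 3 days")
    lo = m.min(axis=1, keepdims=True)
    span = m.max(axis=1, keepdims=True) - lo
    scaled = np.where(span > 0, (m - lo) / np.where(span > 0, span, 1.0), 0.0)
    return np.diff(scaled, axis=1)


def dtw_distance(s1: Sequence[float], s2: Sequence[float],
                 window: int | None = None) -> float:
    """Dynamic Time Warping distance with squared local cost.

    Classic O(nm) dynamic programme; ``window`` adds a Sakoe–Chiba band.
    Symmetric and non-negative, but not a metric (no triangle inequality).
    """
    a = np.asarray(s1, dtype=float)
    b = np.asarray(s2, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("series must be non-empty")
    w = max(window, abs(n - m)) if window is not None else max(n, m)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        j_lo = max(1, i - w)
        j_hi = min(m, i + w)
        for j in range(j_lo, j_hi + 1):
            cost = (a[i - 1] - b[j - 1]) ** 2
            acc[i, j] = cost + min(acc[i - 1, j], acc[i, j - 1],
                                   acc[i - 1, j - 1])
    return float(acc[n, m])


def _dtw_path(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    n, m = len(a), len(b)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = (a[i - 1] - b[j - 1]) ** 2
            acc[i, j] = cost + min(acc[i - 1, j], acc[i, j - 1],
                                   acc[i - 1, j - 1])
    path = [(n - 1, m - 1)]
    i, j = n, m
    while (i, j) != (1, 1):
        moves = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
        i, j = min((p for p in moves if p[0] >= 1 and p[1] >= 1),
                   key=lambda p: acc[p])
        path.append((i - 1, j - 1))
    return path[::-1]


def distance_matrix(series: np.ndarray, mode: str = "dtw",
                    window: int | None = None) -> np.ndarray:
    """Pairwise distances between preprocessed series.

    ``dtw`` is the accumulated squared-difference DTW cost;
    ``euclidean_after_dtw_alignment`` expands each pair along its optimal
    warping path and takes the Euclidean norm of the aligned difference.
    """
    s = np.asarray(series, dtype=float)
    n = len(s)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if mode == "dtw":
                d[i, j] = dtw_distance(s[i], s[j], window)
            elif mode == "euclidean_after_dtw_alignment":
                path = _dtw_path(s[i], s[j])
                diff = np.array([s[i][p] - s[j][q] for p, q in path])
                d[i, j] = float(np.linalg.norm(diff))
            else:
                raise ValueError(f"unknown distance mode {mode!r}")
            d[j, i] = d[i, j]
    return d


def embed_and_cluster(
    series: np.ndarray,
    k: int = 3,
    n_components: int = 2,
    seed: int = 0,
    distance_mode: str = "dtw",
    window: int | None = None,
) -> ClusterResult:
    """Distance matrix → PCA embedding of its rows → k-component GMM.

    The principal-component reduction operates on the rows of the pairwise
    distance matrix (a pragmatic embedding, not classical MDS); the mixture
    uses full covariances and 10 initialisations, deterministic under
    ``seed``.
    """
    s = np.asarray(series, dtype=float)
    if k < 1:
        raise ValueError("k must be at least 1")
    if len(s) < k:
        raise ValueError(f"need at least k={k} samples, got {len(s)}")
    d = distance_matrix(s, distance_mode, window)
    n_comp = min(n_components, len(s))
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(d)
    gmm = GaussianMixture(n_components=k, covariance_type="full",
                          n_init=10, random_state=seed)
    labels = gmm.fit_predict(emb)
    return ClusterResult(labels=labels, embedding=emb, distance_matrix=d,
                         k=k, seed=seed)


def assign_type_labels(result: ClusterResult,
                       py_matrix: np.ndarray) -> dict[int, str]:
    """Map the three clusters onto ripening archetypes.

    C is the largest cluster (the homogeneous majority); of the remaining
    two, A is the one whose members change least in Py overall (the
    stable-dispersion fruit) and B the other (fast ripeners).  Size ties
    break toward the cluster with the smaller mean within-cluster distance
    (the tighter cluster is the C-like one).
    """
    if result.k != 3:
        raise ValueError("type assignment is defined for k = 3 clusters")
    py = np.asarray(py_matrix, dtype=float)
    labels = result.labels
    clusters = sorted(set(labels.tolist()))

    def tightness(c: int) -> float:
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            return np.inf
        sub = result.distance_matrix[np.ix_(idx, idx)]
        return float(sub[np.triu_indices(len(idx), 1)].mean())

    ordered = sorted(clusters,
                     key=lambda c: (-int(np.sum(labels == c)), tightness(c)))
    c_cluster = ordered[0]
    rest = ordered[1:]

    def mean_abs_change(c: int) -> float:
        idx = np.flatnonzero(labels == c)
        return float(np.mean(np.abs(py[idx, -1] - py[idx, 0])))

    rest = sorted(rest, key=mean_abs_change)
    return {c_cluster: "C", rest[0]: "A", rest[1]: "B"}


def label_agreement(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Best-permutation label agreement (fraction of samples matching).

    Label-agnostic: evaluates every bijection between the two label sets and
    returns the highest achievable accuracy.
    """
    from itertools import permutations

    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label arrays must have equal length")
    vals_a = sorted(set(a.tolist()))
    vals_b = sorted(set(b.tolist()))
    k = max(len(vals_a), len(vals_b))
    if k > 6:
        raise ValueError("too many labels for exhaustive permutation matching")
    best = 0.0
    for perm in permutations(range(k)):
        mapping = {va: perm[i] for i, va in enumerate(vals_a)}
        remapped = np.array([mapping[x] for x in a])
        idx = {vb: i for i, vb in enumerate(vals_b)}
        acc = float(np.mean(remapped == np.array([idx[x] for x in b])))
        best = max(best, acc)
    return best
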