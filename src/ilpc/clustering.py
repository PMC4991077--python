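"""Ward/Euclidean hierarchical clustering of the PCA scores.

Clustering runs in the retained-score space (two dimensions by default),
where the reference set separates into six clusters labelled A–F.  The
linkage is Ward's minimum-variance method on Euclidean distances, computed
by the Lance–Williams recurrence with an explicit deterministic tie-break:
among equally cheap merges, the pair whose (smaller, larger) original merge
labels sort first is chosen.  Merge heights follow the common convention
height = sqrt(2 x increase in within-cluster sum of squares), which reduces
to the plain Euclidean distance for two singletons.

Letters are assigned geometrically, matching the verbal cluster anatomy of
the reference map: the half of the centroids with the smaller PC1 values
(small ions) takes A, B, C in ascending PC2 (halides low, fluorinated
anions mid, TFSI-like high); the large-PC1 half takes F for its lowest-PC2
centroid (large cations with halides) and D, E ascending above it.  A rank
split (k//2 lowest PC1 centroids) rather than a sign split keeps the rule
stable when a small-cation cluster drifts just across zero.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster


@dataclass(frozen=True)
class ClusterModel:
    linkage: np.ndarray        # (n-1, 4) scipy-format merge records
    k: int
    labels: tuple[str, ...]    # per training IL, in row order
    centroids: np.ndarray      # (k, n_components), rows ordered A, B, ...
    centroid_labels: tuple[str, ...]


def ward_linkage(scores: np.ndarray, ids: tuple[str, ...] | None = None) -> np.ndarray:
    """Ward minimum-variance agglomeration, scipy-compatible linkage matrix.

    Implements the Lance–Williams distance update
    d(k, i∪j)² = [(n_i+n_k) d(k,i)² + (n_j+n_k) d(k,j)² − n_k d(i,j)²] / (n_i+n_j+n_k)
    with the deterministic tie-break documented in the module docstring.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("ward_linkage needs at least 2 points")
    if ids is not None and len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if list(ids).count(i) > 1})
        raise ValueError(f"duplicate il_id(s): {dup}")

    # squared-distance matrix among active clusters, keyed by merge label
    active: dict[int, int] = {i: 1 for i in range(n)}   # label -> size
    d2: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((X[i] - X[j]) ** 2))

    def dist2(a: int, b: int) -> float:
        return d2[(a, b) if a < b else (b, a)]

    Z = np.zeros((n - 1, 4))
    next_label = n
    for step in range(n - 1):
        labels = sorted(active)
        best = None
        for ai, a in enumerate(labels):
            for b in labels[ai + 1:]:
                cand = (dist2(a, b), a, b)
                if best is None or cand < best:
                    best = cand
        d2_ab, a, b = best
        na, nb = active[a], active[b]
        Z[step] = (a, b, np.sqrt(max(d2_ab, 0.0)), na + nb)
        for c in labels:
            if c in (a, b):
                continue
            nc = active[c]
            new = ((na + nc) * dist2(a, c) + (nb + nc) * dist2(b, c)
                   - nc * d2_ab) / (na + nb + nc)
            d2[(c, next_label) if c < next_label else (next_label, c)] = new
        for c in (a, b):
            del active[c]
            for key in [k for k in d2 if c in k]:
                del d2[key]
        active[next_label] = na + nb
        next_label += 1
    return Z


def _letters(k: int) -> list[str]:
    return list(string.ascii_uppercase[:k])


def _assign_letters(centroids: np.ndarray) -> list[str]:
    """Geometric letter assignment (see module docstring)."""
    k = centroids.shape[0]
    letters = _letters(k)
    pc1 = centroids[:, 0]
    pc2 = centroids[:, 1] if centroids.shape[1] > 1 else np.zeros(k)
    by_pc1 = sorted(range(k), key=lambda i: (pc1[i], pc2[i]))
    low = sorted(by_pc1[: k // 2], key=lambda i: pc2[i])
    high = sorted(by_pc1[k // 2:], key=lambda i: pc2[i])
    out = [""] * k
    for idx, lab in zip(low, letters[:len(low)]):
        out[idx] = lab
    remaining = letters[len(low):]
    if high:
        # lowest-PC2 centroid on the large-ion side takes the last letter
        out[high[0]] = remaining[-1]
        for idx, lab in zip(high[1:], remaining[:-1]):
            out[idx] = lab
    return out


def cut_and_label(linkage: np.ndarray, scores: np.ndarray, k: int = 6) -> ClusterModel:
    """Cut the dendrogram at k clusters and assign geometric letters."""
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} points")
    flat = fcluster(linkage, t=k, criterion="maxclust")
    cluster_ids = sorted(set(flat))
    centroids = np.vstack([X[flat == c].mean(axis=0) for c in cluster_ids])
    letters = _assign_letters(centroids)
    order = np.argsort(letters)
    centroid_labels = tuple(letters[i] for i in order)
    label_of = {cluster_ids[i]: letters[i] for i in range(len(cluster_ids))}
    return ClusterModel(
        linkage=linkage, k=k,
        labels=tuple(label_of[c] for c in flat),
        centroids=centroids[order],
        centroid_labels=centroid_labels,
    )


def assign_cluster(model: ClusterModel, score: np.ndarray
                   ) -> tuple[str, dict[str, float], bool]:
    """Label of the Euclidean-nearest centroid.

    Returns (label, per-label distance report, tie flag).  Exact ties go to
    the alphabetically first label and are flagged.
    """
    score = np.asarray(score, dtype=float)
    dists = {lab: float(np.linalg.norm(score - c))
             for lab, c in zip(model.centroid_labels, model.centroids)}
    best = min(dists.values())
    winners = sorted(lab for lab, d in dists.items() if d == best)
    return winners[0], dists, len(winners) > 1
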