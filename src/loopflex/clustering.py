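"""Conformational clustering of loop ensembles.

Two clustering modes mirror the two stages of the protocol:

* average-linkage hierarchical clustering on the pairwise Ca-RMSD matrix
  with a distance cutoff, used to pick seeding structures from a biased
  exploration ensemble (medoid representatives, so every representative
  is a real frame), and
* k-means in a projected (tICA) space to define the microstates of a
  Markov-state model.

RMSD is the minimum over proper rotations and translations (Kabsch
superposition with reflection correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans

from .errors import ValidationError
from .structure_io import CoordinateTrajectory

__all__ = ["ClusterModel", "kabsch_rmsd", "pairwise_rmsd_matrix",
           "average_linkage_cluster", "kmeans_cluster",
           "write_cluster_table", "write_matrix"]


@dataclass
class ClusterModel:
    """Cluster assignment of trajectory frames."""

    method: str                       # "hierarchical-average" | "kmeans"
    labels: np.ndarray                # per-frame cluster index, 0-based
    representatives: np.ndarray       # frame index per cluster (medoid)
    parameter: float                  # cutoff (A) or k
    metric: str = ""
    centers: Optional[np.ndarray] = None   # k-means centers, if applicable

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.representatives = np.asarray(self.representatives,
                                          dtype=np.int64)
        k = self.n_clusters
        if k != self.representatives.size:
            raise ValidationError("one representative per cluster required")
        counts = np.bincount(self.labels, minlength=k)
        if np.any(counts == 0):
            raise ValidationError("empty cluster in model")
        for c, rep in enumerate(self.representatives):
            if self.labels[rep] != c:
                raise ValidationError(
                    f"representative {rep} not member of cluster {c}")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def kabsch_rmsd(A, B) -> float:
    """Minimum RMSD between two point sets over rotations + translations.

    Proper rotations only (reflections corrected), so chirality is
    respected. Symmetric in its arguments and zero iff the sets differ by
    a rigid motion.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValidationError("point sets must share shape (n, 3)")
    if A.shape[0] < 3:
        raise ValidationError("need at least 3 points")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    with warnings.catch_warnings():
        # degenerate sets (rank-deficient) legitimately have non-unique
        # optimal rotations; the RMSD value is still well defined
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(Ac, Bc)
    # explicit residual: the reported rssd loses precision near zero
    return float(np.sqrt(np.mean(np.sum((Ac - rot.apply(Bc)) ** 2, axis=1))))


def pairwise_rmsd_matrix(traj: CoordinateTrajectory,
                         stride: int = 1) -> np.ndarray:
    """Symmetric matrix of Kabsch RMSDs between (strided) frames."""
    frames = traj.coords[::stride]
    n = frames.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 frames")
    centered = frames - frames.mean(axis=1, keepdims=True)
    D = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for i in range(n):
            for j in range(i + 1, n):
                rot, _ = Rotation.align_vectors(centered[i], centered[j])
                resid = centered[i] - rot.apply(centered[j])
                D[i, j] = D[j, i] = np.sqrt(
                    np.mean(np.sum(resid ** 2, axis=1)))
    return D


def _medoids(D: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    reps = np.empty(k, dtype=np.int64)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        sub = D[np.ix_(members, members)]
        reps[c] = members[int(np.argmin(sub.mean(axis=1)))]
    return reps


def average_linkage_cluster(D: np.ndarray, cutoff: float) -> ClusterModel:
    """Agglomerative average-linkage clustering with a distance cutoff.

    Merging stops when the smallest inter-cluster average distance exceeds
    ``cutoff``; cluster labels are renumbered by first frame appearance and
    each cluster is represented by its medoid (member minimizing the mean
    distance to the other members — ties to the lowest frame index).
    """
    D = np.asarray(D, float)
    if D.size == 0:
        raise ValidationError("empty distance matrix")
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not cutoff > 0:
        raise ValidationError("cutoff must be > 0")
    n = D.shape[0]
    if n == 1:
        return ClusterModel("hierarchical-average", np.zeros(1, np.int64),
                            np.zeros(1, np.int64), cutoff, "kabsch-rmsd")
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=cutoff, criterion="distance")
    # renumber by order of first appearance for determinism
    order = {}
    labels = np.empty(n, dtype=np.int64)
    for i, r in enumerate(raw):
        if r not in order:
            order[r] = len(order)
        labels[i] = order[r]
    k = len(order)
    return ClusterModel("hierarchical-average", labels, _medoids(D, labels, k),
                        cutoff, "kabsch-rmsd")


def kmeans_cluster(points: np.ndarray, k: int, seed: int = 0) -> ClusterModel:
    """k-means microstate clustering (k-means++ init, fixed seed)."""
    points = np.atleast_2d(np.asarray(points, float))
    n = points.shape[0]
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds number of frames {n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=500,
                random_state=int(seed) % (2 ** 31))
    labels = km.fit_predict(points).astype(np.int64)
    # relabel by first appearance, carry centers along
    order = {}
    new_labels = np.empty(n, dtype=np.int64)
    for i, r in enumerate(labels):
        if r not in order:
            order[r] = len(order)
        new_labels[i] = order[r]
    centers = np.empty_like(km.cluster_centers_)
    for old, new in order.items():
        centers[new] = km.cluster_centers_[old]
    reps = np.empty(k, dtype=np.int64)
    for c in range(k):
        members = np.flatnonzero(new_labels == c)
        d = np.linalg.norm(points[members] - centers[c], axis=1)
        reps[c] = members[int(np.argmin(d))]
    return ClusterModel("kmeans", new_labels, reps, float(k), "euclidean",
                        centers=centers)


def write_cluster_table(model: ClusterModel, path) -> None:
    """Delimited table: frame, cluster, is_representative."""
    rep_set = set(int(r) for r in model.representatives)
    with open(path, "w") as fh:
        fh.write("frame\tcluster\tis_representative\n")
        for f, c in enumerate(model.labels):
            fh.write(f"{f}\t{int(c)}\t{int(f in rep_set)}\n")


def write_matrix(M: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(M, float), fmt="%.17g")
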