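"""Ensemble processing: replica combination, RMSD clustering, and
population-based success classification.

The analysis convention follows standard practice for restrained
replica-exchange fibril determination: frames from the lowest-temperature
replicas are pooled after discarding an initial equilibration fraction,
pairwise CA RMSD (whole aggregate, single superposition) defines the
distance matrix, and average-linkage agglomerative clustering with a 2 A
threshold partitions the ensemble.  The population of the top cluster is
the confidence signal: above 40% the centroid is usually the correct
structure, below 20% the prediction is usually unsuccessful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .sampler import TrajectorySet

__all__ = [
    "ClusterSet",
    "Outcome",
    "combine_replicas",
    "rmsd_matrix",
    "average_linkage_cluster",
    "classify_outcome",
    "DEFAULT_EPSILON",
    "SUCCESS_RMSD_CUTOFF",
    "CONFIDENT_POPULATION",
    "FAILURE_POPULATION",
]

DEFAULT_EPSILON = 2.0          # A, average-linkage merge threshold
SUCCESS_RMSD_CUTOFF = 5.0      # A, centroid-to-reference success cutoff
CONFIDENT_POPULATION = 0.40    # top-cluster population for confidence
FAILURE_POPULATION = 0.20      # below this the prediction is suspect
DEFAULT_N_LOWEST = 5
DEFAULT_DISCARD = 0.25


@dataclass
class ClusterSet:
    """Flat clustering of an ensemble; clusters are labelled 0, 1, 2, ...
    in order of decreasing population."""

    labels: np.ndarray          # per-frame cluster id
    populations: np.ndarray     # fraction per cluster, descending
    centroid_frames: np.ndarray  # frame index of each cluster's medoid
    epsilon: float

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def members(self, cluster: int) -> np.ndarray:
        return np.where(self.labels == cluster)[0]

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "clusters": [
                {"id": i, "population": float(p),
                 "centroid_frame": int(c)}
                for i, (p, c) in enumerate(zip(self.populations,
                                               self.centroid_frames))
            ],
        }


class Outcome(NamedTuple):
    verdict: str    # confident_success | ambiguous | likely_failure
    rationale: str


def combine_replicas(traj: TrajectorySet, n_lowest: int = DEFAULT_N_LOWEST,
                     discard_fraction: float = DEFAULT_DISCARD
                     ) -> np.ndarray:
    """Pool frames from the lowest-temperature replicas, dropping each
    replica's first ``discard_fraction`` of frames as equilibration.

    Returns coordinates with shape (n_frames, n_atoms, 3), concatenated in
    replica order.
    """
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must lie in [0, 1)")
    if n_lowest > traj.n_replicas:
        raise ValueError(
            f"n_lowest={n_lowest} exceeds {traj.n_replicas} replicas")
    chunks = []
    for r in range(n_lowest):
        frames = traj.replica_frames(r)
        drop = int(discard_fraction * len(frames))
        chunks.append(frames[drop:])
    out = np.concatenate(chunks, axis=0)
    if len(out) == 0:
        raise ValueError("all frames discarded; nothing to analyse")
    return out


def rmsd_matrix(frames: np.ndarray,
                atom_indices: np.ndarray | None = None) -> np.ndarray:
    """Pairwise whole-aggregate RMSD (A) after optimal superposition.

    ``frames`` has shape (F, N, 3); ``atom_indices`` selects the atoms to
    score (e.g. CA rows), default all.  Uses a batched Kabsch solve: for
    each frame the 3x3 cross-covariances against all later frames are
    decomposed in one vectorised SVD call.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[-1] != 3:
        raise ValueError("frames must have shape (F, N, 3)")
    if atom_indices is not None:
        frames = frames[:, atom_indices, :]
    F, n, _ = frames.shape
    X = frames - frames.mean(axis=1, keepdims=True)
    ss = np.einsum("fij,fij->f", X, X)
    D = np.zeros((F, F))
    for i in range(F - 1):
        rest = X[i + 1:]
        H = np.einsum("nj,fnk->fjk", X[i], rest)
        U, S, Vt = np.linalg.svd(H)
        det = np.linalg.det(U) * np.linalg.det(Vt)
        S = S.copy()
        S[:, 2] *= np.sign(det)
        msd = (ss[i] + ss[i + 1:] - 2.0 * S.sum(axis=1)) / n
        D[i, i + 1:] = np.sqrt(np.maximum(msd, 0.0))
    D = D + D.T
    return D


def average_linkage_cluster(D: np.ndarray,
                            epsilon: float = DEFAULT_EPSILON) -> ClusterSet:
    """Average-linkage agglomerative clustering cut at ``epsilon``.

    Merging proceeds while the smallest average inter-cluster distance is
    <= epsilon and stops once it exceeds epsilon.  Clusters are ordered by
    population (ties: the cluster containing the lower frame index first);
    each cluster's representative is its medoid — the member minimising the
    summed RMSD to the other members.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square distance matrix")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("D must be symmetric")
    F = D.shape[0]
    if F == 1:
        raw = np.zeros(1, dtype=int)
    else:
        Z = linkage(squareform(D, checks=False), method="average")
        raw = fcluster(Z, t=epsilon, criterion="distance") - 1
    # order clusters by population, tie-break on lowest member frame index
    ids = np.unique(raw)
    stats = []
    for cid in ids:
        members = np.where(raw == cid)[0]
        stats.append((-len(members), members.min(), cid))
    stats.sort()
    relabel = {cid: rank for rank, (_, _, cid) in enumerate(stats)}
    labels = np.array([relabel[c] for c in raw])
    populations = np.array([-neg for neg, _, _ in stats], dtype=float) / F
    centroids = np.empty(len(ids), dtype=int)
    for rank, (_, _, cid) in enumerate(stats):
        members = np.where(raw == cid)[0]
        sub = D[np.ix_(members, members)]
        centroids[rank] = members[int(np.argmin(sub.sum(axis=1)))]
    return ClusterSet(labels, populations, centroids, epsilon)


def classify_outcome(cluster_set: ClusterSet,
                     rmsd_c0_to_ref: float | None = None) -> Outcome:
    """Population-based confidence call for a prediction.

    Top-cluster population above 40% signals a confident prediction (which
    additionally requires the centroid within 5.0 A of the reference when
    one is supplied); below 20% signals a likely failure; in between the
    outcome is ambiguous.
    """
    top = float(cluster_set.populations[0]) if cluster_set.n_clusters else 0.0
    if top > CONFIDENT_POPULATION:
        if rmsd_c0_to_ref is None:
            return Outcome(
                "confident_success",
                f"top cluster population {top:.2f} > "
                f"{CONFIDENT_POPULATION:.2f} (no reference supplied)")
        if rmsd_c0_to_ref <= SUCCESS_RMSD_CUTOFF:
            return Outcome(
                "confident_success",
                f"top cluster population {top:.2f} > "
                f"{CONFIDENT_POPULATION:.2f} and centroid RMSD "
                f"{rmsd_c0_to_ref:.2f} A <= {SUCCESS_RMSD_CUTOFF} A")
        return Outcome(
            "ambiguous",
            f"top cluster population {top:.2f} is high but centroid RMSD "
            f"{rmsd_c0_to_ref:.2f} A exceeds {SUCCESS_RMSD_CUTOFF} A")
    if top < FAILURE_POPULATION:
        return Outcome(
            "likely_failure",
            f"top cluster population {top:.2f} < "
            f"{FAILURE_POPULATION:.2f}: ensemble has not condensed")
    return Outcome(
        "ambiguous",
        f"top cluster population {top:.2f} lies between "
        f"{FAILURE_POPULATION:.2f} and {CONFIDENT_POPULATION:.2f}")
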