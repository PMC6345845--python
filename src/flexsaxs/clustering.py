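"""Quality-threshold clustering of conformations under a DRMS metric.

DRMS compares two conformations through internal bead-pair distances, so
it is invariant to global rotation and translation.  The default pair set
is all bead pairs whose members belong to different rigid bodies, which
groups structures by the relative placement of their rigid units rather
than by linker detail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .topology import ComplexTopology, Conformation


@dataclass
class ClusterSet:
    """Disjoint clusters ordered by descending size."""

    clusters: list[list[int]]
    cutoff: float
    metric: str = "drms"

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def membership(self) -> dict[int, int]:
        return {i: ci for ci, cluster in enumerate(self.clusters) for i in cluster}


def default_pair_set(topology: ComplexTopology, max_pairs: int = 5000,
                     seed: int = 0) -> np.ndarray:
    """Inter-body bead pairs (i, j), seeded-subsampled to max_pairs."""
    body = topology.body_of()
    on_body = np.where(body >= 0)[0]
    pairs = [(int(i), int(j))
             for a, i in enumerate(on_body) for j in on_body[a + 1:]
             if body[i] != body[j]]
    pairs = np.array(pairs, dtype=np.int64)
    if len(pairs) == 0:
        raise ValueError("topology has no inter-body bead pairs")
    if len(pairs) > max_pairs:
        rng = np.random.Generator(np.random.PCG64(seed))
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = pairs[np.sort(keep)]
    return pairs


def _coords_of(conf) -> np.ndarray:
    return conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)


def _pair_distances(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    diff = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    return np.sqrt(np.sum(diff**2, axis=1))


def drms(conf_a, conf_b, pair_set: np.ndarray) -> float:
    """Root-mean-square difference of bead-pair distances over pair_set (A)."""
    pair_set = np.asarray(pair_set, dtype=np.int64)
    if pair_set.size == 0:
        raise ValueError("empty pair set")
    d_a = _pair_distances(_coords_of(conf_a), pair_set)
    d_b = _pair_distances(_coords_of(conf_b), pair_set)
    return float(np.sqrt(np.mean((d_a - d_b) ** 2)))


def drms_matrix(conformations: Sequence, pair_set: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise DRMS values."""
    pair_set = np.asarray(pair_set, dtype=np.int64)
    if pair_set.size == 0:
        raise ValueError("empty pair set")
    dists = np.array([_pair_distances(_coords_of(c), pair_set)
                      for c in conformations])
    n = len(dists)
    out = np.zeros((n, n))
    for i in range(n):
        diff = dists[i + 1:] - dists[i]
        vals = np.sqrt(np.mean(diff**2, axis=1))
        out[i, i + 1:] = vals
        out[i + 1:, i] = vals
    return out


def qt_cluster(ids: Sequence[int], distance_matrix: np.ndarray,
               cutoff: float) -> ClusterSet:
    """Classic quality-threshold clustering.

    For every remaining point a candidate cluster is grown greedily: at
    each step add the point whose inclusion gives the smallest new
    diameter, as long as the diameter stays <= cutoff.  The largest
    candidate is committed, its members removed, and the procedure
    repeats.  Ties in diameter growth go to the lowest id; ties in
    candidate size to the lowest seed id.  Singletons are allowed.
    """
    ids = list(ids)
    mat = np.asarray(distance_matrix, dtype=float)
    if mat.shape != (len(ids), len(ids)):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(mat, mat.T, atol=1e-9) or np.any(np.diag(mat) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    order = np.argsort(ids, kind="stable")
    remaining = [int(k) for k in order]  # positions, scanned in id order
    clusters: list[list[int]] = []
    while remaining:
        best_candidate = None
        for seed_pos in remaining:
            members = [seed_pos]
            outside = [p for p in remaining if p != seed_pos]
            # max distance from each outside point to the current members
            far = {p: mat[p, seed_pos] for p in outside}
            diameter = 0.0
            while outside:
                grow = min(outside, key=lambda p: (far[p], ids[p]))
                new_diameter = max(diameter, far[grow])
                if new_diameter > cutoff:
                    break
                members.append(grow)
                outside.remove(grow)
                diameter = new_diameter
                for p in outside:
                    if mat[p, grow] > far[p]:
                        far[p] = mat[p, grow]
            if best_candidate is None or len(members) > len(best_candidate):
                best_candidate = members
        clusters.append(sorted(ids[p] for p in best_candidate))
        committed = set(best_candidate)
        remaining = [p for p in remaining if p not in committed]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return ClusterSet(clusters, cutoff)


def cluster_medoids(cluster_set: ClusterSet, ids: Sequence[int],
                    distance_matrix: np.ndarray) -> list[int]:
    """Medoid (minimum summed DRMS to members) of each cluster."""
    pos = {i: k for k, i in enumerate(ids)}
    medoids = []
    for cluster in cluster_set.clusters:
        rows = [pos[i] for i in cluster]
        sub = distance_matrix[np.ix_(rows, rows)]
        medoids.append(cluster[int(np.argmin(sub.sum(axis=1)))])
    return medoids
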