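"""RMSD-radius clustering of decoy pools with representative picking.

A deterministic leader-then-Lloyd scheme emulating the MMTSB kclust run
(rmsd mode, centroid distance, heavy atoms, least-squares fit, radius 1.0 A):
a first pass in lexicographic id order assigns each decoy to the first
centroid within the radius or seeds a new cluster; subsequent iterations
recompute each centroid as the mean of its members after fitting them onto
it, and reassign members to the nearest centroid (spawning a new cluster for
any member farther than the radius from all centroids, so the radius
invariant always holds at convergence).  Centroids are mathematical
constructs; the retained exemplar of each cluster is its lowest-RMSD member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pdbio import DecoyPool, Structure
from .superpose import kabsch, rmsd_to_many

__all__ = ["Cluster", "ClusterSet", "kclust", "representatives", "pool_coordinates"]


@dataclass
class Cluster:
    centroid_coords: np.ndarray
    member_ids: list[str]
    member_rmsd: dict[str, float]


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    radius: float
    atom_subset: str
    iterations_run: int

    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        out = {}
        for ci, c in enumerate(self.clusters):
            for m in c.member_ids:
                out[m] = ci
        return out


def pool_coordinates(pool: DecoyPool, atom_subset: str = "heavy") -> tuple[list[str], np.ndarray]:
    """Lexicographically ordered ids and a (K, N, 3) coordinate stack over the
    atom subset shared by every pool member."""
    ids = sorted(pool.ids())
    if atom_subset == "ca":
        mats = [pool.decoys[i].ca_coords() for i in ids]
    elif atom_subset == "heavy":
        # atoms common to all members, keyed by (residue index, atom name)
        common: set[tuple[int, str]] | None = None
        for sid in ids:
            keys = {(i, a.name) for i, a in pool.decoys[sid].heavy_atoms()}
            common = keys if common is None else common & keys
        if not common:
            raise ValueError("no heavy atoms shared across the pool")
        order = sorted(common)
        mats = []
        for sid in ids:
            s: Structure = pool.decoys[sid]
            lookup = {(i, a.name): a.coords for i, a in s.heavy_atoms()}
            mats.append(np.asarray([lookup[k] for k in order]))
    else:
        raise ValueError(f"unknown atom subset {atom_subset!r}")
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError("inconsistent atom sets across pool members")
    return ids, np.asarray(mats)


def kclust(
    pool: DecoyPool,
    radius: float = 1.0,
    atom_subset: str = "heavy",
    max_iter: int = 10,
) -> ClusterSet:
    """Partition a pool into clusters of superposed-RMSD radius ``radius``.

    Deterministic given the pool: members are processed in lexicographic id
    order, and at convergence every member lies within ``radius`` of its
    cluster centroid.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    ids, coords = pool_coordinates(pool, atom_subset)
    n = len(ids)

    # leader pass
    centroid_of: list[int] = []
    centroids: list[np.ndarray] = []
    for i in range(n):
        assigned = -1
        if centroids:
            d = rmsd_to_many(coords[i], np.asarray(centroids))
            hits = np.nonzero(d <= radius)[0]
            if hits.size:
                assigned = int(hits[0])
        if assigned < 0:
            centroids.append(coords[i])
            assigned = len(centroids) - 1
        centroid_of.append(assigned)

    iterations = 0
    for iterations in range(1, max_iter + 1):
        # centroid update: mean of members fitted onto the current centroid
        new_centroids = []
        for ci in range(len(centroids)):
            members = [i for i in range(n) if centroid_of[i] == ci]
            if not members:
                continue
            fitted = []
            for i in members:
                res = kabsch(centroids[ci], coords[i])
                fitted.append(res.transform.apply(coords[i]))
            new_centroids.append(np.mean(fitted, axis=0))
        centroids = new_centroids

        # reassignment: nearest centroid, or a fresh cluster beyond the radius
        new_assign: list[int] = []
        for i in range(n):
            d = rmsd_to_many(coords[i], np.asarray(centroids))
            best = int(np.argmin(d))
            if d[best] > radius:
                centroids.append(coords[i])
                best = len(centroids) - 1
            new_assign.append(best)
        # renumber clusters in order of first appearance, drop empties
        remap: dict[int, int] = {}
        for a in new_assign:
            if a not in remap:
                remap[a] = len(remap)
        new_assign = [remap[a] for a in new_assign]
        ordered = sorted(remap.items(), key=lambda t: t[1])
        centroids = [centroids[old] for old, _ in ordered]
        if new_assign == centroid_of:
            break
        centroid_of = new_assign

    clusters: list[Cluster] = []
    for ci in sorted(set(centroid_of)):
        members = [i for i in range(n) if centroid_of[i] == ci]
        member_ids = [ids[i] for i in members]
        d = rmsd_to_many(centroids[ci], coords[members]) if len(members) else np.array([])
        clusters.append(
            Cluster(
                centroid_coords=centroids[ci],
                member_ids=member_ids,
                member_rmsd={ids[i]: float(di) for i, di in zip(members, d)},
            )
        )
    return ClusterSet(
        clusters=clusters, radius=radius, atom_subset=atom_subset, iterations_run=iterations
    )


def representatives(cluster_set: ClusterSet, pool: DecoyPool) -> DecoyPool:
    """One exemplar per cluster: the member of lowest RMSD to its centroid,
    ties resolved by input (lexicographic id) order."""
    rep_ids = []
    for c in cluster_set.clusters:
        rep = min(c.member_ids, key=lambda m: c.member_rmsd[m])
        rep_ids.append(rep)
    return pool.subset(rep_ids)
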