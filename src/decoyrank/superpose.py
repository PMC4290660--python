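"""Optimal rigid-body superposition (Kabsch) and RMSD over atom subsets.

The Kabsch solution is computed by SVD of the cross-covariance matrix with a
determinant sign correction so that only proper rotations (no reflections)
are considered.  ``rmsd_to_many`` evaluates one coordinate set against a
stack of references with a single batched SVD — the hot path of RMSD-radius
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pdbio import Structure

__all__ = ["RigidTransform", "SuperposeResult", "kabsch", "superposed_rmsd", "rmsd", "rmsd_to_many"]

_DEGENERACY_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, rotation proper (det = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class SuperposeResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or b.ndim != 2 or b.shape[1] != 3:
        raise ValueError("coordinate arrays must be N x 3")
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"point count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 3:
        raise ValueError("at least 3 points are required for a unique rotation")
    return a, b


def _collinear(x: np.ndarray) -> bool:
    c = x - x.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return bool(s[1] <= _DEGENERACY_TOL * max(s[0], 1.0))


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperposeResult:
    """Least-squares superposition of ``coords_b`` onto ``coords_a``.

    Returns the proper rigid transform minimizing the RMSD and the minimum
    RMSD itself.  Degenerate (collinear) configurations are rejected because
    the optimal rotation is not unique there.
    """
    a, b = _check_pair(coords_a, coords_b)
    if _collinear(a) or _collinear(b):
        raise ValueError("degenerate (collinear) configuration")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    # explicit residual avoids the cancellation error of the trace formula
    resid = b0 @ rot.T - a0
    msd = float((resid * resid).sum()) / a.shape[0]
    transform = RigidTransform(rotation=rot, translation=ca - rot @ cb)
    return SuperposeResult(transform=transform, rmsd=float(np.sqrt(msd)), n_atoms=a.shape[0])


def superposed_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets (no transform built)."""
    a, b = _check_pair(coords_a, coords_b)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(b0.T @ a0)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    resid = b0 @ rot.T - a0
    return float(np.sqrt((resid * resid).sum() / a.shape[0]))


def rmsd_to_many(coords: np.ndarray, references: np.ndarray) -> np.ndarray:
    """Superposed RMSD of one N x 3 set against a K x N x 3 stack."""
    a = np.asarray(coords, dtype=float)
    refs = np.asarray(references, dtype=float)
    a0 = a - a.mean(axis=0)
    r0 = refs - refs.mean(axis=1, keepdims=True)
    # h_k = a0^T r0_k : optimal rotation maps a0 onto each reference
    h = np.einsum("ni,knj->kij", a0, r0)
    u, s, vt = np.linalg.svd(h)
    sign = np.where(np.linalg.det(h) < 0, -1.0, 1.0)
    corr = np.zeros_like(h)
    corr[:, 0, 0] = 1.0
    corr[:, 1, 1] = 1.0
    corr[:, 2, 2] = sign
    rots = np.einsum("kji,kjl,kml->kim", vt, corr, u)  # V corr U^T per k
    moved = np.einsum("kij,nj->kni", rots, a0)
    resid = moved - r0
    msd = np.einsum("kni,kni->k", resid, resid) / a.shape[0]
    return np.sqrt(np.maximum(0.0, msd))


def _subset_coords(
    sa: Structure,
    sb: Structure,
    subset: str,
    mapping: list[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    rows_a, rows_b = [], []
    if subset == "ca":
        for i, j in mapping:
            ca_a = sa.residues[i].get_atom("CA")
            ca_b = sb.residues[j].get_atom("CA")
            if ca_a is None or ca_b is None:
                continue
            rows_a.append(ca_a.coords)
            rows_b.append(ca_b.coords)
    elif subset == "heavy":
        for i, j in mapping:
            ra, rb = sa.residues[i], sb.residues[j]
            names_a = {a.name for a in ra.atoms if a.element != "H"}
            names_b = {a.name for a in rb.atoms if a.element != "H"}
            for name in sorted(names_a & names_b):
                rows_a.append(ra.get_atom(name).coords)
                rows_b.append(rb.get_atom(name).coords)
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if not rows_a:
        raise ValueError("empty atom selection")
    return np.asarray(rows_a), np.asarray(rows_b)


def rmsd(
    structure_a: Structure,
    structure_b: Structure,
    subset: str = "ca",
    mapping: list[tuple[int, int]] | None = None,
) -> float:
    """Superposed RMSD between two structures over ``ca`` or ``heavy`` atoms.

    ``mapping`` is a list of (residue index in a, residue index in b) pairs;
    by default residues are paired positionally, which requires equal residue
    counts.  Heavy-atom mode intersects atoms by name within each residue
    pair so models with differing side-chain completeness stay comparable.
    """
    if mapping is None:
        if structure_a.n_residues() != structure_b.n_residues():
            raise ValueError(
                "positional mapping requires equal residue counts "
                f"({structure_a.n_residues()} vs {structure_b.n_residues()})"
            )
        mapping = [(i, i) for i in range(structure_a.n_residues())]
    a, b = _subset_coords(structure_a, structure_b, subset, mapping)
    return kabsch(a, b).rmsd
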