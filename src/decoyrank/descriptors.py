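"""The seven physico-chemical descriptors scored by the cumulative metric.

Per structure: four solvent-accessible-surface-area terms (A1 fractional
exposed nonpolar-residue area, A2 fractional exposed nonpolar-atom area, A3
hydropathy-weighted exposed area, A4 total area), two secondary-structure
penalties (PH for helix, PS for strand, percent of predicted residues not
realized in the model), and M1, the mean Calpha distance from the centroid
(a compactness measure).

SASA is Shrake-Rupley with a deterministic generalized-spiral point lattice,
so descriptor values are bit-stable across runs.  Secondary structure is
assigned from phi/psi windows rather than hydrogen-bond patterns: decoys
frequently lack amide hydrogens and carbonyl regularity, and the dihedral
rule is deterministic and dependency-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import dihedral
from .pdbio import NONPOLAR_ELEMENTS, NONPOLAR_RESIDUES, Structure, classify_atoms

__all__ = [
    "SasaResult",
    "SSString",
    "DescriptorVector",
    "KD_HYDROPATHY",
    "sasa",
    "surface_terms",
    "assign_ss",
    "ss_penalty",
    "euclidean_compactness",
    "describe",
    "backbone_dihedrals",
]

#: Kyte-Doolittle hydropathy (1-letter residue keyed by 3-letter code).
KD_HYDROPATHY = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9, "TYR": -1.3,
    "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5, "ASP": -3.5, "ASN": -3.5,
    "LYS": -3.9, "ARG": -4.5,
}

# phi/psi windows (degrees) for secondary-structure assignment
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_STRAND_PHI = (-170.0, -40.0)
# strand psi window wraps: (90, 180] union (-180, -170)
_MIN_HELIX_RUN = 4
_MIN_STRAND_RUN = 3


@dataclass(frozen=True)
class SasaResult:
    per_atom: dict[tuple[int, str], float]
    per_residue: dict[int, float]
    total: float
    probe: float
    n_points: int


@dataclass(frozen=True)
class SSString:
    codes: str
    source: str  # "predicted" | "assigned"

    def __post_init__(self) -> None:
        bad = set(self.codes) - set("HEC")
        if bad:
            raise ValueError(f"invalid secondary-structure codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class DescriptorVector:
    A1: float
    A2: float
    A3: float
    A4: float
    PH: float
    PS: float
    M1: float
    CS: float | None = None


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate centered coordinates into their principal-axes frame with signs
    fixed by third moments, so the test-point lattice samples every rigid
    placement of a structure identically."""
    x = coords - coords.mean(axis=0)
    cov = x.T @ x
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    proj = x @ vecs
    skew = (proj**3).sum(axis=0)
    signs = np.where(skew < 0, -1.0, 1.0)
    return proj * signs


def _spiral_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral lattice of n points on the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(structure: Structure, probe: float = 1.4, n_points: int = 960) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Per-atom area is (exposed test points / n_points) * 4 pi (r + probe)^2,
    with test points from the deterministic spiral lattice.  Hydrogens are
    ignored; decoy pools are typically heavy-atom only.
    """
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    info = classify_atoms(structure)
    keys: list[tuple[int, str]] = []
    centers: list[np.ndarray] = []
    radii: list[float] = []
    for i, res in enumerate(structure.residues):
        for atom in res.atoms:
            if atom.element == "H":
                continue
            keys.append((i, atom.name))
            centers.append(atom.coords)
            radii.append(info[(i, atom.name)]["radius"])
    if not centers:
        raise ValueError("structure has no heavy atoms")
    centers_arr = _canonical_frame(np.asarray(centers))
    r_eff = np.asarray(radii) + probe
    unit = _spiral_points(n_points)
    tree = cKDTree(centers_arr)
    r_max = float(r_eff.max())
    neighbor_lists = tree.query_ball_point(centers_arr, r_eff + r_max)
    per_atom: dict[tuple[int, str], float] = {}
    for idx, key in enumerate(keys):
        nbrs = [j for j in neighbor_lists[idx] if j != idx]
        if nbrs:
            pts = centers_arr[idx] + r_eff[idx] * unit
            nc = centers_arr[nbrs]
            # |p - c|^2 = |p|^2 + |c|^2 - 2 p.c, with the cross term via BLAS
            d2 = (
                (pts * pts).sum(axis=1)[:, None]
                + (nc * nc).sum(axis=1)[None, :]
                - 2.0 * (pts @ nc.T)
            )
            n_exposed = int(np.all(d2 > r_eff[nbrs] ** 2, axis=1).sum())
        else:
            n_exposed = n_points
        area = 4.0 * np.pi * r_eff[idx] ** 2 * n_exposed / n_points
        per_atom[key] = float(area)
    per_residue: dict[int, float] = {}
    for (i, _), area in per_atom.items():
        per_residue[i] = per_residue.get(i, 0.0) + area
    total = float(sum(per_atom.values()))
    return SasaResult(
        per_atom=per_atom,
        per_residue=per_residue,
        total=total,
        probe=probe,
        n_points=n_points,
    )


def surface_terms(
    sasa_result: SasaResult,
    structure: Structure,
    nonpolar_residues: frozenset[str] = NONPOLAR_RESIDUES,
    hydropathy: dict[str, float] | None = None,
) -> dict[str, float]:
    """A1-A4 from a SASA result.

    A1: fraction of total area on nonpolar residues.  A2: fraction of total
    area on nonpolar (C/S) atoms.  A3: exposed area weighted per residue by
    shifted Kyte-Doolittle hydropathy (KD + 4.5, so weights are >= 0).  A4:
    total area.  The residue set and weight table are configurable.
    """
    if sasa_result.total <= 0:
        raise ValueError("total surface area is zero")
    hp = hydropathy or KD_HYDROPATHY
    a1_num = sum(
        area
        for i, area in sasa_result.per_residue.items()
        if structure.residues[i].res_name in nonpolar_residues
    )
    elements = {
        (i, a.name): a.element
        for i, r in enumerate(structure.residues)
        for a in r.atoms
    }
    a2_num = sum(
        area
        for key, area in sasa_result.per_atom.items()
        if elements[key] in NONPOLAR_ELEMENTS
    )
    a3 = sum(
        (hp.get(structure.residues[i].res_name, -4.5) + 4.5) * area
        for i, area in sasa_result.per_residue.items()
    )
    return {
        "A1": a1_num / sasa_result.total,
        "A2": a2_num / sasa_result.total,
        "A3": a3,
        "A4": sasa_result.total,
    }


def backbone_dihedrals(structure: Structure) -> list[tuple[float | None, float | None]]:
    """(phi, psi) per residue in degrees; None where an angle is undefined
    (chain termini or missing backbone atoms)."""
    n = structure.n_residues()
    coords = []
    for res in structure.residues:
        row = {}
        for name in ("N", "CA", "C"):
            atom = res.get_atom(name)
            row[name] = atom.coords if atom is not None else None
        coords.append(row)
    out: list[tuple[float | None, float | None]] = []
    for i in range(n):
        phi = psi = None
        c_prev = coords[i - 1]["C"] if i > 0 else None
        n_i, ca_i, c_i = coords[i]["N"], coords[i]["CA"], coords[i]["C"]
        n_next = coords[i + 1]["N"] if i < n - 1 else None
        backbone_ok = n_i is not None and ca_i is not None and c_i is not None
        if c_prev is not None and backbone_ok:
            phi = dihedral(c_prev, n_i, ca_i, c_i)
        if n_next is not None and backbone_ok:
            psi = dihedral(n_i, ca_i, c_i, n_next)
        out.append((phi, psi))
    return out


def _in_strand_psi(psi: float) -> bool:
    return (90.0 < psi <= 180.0) or (-180.0 <= psi < -170.0)


def _prune_runs(labels: list[str], code: str, min_run: int) -> None:
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] == code:
            j = i
            while j < n and labels[j] == code:
                j += 1
            if j - i < min_run:
                for k in range(i, j):
                    labels[k] = "C"
            i = j
        else:
            i += 1


def assign_ss(structure: Structure) -> SSString:
    """Assign H/E/C per residue from backbone dihedral windows.

    H requires phi in (-100, -30) and psi in (-80, -5) in runs of >= 4;
    E requires phi in (-170, -40) and psi in (90, 180] or [-180, -170) in
    runs of >= 3; everything else is coil.  Structures without full backbone
    fall back to a Calpha-only rule (i to i+3 distance 5.0 +/- 1.0 A marks
    helix); fewer than 3 residues yields all coil.
    """
    n = structure.n_residues()
    if n < 3:
        return SSString(codes="C" * n, source="assigned")
    has_backbone = all(
        structure.residues[i].get_atom(nm) is not None
        for i in range(n)
        for nm in ("N", "CA", "C")
    )
    if has_backbone:
        labels = []
        for phi, psi in backbone_dihedrals(structure):
            if phi is None or psi is None:
                labels.append("C")
            elif _HELIX_PHI[0] < phi < _HELIX_PHI[1] and _HELIX_PSI[0] < psi < _HELIX_PSI[1]:
                labels.append("H")
            elif _STRAND_PHI[0] < phi < _STRAND_PHI[1] and _in_strand_psi(psi):
                labels.append("E")
            else:
                labels.append("C")
    else:
        ca = structure.ca_coords()
        labels = ["C"] * n
        for i in range(n - 3):
            d = float(np.linalg.norm(ca[i + 3] - ca[i]))
            if 4.0 <= d <= 6.0:
                labels[i] = "H"
    _prune_runs(labels, "H", _MIN_HELIX_RUN)
    _prune_runs(labels, "E", _MIN_STRAND_RUN)
    return SSString(codes="".join(labels), source="assigned")


def ss_penalty(predicted: SSString, assigned: SSString) -> dict[str, float]:
    """Percent of predicted-helix (PH) / predicted-strand (PS) residues not
    realized in the assigned string; 0 when nothing is predicted in a class."""
    if len(predicted) != len(assigned):
        raise ValueError(
            f"length mismatch: predicted {len(predicted)} vs assigned {len(assigned)}"
        )
    out = {}
    for key, code in (("PH", "H"), ("PS", "E")):
        pred_idx = [i for i, c in enumerate(predicted.codes) if c == code]
        if not pred_idx:
            out[key] = 0.0
        else:
            missed = sum(1 for i in pred_idx if assigned.codes[i] != code)
            out[key] = 100.0 * missed / len(pred_idx)
    return out


def euclidean_compactness(structure: Structure) -> float:
    """M1: mean Euclidean distance of Calpha atoms from their centroid (A)."""
    ca = structure.ca_coords()
    centroid = ca.mean(axis=0)
    return float(np.mean(np.linalg.norm(ca - centroid, axis=1)))


def describe(
    structure: Structure,
    predicted_ss: SSString,
    probe: float = 1.4,
    n_points: int = 960,
) -> DescriptorVector:
    """Evaluate all seven descriptors for one structure (CS left unset)."""
    if len(predicted_ss) != structure.n_residues():
        raise ValueError("predicted secondary structure length mismatch")
    sr = sasa(structure, probe=probe, n_points=n_points)
    terms = surface_terms(sr, structure)
    assigned = assign_ss(structure)
    pens = ss_penalty(predicted_ss, assigned)
    return DescriptorVector(
        A1=terms["A1"],
        A2=terms["A2"],
        A3=terms["A3"],
        A4=terms["A4"],
        PH=pens["PH"],
        PS=pens["PS"],
        M1=euclidean_compactness(structure),
    )
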