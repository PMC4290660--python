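"""Composite structure-quality score ("protsav-standin").

The production pipeline this package models aggregates six external
assessment tools into one quality number; those binaries are out of reach of
a library, so this module provides a transparent two-component stand-in:
the fraction of Ramachandran outliers (torsion quality) and the number of
steric clashes per residue (packing quality), combined with fixed documented
weights.  Low values mean good structures, zero on ideal geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .descriptors import backbone_dihedrals
from .pdbio import Structure

__all__ = ["QualityReport", "ramachandran", "clashes", "composite_quality"]

logger = logging.getLogger(__name__)

_RAMA_WEIGHT = 100.0
_CLASH_WEIGHT = 10.0


@dataclass(frozen=True)
class QualityReport:
    rama_outlier_fraction: float
    clashes_per_residue: float
    composite: float  # 100*rama + 10*clashes; low = good


def _psi_in_sheet(psi: float) -> bool:
    # sheet box psi in (45, 240) taken mod 360: (45, 180] union [-180, -120)
    return 45.0 < psi <= 180.0 or -180.0 <= psi < -120.0


def _allowed(phi: float, psi: float) -> bool:
    if -180.0 < phi < -20.0 and -120.0 < psi < 45.0:
        return True  # generous helix region
    if -180.0 < phi < -20.0 and _psi_in_sheet(psi):
        return True  # generous sheet region
    if 20.0 < phi < 120.0 and -60.0 < psi < 90.0:
        return True  # left-handed helix region
    return False


def ramachandran(structure: Structure) -> float:
    """Fraction of non-terminal residues with (phi, psi) outside the
    generously bounded favored/allowed regions."""
    scorable = 0
    outliers = 0
    for phi, psi in backbone_dihedrals(structure):
        if phi is None or psi is None:
            continue  # termini or missing backbone atoms
        scorable += 1
        if not _allowed(phi, psi):
            outliers += 1
    if scorable == 0:
        logger.warning("no scorable residues for Ramachandran analysis in %s", structure.id)
        return 0.0
    return outliers / scorable


def clashes(structure: Structure, cutoff: float = 2.0) -> float:
    """Non-bonded heavy-atom pairs closer than ``cutoff`` A per residue.

    Pairs within the same or adjacent residues are excluded (bonded or
    1-3/1-4 neighbours), leaving only genuine packing violations.
    """
    pairs = structure.heavy_atoms()
    if len(pairs) < 2:
        return 0.0
    res_idx = np.asarray([i for i, _ in pairs])
    coords = np.asarray([a.coords for _, a in pairs])
    tree = cKDTree(coords)
    count = 0
    for i, j in tree.query_pairs(cutoff):
        if abs(int(res_idx[i]) - int(res_idx[j])) >= 2:
            count += 1
    return count / structure.n_residues()


def composite_quality(structure: Structure, clash_cutoff: float = 2.0) -> QualityReport:
    """Fill the full quality report; deterministic."""
    rama = ramachandran(structure)
    cl = clashes(structure, cutoff=clash_cutoff)
    return QualityReport(
        rama_outlier_fraction=rama,
        clashes_per_residue=cl,
        composite=_RAMA_WEIGHT * rama + _CLASH_WEIGHT * cl,
    )
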