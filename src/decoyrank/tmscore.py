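"""Template-modeling score (TM-score) between a model and a reference.

TM-score normalizes per-residue distance errors by a length-dependent scale
d0(L) so that the score of a random pair of structures is length-independent
and a score above 0.5 conventionally indicates the same fold.  The score is
maximized over superpositions found by seeding from contiguous aligned
fragments and iteratively refining the included residue set, in the spirit
of the original algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pdbio import Structure
from .superpose import kabsch

__all__ = ["TmParams", "TmResult", "d0", "tm_score", "tm_score_coords"]


@dataclass(frozen=True)
class TmParams:
    L_target: int
    d0: float


@dataclass(frozen=True)
class TmResult:
    score: float
    params: TmParams
    n_aligned: int


def d0(L: int) -> float:
    """Length-dependent distance scale in Angstroms, floored at 0.5 A."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if L <= 15:
        return 0.5
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)


def _score(dists: np.ndarray, d0v: float, L_target: int) -> float:
    return float(np.sum(1.0 / (1.0 + (dists / d0v) ** 2)) / L_target)


def _refine(
    xm: np.ndarray, xr: np.ndarray, seed_idx: np.ndarray, d0v: float, L_target: int
) -> float:
    """Superpose on a seed subset, then iterate inclusion-by-distance to a
    fixed point; return the best score over all all-pair evaluations."""
    best = 0.0
    included = seed_idx
    d_base = max(d0v + 1.0, 4.5)
    for _ in range(20):
        try:
            res = kabsch(xr[included], xm[included])
        except ValueError:  # collinear seed fragment: no unique rotation
            break
        moved = res.transform.apply(xm)
        dists = np.linalg.norm(moved - xr, axis=1)
        best = max(best, _score(dists, d0v, L_target))
        d_cut = d_base
        new_included = np.nonzero(dists < d_cut)[0]
        while new_included.size < 3:
            d_cut += 0.5
            new_included = np.nonzero(dists < d_cut)[0]
        if new_included.size == included.size and np.array_equal(new_included, included):
            break
        included = new_included
    return best


def tm_score_coords(
    model_ca: np.ndarray,
    reference_ca: np.ndarray,
    L_target: int,
    fragment_lengths: list[int] | None = None,
) -> float:
    """TM-score from paired Calpha coordinate arrays (one row per aligned pair)."""
    xm = np.asarray(model_ca, dtype=float)
    xr = np.asarray(reference_ca, dtype=float)
    L_aln = xm.shape[0]
    if L_aln < 3:
        raise ValueError("need at least 3 aligned residue pairs")
    d0v = d0(L_target)
    if fragment_lengths is None:
        fragment_lengths = sorted(
            {L_aln, max(4, L_aln // 2), max(4, L_aln // 4)}, reverse=True
        )
    fragment_lengths = [min(L_aln, max(3, f)) for f in fragment_lengths]
    best = 0.0
    for frag in dict.fromkeys(fragment_lengths):
        for start in range(0, L_aln - frag + 1):
            seed = np.arange(start, start + frag)
            best = max(best, _refine(xm, xr, seed, d0v, L_target))
    return best


def tm_score(
    model: Structure,
    reference: Structure,
    mapping: list[tuple[int, int]] | None = None,
) -> TmResult:
    """TM-score of ``model`` against ``reference``.

    ``mapping`` lists (model residue index, reference residue index) pairs;
    identity mapping is used when omitted and the residue counts agree.  The
    score is normalized by the reference length, matching CASP evaluation
    practice.
    """
    if mapping is None:
        if model.n_residues() != reference.n_residues():
            raise ValueError("identity mapping requires equal residue counts")
        mapping = [(i, i) for i in range(model.n_residues())]
    if not mapping:
        raise ValueError("empty mapping")
    xm_rows, xr_rows = [], []
    for i, j in mapping:
        ca_m = model.residues[i].get_atom("CA")
        ca_r = reference.residues[j].get_atom("CA")
        if ca_m is None or ca_r is None:
            raise ValueError(f"missing CA on mapped pair ({i}, {j})")
        xm_rows.append(ca_m.coords)
        xr_rows.append(ca_r.coords)
    L_target = reference.n_residues()
    score = tm_score_coords(np.asarray(xm_rows), np.asarray(xr_rows), L_target)
    return TmResult(
        score=score,
        params=TmParams(L_target=L_target, d0=d0(L_target)),
        n_aligned=len(mapping),
    )
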