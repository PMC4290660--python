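"""Cumulative physico-chemical score (pcSM) and decoy ranking.

CS = c_A1*A1 + c_A2*A2 + c_A3*A3 + c_A4*A4 + max(c_PH*PH, c_PS*PS) + c_M1*M1

All six contributing terms are penalty-like (exposed nonpolar surface,
secondary-structure mismatch, non-compactness), so lower CS marks the more
native-like model and ranking is ascending.  The helix and strand penalties
each carry their own coefficient; the larger of the two products enters the
sum.
"""

from __future__ import annotations

from dataclasses import dataclass

from .descriptors import DescriptorVector
from .pdbio import DecoyPool

__all__ = ["PcsmCoefficients", "RankedList", "cumulative_score", "rank"]


@dataclass(frozen=True)
class PcsmCoefficients:
    """Optimized multipliers of the cumulative score (defaults as published)."""

    c_A1: float = 10.0
    c_A2: float = 0.1
    c_A3: float = 0.00001
    c_A4: float = 0.001
    c_PH: float = 0.15
    c_PS: float = 0.21
    c_M1: float = 0.001


DEFAULT_COEFFICIENTS = PcsmCoefficients()


@dataclass(frozen=True)
class RankedList:
    """(id, CS) pairs in ascending CS order; ties keep input order."""

    entries: tuple[tuple[str, float], ...]

    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def cumulative_score(
    d: DescriptorVector, coeffs: PcsmCoefficients = DEFAULT_COEFFICIENTS
) -> float:
    """Evaluate CS for one descriptor vector (does not mutate ``d``)."""
    fields = (d.A1, d.A2, d.A3, d.A4, d.PH, d.PS, d.M1)
    if any(v is None for v in fields):
        raise ValueError("descriptor vector has unset fields")
    return (
        coeffs.c_A1 * d.A1
        + coeffs.c_A2 * d.A2
        + coeffs.c_A3 * d.A3
        + coeffs.c_A4 * d.A4
        + max(coeffs.c_PH * d.PH, coeffs.c_PS * d.PS)
        + coeffs.c_M1 * d.M1
    )


def rank(
    pool: DecoyPool,
    descriptors: dict[str, DescriptorVector],
    k: int = 10,
    coeffs: PcsmCoefficients = DEFAULT_COEFFICIENTS,
) -> RankedList:
    """Top-k decoys by ascending CS (lower = more native-like).

    Requires a descriptor vector for every pool member; the CS field of each
    vector is filled in as a side effect.  Ties are broken stably by pool
    order.
    """
    missing = [i for i in pool.ids() if i not in descriptors]
    if missing:
        raise ValueError(f"missing descriptors for: {', '.join(sorted(missing))}")
    scored = []
    for sid in pool.ids():
        cs = cumulative_score(descriptors[sid], coeffs)
        descriptors[sid].CS = cs
        scored.append((sid, cs))
    scored.sort(key=lambda t: t[1])  # stable: ties keep pool order
    return RankedList(entries=tuple(scored[: max(0, k)]))
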