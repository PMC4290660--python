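"""Descriptors: SASA closed forms and convergence, surface terms, secondary
structure assignment/penalties, compactness, rigid invariance."""

import numpy as np
import pytest

from decoyrank import descriptors, synthgen
from decoyrank.descriptors import (
    SSString,
    assign_ss,
    describe,
    euclidean_compactness,
    sasa,
    ss_penalty,
    surface_terms,
)
from decoyrank.pdbio import Atom, Residue, Structure


def _carbon(serial, name, xyz, res_name="ALA", seq=1):
    return Residue("A", seq, "", res_name, [Atom(serial, name, "C", np.asarray(xyz, float))])


def test_sasa_isolated_sphere():
    s = Structure(id="c1", residues=[_carbon(1, "CA", [0, 0, 0])])
    expected = 4 * np.pi * (1.70 + 1.4) ** 2
    assert sasa(s).total == pytest.approx(expected, rel=0.005)


def test_sasa_additivity_at_separation():
    s = Structure(
        id="c2",
        residues=[_carbon(1, "CA", [0, 0, 0], seq=1), _carbon(2, "CA", [100, 0, 0], seq=2)],
    )
    expected = 2 * 4 * np.pi * (1.70 + 1.4) ** 2
    assert sasa(s).total == pytest.approx(expected, rel=0.005)


def test_sasa_buried_atom_in_cage():
    """A carbon enclosed by 26 carbons at 2.0 A is essentially buried; a
    fine 10,242-point lattice is the reference."""
    cage = []
    serial = 0
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                serial += 1
                v = np.array([dx, dy, dz], dtype=float)
                v = 2.0 * v / np.linalg.norm(v)
                cage.append(_carbon(serial, "CA", v, seq=serial + 1))
    center = _carbon(100, "CA", [0, 0, 0], seq=100)
    s = Structure(id="cage", residues=[center] + cage)
    coarse = sasa(s, n_points=960).per_atom[(0, "CA")]
    fine = sasa(s, n_points=10242).per_atom[(0, "CA")]
    assert fine < 1.0
    assert coarse < 1.0


def test_sasa_lattice_convergence(helix12, hairpin16, hlh60):
    for s in (helix12, hairpin16, hlh60):
        coarse = sasa(s, n_points=960).total
        fine = sasa(s, n_points=10242).total
        assert abs(coarse - fine) / fine <= 0.01


def test_sasa_totals_are_consistent(helix12):
    sr = sasa(helix12)
    assert sr.total == pytest.approx(sum(sr.per_atom.values()), abs=1e-6)
    assert sr.total == pytest.approx(sum(sr.per_residue.values()), abs=1e-6)
    assert all(a >= 0 for a in sr.per_atom.values())


def test_surface_terms_all_nonpolar_residues():
    s = Structure(
        id="ala2",
        residues=[_carbon(1, "CA", [0, 0, 0], "ALA", 1), _carbon(2, "CA", [5, 0, 0], "ALA", 2)],
    )
    terms = surface_terms(sasa(s), s)
    assert terms["A1"] == pytest.approx(1.0)
    assert terms["A2"] == pytest.approx(1.0)  # all atoms are carbon
    assert terms["A4"] > 0


def test_surface_terms_a3_hand_sum(helix12):
    sr = sasa(helix12)
    terms = surface_terms(sr, helix12)
    hand = 0.0
    for i, area in sr.per_residue.items():
        kd = descriptors.KD_HYDROPATHY[helix12.residues[i].res_name]
        hand += (kd + 4.5) * area
    assert terms["A3"] == pytest.approx(hand, rel=1e-12)


def test_assign_ss_ideal_fixtures(helix12, hairpin16):
    helix_codes = assign_ss(helix12).codes
    assert set(helix_codes[1:-1]) == {"H"}
    hairpin_codes = assign_ss(hairpin16).codes
    runs = [r for r in hairpin_codes.replace("C", " ").split() if set(r) == {"E"}]
    assert len(runs) == 2


def test_assign_ss_no_helix_without_phi_window(monkeypatch):
    """Extended phi with helical psi alone must not produce helix runs."""
    import decoyrank.synthgen as sg

    monkeypatch.setattr(sg, "_phi_psi_schedule", lambda topology, n: [(-120.0, -47.0)] * n)
    s = sg.make_toy(sg.ToySpec(topology="helix", n_residues=14))
    assert "H" not in assign_ss(s).codes


def test_assign_ss_tiny_structure():
    s = Structure(id="t", residues=[_carbon(1, "CA", [0, 0, 0])])
    assert assign_ss(s).codes == "C"


def test_assign_ss_ca_only_fallback(helix12):
    stripped = Structure(
        id="ca_only",
        residues=[
            Residue(r.chain_id, r.seq_number, r.insertion_code, r.res_name,
                    [a for a in r.atoms if a.name == "CA"])
            for r in helix12.residues
        ],
    )
    codes = assign_ss(stripped).codes
    assert "H" in codes  # i->i+3 distance rule recovers the helix


def test_ss_penalty_counts():
    pred = SSString(codes="H" * 10, source="predicted")
    assert ss_penalty(pred, SSString(codes="H" * 10, source="assigned"))["PH"] == 0.0
    assigned = SSString(codes="H" * 6 + "C" * 4, source="assigned")
    pens = ss_penalty(pred, assigned)
    assert pens["PH"] == pytest.approx(40.0)
    assert pens["PS"] == 0.0  # nothing predicted E


def test_ss_penalty_length_mismatch():
    with pytest.raises(ValueError):
        ss_penalty(SSString("HH", "predicted"), SSString("H", "assigned"))


def test_euclidean_compactness_cases(hlh60):
    coincident = Structure(
        id="z", residues=[_carbon(1, "CA", [1, 2, 3], seq=1), _carbon(2, "CA", [1, 2, 3], seq=2)]
    )
    assert euclidean_compactness(coincident) == pytest.approx(0.0)
    pair = Structure(
        id="p", residues=[_carbon(1, "CA", [0, 0, 0], seq=1), _carbon(2, "CA", [2, 0, 0], seq=2)]
    )
    assert euclidean_compactness(pair) == pytest.approx(1.0)
    ca = hlh60.ca_coords()
    direct = np.mean(np.linalg.norm(ca - ca.mean(axis=0), axis=1))
    assert euclidean_compactness(hlh60) == pytest.approx(direct, abs=1e-9)


def test_describe_deterministic_and_rigid_invariant(hlh60, rng):
    ss = SSString(codes=assign_ss(hlh60).codes, source="predicted")
    d1 = describe(hlh60, ss)
    d2 = describe(hlh60, ss)
    for f in ("A1", "A2", "A3", "A4", "PH", "PS", "M1"):
        assert getattr(d1, f) == getattr(d2, f)
    moved = synthgen._displace(hlh60, 0.0, rng, "moved")
    d3 = describe(moved, ss)
    for f in ("A1", "A2", "A3", "A4", "PH", "PS", "M1"):
        assert getattr(d3, f) == pytest.approx(getattr(d1, f), abs=1e-6)


def test_noise_increases_area_and_compactness(hlh60, small_pool):
    """A4 and M1 grow, on average, as decoys unfold; A1/A2 stay in [0,1]."""
    ss = SSString(codes=assign_ss(hlh60).codes, source="predicted")
    native = describe(hlh60, ss)
    by_sigma: dict[float, list] = {}
    for sid, pr in small_pool.provenance.items():
        d = describe(small_pool.decoys[sid], ss)
        assert 0.0 <= d.A1 <= 1.0 and 0.0 <= d.A2 <= 1.0
        by_sigma.setdefault(pr["noise_sigma"], []).append(d)
    sigmas = sorted(by_sigma)
    mean_a4 = [np.mean([d.A4 for d in by_sigma[s]]) for s in sigmas]
    mean_m1 = [np.mean([d.M1 for d in by_sigma[s]]) for s in sigmas]
    assert all(x < y for x, y in zip(mean_a4, mean_a4[1:]))
    assert all(x < y for x, y in zip(mean_m1, mean_m1[1:]))
    assert mean_a4[-1] > native.A4
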