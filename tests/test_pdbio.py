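"""Structure I/O: round-trips, pool dialects, sequence and atom typing."""

import numpy as np
import pytest

from decoyrank import pdbio, synthgen
from decoyrank.pdbio import Atom, DecoyPool, PDBError, Residue, Structure


def _max_coord_error(s1, s2):
    return max(
        float(np.max(np.abs(a1.coords - a2.coords)))
        for r1, r2 in zip(s1.residues, s2.residues)
        for a1, a2 in zip(r1.atoms, r2.atoms)
    )


@pytest.mark.parametrize("topology,n", [("helix", 12), ("hairpin", 16), ("helix-loop-helix", 30)])
def test_write_read_round_trip(tmp_path, topology, n):
    s = synthgen.make_toy(synthgen.ToySpec(topology=topology, n_residues=n))
    path = tmp_path / "s.pdb"
    pdbio.write_structure(s, path)
    s2 = pdbio.read_structure(path)
    assert s2.n_residues() == s.n_residues()
    for r1, r2 in zip(s.residues, s2.residues):
        assert r1.res_name == r2.res_name
        assert r1.seq_number == r2.seq_number
        assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
    assert _max_coord_error(s, s2) <= 1e-3


def test_insertion_codes_preserved(tmp_path, helix12):
    import copy

    s = Structure(id="ins", residues=copy.deepcopy(helix12.residues))
    s.residues[3].insertion_code = "A"
    path = tmp_path / "ins.pdb"
    pdbio.write_structure(s, path)
    s2 = pdbio.read_structure(path)
    assert s2.residues[3].insertion_code == "A"


def test_empty_structure_rejected():
    with pytest.raises(PDBError):
        Structure(id="empty", residues=[])


def test_read_empty_file_is_parse_error(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("")
    with pytest.raises(PDBError):
        pdbio.read_structure(path)


def test_read_missing_file(tmp_path):
    with pytest.raises(FileNotFoundError):
        pdbio.read_structure(tmp_path / "nope.pdb")


def test_malformed_coordinates_rejected(tmp_path, helix12):
    path = tmp_path / "bad.pdb"
    text = pdbio.write_structure(helix12, tmp_path / "good.pdb").read_text()
    lines = text.splitlines()
    lines[2] = lines[2][:30] + "abcdefgh" + lines[2][38:]
    path.write_text("\n".join(lines))
    with pytest.raises(PDBError):
        pdbio.read_structure(path)


def test_multi_model_selection(tmp_path, helix12, hairpin16):
    # two models differing in coordinates; model_index follows MODEL numbering
    shifted = Structure(
        id="m2",
        residues=[
            Residue(
                r.chain_id, r.seq_number, r.insertion_code, r.res_name,
                [Atom(a.serial, a.name, a.element, a.coords + 5.0) for a in r.atoms],
            )
            for r in helix12.residues
        ],
    )
    pool = DecoyPool(
        decoys={"a": helix12, "b": shifted},
        shared_sequence=pdbio.extract_sequence(helix12),
    )
    path = tmp_path / "multi.pdb"
    pdbio.write_pool(pool, path)
    first = pdbio.read_structure(path)
    second = pdbio.read_structure(path, model_index=2)
    delta = second.residues[0].atoms[0].coords - first.residues[0].atoms[0].coords
    assert np.allclose(delta, 5.0, atol=1e-3)


def test_read_pool_directory(tmp_path, helix12):
    for k in range(5):
        pdbio.write_structure(helix12, tmp_path / f"d{k}.pdb")
    pool = pdbio.read_pool(tmp_path)
    assert len(pool) == 5
    assert sorted(pool.ids()) == [f"d{k}" for k in range(5)]


def test_read_pool_multimodel(tmp_path, helix12):
    pool = DecoyPool(
        decoys={f"x{k}": helix12 for k in range(3)},
        shared_sequence=pdbio.extract_sequence(helix12),
    )
    path = tmp_path / "pool.pdb"
    pdbio.write_pool(pool, path)
    loaded = pdbio.read_pool(path)
    assert len(loaded) == 3
    assert loaded.ids() == ["model_1", "model_2", "model_3"]


def test_read_pool_sequence_mismatch(tmp_path, helix12, hairpin16):
    pdbio.write_structure(helix12, tmp_path / "a.pdb")
    pdbio.write_structure(hairpin16, tmp_path / "b.pdb")
    with pytest.raises(PDBError, match="b"):
        pdbio.read_pool(tmp_path)


def test_extract_sequence_basic():
    residues = [
        Residue("A", i + 1, "", name, [Atom(1, "CA", "C", np.zeros(3))])
        for i, name in enumerate(["ALA", "GLY", "SER"])
    ]
    assert pdbio.extract_sequence(Structure(id="ags", residues=residues)) == "AGS"


def test_extract_sequence_nonstandard_maps_to_x():
    residues = [Residue("A", 1, "", "MSE", [Atom(1, "CA", "C", np.zeros(3))])]
    assert pdbio.extract_sequence(Structure(id="mse", residues=residues)) == "X"


def test_extract_sequence_length_matches(small_pool):
    for s in small_pool.decoys.values():
        assert len(pdbio.extract_sequence(s)) == s.n_residues()


def test_classify_atoms_table(helix12):
    info = pdbio.classify_atoms(helix12)
    ca = info[(0, "CA")]
    assert ca["radius"] == pytest.approx(1.70) and ca["polarity"] == "nonpolar"
    n = info[(0, "N")]
    assert n["radius"] == pytest.approx(1.55) and n["polarity"] == "polar"


def test_classify_atoms_sulfur_nonpolar():
    res = Residue(
        "A", 1, "", "MET",
        [Atom(1, "CA", "C", np.zeros(3)), Atom(2, "SD", "S", np.ones(3))],
    )
    info = pdbio.classify_atoms(Structure(id="met", residues=[res]))
    assert info[(0, "SD")]["polarity"] == "nonpolar"
    assert info[(0, "SD")]["radius"] == pytest.approx(1.80)


def test_classify_atoms_unknown_element():
    res = Residue("A", 1, "", "ALA", [Atom(1, "FE", "FE", np.zeros(3))])
    with pytest.raises(PDBError, match="FE"):
        pdbio.classify_atoms(Structure(id="fe", residues=[res]))


def test_classify_total_over_synthetic(small_pool):
    for s in small_pool.decoys.values():
        info = pdbio.classify_atoms(s)
        assert len(info) == sum(len(r.atoms) for r in s.residues)
        break


def test_read_ss_plain_and_ss2(tmp_path):
    plain = tmp_path / "ss.txt"
    plain.write_text("HHHCCEEE\n")
    assert pdbio.read_ss(plain) == "HHHCCEEE"

    ss2 = tmp_path / "pred.ss2"
    rows = ["# PSIPRED VFORMAT (PSIPRED V4.0)", ""]
    codes = "CHHHEEC"
    for i, c in enumerate(codes, start=1):
        rows.append(f"{i:4d} A {c}   0.100  0.800  0.100")
    ss2.write_text("\n".join(rows) + "\n")
    assert pdbio.read_ss(ss2) == codes


def test_read_ss_rejects_bad_codes():
    with pytest.raises(PDBError):
        pdbio.read_ss("HHQX")
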