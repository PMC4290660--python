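"""Protein structure I/O and the atomic data model.

Structures are stored as plain ordered residue/atom records with coordinates
in Angstroms — the common currency of every downstream module (superposition,
SASA, scoring, clustering).  Reading goes through Bio.PDB; writing emits
standard fixed-column PDB so that read(write(s)) round-trips names, numbering
and coordinates to the format's 3-decimal precision.

Scope: single-chain protein monomers, heavy atoms.  HETATM records and waters
are skipped on input; alternate locations are resolved to the highest
occupancy (ties broken alphabetically by altloc id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "DecoyPool",
    "PDBError",
    "read_structure",
    "read_pool",
    "write_structure",
    "extract_sequence",
    "classify_atoms",
    "read_ss",
    "VDW_RADII",
    "NONPOLAR_RESIDUES",
    "NONPOLAR_ELEMENTS",
]


class PDBError(ValueError):
    """Raised for unreadable, empty or inconsistent structure input."""


#: van der Waals radii in Angstroms (standard set; hydrogens are ignored by
#: default in surface calculations since decoy sets are typically heavy-atom).
VDW_RADII: Mapping[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

#: Conventional hydrophobic residue set used for the exposed-nonpolar fraction.
NONPOLAR_RESIDUES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "GLY"}
)

#: Elements counted as nonpolar at the atom level (carbon and sulfur).
NONPOLAR_ELEMENTS = frozenset({"C", "S", "H"})


@dataclass(slots=True)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0


@dataclass(slots=True)
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass(slots=True)
class Structure:
    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise PDBError(f"structure {self.id!r} has no residues")

    def n_residues(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(N, 3) array of Calpha coordinates; errors if any residue lacks CA."""
        rows = []
        for r in self.residues:
            ca = r.get_atom("CA")
            if ca is None:
                raise PDBError(
                    f"residue {r.res_name} {r.seq_number} in {self.id!r} has no CA atom"
                )
            rows.append(ca.coords)
        return np.asarray(rows, dtype=float)

    def heavy_atoms(self) -> list[tuple[int, Atom]]:
        """(residue index, atom) pairs for all non-hydrogen atoms."""
        out = []
        for i, r in enumerate(self.residues):
            for a in r.atoms:
                if a.element != "H":
                    out.append((i, a))
        return out


@dataclass
class DecoyPool:
    """Same-sequence candidate structures, optionally with known ground truth.

    ``provenance`` maps decoy id to ``{"noise_sigma": A, "true_ca_rmsd": A}``
    when the pool was generated synthetically.
    """

    decoys: dict[str, Structure]
    shared_sequence: str
    provenance: dict[str, dict[str, float]] | None = None

    def __len__(self) -> int:
        return len(self.decoys)

    def ids(self) -> list[str]:
        return list(self.decoys)

    def subset(self, ids: Iterable[str]) -> "DecoyPool":
        ids = list(ids)
        prov = None
        if self.provenance is not None:
            prov = {i: self.provenance[i] for i in ids if i in self.provenance}
        return DecoyPool(
            decoys={i: self.decoys[i] for i in ids},
            shared_sequence=self.shared_sequence,
            provenance=prov,
        )


def _infer_element(name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            # leading digits mark hydrogens like "1HB"
            if stripped[0].isdigit():
                return "H"
            return ch.upper()
    raise PDBError(f"cannot infer element for atom name {name!r}")


def _pick_altloc(bio_atom):
    if bio_atom.is_disordered():
        children = sorted(
            bio_atom.disordered_get_list(),
            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
        )
        return children[0]
    return bio_atom


def _convert_model(model, struct_id: str) -> Structure:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag, seqnum, icode = res.get_id()
            if hetflag != " ":  # HETATM (incl. waters) skipped
                continue
            atoms = []
            for bio_atom in res.get_list():
                a = _pick_altloc(bio_atom)
                element = (a.element or "").strip().upper()
                if not element:
                    element = _infer_element(a.get_name())
                atoms.append(
                    Atom(
                        serial=int(a.get_serial_number() or 0),
                        name=a.get_name(),
                        element=element,
                        coords=np.asarray(a.get_coord(), dtype=float),
                        occupancy=float(a.get_occupancy() or 1.0),
                        bfactor=float(a.get_bfactor() or 0.0),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=chain.id if chain.id.strip() else "A",
                        seq_number=int(seqnum),
                        insertion_code=icode if icode.strip() else "",
                        res_name=res.get_resname().strip(),
                        atoms=atoms,
                    )
                )
    if not residues:
        raise PDBError(f"no ATOM records found in {struct_id!r}")
    return Structure(id=struct_id, residues=residues)


def _parse_file(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            return parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:
        raise PDBError(f"malformed PDB file {path}: {exc}") from exc
    except ValueError as exc:
        raise PDBError(f"malformed coordinate field in {path}: {exc}") from exc


def read_structure(path: str | Path, model_index: int | None = None) -> Structure:
    """Read one model from a PDB file.

    ``model_index`` matches the MODEL record serial number (1-based); the
    default is the first model in the file.
    """
    bio = _parse_file(path)
    models = list(bio)
    if not models:
        raise PDBError(f"no ATOM records found in {path}")
    if model_index is None:
        model = models[0]
    else:
        by_serial = {int(m.serial_num): m for m in models}
        if model_index in by_serial:
            model = by_serial[model_index]
        elif 1 <= model_index <= len(models):
            model = models[model_index - 1]
        else:
            raise PDBError(f"model {model_index} not present in {path}")
    return _convert_model(model, Path(path).stem)


def read_pool(path: str | Path) -> DecoyPool:
    """Read a decoy pool from a directory of PDB files or a multi-model file.

    Ids are file stems (directory dialect) or ``model_<k>`` (multi-model
    dialect).  All members must share one sequence.
    """
    path = Path(path)
    structures: dict[str, Structure] = {}
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".pdb", ".ent"}
        )
        if not files:
            raise PDBError(f"no PDB files in directory {path}")
        for f in files:
            structures[f.stem] = read_structure(f)
    else:
        bio = _parse_file(path)
        models = list(bio)
        if not models:
            raise PDBError(f"no ATOM records found in {path}")
        for k, model in enumerate(models, start=1):
            sid = f"model_{k}"
            s = _convert_model(model, sid)
            structures[sid] = s
    sequences = {sid: extract_sequence(s) for sid, s in structures.items()}
    ref = next(iter(sequences.values()))
    bad = [sid for sid, seq in sequences.items() if seq != ref]
    if bad:
        raise PDBError(
            "pool members disagree on sequence: " + ", ".join(sorted(bad))
        )
    return DecoyPool(decoys=structures, shared_sequence=ref)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: 1-char elements start at column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and not name[:1].isdigit():
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Write a structure as fixed-column PDB (ATOM/TER/END)."""
    path = Path(path)
    lines = []
    serial = 0
    for res in structure.residues:
        for atom in res.atoms:
            serial += 1
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d} {_format_atom_name(atom.name, atom.element)}"
                f" {res.res_name:>3s} {res.chain_id:1s}{res.seq_number:4d}"
                f"{res.insertion_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                f"          {atom.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_pool(pool: DecoyPool, path: str | Path) -> Path:
    """Write a pool as a multi-model PDB file (MODEL/ENDMDL)."""
    path = Path(path)
    lines = []
    for k, (sid, s) in enumerate(pool.decoys.items(), start=1):
        lines.append(f"MODEL     {k:4d}")
        serial = 0
        for res in s.residues:
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {_format_atom_name(atom.name, atom.element)}"
                    f" {res.res_name:>3s} {res.chain_id:1s}{res.seq_number:4d}"
                    f"{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def extract_sequence(structure: Structure) -> str:
    """1-letter sequence in chain order; nonstandard residues map to 'X'."""
    return "".join(
        protein_letters_3to1.get(r.res_name, "X") for r in structure.residues
    )


def classify_atoms(structure: Structure) -> dict[tuple[int, str], dict]:
    """Radius (A) and polarity per atom, keyed by (residue index, atom name).

    Carbon and sulfur atoms are nonpolar; nitrogen and oxygen polar.
    """
    out: dict[tuple[int, str], dict] = {}
    for i, res in enumerate(structure.residues):
        for atom in res.atoms:
            if atom.element not in VDW_RADII:
                raise PDBError(
                    f"unknown element {atom.element!r} for atom {atom.name} "
                    f"in residue {res.res_name} {res.seq_number}"
                )
            out[(i, atom.name)] = {
                "radius": VDW_RADII[atom.element],
                "polarity": "nonpolar" if atom.element in NONPOLAR_ELEMENTS else "polar",
            }
    return out


def read_ss(source: str | Path) -> str:
    """Read a predicted secondary-structure string (H/E/C per residue).

    Accepts a plain string, a plain-text file holding the string, or a
    PSIPRED ``.ss2`` file (per-residue rows; the state letter is the third
    column).
    """
    text: str
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    # ss2 dialect: comment header then "idx aa state prob prob prob" rows
    data_rows = [ln.split() for ln in lines if not ln.lstrip().startswith("#")]
    if data_rows and all(len(r) >= 3 and r[0].isdigit() for r in data_rows):
        ss = "".join(r[2] for r in data_rows)
    else:
        ss = "".join(lines)
    ss = ss.strip().upper()
    bad = set(ss) - set("HEC")
    if bad:
        raise PDBError(f"invalid secondary-structure codes: {sorted(bad)}")
    return ss
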