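"""Reading and writing of crystallographic structure files.

PDB and mmCIF files are parsed (via :mod:`biotite`) into a minimal uniform
in-memory model — a flat list of :class:`AtomRecord` — sufficient for
metal-site analysis: atom identity, residue identity, chain, Cartesian
coordinates in Å, occupancy and altloc.  Only the first model of
multi-model files is used (crystal structures are the target; NMR
ensembles are out of scope), and alternate-location conformers are
resolved to the highest-occupancy copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as _pdb
from biotite.structure.io import pdbx as _pdbx

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Structure",
    "StructureFormatError",
    "read_structure",
    "find_mg_ions",
    "write_pdb",
    "write_mmcif",
]


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    """One crystallographic atom.

    Coordinates are Å as deposited; residue numbering is author numbering,
    so site reports can be read against the literature ("A6", "U41", ...).
    """

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    insertion_code: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"invalid position for atom {self.atom_name}: {self.position}")
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """Hashable residue identity: (chain_id, residue_number, insertion_code)."""
        return (self.chain_id, self.residue_number, self.insertion_code)

    def label(self) -> str:
        """Human-readable residue label in the literature style, e.g. ``U41``."""
        return f"{self.residue_name}{self.residue_number}"


@dataclass
class Structure:
    """An ordered atom collection with provenance."""

    atoms: list[AtomRecord]
    source_format: str = "pdb"
    identifier: str = ""
    _residue_atoms: dict[tuple[str, int, str], frozenset[str]] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def __len__(self) -> int:
        return len(self.atoms)

    def residue_atom_names(self, key: tuple[str, int, str]) -> frozenset[str]:
        """Atom-name set of one residue (used for nucleotide recognition)."""
        if self._residue_atoms is None:
            by_res: dict[tuple[str, int, str], set[str]] = {}
            for a in self.atoms:
                by_res.setdefault(a.residue_key, set()).add(a.atom_name)
            self._residue_atoms = {k: frozenset(v) for k, v in by_res.items()}
        return self._residue_atoms.get(key, frozenset())

    def coordinates(self) -> np.ndarray:
        """(n, 3) coordinate array in atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    # Keep the highest-occupancy conformer; ties broken by altloc id
    # (lexicographic), which is deterministic and standard practice.
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    n_dropped = 0
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code, a.atom_name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            order.append(key)
        else:
            n_dropped += 1
            if (a.occupancy, _altloc_rank(a.altloc)) > (cur.occupancy, _altloc_rank(cur.altloc)):
                best[key] = a
    if n_dropped:
        logger.info("dropped %d alternate-location conformers", n_dropped)
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # Lexicographically smaller altloc wins on an occupancy tie.
    return -ord(altloc) if altloc else 0.0


def _from_atom_array(arr: struc.AtomArray, fmt: str, identifier: str) -> Structure:
    occ = (
        np.asarray(arr.occupancy, dtype=float)
        if "occupancy" in arr.get_annotation_categories()
        else np.ones(arr.array_length())
    )
    occ = np.clip(np.nan_to_num(occ, nan=1.0), 0.0, 1.0)
    alt = (
        np.asarray(arr.get_annotation("altloc_id"))
        if "altloc_id" in arr.get_annotation_categories()
        else np.full(arr.array_length(), "")
    )
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            AtomRecord(
                atom_name=str(arr.atom_name[i]),
                element=str(arr.element[i]).upper(),
                residue_name=str(arr.res_name[i]),
                residue_number=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]),
                position=np.asarray(arr.coord[i], dtype=float),
                occupancy=float(occ[i]),
                altloc=str(alt[i]).strip(),
                insertion_code=str(arr.ins_code[i]).strip(),
            )
        )
    atoms = _resolve_altlocs(atoms)
    if not atoms:
        raise StructureFormatError(f"no atoms parsed from {identifier!r}")
    return Structure(atoms=atoms, source_format=fmt, identifier=identifier)


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".pdb", ".ent"}:
        return "pdb"
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    # Content dispatch: mmCIF files start with a data block.
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "mmcif" if line.startswith("data_") else "pdb"
    raise StructureFormatError(f"{path}: empty file")


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All ATOM/HETATM records of the first model are kept (hydrogens
    included, if present); for alternate locations only the
    highest-occupancy conformer survives.  Multi-model files trigger a
    logged warning.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"pdb"``, ``"mmcif"``, or ``"auto"`` (dispatch on extension,
        then on content).
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read structure file: {path}")
    fmt = format if format != "auto" else _detect_format(path)
    if fmt not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown format {format!r}")
    try:
        if fmt == "pdb":
            pfile = _pdb.PDBFile.read(path)
            n_models = pfile.get_model_count()
            arr = pfile.get_structure(model=1, altloc="all", extra_fields=["occupancy"])
        else:
            cfile = _pdbx.CIFFile.read(path)
            arr = _pdbx.get_structure(cfile, model=1, altloc="all", extra_fields=["occupancy"])
            n_models = 1  # biotite raises if model 1 is absent
    except StructureFormatError:
        raise
    except Exception as exc:
        raise StructureFormatError(f"{path}: could not parse as {fmt}: {exc}") from exc
    if fmt == "pdb" and n_models > 1:
        logger.warning("%s: %d models present; using only the first", path.name, n_models)
    identifier = path.stem
    return _from_atom_array(arr, fmt, identifier)


MG_RESIDUE_NAMES = {"MG", "MO6"}


def find_mg_ions(structure: Structure) -> list[AtomRecord]:
    """All Mg²⁺ atoms of the structure, in file order.

    Selection is by element (with the residue name ``MG`` accepted as a
    fallback for files lacking element columns); an empty list is a valid
    result.
    """
    return [
        a
        for a in structure.atoms
        if a.element == "MG" or (not a.element and a.residue_name in MG_RESIDUE_NAMES)
    ]


def to_atom_array(structure: Structure) -> struc.AtomArray:
    """Convert to a biotite ``AtomArray`` (for file output)."""
    n = len(structure.atoms)
    arr = struc.AtomArray(n)
    arr.coord = structure.coordinates().astype(np.float32)
    arr.chain_id = np.array([a.chain_id for a in structure.atoms])
    arr.res_id = np.array([a.residue_number for a in structure.atoms])
    arr.ins_code = np.array([a.insertion_code for a in structure.atoms])
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = np.array([a.atom_name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    # HETATM for anything that is not a standard polymer residue
    arr.hetero = np.array(
        [a.residue_name in {"HOH", "WAT", "MG", "F", "CL", "NA", "K"} for a in structure.atoms]
    )
    arr.set_annotation("occupancy", np.array([a.occupancy for a in structure.atoms]))
    return arr


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure as a fixed-column PDB file."""
    pfile = _pdb.PDBFile()
    pfile.set_structure(to_atom_array(structure))
    pfile.write(str(path))


def write_mmcif(structure: Structure, path: str | Path) -> None:
    """Write the structure as an mmCIF file (atom_site category)."""
    cfile = _pdbx.CIFFile()
    _pdbx.set_structure(cfile, to_atom_array(structure))
    cfile.write(str(path))
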