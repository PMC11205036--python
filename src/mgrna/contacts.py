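"""Inner- and outer-sphere contact detection around Mg²⁺ ions.

An *inner-sphere* contact is a direct coordination bond from Mg²⁺ to a
ligand heteroatom (phosphate oxygen, ribose oxygen, base N/O, or an
exogenous ion such as F⁻).  An *outer-sphere* contact is a hydrogen bond
from a water in the Mg²⁺ first hydration shell to an RNA heteroatom, the
water bridging metal and RNA.  Crystal structures generally lack
hydrogens, so hydrogen bonds are recognised by a donor–acceptor distance
window with no angular criterion.

Default windows: inner-sphere cutoff 2.6 Å (crystallographic Mg–O sits
near 2.07 Å; 2.6 Å tolerates refinement error while excluding the second
shell) and outer-sphere water-O-to-heteroatom window [2.4, 3.5] Å.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "LigandClass",
    "Contact",
    "MgSite",
    "DetectionParams",
    "classify_ligand",
    "find_inner_sphere",
    "find_outer_sphere",
    "build_site",
]

DEFAULT_INNER_CUTOFF = 2.6
DEFAULT_HBOND_MIN = 2.4
DEFAULT_HBOND_MAX = 3.5

WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}
STANDARD_NUCLEOTIDES = {"A", "U", "G", "C", "I", "DA", "DU", "DG", "DC", "DT", "DI"}

PHOSPHATE_OXYGENS = {"OP1", "OP2", "OP3", "O1P", "O2P", "O3P", "O5'", "O3'", "O5*", "O3*"}
RIBOSE_OXYGENS = {"O2'", "O4'", "O2*", "O4*"}
BASE_HETEROATOMS = {"N1", "N3", "N7", "O2", "O4", "O6", "N6", "N4", "N2"}

# Elements eligible as coordination/H-bond partners; carbon, phosphorus,
# hydrogen and metal cations never count as ligand atoms themselves.
_LIGAND_ELEMENTS = {"O", "N", "F", "CL", "BR", "I", "S", "SE"}


class LigandClass(str, Enum):
    """Ligand-atom category used for contact bookkeeping and site tables."""

    PHOSPHATE_OXYGEN = "phosphate_oxygen"
    RIBOSE_OXYGEN = "ribose_oxygen"
    BASE_HETEROATOM = "base_heteroatom"
    EXOGENOUS = "exogenous"
    WATER = "water"


@dataclass(frozen=True)
class Contact:
    """One Mg–ligand interaction.

    For inner contacts ``distance`` is Mg–ligand; for outer contacts it is
    the bridging-water-oxygen-to-acceptor distance and ``bridging_water``
    carries the first-shell water.
    """

    mg_ref: AtomRecord
    ligand_atom: AtomRecord
    mode: str  # "inner" | "outer"
    ligand_class: LigandClass
    distance: float
    bridging_water: AtomRecord | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("inner", "outer"):
            raise ValueError(f"invalid contact mode {self.mode!r}")
        if self.mode == "outer" and self.bridging_water is None:
            raise ValueError("outer-sphere contact requires a bridging water")
        if self.mode == "inner" and self.bridging_water is not None:
            raise ValueError("inner-sphere contact cannot have a bridging water")
        if not self.distance > 0:
            raise ValueError("contact distance must be positive")


@dataclass
class MgSite:
    """One Mg²⁺ ion with its full contact environment."""

    mg: AtomRecord
    inner_contacts: list[Contact] = field(default_factory=list)
    bound_waters: list[AtomRecord] = field(default_factory=list)
    outer_contacts: list[Contact] = field(default_factory=list)
    structure_id: str = ""

    @property
    def n_inner(self) -> int:
        """Non-water inner-sphere contact count (waters never score)."""
        return len(self.inner_contacts)

    @property
    def n_outer(self) -> int:
        return len(self.outer_contacts)

    @property
    def first_shell_size(self) -> int:
        return len(self.inner_contacts) + len(self.bound_waters)

    def chains_involved(self) -> set[str]:
        """Chains of the RNA/ligand atoms contacted (waters excluded)."""
        return {c.ligand_atom.chain_id for c in self.inner_contacts} | {
            c.ligand_atom.chain_id for c in self.outer_contacts
        }


@dataclass(frozen=True)
class DetectionParams:
    inner_cutoff: float = DEFAULT_INNER_CUTOFF
    hbond_min: float = DEFAULT_HBOND_MIN
    hbond_max: float = DEFAULT_HBOND_MAX

    def __post_init__(self) -> None:
        if not (0.0 < self.inner_cutoff <= 4.0):
            raise ValueError(f"inner cutoff {self.inner_cutoff} outside (0, 4.0] Å")
        if self.hbond_min >= self.hbond_max:
            raise ValueError("hbond_min must be below hbond_max")


def is_water(atom: AtomRecord) -> bool:
    return atom.residue_name in WATER_RESIDUES


def _is_nucleotide(atom: AtomRecord, structure: Structure) -> bool:
    if atom.residue_name in STANDARD_NUCLEOTIDES:
        return True
    # Modified nucleotides: a residue carrying a full phosphate group plus
    # a ribose atom is treated as a nucleotide; anything else is exogenous.
    names = structure.residue_atom_names(atom.residue_key)
    has_phosphate = "P" in names and (
        {"OP1", "OP2"} <= names or {"O1P", "O2P"} <= names
    )
    has_ribose = bool(names & {"C1'", "O4'", "C1*", "O4*"})
    return has_phosphate and has_ribose


def classify_ligand(atom: AtomRecord, structure: Structure) -> LigandClass:
    """Assign the ligand class of a contact atom.

    Backbone oxygens (including the O5'/O3' bridges) are phosphate class;
    O2'/O4' are ribose class; the standard base ring and exocyclic N/O set
    is base class; waters are water; everything else (free anions, other
    hetero groups, non-nucleotide residues) is exogenous.
    """
    if is_water(atom):
        return LigandClass.WATER
    if _is_nucleotide(atom, structure):
        if atom.atom_name in PHOSPHATE_OXYGENS:
            return LigandClass.PHOSPHATE_OXYGEN
        if atom.atom_name in RIBOSE_OXYGENS:
            return LigandClass.RIBOSE_OXYGEN
        if atom.atom_name in BASE_HETEROATOMS:
            return LigandClass.BASE_HETEROATOM
    return LigandClass.EXOGENOUS


class NeighborIndex:
    """k-d tree over the ligand-eligible heteroatoms of a structure.

    Candidate atoms are the non-carbon, non-phosphorus, non-metal
    heteroatoms (O, N, halides, S/Se); building the tree once per
    structure makes per-ion queries cheap.
    """

    def __init__(self, structure: Structure):
        self.structure = structure
        self.atoms = [a for a in structure.atoms if a.element in _LIGAND_ELEMENTS]
        coords = (
            np.array([a.position for a in self.atoms])
            if self.atoms
            else np.empty((0, 3))
        )
        self._tree = cKDTree(coords) if len(self.atoms) else None

    def within(self, center: np.ndarray, radius: float) -> list[tuple[AtomRecord, float]]:
        """Atoms within ``radius`` of ``center``, with distances."""
        if self._tree is None:
            return []
        idx = self._tree.query_ball_point(center, r=radius)
        out = []
        for i in idx:
            d = float(np.linalg.norm(self.atoms[i].position - center))
            out.append((self.atoms[i], d))
        return out


def _sort_key(pair: tuple[AtomRecord, float]) -> tuple:
    a, d = pair
    return (d, a.chain_id, a.residue_number, a.atom_name)


def find_inner_sphere(
    mg: AtomRecord,
    structure: Structure,
    cutoff: float = DEFAULT_INNER_CUTOFF,
    index: NeighborIndex | None = None,
) -> tuple[list[Contact], list[AtomRecord]]:
    """First coordination shell of one Mg²⁺ ion.

    Every eligible heteroatom within ``cutoff`` of the metal is collected
    and partitioned into first-shell waters (``bound_waters``) and
    non-water ligands (``inner_contacts``, classified by
    :class:`LigandClass`).  Atoms of the Mg's own residue are excluded;
    contacts are sorted by distance.
    """
    if not (0.0 < cutoff <= 4.0):
        raise ValueError(f"inner cutoff {cutoff} outside (0, 4.0] Å")
    if index is None:
        index = NeighborIndex(structure)
    hits = [
        (a, d)
        for a, d in index.within(mg.position, cutoff)
        if a.residue_key != mg.residue_key
    ]
    hits.sort(key=_sort_key)
    contacts: list[Contact] = []
    waters: list[AtomRecord] = []
    for atom, dist in hits:
        cls = classify_ligand(atom, structure)
        if cls is LigandClass.WATER:
            # one oxygen per water; hydrogens (if present) are not ligands
            if atom.element == "O":
                waters.append(atom)
        else:
            contacts.append(
                Contact(
                    mg_ref=mg,
                    ligand_atom=atom,
                    mode="inner",
                    ligand_class=cls,
                    distance=dist,
                )
            )
    return contacts, waters


def find_outer_sphere(
    site: MgSite,
    structure: Structure,
    hbond_min: float = DEFAULT_HBOND_MIN,
    hbond_max: float = DEFAULT_HBOND_MAX,
    index: NeighborIndex | None = None,
) -> list[Contact]:
    """Water-mediated outer-sphere contacts of a site.

    For each first-shell water, every RNA/ligand heteroatom whose distance
    to the water oxygen lies in ``[hbond_min, hbond_max]`` yields one
    outer contact.  Waters themselves and atoms already coordinated
    inner-sphere are excluded, and an atom reachable through two bridging
    waters is counted once, keeping the shortest bridge.
    """
    if hbond_min >= hbond_max:
        raise ValueError("hbond_min must be below hbond_max")
    if index is None:
        index = NeighborIndex(structure)
    inner_atoms = {id(c.ligand_atom) for c in site.inner_contacts}
    water_ids = {id(w) for w in site.bound_waters}
    # water residue keys, to exclude self-hits and water-water H-bonds
    best: dict[tuple, tuple[float, AtomRecord, AtomRecord]] = {}
    for water in site.bound_waters:
        for atom, dist in index.within(water.position, hbond_max):
            if dist < hbond_min:
                continue
            if is_water(atom):
                continue
            if id(atom) in inner_atoms or id(atom) in water_ids:
                continue
            if atom.residue_key == site.mg.residue_key:
                continue
            key = (atom.chain_id, atom.residue_number, atom.insertion_code, atom.atom_name)
            cur = best.get(key)
            if cur is None or dist < cur[0]:
                best[key] = (dist, atom, water)
    contacts = [
        Contact(
            mg_ref=site.mg,
            ligand_atom=atom,
            mode="outer",
            ligand_class=classify_ligand(atom, structure),
            distance=dist,
            bridging_water=water,
        )
        for dist, atom, water in best.values()
    ]
    contacts.sort(key=lambda c: _sort_key((c.ligand_atom, c.distance)))
    return contacts


def build_site(
    mg: AtomRecord,
    structure: Structure,
    params: DetectionParams | None = None,
    index: NeighborIndex | None = None,
) -> MgSite:
    """Full contact environment of one Mg²⁺ ion (inner then outer shell)."""
    params = params or DetectionParams()
    if index is None:
        index = NeighborIndex(structure)
    inner, waters = find_inner_sphere(mg, structure, params.inner_cutoff, index=index)
    site = MgSite(
        mg=mg,
        inner_contacts=inner,
        bound_waters=waters,
        structure_id=structure.identifier,
    )
    site.outer_contacts = find_outer_sphere(
        site, structure, params.hbond_min, params.hbond_max, index=index
    )
    if site.first_shell_size > 6:
        logger.warning(
            "Mg %s/%d: %d first-shell ligands exceeds octahedral expectation",
            mg.chain_id,
            mg.residue_number,
            site.first_shell_size,
        )
    return site
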