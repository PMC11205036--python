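"""Shared helpers: structure builders and the brute-force contact oracle."""

from __future__ import annotations

import numpy as np
import pytest

from mgrna.structure_io import AtomRecord, Structure

# Elements a contact atom may have; mirrors the detector's eligibility rule
# but is applied here by exhaustive O(n^2) scanning, with no spatial index.
_ORACLE_ELEMENTS = {"O", "N", "F", "CL", "BR", "I", "S", "SE"}
_WATERS = {"HOH", "WAT", "DOD", "H2O"}


def atom(
    name,
    element,
    res_name,
    res_num,
    chain="A",
    pos=(0.0, 0.0, 0.0),
    occupancy=1.0,
    altloc="",
    icode="",
):
    return AtomRecord(
        atom_name=name,
        element=element,
        residue_name=res_name,
        residue_number=res_num,
        chain_id=chain,
        position=np.asarray(pos, dtype=float),
        occupancy=occupancy,
        altloc=altloc,
        insertion_code=icode,
    )


def make_structure(atoms, identifier="test"):
    return Structure(atoms=list(atoms), source_format="pdb", identifier=identifier)


def _akey(a: AtomRecord):
    return (a.chain_id, a.residue_number, a.insertion_code, a.atom_name)


def brute_force_site(structure, mg, inner_cutoff=2.6, hbond_min=2.4, hbond_max=3.5):
    """Independent all-pairs contact scan.

    Returns (inner, waters, outer) as identity/distance sets:
    inner  = {(atom key, distance)}
    waters = {atom key}
    outer  = {(atom key, distance, bridging water key)} with the shortest
    bridge kept when an atom is reachable through several waters.
    """
    inner = set()
    waters = {}
    for a in structure.atoms:
        if a is mg or a.residue_key == mg.residue_key:
            continue
        if a.element not in _ORACLE_ELEMENTS:
            continue
        d = float(np.linalg.norm(a.position - mg.position))
        if d <= inner_cutoff:
            if a.residue_name in _WATERS:
                if a.element == "O":
                    waters[_akey(a)] = a
            else:
                inner.add((_akey(a), round(d, 9)))
    inner_keys = {k for k, _ in inner}
    best = {}
    for wkey, w in waters.items():
        for a in structure.atoms:
            if a.element not in _ORACLE_ELEMENTS or a.residue_name in _WATERS:
                continue
            if _akey(a) in inner_keys or a.residue_key == mg.residue_key:
                continue
            d = float(np.linalg.norm(a.position - w.position))
            if hbond_min <= d <= hbond_max:
                cur = best.get(_akey(a))
                if cur is None or d < cur[0]:
                    best[_akey(a)] = (d, wkey)
    outer = {(k, round(d, 9), wkey) for k, (d, wkey) in best.items()}
    return inner, set(waters), outer


def site_as_sets(site):
    """Project a detected MgSite onto the oracle's set representation."""
    inner = {(_akey(c.ligand_atom), round(c.distance, 9)) for c in site.inner_contacts}
    waters = {_akey(w) for w in site.bound_waters}
    outer = {
        (_akey(c.ligand_atom), round(c.distance, 9), _akey(c.bridging_water))
        for c in site.outer_contacts
    }
    return inner, waters, outer


@pytest.fixture
def simple_mg_structure():
    """Mg with 4 phosphate oxygens at 2.07 Å and 2 waters at 2.10 Å."""
    d = 2.07
    atoms = [
        atom("MG", "MG", "MG", 1, "M"),
        atom("OP1", "O", "A", 6, "A", (d, 0, 0)),
        atom("OP1", "O", "U", 7, "A", (0, d, 0)),
        atom("OP1", "O", "U", 41, "A", (-d, 0, 0)),
        atom("OP1", "O", "G", 42, "A", (0, -d, 0)),
        atom("O", "O", "HOH", 101, "W", (0, 0, 2.10)),
        atom("O", "O", "HOH", 102, "W", (0, 0, -2.10)),
    ]
    return make_structure(atoms)
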