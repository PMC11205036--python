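"""Inner/outer-sphere detection against brute-force scans and edge rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgrna.contacts import (
    DetectionParams,
    LigandClass,
    MgSite,
    build_site,
    classify_ligand,
    find_inner_sphere,
    find_outer_sphere,
)
from mgrna.fixtures import FixtureSpec, build_fixture
from mgrna.structure_io import find_mg_ions

from conftest import atom, brute_force_site, make_structure, site_as_sets


def test_ideal_octahedron_partition(simple_mg_structure):
    mg = find_mg_ions(simple_mg_structure)[0]
    inner, waters = find_inner_sphere(mg, simple_mg_structure, cutoff=2.6)
    assert len(inner) == 4
    assert all(c.ligand_class is LigandClass.PHOSPHATE_OXYGEN for c in inner)
    assert all(c.mode == "inner" and c.bridging_water is None for c in inner)
    assert len(waters) == 2
    # sorted by distance: the 2.07 Å phosphates precede nothing closer
    assert [round(c.distance, 2) for c in inner] == [2.07] * 4


def test_atom_outside_cutoff_ignored():
    atoms = [atom("MG", "MG", "MG", 1, "M"), atom("OP1", "O", "U", 5, "A", (3.0, 0, 0))]
    s = make_structure(atoms)
    inner, waters = find_inner_sphere(s.atoms[0], s, cutoff=2.6)
    assert inner == [] and waters == []
    inner, _ = find_inner_sphere(s.atoms[0], s, cutoff=3.2)
    assert len(inner) == 1


def test_isolated_mg_empty_site():
    s = make_structure([atom("MG", "MG", "MG", 1, "M")])
    site = build_site(s.atoms[0], s)
    assert site.n_inner == 0 and site.n_outer == 0 and site.bound_waters == []


def test_cutoff_validation(simple_mg_structure):
    mg = find_mg_ions(simple_mg_structure)[0]
    for bad in (0.0, -1.0, 4.5):
        with pytest.raises(ValueError):
            find_inner_sphere(mg, simple_mg_structure, cutoff=bad)
    with pytest.raises(ValueError):
        DetectionParams(hbond_min=3.5, hbond_max=2.4)


def test_outer_sphere_window():
    d = 2.07
    atoms = [
        atom("MG", "MG", "MG", 1, "M"),
        atom("O", "O", "HOH", 101, "W", (d, 0, 0)),
        atom("OP1", "O", "U", 5, "A", (d + 2.8, 0, 0)),  # 2.8 Å from water
        atom("OP1", "O", "U", 9, "A", (d, 3.6, 0)),  # 3.6 Å from water
    ]
    s = make_structure(atoms)
    site = build_site(s.atoms[0], s)
    assert len(site.bound_waters) == 1
    assert site.n_outer == 1
    contact = site.outer_contacts[0]
    assert contact.ligand_class is LigandClass.PHOSPHATE_OXYGEN
    assert contact.distance == pytest.approx(2.8)
    assert contact.bridging_water is site.bound_waters[0]


def test_no_waters_no_outer_contacts(simple_mg_structure):
    mg = find_mg_ions(simple_mg_structure)[0]
    site = MgSite(mg=mg, inner_contacts=[], bound_waters=[])
    assert find_outer_sphere(site, simple_mg_structure) == []


def test_two_water_bridge_counted_once():
    d = 2.07
    atoms = [
        atom("MG", "MG", "MG", 1, "M"),
        atom("O", "O", "HOH", 101, "W", (d, 0, 0)),
        atom("O", "O", "HOH", 102, "W", (0, d, 0)),
        atom("OP1", "O", "U", 5, "A", (2.6, 2.4, 0)),  # reachable from both waters
    ]
    s = make_structure(atoms)
    site = build_site(s.atoms[0], s)
    assert site.n_outer == 1
    c = site.outer_contacts[0]
    d1 = np.linalg.norm(np.array([2.6, 2.4, 0]) - np.array([d, 0, 0]))
    assert c.distance == pytest.approx(float(d1))  # shortest bridge kept
    assert c.bridging_water.residue_number == 101


def test_inner_atoms_excluded_from_outer():
    # a trans ligand sits 2.07+2.07 = 4.14 Å from the water: outside the
    # window; a cis ligand at ~2.93 Å would be inside but is inner-sphere
    d = 2.07
    atoms = [
        atom("MG", "MG", "MG", 1, "M"),
        atom("O", "O", "HOH", 101, "W", (d, 0, 0)),
        atom("OP1", "O", "U", 5, "A", (0, d, 0)),
    ]
    s = make_structure(atoms)
    site = build_site(s.atoms[0], s)
    assert site.n_inner == 1
    assert site.n_outer == 0


def test_ligand_classification_rules():
    # classification needs residue context for the modified-nucleotide rule
    base = [
        atom("MG", "MG", "MG", 1, "M"),
        atom("OP1", "O", "U", 5, "A", (2.07, 0, 0)),
        atom("O3'", "O", "G", 6, "A", (0, 2.07, 0)),
        atom("O2'", "O", "C", 7, "A", (-2.07, 0, 0)),
        atom("N7", "N", "A", 8, "A", (0, -2.07, 0)),
        atom("F", "F", "F", 9, "A", (0, 0, 2.07)),
        # modified nucleotide: non-standard name, phosphate + ribose atom set
        atom("OP2", "O", "5MC", 10, "A", (0, 0, -2.07)),
        atom("P", "P", "5MC", 10, "A", (30, 30, 30)),
        atom("OP1", "O", "5MC", 10, "A", (31, 30, 30)),
        atom("O4'", "O", "5MC", 10, "A", (30, 31, 30)),
        # bare hetero group: oxygen of an unknown ligand
        atom("O1", "O", "LIG", 11, "A", (1.2, 1.2, 1.0)),
    ]
    s = make_structure(base)
    expected = {
        ("U", 5): LigandClass.PHOSPHATE_OXYGEN,
        ("G", 6): LigandClass.PHOSPHATE_OXYGEN,  # O3' bridge counts as phosphate
        ("C", 7): LigandClass.RIBOSE_OXYGEN,
        ("A", 8): LigandClass.BASE_HETEROATOM,
        ("F", 9): LigandClass.EXOGENOUS,
        ("5MC", 10): LigandClass.PHOSPHATE_OXYGEN,
        ("LIG", 11): LigandClass.EXOGENOUS,
    }
    seen = {}
    for a in s.atoms:
        if a.residue_name in ("MG",) or a.position[0] > 20:
            continue
        seen[(a.residue_name, a.residue_number)] = classify_ligand(a, s)
    assert seen == expected


@pytest.mark.parametrize("seed", range(8))
def test_fixture_recovery_matches_ground_truth(seed):
    spec = FixtureSpec(
        n_inner_pi=2,
        n_inner_ribose=1,
        n_waters=3,
        outer_acceptors_per_water=(("pi", "base"), ("ribose",), ()),
        motif_template="ten_ring",
        noise_sd=0.05,
        seed=seed,
    )
    s = build_fixture(spec)
    site = build_site(find_mg_ions(s)[0], s)
    assert site.n_inner == 3
    assert len(site.bound_waters) == 3
    assert site.n_outer == 3


@pytest.mark.parametrize("seed", range(5))
def test_spatial_search_equals_brute_force(seed):
    spec = FixtureSpec(
        n_inner_pi=3,
        n_inner_other=1,
        n_waters=2,
        outer_acceptors_per_water=(("pi", "base", "ribose"), ("pi",)),
        motif_template="ten_ring_plus_distant_pi",
        noise_sd=0.03,
        seed=seed,
    )
    s = build_fixture(spec)
    mg = find_mg_ions(s)[0]
    site = build_site(mg, s)
    assert site_as_sets(site) == brute_force_site(s, mg)


@given(st.floats(min_value=1.0, max_value=4.0), st.integers(0, 50))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_cutoff_monotonicity(cutoff, seed):
    """Enlarging the inner cutoff never removes a contact."""
    rng = np.random.default_rng(seed)
    atoms = [atom("MG", "MG", "MG", 1, "M")]
    for i in range(25):
        pos = rng.uniform(-4, 4, size=3)
        atoms.append(atom("OP1", "O", "U", 5 + i, "A", pos))
    s = make_structure(atoms)
    mg = s.atoms[0]
    small, _ = find_inner_sphere(mg, s, cutoff=min(cutoff, 2.6))
    large, _ = find_inner_sphere(mg, s, cutoff=max(cutoff, 2.6))
    small_keys = {(c.ligand_atom.residue_number, c.ligand_atom.atom_name) for c in small}
    large_keys = {(c.ligand_atom.residue_number, c.ligand_atom.atom_name) for c in large}
    assert small_keys <= large_keys


def test_determinism_byte_identical(tmp_path):
    from mgrna.pipeline import analyze_file
    from mgrna.site_table import write_site_table
    from mgrna.fixtures import write_fixture

    spec = FixtureSpec(
        n_inner_pi=2, n_waters=2, outer_acceptors_per_water=(("pi",),),
        motif_template="ten_ring", noise_sd=0.02, seed=11,
    )
    path = tmp_path / "s.pdb"
    write_fixture(spec, path)
    outputs = []
    for i in range(2):
        out = tmp_path / f"r{i}.tsv"
        write_site_table([a.to_row() for a in analyze_file(path)], out)
        outputs.append(out.read_bytes())
    assert outputs[0] == outputs[1]
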