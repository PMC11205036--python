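"""Chelate-ring pairing, motif taxonomy, and packing flags."""

import numpy as np
import pytest

from mgrna.contacts import build_site
from mgrna.fixtures import FixtureSpec, build_fixture
from mgrna.motifs import classify_motif, find_ten_ring_pairs, flag_symmetry_artifact
from mgrna.structure_io import AtomRecord, Structure, find_mg_ions

from conftest import atom, make_structure

_DIRS = [
    (1, 0, 0), (0, 1, 0), (-1, 0, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]


def _site_with_phosphates(residues, icodes=None):
    """Mg plus OP1 phosphate contacts on the given (chain, number) residues."""
    icodes = icodes or [""] * len(residues)
    atoms = [atom("MG", "MG", "MG", 1, "M")]
    for (chain, num), icode, d in zip(residues, icodes, _DIRS):
        atoms.append(
            atom("OP1", "O", "U", num, chain, 2.07 * np.asarray(d, float), icode=icode)
        )
    s = make_structure(atoms)
    return build_site(s.atoms[0], s)


def test_adjacent_pair_found():
    site = _site_with_phosphates([("A", 6), ("A", 7)])
    pairs = find_ten_ring_pairs(site)
    assert len(pairs) == 1
    assert pairs[0].residues == (("A", 6), ("A", 7))
    assert pairs[0].bite_angle == pytest.approx(90.0)


def test_non_adjacent_and_cross_chain_not_paired():
    assert find_ten_ring_pairs(_site_with_phosphates([("A", 10), ("A", 14)])) == []
    assert find_ten_ring_pairs(_site_with_phosphates([("A", 6), ("B", 7)])) == []


def test_insertion_code_breaks_adjacency():
    site = _site_with_phosphates([("A", 6), ("A", 7)], icodes=["", "A"])
    assert find_ten_ring_pairs(site) == []


def test_two_pairs_found():
    site = _site_with_phosphates([("A", 6), ("A", 7), ("A", 41), ("A", 42)])
    pairs = find_ten_ring_pairs(site)
    assert {p.residues for p in pairs} == {(("A", 6), ("A", 7)), (("A", 41), ("A", 42))}


def test_greedy_pairing_prefers_shorter_combined_distance():
    # residue 7 is adjacent to both 6 and 8; 6 sits closer to the Mg
    atoms = [
        atom("MG", "MG", "MG", 1, "M"),
        atom("OP1", "O", "U", 6, "A", (2.05, 0, 0)),
        atom("OP1", "O", "U", 7, "A", (0, 2.07, 0)),
        atom("OP1", "O", "U", 8, "A", (-2.45, 0, 0)),
    ]
    s = make_structure(atoms)
    site = build_site(s.atoms[0], s)
    pairs = find_ten_ring_pairs(site)
    assert len(pairs) == 1
    assert pairs[0].residues == (("A", 6), ("A", 7))


@pytest.mark.parametrize(
    "residues,label,packing",
    [
        ([("A", 6), ("A", 7), ("A", 41), ("A", 42)], "magnesium_clamp", False),
        ([("A", 6), ("A", 7), ("B", 33)], "y_clamp", True),
        ([("A", 6), ("A", 7), ("A", 30)], "y_clamp", False),
        ([("A", 6), ("A", 7)], "ten_membered_ring", False),
        ([("A", 6)], "other", False),
        ([], "other", False),
    ],
)
def test_motif_precedence(residues, label, packing):
    site = _site_with_phosphates(residues)
    assignment = classify_motif(site)
    assert assignment.label == label
    assert assignment.packing_suspect is packing


def test_adjacent_third_phosphate_is_not_a_y_clamp():
    # third phosphate at separation 1 from the pair: not "distant"
    site = _site_with_phosphates([("A", 6), ("A", 7), ("A", 8)])
    assignment = classify_motif(site)
    assert assignment.label == "ten_membered_ring"


def test_clamp_requires_ring_pairs():
    for residues in ([("A", 6), ("A", 7), ("A", 41), ("A", 42)], [("A", 6), ("A", 7), ("B", 33)]):
        assignment = classify_motif(_site_with_phosphates(residues))
        if assignment.label in ("magnesium_clamp", "y_clamp"):
            assert len(assignment.ring_pairs) >= 1


def test_renumbering_offset_invariance():
    base = [("A", 6), ("A", 7), ("A", 30)]
    for offset in (0, 100, -3):
        shifted = [(c, n + offset) for c, n in base]
        assert classify_motif(_site_with_phosphates(shifted)).label == "y_clamp"


def test_chain_relabel_invariance():
    one = classify_motif(_site_with_phosphates([("A", 6), ("A", 7), ("B", 33)]))
    two = classify_motif(_site_with_phosphates([("Q", 6), ("Q", 7), ("R", 33)]))
    assert one.label == two.label == "y_clamp"
    assert one.packing_suspect and two.packing_suspect


def test_flag_symmetry_artifact_messages():
    flagged, message = flag_symmetry_artifact(
        _site_with_phosphates([("A", 6), ("A", 7), ("B", 33)])
    )
    assert flagged and "A" in message and "B" in message
    clean, message = flag_symmetry_artifact(_site_with_phosphates([("B", 6), ("B", 7)]))
    assert not clean and message == ""
    empty_site = build_site(
        make_structure([atom("MG", "MG", "MG", 1, "M")]).atoms[0],
        make_structure([atom("MG", "MG", "MG", 1, "M")]),
    )
    assert flag_symmetry_artifact(empty_site)[0] is False


def test_outer_contacts_count_toward_packing():
    # inner sphere on one chain, an outer contact on another chain
    atoms = [
        atom("MG", "MG", "MG", 1, "M"),
        atom("OP1", "O", "U", 6, "A", (2.07, 0, 0)),
        atom("OP1", "O", "U", 7, "A", (0, 2.07, 0)),
        atom("O", "O", "HOH", 101, "W", (0, 0, 2.07)),
        atom("OP1", "O", "C", 40, "B", (0, 0, 4.87)),
    ]
    s = make_structure(atoms)
    site = build_site(s.atoms[0], s)
    assert site.n_outer == 1
    assert classify_motif(site).packing_suspect is True


@pytest.mark.parametrize(
    "template,n_pi,expected",
    [
        ("none", 2, "other"),
        ("ten_ring", 2, "ten_membered_ring"),
        ("ten_ring_plus_distant_pi", 3, "y_clamp"),
        ("two_ten_rings_one_chain", 4, "magnesium_clamp"),
        ("two_chains_bridge", 3, "y_clamp"),
    ],
)
def test_motif_templates_detected(template, n_pi, expected):
    spec = FixtureSpec(n_inner_pi=n_pi, motif_template=template, noise_sd=0.02, seed=4)
    s = build_fixture(spec)
    site = build_site(find_mg_ions(s)[0], s)
    assert classify_motif(site).label == expected
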