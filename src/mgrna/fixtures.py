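"""Synthetic Mg²⁺ coordination fixtures with exact ground truth.

Each fixture is an idealised crystallographic scene: one Mg²⁺ at the
origin of an octahedral frame, first-shell ligand and water oxygens at
2.07 Å along octahedral axes, and second-shell hydrogen-bond acceptors
at 2.8 Å from their bridging water — both distances sitting well inside
the default detection windows with ≥ 0.3 Å margin.  Residue numbering
and chain topology are chosen per *motif template* so that chelate-ring
detection has a known answer (consecutive numbering for a 10-membered
ring; a second chain for a bridging site).

Noise model: the whole assembly receives a random rigid rotation and
translation, and every non-metal atom is jittered *radially* (along its
direction from the Mg) by a Gaussian of the requested standard
deviation.  This perturbs every detection-relevant distance while
leaving ligand–Mg–ligand angles exact, so the generated labels remain
valid ground truth at any noise level that respects the distance
margins.  Stereochemistry is not simulated: parent-residue scaffold
atoms (P, OP2, C1') live in a remote block, and only topology and
distances are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from itertools import cycle
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import AtomRecord, Structure, write_pdb

__all__ = ["FixtureSpec", "GroundTruth", "build_fixture", "ground_truth", "write_fixture"]

MG_LIGAND_DISTANCE = 2.07  # Å, ideal crystallographic Mg–O
WATER_ACCEPTOR_DISTANCE = 2.8  # Å, water-O to H-bond acceptor

_AXES = {
    "+x": np.array([1.0, 0.0, 0.0]),
    "-x": np.array([-1.0, 0.0, 0.0]),
    "+y": np.array([0.0, 1.0, 0.0]),
    "-y": np.array([0.0, -1.0, 0.0]),
    "+z": np.array([0.0, 0.0, 1.0]),
    "-z": np.array([0.0, 0.0, -1.0]),
}
# Fill order keeps consecutive entries cis, so a chelate-ring pair sits at
# 90° and four phosphates span the equatorial plane with the axial slots
# (e.g. for a bound anion) last.
_FILL_ORDER = ["+x", "+y", "-x", "-y", "+z", "-z"]

_GEOMETRY_DIRECTIONS = {
    "cis": ["+x", "+y"],
    "trans": ["+x", "-x"],
    "fac": ["+x", "+y", "+z"],
    "mer": ["+x", "-x", "+y"],
}

GEOMETRY_TEMPLATES = ("cis", "trans", "fac", "mer", "octahedral_full")
MOTIF_TEMPLATES = (
    "none",
    "ten_ring",
    "two_ten_rings_one_chain",
    "ten_ring_plus_distant_pi",
    "two_chains_bridge",
)
ACCEPTOR_CLASSES = ("pi", "ribose", "base")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic site; ground truth derives from it alone."""

    n_inner_pi: int = 0
    n_inner_ribose: int = 0
    n_inner_other: int = 0
    n_waters: int = 0
    outer_acceptors_per_water: tuple[tuple[str, ...], ...] = ()
    geometry_template: str = "octahedral_full"
    motif_template: str = "none"
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def n_inner(self) -> int:
        return self.n_inner_pi + self.n_inner_ribose + self.n_inner_other

    @property
    def n_outer(self) -> int:
        return sum(len(a) for a in self.outer_acceptors_per_water)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "outer_acceptors_per_water",
            tuple(tuple(w) for w in self.outer_acceptors_per_water),
        )
        if min(self.n_inner_pi, self.n_inner_ribose, self.n_inner_other, self.n_waters) < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.geometry_template not in GEOMETRY_TEMPLATES:
            raise ValueError(f"unknown geometry template {self.geometry_template!r}")
        if self.motif_template not in MOTIF_TEMPLATES:
            raise ValueError(f"unknown motif template {self.motif_template!r}")
        if self.n_inner + self.n_waters > 6:
            raise ValueError("octahedral shell over-full: inner ligands + waters > 6")
        arity = {"cis": 2, "trans": 2, "fac": 3, "mer": 3}.get(self.geometry_template)
        if arity is not None and self.n_inner != arity:
            raise ValueError(
                f"{self.geometry_template} template requires exactly {arity} inner ligands"
            )
        if len(self.outer_acceptors_per_water) > self.n_waters:
            raise ValueError("more acceptor groups than waters")
        for group in self.outer_acceptors_per_water:
            if len(group) > 4:
                raise ValueError("at most 4 acceptors per bridging water")
            for cls in group:
                if cls not in ACCEPTOR_CLASSES:
                    raise ValueError(f"unknown acceptor class {cls!r}")
        minimum_pi = {
            "none": 0,
            "ten_ring": 2,
            "two_ten_rings_one_chain": 4,
            "ten_ring_plus_distant_pi": 3,
            "two_chains_bridge": 2,
        }[self.motif_template]
        if self.n_inner_pi < minimum_pi:
            raise ValueError(
                f"motif template {self.motif_template!r} requires ≥ {minimum_pi} inner phosphates"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Expected pipeline output, derived from the recipe without coordinates."""

    n_inner: int
    n_inner_pi: int
    n_inner_ribose: int
    n_inner_other: int
    n_waters: int
    n_outer: int
    n_outer_pi: int
    n_outer_ribose: int
    n_outer_base: int
    geometry_label: str | None
    motif_label: str
    packing_suspect: bool
    dg_inner_total: Decimal
    dg_outer_total: Decimal
    dg_total: Decimal


def _pi_residues(spec: FixtureSpec) -> list[tuple[str, int]]:
    """(chain, residue number) for each inner phosphate, per motif template."""
    n = spec.n_inner_pi
    out: list[tuple[str, int]] = []
    if spec.motif_template == "none":
        out = [("A", 5 + 5 * i) for i in range(n)]
    elif spec.motif_template == "ten_ring":
        out = [("A", 6), ("A", 7)] + [("A", 20 + 5 * i) for i in range(n - 2)]
    elif spec.motif_template == "two_ten_rings_one_chain":
        out = [("A", 6), ("A", 7), ("A", 41), ("A", 42)] + [
            ("A", 60 + 5 * i) for i in range(n - 4)
        ]
    elif spec.motif_template == "ten_ring_plus_distant_pi":
        out = [("A", 6), ("A", 7), ("A", 30)] + [("A", 60 + 5 * i) for i in range(n - 3)]
    elif spec.motif_template == "two_chains_bridge":
        if n >= 3:
            out = [("A", 6), ("A", 7)] + [("B", 33 + 10 * i) for i in range(n - 2)]
        else:
            out = [("A", 6), ("B", 33)][:n]
    return out


def ground_truth(spec: FixtureSpec) -> GroundTruth:
    """Expected detection/classification/scoring result for a fixture.

    Derived from the recipe alone (counts, template topology, and the
    additive per-contact energies) — never from the generated coordinates
    — so it serves as an independent oracle for the pipeline.
    """
    n_outer_pi = sum(g.count("pi") for g in spec.outer_acceptors_per_water)
    n_outer_ribose = sum(g.count("ribose") for g in spec.outer_acceptors_per_water)
    n_outer_base = sum(g.count("base") for g in spec.outer_acceptors_per_water)

    if spec.geometry_template in _GEOMETRY_DIRECTIONS:
        geometry = spec.geometry_template
    else:  # octahedral_full fill order: cis, then equatorial plane, then axial
        geometry = {0: None, 1: "mono", 2: "cis", 3: "mer", 4: "trans"}.get(
            spec.n_inner, "other"
        )

    n_pi = spec.n_inner_pi
    template = spec.motif_template
    if template in ("ten_ring", "two_chains_bridge") and n_pi == 2:
        motif = "ten_membered_ring" if template == "ten_ring" else "other"
    elif template == "ten_ring" and n_pi >= 3:
        motif = "y_clamp"  # extras are placed sequence-distant
    elif template == "two_ten_rings_one_chain":
        motif = "magnesium_clamp"
    elif template == "ten_ring_plus_distant_pi":
        motif = "y_clamp"
    elif template == "two_chains_bridge":
        motif = "y_clamp"
    else:
        motif = "other"

    dg_is = spec.n_inner * Decimal("-3.3")
    dg_os = spec.n_outer * Decimal("-1.2")
    return GroundTruth(
        n_inner=spec.n_inner,
        n_inner_pi=spec.n_inner_pi,
        n_inner_ribose=spec.n_inner_ribose,
        n_inner_other=spec.n_inner_other,
        n_waters=spec.n_waters,
        n_outer=spec.n_outer,
        n_outer_pi=n_outer_pi,
        n_outer_ribose=n_outer_ribose,
        n_outer_base=n_outer_base,
        geometry_label=geometry,
        motif_label=motif,
        packing_suspect=spec.motif_template == "two_chains_bridge",
        dg_inner_total=dg_is,
        dg_outer_total=dg_os,
        dg_total=dg_is + dg_os,
    )


def _perpendicular_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(d, e1)


def _acceptor_position(water_pos: np.ndarray, d: np.ndarray, k: int) -> np.ndarray:
    """k-th acceptor of one water: straight out, then on a 45° cone."""
    if k == 0:
        return water_pos + WATER_ACCEPTOR_DISTANCE * d
    e1, e2 = _perpendicular_frame(d)
    azimuth = np.radians(120.0 * (k - 1))
    direction = np.cos(np.radians(45.0)) * d + np.sin(np.radians(45.0)) * (
        np.cos(azimuth) * e1 + np.sin(azimuth) * e2
    )
    return water_pos + WATER_ACCEPTOR_DISTANCE * direction


def build_fixture(spec: FixtureSpec) -> Structure:
    """Materialise a fixture recipe as a coordinate :class:`Structure`.

    Atom layout: Mg at the (pre-transform) origin; inner ligands on the
    template axes; waters on the remaining axes in fill order; acceptors
    fanning outward from their water; each nucleotide residue's scaffold
    atoms (P / OP2 / C1') in a far-away block so they can never enter a
    detection window.
    """
    rng = np.random.default_rng(spec.seed)
    base_names = cycle(["A", "U", "G", "C"])
    atoms: list[AtomRecord] = []

    def add(name, element, res_name, res_num, chain, pos):
        atoms.append(
            AtomRecord(
                atom_name=name,
                element=element,
                residue_name=res_name,
                residue_number=res_num,
                chain_id=chain,
                position=np.asarray(pos, dtype=float),
            )
        )

    mg = AtomRecord(
        atom_name="MG",
        element="MG",
        residue_name="MG",
        residue_number=1,
        chain_id="M",
        position=np.zeros(3),
    )
    atoms.append(mg)

    # --- first shell -----------------------------------------------------
    if spec.geometry_template in _GEOMETRY_DIRECTIONS:
        inner_axes = list(_GEOMETRY_DIRECTIONS[spec.geometry_template])
    else:
        inner_axes = _FILL_ORDER[: spec.n_inner]
    water_axes = [ax for ax in _FILL_ORDER if ax not in inner_axes][: spec.n_waters]

    scaffold_index = 0

    def scaffold_origin() -> np.ndarray:
        nonlocal scaffold_index
        scaffold_index += 1
        return np.array([30.0 + 6.0 * scaffold_index, 30.0, 30.0])

    def add_nucleotide_scaffold(res_name, res_num, chain, with_phosphate):
        origin = scaffold_origin()
        if with_phosphate:
            add("P", "P", res_name, res_num, chain, origin)
            add("OP2", "O", res_name, res_num, chain, origin + [1.5, 0.0, 0.0])
        add("C1'", "C", res_name, res_num, chain, origin + [0.0, 1.5, 0.0])

    axis_iter = iter(inner_axes)
    for chain, res_num in _pi_residues(spec):
        d = _AXES[next(axis_iter)]
        name = next(base_names)
        add("OP1", "O", name, res_num, chain, MG_LIGAND_DISTANCE * d)
        add_nucleotide_scaffold(name, res_num, chain, with_phosphate=True)
    for i in range(spec.n_inner_ribose):
        d = _AXES[next(axis_iter)]
        name = next(base_names)
        add("O2'", "O", name, 50 + 2 * i, "A", MG_LIGAND_DISTANCE * d)
        add_nucleotide_scaffold(name, 50 + 2 * i, "A", with_phosphate=False)
    for i in range(spec.n_inner_other):
        d = _AXES[next(axis_iter)]
        add("F", "F", "F", 91 + i, "A", MG_LIGAND_DISTANCE * d)

    water_positions: list[np.ndarray] = []
    water_dirs: list[np.ndarray] = []
    for i, ax in enumerate(water_axes):
        d = _AXES[ax]
        pos = MG_LIGAND_DISTANCE * d
        add("O", "O", "HOH", 101 + i, "W", pos)
        water_positions.append(pos)
        water_dirs.append(d)

    # --- second shell ----------------------------------------------------
    acceptor_res = 150
    for w_idx, group in enumerate(spec.outer_acceptors_per_water):
        for k, cls in enumerate(group):
            pos = _acceptor_position(water_positions[w_idx], water_dirs[w_idx], k)
            name = next(base_names)
            if cls == "pi":
                add("OP1", "O", name, acceptor_res, "A", pos)
                add_nucleotide_scaffold(name, acceptor_res, "A", with_phosphate=True)
            elif cls == "ribose":
                add("O2'", "O", name, acceptor_res, "A", pos)
                add_nucleotide_scaffold(name, acceptor_res, "A", with_phosphate=False)
            else:
                add("N7", "N", name, acceptor_res, "A", pos)
                add_nucleotide_scaffold(name, acceptor_res, "A", with_phosphate=False)
            acceptor_res += 2

    # --- noise: radial jitter, then a rigid rotation + translation -------
    if spec.noise_sd > 0:
        jittered = []
        for a in atoms:
            r = np.linalg.norm(a.position)
            if a.atom_name == "MG" or r < 1e-9:
                jittered.append(a)
                continue
            shift = rng.normal(0.0, spec.noise_sd)
            pos = a.position * (1.0 + shift / r)
            jittered.append(
                AtomRecord(
                    atom_name=a.atom_name,
                    element=a.element,
                    residue_name=a.residue_name,
                    residue_number=a.residue_number,
                    chain_id=a.chain_id,
                    position=pos,
                )
            )
        atoms = jittered
    rotation = Rotation.random(rng=rng)
    translation = rng.uniform(-10.0, 10.0, size=3)
    atoms = [
        AtomRecord(
            atom_name=a.atom_name,
            element=a.element,
            residue_name=a.residue_name,
            residue_number=a.residue_number,
            chain_id=a.chain_id,
            position=rotation.apply(a.position) + translation,
        )
        for a in atoms
    ]
    return Structure(atoms=atoms, source_format="pdb", identifier=f"fixture-{spec.seed}")


def write_fixture(spec: FixtureSpec, path: str | Path) -> Structure:
    """Build a fixture and write it as a strict fixed-column PDB file."""
    structure = build_fixture(spec)
    write_pdb(structure, path)
    return structure


def example_site_specs(seed: int = 0, noise_sd: float = 0.0) -> dict[str, FixtureSpec]:
    """Synthetic stand-ins for the three published example binding modes.

    Each recipe reproduces the *contact topology* of a well-characterised
    site class — not the deposited coordinates, which are not shipped:

    * ``synthetic_fluoride_riboswitch_site`` — two chelate-ring phosphate
      pairs in the equatorial plane plus an axial fluoride: five
      inner-sphere contacts, no outer sphere (ΔG_b = −16.5 kcal/mol).
    * ``synthetic_glycine_riboswitch_site`` — phosphates from two chains
      plus an inner ribose oxygen, with three water-mediated base
      contacts (ΔG_b = −13.5 kcal/mol); inter-chain, so packing-suspect.
    * ``synthetic_ribozyme_site`` — a single inner phosphate and six
      outer-sphere contacts through five waters (ΔG_b = −10.5 kcal/mol).
    """
    return {
        "synthetic_fluoride_riboswitch_site": FixtureSpec(
            n_inner_pi=4,
            n_inner_other=1,
            n_waters=1,
            geometry_template="octahedral_full",
            motif_template="two_ten_rings_one_chain",
            noise_sd=noise_sd,
            seed=seed,
        ),
        "synthetic_glycine_riboswitch_site": FixtureSpec(
            n_inner_pi=2,
            n_inner_ribose=1,
            n_waters=3,
            outer_acceptors_per_water=(("base",), ("base",), ("base",)),
            geometry_template="octahedral_full",
            motif_template="two_chains_bridge",
            noise_sd=noise_sd,
            seed=seed + 1,
        ),
        "synthetic_ribozyme_site": FixtureSpec(
            n_inner_pi=1,
            n_waters=5,
            outer_acceptors_per_water=(("pi",), ("pi",), ("pi",), ("ribose",), ("base", "base")),
            geometry_template="octahedral_full",
            motif_template="none",
            noise_sd=noise_sd,
            seed=seed + 2,
        ),
    }
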