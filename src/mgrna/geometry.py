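"""Coordination-geometry labels for the non-water inner-sphere ligand set.

Mg²⁺ is octahedral; the arrangement of the RNA (non-water) ligands on the
octahedron is labelled with the classical coordination-isomer vocabulary:
two ligands at ~90° are *cis*, at ~180° *trans*; three ligands on one
octahedral face are *fac*, in one plane with a trans pair *mer*.  A single
ligand is *mono*; arrangements matching none of these are *other*.

The default angular tolerance is a generous 30° because RNA chelate rings
(notably the 10-membered ring's O–Mg–O bite) distort ideal octahedral
angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .contacts import MgSite

logger = logging.getLogger(__name__)

__all__ = ["GeometryAssignment", "GeometryError", "classify_geometry", "ligand_angles"]

DEFAULT_ANGLE_TOLERANCE = 30.0


class GeometryError(ValueError):
    """Raised when no geometry label is defined for a site."""


@dataclass(frozen=True)
class GeometryAssignment:
    n_ligands: int
    pairwise_angles: tuple[float, ...]  # ligand–Mg–ligand, degrees
    label: str  # cis | trans | fac | mer | mono | other
    angle_tolerance: float


def angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two vectors in degrees, in (0, 180]."""
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def ligand_angles(site: MgSite) -> tuple[float, ...]:
    """All pairwise ligand–Mg–ligand angles over non-water inner ligands."""
    vecs = [c.ligand_atom.position - site.mg.position for c in site.inner_contacts]
    return tuple(angle_deg(v1, v2) for v1, v2 in combinations(vecs, 2))


def _is_cis(angle: float, tol: float) -> bool:
    return 90.0 - tol <= angle <= 90.0 + tol


def _is_trans(angle: float, tol: float) -> bool:
    return angle >= 180.0 - tol


def classify_geometry(
    site: MgSite, tolerance: float = DEFAULT_ANGLE_TOLERANCE
) -> GeometryAssignment:
    """Label the arrangement of the non-water inner-sphere ligands.

    * 1 ligand → ``mono``.
    * 2 ligands → ``cis`` (≈90°), ``trans`` (≈180°), else ``other``.
    * 3 ligands → ``fac`` when all three pairs are cis, ``mer`` when
      exactly one pair is trans and the remaining pairs cis, else
      ``other``.
    * 4 ligands → the dominant octahedral pattern: two mutually trans
      pairs (the planar arrangement) map to ``trans``; four mutually cis
      map to ``cis``; else ``other``.
    * ≥5 ligands → ``other`` (logged; no such motif is expected).

    Raises :class:`GeometryError` for a site with no non-water inner
    ligand, where the label is undefined.
    """
    n = len(site.inner_contacts)
    if n == 0:
        raise GeometryError("geometry label undefined for a site without RNA inner-sphere ligands")
    angles = ligand_angles(site)
    tol = float(tolerance)

    if n == 1:
        label = "mono"
    elif n == 2:
        a = angles[0]
        label = "cis" if _is_cis(a, tol) else "trans" if _is_trans(a, tol) else "other"
    elif n == 3:
        n_trans = sum(_is_trans(a, tol) for a in angles)
        n_cis = sum(_is_cis(a, tol) for a in angles)
        if n_cis == 3:
            label = "fac"
        elif n_trans == 1 and n_cis == 2:
            label = "mer"
        else:
            label = "other"
    elif n == 4:
        trans_pairs = _disjoint_trans_pairs(site, tol)
        if trans_pairs >= 2:
            label = "trans"
        elif all(_is_cis(a, tol) for a in angles):
            label = "cis"
        else:
            label = "other"
    else:
        logger.info(
            "site %s Mg %d: %d non-water inner ligands; labelling 'other'",
            site.structure_id,
            site.mg.residue_number,
            n,
        )
        label = "other"
    return GeometryAssignment(
        n_ligands=n, pairwise_angles=angles, label=label, angle_tolerance=tol
    )


def _disjoint_trans_pairs(site: MgSite, tol: float) -> int:
    """Count disjoint mutually-trans ligand pairs (greedy, by angle)."""
    vecs = [c.ligand_atom.position - site.mg.position for c in site.inner_contacts]
    pairs = sorted(
        (
            (angle_deg(vecs[i], vecs[j]), i, j)
            for i, j in combinations(range(len(vecs)), 2)
        ),
        key=lambda t: -t[0],
    )
    used: set[int] = set()
    count = 0
    for a, i, j in pairs:
        if _is_trans(a, tol) and i not in used and j not in used:
            used.update((i, j))
            count += 1
    return count
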