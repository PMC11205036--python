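"""Phosphate chelate motif taxonomy and crystal-packing flags.

The fundamental high-affinity Mg²⁺ motif in RNA is the *10-membered
ring*: the metal chelated by phosphate oxygens of two sequence-adjacent
nucleotides, closing a ten-atom ring through the sugar–phosphate
backbone (the RNA analogue of a classical cis chelate).  Composite
motifs build on it:

* *magnesium clamp* — two 10-membered-ring pairs chelating one ion
  (e.g. bridging two strand segments);
* *Y-clamp* — one ring pair plus a third, sequence-distant or
  other-chain phosphate, giving a mer/T-shaped arrangement.

Sites whose contacts span two or more chains are flagged as
crystal-packing suspects: without symmetry-operator bookkeeping an
inter-chain bridge cannot be distinguished from a packing artifact, and
such sites are unlikely to survive in solution, so they are marked for
user review rather than interpreted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .contacts import Contact, LigandClass, MgSite
from .geometry import angle_deg

logger = logging.getLogger(__name__)

__all__ = [
    "TenRingPair",
    "MotifAssignment",
    "find_ten_ring_pairs",
    "classify_motif",
    "flag_symmetry_artifact",
]

# Minimum sequence separation for the Y-clamp's "distant" third phosphate.
DISTANT_SEPARATION = 2


@dataclass(frozen=True)
class TenRingPair:
    """Two inner-sphere phosphate oxygens from consecutive residues."""

    residue_a: tuple[str, int]  # (chain_id, residue_number)
    residue_b: tuple[str, int]
    atoms: tuple[Contact, Contact]
    bite_angle: float  # O–Mg–O, degrees

    @property
    def residues(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.residue_a, self.residue_b)


@dataclass
class MotifAssignment:
    label: str  # ten_membered_ring | magnesium_clamp | y_clamp | other
    ring_pairs: list[TenRingPair] = field(default_factory=list)
    extra_phosphates: list[Contact] = field(default_factory=list)
    chains_involved: set[str] = field(default_factory=set)
    packing_suspect: bool = False


def _phosphate_contacts(site: MgSite) -> list[Contact]:
    return [c for c in site.inner_contacts if c.ligand_class is LigandClass.PHOSPHATE_OXYGEN]


def find_ten_ring_pairs(site: MgSite) -> list[TenRingPair]:
    """Maximal pairing of inner phosphate oxygens on consecutive residues.

    Adjacency means author residue numbers differing by exactly 1 within
    one chain; insertion codes break adjacency.  When a phosphate could
    pair with two partners the pair with the smaller combined Mg distance
    wins (greedy, logged), and each contact joins at most one pair.
    """
    phosphates = _phosphate_contacts(site)
    candidates = []
    for i in range(len(phosphates)):
        for j in range(i + 1, len(phosphates)):
            a, b = phosphates[i], phosphates[j]
            ra, rb = a.ligand_atom, b.ligand_atom
            if ra.chain_id != rb.chain_id:
                continue
            if ra.insertion_code or rb.insertion_code:
                continue
            if abs(ra.residue_number - rb.residue_number) != 1:
                continue
            if ra.residue_key == rb.residue_key:
                continue
            candidates.append((a.distance + b.distance, i, j))
    candidates.sort(key=lambda t: t[0])
    if len(candidates) > 1 and len({i for _, i, j in candidates} | {j for _, i, j in candidates}) < 2 * len(candidates):
        logger.info("ten-ring pairing: overlapping candidates resolved greedily by combined Mg distance")
    used: set[int] = set()
    pairs: list[TenRingPair] = []
    for _, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        a, b = phosphates[i], phosphates[j]
        if a.ligand_atom.residue_number > b.ligand_atom.residue_number:
            a, b = b, a
        bite = angle_deg(
            a.ligand_atom.position - site.mg.position,
            b.ligand_atom.position - site.mg.position,
        )
        pairs.append(
            TenRingPair(
                residue_a=(a.ligand_atom.chain_id, a.ligand_atom.residue_number),
                residue_b=(b.ligand_atom.chain_id, b.ligand_atom.residue_number),
                atoms=(a, b),
                bite_angle=bite,
            )
        )
    return pairs


def _is_distant(contact: Contact, pair: TenRingPair) -> bool:
    atom = contact.ligand_atom
    (chain_a, num_a), (chain_b, num_b) = pair.residues
    if atom.chain_id != chain_a:
        return True
    return all(
        abs(atom.residue_number - n) >= DISTANT_SEPARATION for n in (num_a, num_b)
    )


def classify_motif(site: MgSite, pairs: list[TenRingPair] | None = None) -> MotifAssignment:
    """Assign the chelate-motif label of a site.

    Precedence: two ring pairs → ``magnesium_clamp``; one ring pair plus
    at least one additional, sequence-distant (separation ≥ 2) or
    other-chain inner phosphate → ``y_clamp``; any ring pair otherwise →
    ``ten_membered_ring``; else ``other``.  The clamp-before-ring order
    resolves the overlap between the two-pair ring reading and the clamp
    (logged when it fires); both the label and the pair list are reported
    so either reading can be applied downstream.

    ``packing_suspect`` is set when the site's inner or outer contacts
    span two or more chains.
    """
    if pairs is None:
        pairs = find_ten_ring_pairs(site)
    paired_ids = {id(c) for p in pairs for c in p.atoms}
    extra = [c for c in _phosphate_contacts(site) if id(c) not in paired_ids]
    chains = site.chains_involved()
    packing = len(chains) >= 2

    if len(pairs) >= 2:
        label = "magnesium_clamp"
        logger.info(
            "site %s Mg %d: two 10-membered-ring pairs; clamp label takes precedence",
            site.structure_id,
            site.mg.residue_number,
        )
    elif len(pairs) == 1 and any(_is_distant(c, pairs[0]) for c in extra):
        label = "y_clamp"
    elif len(pairs) >= 1:
        label = "ten_membered_ring"
    else:
        label = "other"
    return MotifAssignment(
        label=label,
        ring_pairs=pairs,
        extra_phosphates=extra,
        chains_involved=chains,
        packing_suspect=packing,
    )


def flag_symmetry_artifact(site: MgSite) -> tuple[bool, str]:
    """Flag sites whose contacts bridge several chains.

    Inter-chain bridges in a crystal frequently reflect packing rather
    than solution chemistry; the flag marks the site for review (no
    functional role should be inferred from a packing site) and the
    message names the chains involved.
    """
    chains = sorted(site.chains_involved())
    if len(chains) >= 2:
        return True, (
            f"Mg {site.mg.chain_id}/{site.mg.residue_number} bridges chains "
            f"{', '.join(chains)}; possible crystal-packing artifact — review before "
            "inferring a functional role"
        )
    return False, ""
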