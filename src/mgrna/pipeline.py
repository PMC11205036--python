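"""End-to-end site analysis: structure file in, ranked site table out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path

from . import contacts, geometry, motifs, thermo
from .contacts import DetectionParams, LigandClass, MgSite, NeighborIndex
from .site_table import LigandLabel, SiteRow
from .structure_io import Structure, find_mg_ions, read_structure
from .thermo import EnergyParameters, RoleBounds

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SiteAnalysis", "analyze_structure", "analyze_file"]


@dataclass(frozen=True)
class RunConfig:
    """Effective parameter set of one analysis run."""

    inner_cutoff: float = contacts.DEFAULT_INNER_CUTOFF
    hbond_min: float = contacts.DEFAULT_HBOND_MIN
    hbond_max: float = contacts.DEFAULT_HBOND_MAX
    angle_tolerance: float = geometry.DEFAULT_ANGLE_TOLERANCE
    dg_inner: Decimal = Decimal("-3.3")
    dg_outer: Decimal = Decimal("-1.2")
    role_bounds: tuple[Decimal, Decimal] = (Decimal("-13.2"), Decimal("-9.0"))

    def detection_params(self) -> DetectionParams:
        return DetectionParams(self.inner_cutoff, self.hbond_min, self.hbond_max)

    def energy_params(self) -> EnergyParameters:
        return EnergyParameters(self.dg_inner, self.dg_outer)

    def role_bounds_obj(self) -> RoleBounds:
        lo, hi = sorted(self.role_bounds)
        return RoleBounds(structural_at_or_below=lo, charge_neutralization_above=hi)


@dataclass
class SiteAnalysis:
    """All per-site results for one Mg²⁺ ion."""

    site: MgSite
    geometry: geometry.GeometryAssignment | None
    motif: motifs.MotifAssignment
    energy: thermo.EnergyReport
    packing_message: str = ""

    def to_row(self) -> SiteRow:
        def labels(mode_contacts, wanted: set[LigandClass]) -> list[LigandLabel]:
            return [
                LigandLabel.parse(c.ligand_atom.label())
                for c in mode_contacts
                if c.ligand_class in wanted
            ]

        inner = self.site.inner_contacts
        outer = self.site.outer_contacts
        return SiteRow(
            pdb_id=self.site.structure_id,
            is_pi=labels(inner, {LigandClass.PHOSPHATE_OXYGEN}),
            is_ribose=labels(inner, {LigandClass.RIBOSE_OXYGEN}),
            is_other=labels(inner, {LigandClass.BASE_HETEROATOM, LigandClass.EXOGENOUS}),
            os_pi=labels(outer, {LigandClass.PHOSPHATE_OXYGEN}),
            os_ribose=labels(outer, {LigandClass.RIBOSE_OXYGEN}),
            os_base=labels(outer, {LigandClass.BASE_HETEROATOM, LigandClass.EXOGENOUS}),
            dg_is=self.energy.dg_inner_total,
            dg_os=self.energy.dg_outer_total,
            dg_total=self.energy.dg_total,
            motif=self.motif.label,
            role=self.energy.role,
            packing_suspect=self.motif.packing_suspect,
        )


def analyze_structure(structure: Structure, config: RunConfig | None = None) -> list[SiteAnalysis]:
    """Detect, classify, and score every Mg²⁺ site of a structure.

    Results are ranked by total binding free energy (most negative first;
    ties by inner-contact count, then file order).  A structure without
    Mg²⁺ yields an empty list with a logged warning.
    """
    config = config or RunConfig()
    ions = find_mg_ions(structure)
    if not ions:
        logger.warning("%s: no Mg ions found", structure.identifier or "structure")
        return []
    index = NeighborIndex(structure)
    params = config.detection_params()
    energy_params = config.energy_params()
    bounds = config.role_bounds_obj()
    analyses: list[SiteAnalysis] = []
    for mg in ions:
        site = contacts.build_site(mg, structure, params, index=index)
        if site.inner_contacts:
            geom = geometry.classify_geometry(site, config.angle_tolerance)
        else:
            geom = None
        motif = motifs.classify_motif(site)
        suspect, message = motifs.flag_symmetry_artifact(site)
        if suspect:
            logger.warning("%s", message)
        energy = thermo.score_site(site, energy_params, bounds)
        logger.info(
            "Mg %s/%d: %d inner, %d waters, %d outer; geometry=%s motif=%s ΔG=%s (%s)",
            mg.chain_id,
            mg.residue_number,
            site.n_inner,
            len(site.bound_waters),
            site.n_outer,
            geom.label if geom else "n/a",
            motif.label,
            energy.dg_total,
            energy.role,
        )
        analyses.append(
            SiteAnalysis(
                site=site,
                geometry=geom,
                motif=motif,
                energy=energy,
                packing_message=message,
            )
        )
    analyses.sort(key=lambda a: (a.energy.dg_total, -a.energy.n_inner))
    return analyses


def analyze_file(
    path: str | Path, config: RunConfig | None = None, format: str = "auto"
) -> list[SiteAnalysis]:
    """Convenience wrapper: read a PDB/mmCIF file and analyze it."""
    return analyze_structure(read_structure(path, format=format), config)
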