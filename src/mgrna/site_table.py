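"""Per-site contact tables (TSV/CSV) and coordinate-free rescoring.

The table format mirrors the published per-site layout: one row per Mg²⁺
site, with comma-separated residue-label lists for each contact class —
inner-sphere phosphate / ribose / other, outer-sphere phosphate / ribose
/ base — plus the component and total binding free energies, the motif
and role labels, and the packing flag.  Energies are always recomputable
from the ligand lists alone, so tables can be (re)scored without
coordinates.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from decimal import Decimal
from pathlib import Path

from .thermo import EnergyParameters, RoleBounds, score_from_counts

logger = logging.getLogger(__name__)

__all__ = ["SiteRow", "LigandLabel", "SiteTableError", "parse_site_table", "write_site_table", "rescore_rows"]

COLUMNS = [
    "pdb_id",
    "is_pi",
    "is_ribose",
    "is_other",
    "os_pi",
    "os_ribose",
    "os_base",
    "dg_is",
    "dg_os",
    "dg_total",
    "motif",
    "role",
    "packing_suspect",
]
_MANDATORY = COLUMNS[:7]
_LIGAND_COLUMNS = COLUMNS[1:7]

# "A6", "G32", "U41:B" (optional chain suffix); anything else is kept verbatim.
_LABEL_RE = re.compile(r"^([A-Za-z]{1,3})(\d+)(?::([A-Za-z0-9]))?$")


class SiteTableError(ValueError):
    """Raised for a structurally invalid site table."""


@dataclass(frozen=True)
class LigandLabel:
    """One residue label from a ligand-list cell.

    The verbatim token is always preserved; ``base``/``number``/``chain``
    are filled when the token parses as a residue label.
    """

    raw: str
    base: str | None = None
    number: int | None = None
    chain: str | None = None

    @classmethod
    def parse(cls, token: str) -> "LigandLabel":
        token = token.strip()
        m = _LABEL_RE.match(token)
        if m is None:
            return cls(raw=token)
        return cls(raw=token, base=m.group(1), number=int(m.group(2)), chain=m.group(3))

    def __str__(self) -> str:
        return self.raw


@dataclass
class SiteRow:
    """One magnesium site as a table row."""

    pdb_id: str
    is_pi: list[LigandLabel] = field(default_factory=list)
    is_ribose: list[LigandLabel] = field(default_factory=list)
    is_other: list[LigandLabel] = field(default_factory=list)
    os_pi: list[LigandLabel] = field(default_factory=list)
    os_ribose: list[LigandLabel] = field(default_factory=list)
    os_base: list[LigandLabel] = field(default_factory=list)
    dg_is: Decimal = Decimal("0")
    dg_os: Decimal = Decimal("0")
    dg_total: Decimal = Decimal("0")
    motif: str = ""
    role: str = ""
    packing_suspect: bool = False

    @property
    def n_inner(self) -> int:
        return len(self.is_pi) + len(self.is_ribose) + len(self.is_other)

    @property
    def n_outer(self) -> int:
        return len(self.os_pi) + len(self.os_ribose) + len(self.os_base)


def _parse_ligands(cell: str) -> list[LigandLabel]:
    cell = cell.strip()
    if not cell:
        return []
    labels = []
    for token in cell.split(","):
        token = token.strip()
        if not token:
            continue
        label = LigandLabel.parse(token)
        if label.base is None:
            logger.warning("unparseable ligand token %r kept verbatim", token)
        labels.append(label)
    return labels


def _parse_energy(cell: str) -> Decimal | None:
    # The published tables print U+2212 for the minus sign; accept both.
    cell = cell.strip().replace("−", "-")
    if not cell:
        return None
    try:
        return Decimal(cell)
    except Exception:
        logger.warning("unparseable energy value %r ignored", cell)
        return None


def _detect_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    delim = "\t" if "\t" in header else ","
    logger.debug("site table %s: delimiter %r", path.name, delim)
    return delim


def parse_site_table(
    path: str | Path,
    params: EnergyParameters | None = None,
) -> list[SiteRow]:
    """Read a per-site table, recomputing energies from the ligand lists.

    The delimiter is autodetected (tab preferred, comma fallback).  When a
    row tabulates an energy that disagrees with the value recomputed from
    its ligand lists, the discrepancy is logged and the recomputed value
    is kept.
    """
    path = Path(path)
    params = params or EnergyParameters()
    delim = _detect_delimiter(path)
    rows: list[SiteRow] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in _MANDATORY if c not in header]
        if missing:
            raise SiteTableError(f"{path}: missing mandatory columns {missing}")
        for record in reader:
            row = SiteRow(
                pdb_id=(record.get("pdb_id") or "").strip(),
                **{col: _parse_ligands(record.get(col) or "") for col in _LIGAND_COLUMNS},
            )
            report = score_from_counts(row.n_inner, row.n_outer, params)
            for col, recomputed in (
                ("dg_is", report.dg_inner_total),
                ("dg_os", report.dg_outer_total),
                ("dg_total", report.dg_total),
            ):
                tabulated = _parse_energy(record.get(col) or "")
                if tabulated is not None and tabulated != recomputed:
                    logger.warning(
                        "%s row %r: tabulated %s=%s disagrees with recomputed %s",
                        path.name,
                        row.pdb_id,
                        col,
                        tabulated,
                        recomputed,
                    )
            row.dg_is = report.dg_inner_total
            row.dg_os = report.dg_outer_total
            row.dg_total = report.dg_total
            row.motif = (record.get("motif") or "").strip()
            row.role = (record.get("role") or "").strip()
            row.packing_suspect = (record.get("packing_suspect") or "").strip().lower() in (
                "true",
                "1",
                "yes",
            )
            rows.append(row)
    return rows


def _fmt_energy(value: Decimal) -> str:
    # one decimal place, ASCII hyphen-minus
    return str(value.quantize(Decimal("0.1")))


def _fmt_ligands(labels: list[LigandLabel]) -> str:
    return ", ".join(str(l) for l in labels)


def write_site_table(rows: list[SiteRow], path) -> None:
    """Write rows as a TSV in canonical column order (input row order kept).

    ``path`` may be a filesystem path or an open text stream.
    """
    if hasattr(path, "write"):
        _write_rows(rows, path)
        return
    with open(Path(path), "w", encoding="utf-8", newline="") as fh:
        _write_rows(rows, fh)


def _write_rows(rows: list[SiteRow], fh) -> None:
    writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
    writer.writerow(COLUMNS)
    for row in rows:
        writer.writerow(
            [
                row.pdb_id,
                _fmt_ligands(row.is_pi),
                _fmt_ligands(row.is_ribose),
                _fmt_ligands(row.is_other),
                _fmt_ligands(row.os_pi),
                _fmt_ligands(row.os_ribose),
                _fmt_ligands(row.os_base),
                _fmt_energy(row.dg_is),
                _fmt_energy(row.dg_os),
                _fmt_energy(row.dg_total),
                row.motif,
                row.role,
                "true" if row.packing_suspect else "false",
            ]
        )


def rescore_rows(
    rows: list[SiteRow],
    params: EnergyParameters | None = None,
    bounds: RoleBounds | None = None,
) -> list[SiteRow]:
    """Recompute energies and roles from ligand lists under new parameters.

    Structure-derived columns (motif, packing flag) pass through.
    """
    out = []
    for row in rows:
        report = score_from_counts(row.n_inner, row.n_outer, params, bounds)
        out.append(
            replace(
                row,
                dg_is=report.dg_inner_total,
                dg_os=report.dg_outer_total,
                dg_total=report.dg_total,
                role=report.role,
            )
        )
    return out
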