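"""Additive binding-free-energy model for Mg²⁺–RNA sites.

Each inner-sphere contact contributes −3.3 kcal/mol and each
water-mediated outer-sphere contact −1.2 kcal/mol (experimental
per-contact values); the site total is

    ΔG_b = n_IS · ΔG_IS + n_OS · ΔG_OS

with first-shell waters contributing nothing themselves.  A single
per-contact inner-sphere value is used for all ligand classes — no
class-resolved experimental energies exist, and the inner/outer gap
dwarfs any class distinction.

The total maps onto a functional-role class:

* ``charge_neutralization`` for ΔG_b > −9 kcal/mol — weak, largely
  outer-sphere ions balancing backbone charge;
* ``structural`` for ΔG_b ≤ −13.2 kcal/mol (the energy of four
  inner-sphere phosphates, i.e. two chelate ring pairs) — high-affinity,
  motif-stabilizing ions saturated at physiological free Mg²⁺;
* ``transition`` in between, around the ~−10 kcal/mol crossover where
  minimal inner-sphere and compensatory outer-sphere modes coexist.

Energies are carried as exact decimals (tenths of kcal/mol) so tabulated
totals reproduce bit-exactly with no floating-point accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal

from .contacts import MgSite

__all__ = [
    "EnergyParameters",
    "RoleBounds",
    "EnergyReport",
    "score_from_counts",
    "score_site",
    "classify_role",
    "rank_sites",
]


def _dec(x: float | int | str | Decimal) -> Decimal:
    """Exact decimal from a user-supplied number (via its repr, not its bits)."""
    return x if isinstance(x, Decimal) else Decimal(str(x))


@dataclass(frozen=True)
class EnergyParameters:
    """Per-contact binding free energies, kcal/mol."""

    dg_inner: Decimal = Decimal("-3.3")
    dg_outer: Decimal = Decimal("-1.2")

    def __post_init__(self) -> None:
        object.__setattr__(self, "dg_inner", _dec(self.dg_inner))
        object.__setattr__(self, "dg_outer", _dec(self.dg_outer))
        if not (self.dg_inner < self.dg_outer < 0):
            raise ValueError(
                "require dg_inner < dg_outer < 0: an inner-sphere bond always "
                f"outweighs an outer-sphere hydrogen bond (got {self.dg_inner}, {self.dg_outer})"
            )


@dataclass(frozen=True)
class RoleBounds:
    """ΔG_b boundaries (kcal/mol) between the functional-role classes."""

    charge_neutralization_above: Decimal = Decimal("-9.0")
    structural_at_or_below: Decimal = Decimal("-13.2")

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "charge_neutralization_above", _dec(self.charge_neutralization_above)
        )
        object.__setattr__(self, "structural_at_or_below", _dec(self.structural_at_or_below))
        if not self.structural_at_or_below < self.charge_neutralization_above:
            raise ValueError("structural bound must lie below the charge-neutralization bound")


@dataclass(frozen=True)
class EnergyReport:
    """Contact counts, component and total binding free energy, role."""

    n_inner: int
    n_outer: int
    dg_inner_total: Decimal
    dg_outer_total: Decimal
    dg_total: Decimal
    role: str


def classify_role(dg_total: float | Decimal, bounds: RoleBounds | None = None) -> str:
    """Functional-role class of a site from its total binding free energy."""
    bounds = bounds or RoleBounds()
    dg = _dec(dg_total)
    if dg > bounds.charge_neutralization_above:
        return "charge_neutralization"
    if dg <= bounds.structural_at_or_below:
        return "structural"
    return "transition"


def score_from_counts(
    n_inner: int,
    n_outer: int,
    params: EnergyParameters | None = None,
    bounds: RoleBounds | None = None,
) -> EnergyReport:
    """Score a site from its inner- and outer-sphere contact counts.

    ``n_inner`` counts non-water inner-sphere contacts only; first-shell
    waters carry no energy of their own.
    """
    if n_inner < 0 or n_outer < 0:
        raise ValueError("contact counts must be non-negative")
    params = params or EnergyParameters()
    # multiplying by a zero count yields Decimal("-0.0"); normalise the sign
    dg_is = n_inner * params.dg_inner if n_inner else Decimal("0.0")
    dg_os = n_outer * params.dg_outer if n_outer else Decimal("0.0")
    total = dg_is + dg_os
    return EnergyReport(
        n_inner=n_inner,
        n_outer=n_outer,
        dg_inner_total=dg_is,
        dg_outer_total=dg_os,
        dg_total=total,
        role=classify_role(total, bounds),
    )


def score_site(
    site: MgSite,
    params: EnergyParameters | None = None,
    bounds: RoleBounds | None = None,
) -> EnergyReport:
    """Score a detected site (all non-water inner contacts count equally)."""
    return score_from_counts(site.n_inner, site.n_outer, params, bounds)


def rank_sites(reports: list[EnergyReport]) -> list[EnergyReport]:
    """Order sites by affinity: most negative ΔG_b first.

    Ties are broken by inner-contact count (more inner first), then by
    input order (stable sort).
    """
    return sorted(reports, key=lambda r: (r.dg_total, -r.n_inner))
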