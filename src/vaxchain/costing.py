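"""Vaccine costing: administration, wasted doses, and disposal.

The cost of using a vial presentation over a simulated year is the sum
of three components:

* administration — doses administered times (price per dose + injection
  syringe cost), plus one reconstitution syringe per opened vial for
  lyophilized presentations (oral vaccines consume no injection
  syringe);
* wasted doses — open-vial wasted doses times price per dose (zero by
  construction for 1-dose vials);
* disposal — a safety-box cost per administered dose plus the waste
  disposal cost per gram applied to the mass of discarded vials and
  syringes (empty-vial masses; residual liquid mass is not published).

Cost per injection is total cost over doses administered.  Unknown
prices or masses (the 2-dose measles presentation) raise
:class:`~vaxchain.catalog.MissingCostError` rather than being imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .catalog import Catalog, CostInputs, MissingCostError, VaccinePresentation
from .engine import SimulationResults

__all__ = [
    "CostBreakdown",
    "administration_cost",
    "wasted_dose_cost",
    "disposal_cost",
    "cost_per_injection",
    "scenario_cost",
    "cost_report",
]


@dataclass
class CostBreakdown:
    administration_cost: float
    wasted_dose_cost: float
    disposal_cost: float
    doses_administered: int

    @property
    def total(self) -> float:
        return self.administration_cost + self.wasted_dose_cost + self.disposal_cost

    @property
    def cost_per_injection(self) -> float:
        return cost_per_injection(self.total, self.doses_administered)


def administration_cost(
    doses_administered: int,
    vials_opened: int,
    costs: CostInputs,
    presentation: VaccinePresentation,
) -> float:
    """doses x (price + injection syringe) + opened vials x reconstitution
    syringe (lyophilized only; oral routes use no injection syringe)."""
    if doses_administered < 0 or vials_opened < 0:
        raise ValueError("counts must be >= 0")
    price = presentation.require_price()
    syringe = costs.injection_syringe_cost if presentation.needs_injection_syringe else 0.0
    recon = (
        costs.reconstitution_syringe_cost * vials_opened
        if presentation.formulation == "lyophilized"
        else 0.0
    )
    return doses_administered * (price + syringe) + recon


def wasted_dose_cost(n_wasted: int, price_per_dose: float | None) -> float:
    """Open-vial wasted doses times price per dose."""
    if n_wasted < 0:
        raise ValueError("n_wasted must be >= 0")
    if n_wasted == 0:
        return 0.0
    if price_per_dose is None:
        raise MissingCostError(
            "price per dose unknown; cannot cost wasted doses"
        )
    return n_wasted * price_per_dose


def disposal_cost(
    vials_discarded: dict[int, int],
    reconstitution_syringes: int,
    injection_syringes: int,
    doses_administered: int,
    costs: CostInputs,
) -> float:
    """Safety-box cost per administered dose plus the per-gram disposal
    rate applied to discarded vial and syringe mass.

    ``vials_discarded`` maps doses-per-vial to counts (masses differ by
    vial size)."""
    mass = 0.0
    for size, count in vials_discarded.items():
        if count < 0:
            raise ValueError("counts must be >= 0")
        if count:
            mass += count * costs.require_vial_mass(size)
    mass += reconstitution_syringes * costs.reconstitution_syringe_mass_g
    mass += injection_syringes * costs.injection_syringe_mass_g
    return (
        costs.effective_safety_box_cost() * doses_administered
        + costs.waste_disposal_cost_per_g * mass
    )


def cost_per_injection(total: float, doses_administered: int) -> float:
    """Total cost over administered doses; NaN when nothing was
    administered (undefined, reported missing)."""
    if doses_administered < 0:
        raise ValueError("doses_administered must be >= 0")
    if doses_administered == 0:
        return math.nan
    return total / doses_administered


def scenario_cost(
    results: SimulationResults,
    catalog: Catalog,
    costs: CostInputs,
    antigen: str = "M",
) -> CostBreakdown:
    """Mean-over-replications cost breakdown for one antigen's scenario.

    Counts (doses administered, vials opened, open-vial waste) are
    averaged over replications and rounded to whole units before the
    cost equations are applied.  For a 1-dose presentation the wasted
    dose component is identically zero, so total = administration +
    disposal."""
    p = catalog.active_presentation(antigen)
    n = len(results.replications)
    administered = round(
        sum(
            st.administered
            for rep in results.replications
            for (c, a), st in rep.clinic_stats.items()
            if a == antigen
        )
        / n
    )
    vials_opened = round(
        sum(
            st.vials_opened
            for rep in results.replications
            for (c, a), st in rep.clinic_stats.items()
            if a == antigen
        )
        / n
    )
    waste = round(
        sum(rep.ledgers[antigen].open_vial_waste for rep in results.replications) / n
    )
    admin = administration_cost(administered, vials_opened, costs, p)
    wasted = wasted_dose_cost(waste, p.price_per_dose) if waste else 0.0
    recon = vials_opened if p.formulation == "lyophilized" else 0
    syringes = administered if p.needs_injection_syringe else 0
    disposal = disposal_cost(
        {p.doses_per_vial: vials_opened}, recon, syringes, administered, costs
    )
    return CostBreakdown(
        administration_cost=admin,
        wasted_dose_cost=wasted,
        disposal_cost=disposal,
        doses_administered=administered,
    )


def cost_report(
    breakdowns: dict[str, CostBreakdown]
) -> pd.DataFrame:
    """One row per scenario: components, total, administered doses, cost
    per injection (cents precision for reporting)."""
    rows = []
    for name, b in breakdowns.items():
        rows.append(
            {
                "scenario": name,
                "administration_cost_usd": b.administration_cost,
                "wasted_dose_cost_usd": b.wasted_dose_cost,
                "disposal_cost_usd": b.disposal_cost,
                "total_cost_usd": b.total,
                "doses_administered": b.doses_administered,
                "cost_per_injection_usd": round(b.cost_per_injection, 2)
                if not math.isnan(b.cost_per_injection)
                else math.nan,
            }
        )
    return pd.DataFrame(rows)
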