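"""Vaccine presentation catalog and cost-input tables.

A *presentation* is one antigen in one packaging format: its doses per
vial, per-dose packaged volume, formulation (lyophilized vaccines are
reconstituted with diluent and must be discarded at the end of the
session in which the vial was opened; liquid vaccines may be kept up to
28 days after opening under the multi-dose vial policy), storage
temperature class and price.  A :class:`Catalog` holds every bundled
presentation plus an *active* map naming, per antigen, the presentation
currently in the immunization schedule — the vial-size substitution
experiments are expressed by switching the active measles presentation.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "VaccinePresentation",
    "Catalog",
    "CostInputs",
    "CatalogSchemaError",
    "CatalogValidationError",
    "PresentationLookupError",
    "MissingCostError",
    "load_vaccine_catalog",
    "save_vaccine_catalog",
    "default_catalog",
    "load_cost_inputs",
    "default_cost_inputs",
    "substitute_presentation",
    "adjust_cost_year",
]


class CatalogSchemaError(ValueError):
    """A catalog/cost file is structurally invalid (missing column, empty)."""


class CatalogValidationError(ValueError):
    """A catalog row violates a domain constraint (e.g. doses_per_vial < 1)."""


class PresentationLookupError(KeyError):
    """No presentation with the requested (antigen, doses-per-vial)."""


class MissingCostError(ValueError):
    """A cost computation touched an explicitly-unknown price or mass."""


@dataclass(frozen=True)
class VaccinePresentation:
    """One antigen at one vial size.

    ``price_per_dose`` may be ``None`` (explicitly unknown — the 2-dose
    measles price is not published); any cost computation touching it
    raises :class:`MissingCostError` rather than imputing a value.
    ``open_vial_lifetime_days`` is ``None`` for lyophilized vaccines,
    meaning "end of session".
    """

    antigen_id: str
    schedule: str
    schedule_ages_weeks: tuple[float, ...]
    doses_per_person: int
    doses_per_vial: int
    packed_volume_per_dose: float  # cm3, sealed vial, excluding diluent
    diluent_volume_per_dose: float  # cm3
    route: str  # intradermal | intramuscular | subcutaneous | oral
    storage_class: str  # refrigerator | freezer
    formulation: str  # lyophilized | liquid
    open_vial_lifetime_days: float | None
    price_per_dose: float | None
    shelf_life_days: float
    in_schedule: bool

    def __post_init__(self) -> None:
        if self.doses_per_vial < 1:
            raise CatalogValidationError(
                f"{self.antigen_id}: doses_per_vial must be >= 1, "
                f"got {self.doses_per_vial}"
            )
        if self.packed_volume_per_dose <= 0:
            raise CatalogValidationError(
                f"{self.antigen_id}: packed_volume_per_dose must be > 0"
            )
        if self.diluent_volume_per_dose < 0:
            raise CatalogValidationError(
                f"{self.antigen_id}: diluent_volume_per_dose must be >= 0"
            )
        if self.storage_class not in ("refrigerator", "freezer"):
            raise CatalogValidationError(
                f"{self.antigen_id}: unknown storage_class {self.storage_class!r}"
            )
        if self.formulation not in ("lyophilized", "liquid"):
            raise CatalogValidationError(
                f"{self.antigen_id}: unknown formulation {self.formulation!r}"
            )
        if self.price_per_dose is not None and self.price_per_dose < 0:
            raise CatalogValidationError(f"{self.antigen_id}: negative price")

    @property
    def volume_per_vial(self) -> float:
        """Packaged cm3 of one sealed vial (diluent excluded)."""
        return self.packed_volume_per_dose * self.doses_per_vial

    @property
    def diluent_volume_per_vial(self) -> float:
        return self.diluent_volume_per_dose * self.doses_per_vial

    @property
    def temperature_class(self) -> str:
        return "frozen" if self.storage_class == "freezer" else "refrigerated"

    @property
    def needs_injection_syringe(self) -> bool:
        return self.route != "oral"

    def require_price(self) -> float:
        if self.price_per_dose is None:
            raise MissingCostError(
                f"price per dose of the {self.doses_per_vial}-dose "
                f"{self.antigen_id} presentation is unknown; supply a value "
                "explicitly before costing this scenario"
            )
        return self.price_per_dose


@dataclass
class Catalog:
    """All bundled presentations plus the per-antigen active selection."""

    presentations: list[VaccinePresentation]
    active: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.active:
            self.active = {
                p.antigen_id: p.doses_per_vial
                for p in self.presentations
                if p.in_schedule
            }
        for antigen, dpv in self.active.items():
            self.get(antigen, dpv)  # raises if missing

    def antigens(self) -> list[str]:
        """Antigens with an active presentation, in catalog order."""
        seen: list[str] = []
        for p in self.presentations:
            if p.antigen_id in self.active and p.antigen_id not in seen:
                seen.append(p.antigen_id)
        return seen

    def get(self, antigen_id: str, doses_per_vial: int) -> VaccinePresentation:
        for p in self.presentations:
            if p.antigen_id == antigen_id and p.doses_per_vial == doses_per_vial:
                return p
        raise PresentationLookupError(
            f"no {doses_per_vial}-dose presentation of {antigen_id!r} in catalog"
        )

    def active_presentation(self, antigen_id: str) -> VaccinePresentation:
        if antigen_id not in self.active:
            raise PresentationLookupError(f"unknown antigen {antigen_id!r}")
        return self.get(antigen_id, self.active[antigen_id])

    def active_presentations(self) -> list[VaccinePresentation]:
        return [self.active_presentation(a) for a in self.antigens()]


_REQUIRED_COLUMNS = [
    "antigen_id",
    "schedule",
    "schedule_ages_weeks",
    "doses_per_person",
    "doses_per_vial",
    "packed_volume_per_dose_cm3",
    "diluent_volume_per_dose_cm3",
    "route",
    "storage_class",
    "formulation",
    "open_vial_lifetime_days",
    "price_per_dose_usd",
    "shelf_life_days",
    "in_schedule",
]


def _opt_float(raw: str) -> float | None:
    raw = raw.strip()
    return float(raw) if raw else None


def _row_to_presentation(row: dict[str, str]) -> VaccinePresentation:
    try:
        ages = tuple(
            float(a) for a in row["schedule_ages_weeks"].split(";") if a.strip()
        )
        return VaccinePresentation(
            antigen_id=row["antigen_id"].strip(),
            schedule=row["schedule"].strip(),
            schedule_ages_weeks=ages,
            doses_per_person=int(row["doses_per_person"]),
            doses_per_vial=int(row["doses_per_vial"]),
            packed_volume_per_dose=float(row["packed_volume_per_dose_cm3"]),
            diluent_volume_per_dose=float(row["diluent_volume_per_dose_cm3"]),
            route=row["route"].strip(),
            storage_class=row["storage_class"].strip(),
            formulation=row["formulation"].strip(),
            open_vial_lifetime_days=_opt_float(row["open_vial_lifetime_days"]),
            price_per_dose=_opt_float(row["price_per_dose_usd"]),
            shelf_life_days=float(row["shelf_life_days"]),
            in_schedule=row["in_schedule"].strip() in ("1", "true", "True"),
        )
    except (KeyError, ValueError) as exc:
        if isinstance(exc, CatalogValidationError):
            raise
        raise CatalogSchemaError(f"bad catalog row {row!r}: {exc}") from exc


def load_vaccine_catalog(path: str | Path) -> Catalog:
    """Read a presentation catalog from CSV (or an equivalent JSON list).

    Raises :class:`CatalogSchemaError` naming the missing column for
    structurally bad files, :class:`CatalogValidationError` for rows
    violating domain constraints.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list) or not rows:
            raise CatalogSchemaError(f"{path}: expected a non-empty JSON list")
        rows = [{k: str(v) if v is not None else "" for k, v in r.items()} for r in rows]
        header = list(rows[0])
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            rows = list(reader)
    for col in _REQUIRED_COLUMNS:
        if col not in header:
            raise CatalogSchemaError(f"{path}: missing required column {col!r}")
    if not rows:
        raise CatalogSchemaError(f"{path}: catalog has no rows")
    return Catalog(presentations=[_row_to_presentation(r) for r in rows])


def save_vaccine_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalog back to CSV; round-trips through
    :func:`load_vaccine_catalog` identically."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_REQUIRED_COLUMNS)
        writer.writeheader()
        for p in catalog.presentations:
            writer.writerow(
                {
                    "antigen_id": p.antigen_id,
                    "schedule": p.schedule,
                    "schedule_ages_weeks": ";".join(
                        f"{a:g}" for a in p.schedule_ages_weeks
                    ),
                    "doses_per_person": p.doses_per_person,
                    "doses_per_vial": p.doses_per_vial,
                    "packed_volume_per_dose_cm3": f"{p.packed_volume_per_dose:g}",
                    "diluent_volume_per_dose_cm3": f"{p.diluent_volume_per_dose:g}",
                    "route": p.route,
                    "storage_class": p.storage_class,
                    "formulation": p.formulation,
                    "open_vial_lifetime_days": (
                        "" if p.open_vial_lifetime_days is None
                        else f"{p.open_vial_lifetime_days:g}"
                    ),
                    "price_per_dose_usd": (
                        "" if p.price_per_dose is None else f"{p.price_per_dose:g}"
                    ),
                    "shelf_life_days": f"{p.shelf_life_days:g}",
                    "in_schedule": int(p.in_schedule),
                }
            )


def default_catalog() -> Catalog:
    """The bundled national EPI catalog (six antigens, four measles
    presentations)."""
    with resources.as_file(
        resources.files("vaxchain.data") / "epi_vaccines.csv"
    ) as p:
        return load_vaccine_catalog(p)


def substitute_presentation(
    catalog: Catalog, antigen_id: str, target_doses_per_vial: int
) -> Catalog:
    """Return a catalog whose active presentation for ``antigen_id`` is the
    ``target_doses_per_vial`` one; all other antigens unchanged.

    Idempotent, and invertible by substituting the original size back.
    """
    catalog.get(antigen_id, target_doses_per_vial)  # lookup error if absent
    active = dict(catalog.active)
    active[antigen_id] = target_doses_per_vial
    return Catalog(presentations=list(catalog.presentations), active=active)


def adjust_cost_year(
    amount: float, from_year: int, to_year: int, rate: float = 0.03
) -> float:
    """Compound ``amount`` from ``from_year`` to ``to_year`` at an annual
    discount ``rate`` (negative year spans deflate)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return amount * (1.0 + rate) ** (to_year - from_year)


@dataclass
class CostInputs:
    """Accessory masses and unit costs used by the cost equations.

    ``None`` entries are explicitly-unknown published values (2-dose
    measles price and empty-vial mass); touching them in a computation
    raises :class:`MissingCostError`.  ``safety_box_cost_per_dose`` has
    no published value and defaults to 0 with a warning when unset.
    """

    price_per_dose: dict[int, float | None]  # measles, by doses per vial
    empty_vial_mass_g: dict[int, float | None]
    reconstitution_syringe_mass_g: float = 6.625
    injection_syringe_mass_g: float = 6.625
    injection_syringe_cost: float = 0.070
    reconstitution_syringe_cost: float = 0.060
    waste_disposal_cost_per_g: float = 0.0069
    safety_box_cost_per_dose: float | None = None
    discount_rate: float = 0.03

    @property
    def waste_disposal_cost_per_kg(self) -> float:
        return self.waste_disposal_cost_per_g * 1000.0

    def require_vial_mass(self, doses_per_vial: int) -> float:
        mass = self.empty_vial_mass_g.get(doses_per_vial)
        if mass is None:
            raise MissingCostError(
                f"empty-vial mass for the {doses_per_vial}-dose vial is "
                "unknown; supply a value explicitly"
            )
        return mass

    def effective_safety_box_cost(self) -> float:
        if self.safety_box_cost_per_dose is None:
            warnings.warn(
                "safety box cost per dose unset; defaulting to 0 USD/dose",
                stacklevel=2,
            )
            return 0.0
        return self.safety_box_cost_per_dose


def load_cost_inputs(path: str | Path) -> CostInputs:
    """Read cost inputs from the long-format CSV (variable, vial_size,
    mean, min, max) or an equivalent flat JSON object."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        return CostInputs(
            price_per_dose={int(k): v for k, v in obj["price_per_dose_usd"].items()},
            empty_vial_mass_g={
                int(k): v for k, v in obj["empty_vial_mass_g"].items()
            },
            reconstitution_syringe_mass_g=obj["reconstitution_syringe_mass_g"],
            injection_syringe_mass_g=obj["injection_syringe_mass_g"],
            injection_syringe_cost=obj["injection_syringe_cost_usd"],
            reconstitution_syringe_cost=obj["reconstitution_syringe_cost_usd"],
            waste_disposal_cost_per_g=obj["waste_disposal_cost_per_g_usd"],
            safety_box_cost_per_dose=obj.get("safety_box_cost_per_dose_usd"),
            discount_rate=obj.get("discount_rate_per_year", 0.03),
        )
    prices: dict[int, float | None] = {}
    masses: dict[int, float | None] = {}
    scalars: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for col in ("variable", "vial_size", "mean"):
            if col not in (reader.fieldnames or []):
                raise CatalogSchemaError(f"{path}: missing required column {col!r}")
        for row in reader:
            var = row["variable"].strip()
            val = _opt_float(row["mean"])
            size = row["vial_size"].strip()
            if var == "price_per_dose_usd":
                prices[int(size)] = val
            elif var == "empty_vial_mass_g":
                masses[int(size)] = val
            elif val is not None:
                scalars[var] = val
    if not prices or not masses:
        raise CatalogSchemaError(f"{path}: no price/mass rows found")
    return CostInputs(
        price_per_dose=prices,
        empty_vial_mass_g=masses,
        reconstitution_syringe_mass_g=scalars["reconstitution_syringe_mass_g"],
        injection_syringe_mass_g=scalars["injection_syringe_mass_g"],
        injection_syringe_cost=scalars["injection_syringe_cost_usd"],
        reconstitution_syringe_cost=scalars["reconstitution_syringe_cost_usd"],
        waste_disposal_cost_per_g=scalars["waste_disposal_cost_per_g_usd"],
        safety_box_cost_per_dose=scalars.get("safety_box_cost_per_dose_usd"),
        discount_rate=scalars.get("discount_rate_per_year", 0.03),
    )


def default_cost_inputs() -> CostInputs:
    with resources.as_file(
        resources.files("vaxchain.data") / "cost_inputs.csv"
    ) as p:
        return load_cost_inputs(p)
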