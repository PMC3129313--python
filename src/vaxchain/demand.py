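"""Patient demand at clinics.

Demand is built from a national birth cohort projected at a fixed annual
growth rate, split across clinics by share weights, and expressed as
*visit streams*: every child attends the schedule's visits (birth, 6, 10
and 14 weeks, 9 months), each visit carrying the antigens due at that
age.  Tetanus toxoid, given to women at antenatal contacts rather than
to infants, is folded into one aggregate stream whose annual volume is
doses-per-person times the birth cohort.  In ``static`` mode session
arrival counts are a deterministic equal split of the clinic's annual
target; in ``dynamic`` mode each session draws Poisson(lambda).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .catalog import Catalog

__all__ = [
    "DemandModel",
    "VisitStream",
    "project_annual_births",
    "visit_streams",
    "doses_due",
    "session_arrivals",
]

TT_STREAM = "tt_contact"


def project_annual_births(base: int, rate: float, years: int) -> int:
    """base * (1 + rate)^years, rounded to a whole count."""
    if rate < 0 or years < 0:
        raise ValueError("rate and years must be >= 0")
    return round(base * (1.0 + rate) ** years)


@dataclass(frozen=True)
class VisitStream:
    """One arrival stream at clinics: a schedule visit (or the aggregate
    TT contact stream), the antigen doses due at it, and its annual
    arrivals per birth."""

    name: str
    age_weeks: float | None  # None for the aggregate TT stream
    doses: tuple[tuple[str, int], ...]  # (antigen, dose index starting at 1)
    arrivals_per_birth: float


def visit_streams(catalog: Catalog) -> list[VisitStream]:
    """Derive the visit structure from the active schedule.

    Infant visits are the sorted union of schedule ages of non-TT
    antigens; each visit is attended once per birth.  TT becomes one
    aggregate stream with doses_per_person arrivals per birth, each
    needing a single TT dose.
    """
    ages: list[float] = []
    for p in catalog.active_presentations():
        if p.antigen_id == "TT":
            continue
        for a in p.schedule_ages_weeks:
            if a not in ages:
                ages.append(a)
    streams: list[VisitStream] = []
    for age in sorted(ages):
        doses: list[tuple[str, int]] = []
        for p in catalog.active_presentations():
            if p.antigen_id == "TT":
                continue
            if age in p.schedule_ages_weeks:
                doses.append((p.antigen_id, p.schedule_ages_weeks.index(age) + 1))
        streams.append(
            VisitStream(
                name=f"visit_{age:g}w",
                age_weeks=age,
                doses=tuple(doses),
                arrivals_per_birth=1.0,
            )
        )
    if "TT" in catalog.active:
        tt = catalog.active_presentation("TT")
        streams.append(
            VisitStream(
                name=TT_STREAM,
                age_weeks=None,
                doses=(("TT", 1),),
                arrivals_per_birth=float(tt.doses_per_person),
            )
        )
    return streams


def doses_due(age_weeks: float, catalog: Catalog) -> set[tuple[str, int]]:
    """The (antigen, dose index) set due at an exact schedule age within
    the 0-24-month window (TT is handled by its aggregate stream)."""
    if not 0 <= age_weeks <= 104:
        raise ValueError("age must lie within 0-24 months")
    due: set[tuple[str, int]] = set()
    for s in visit_streams(catalog):
        if s.age_weeks is not None and abs(s.age_weeks - age_weeks) < 0.5:
            due.update(s.doses)
    return due


@dataclass
class DemandModel:
    """National demand configuration.

    ``annual_births`` is the already-projected cohort for the simulated
    year; ``clinic_shares`` maps clinic ids to their share of it (must
    sum to 1).
    """

    annual_births: int
    clinic_shares: dict[str, float]
    target_fraction: float = 1.0
    mode: str = "dynamic"  # static | dynamic
    sessions_per_month: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.target_fraction <= 1:
            raise ValueError("target_fraction must lie in (0, 1]")
        if self.mode not in ("static", "dynamic"):
            raise ValueError(f"unknown demand mode {self.mode!r}")
        total = sum(self.clinic_shares.values())
        if self.clinic_shares and abs(total - 1.0) > 1e-6:
            raise ValueError(f"clinic shares sum to {total}, expected 1")

    @property
    def sessions_per_year(self) -> int:
        return self.sessions_per_month * 12

    def annual_stream_target(self, clinic_id: str, stream: VisitStream) -> float:
        """Expected annual arrivals of one stream at one clinic."""
        share = self.clinic_shares[clinic_id]
        return (
            self.annual_births
            * share
            * self.target_fraction
            * stream.arrivals_per_birth
        )

    def session_lambda(self, clinic_id: str, stream: VisitStream) -> float:
        return self.annual_stream_target(clinic_id, stream) / self.sessions_per_year


def _static_count(annual_target: float, session_index: int, sessions: int) -> int:
    # cumulative rounding: exact annual total, maximally even split
    lo = round(annual_target * session_index / sessions)
    hi = round(annual_target * (session_index + 1) / sessions)
    return hi - lo


def session_arrivals(
    demand: DemandModel,
    clinic_id: str,
    session_index: int,
    rng: np.random.Generator,
    catalog: Catalog,
) -> dict[str, int]:
    """Arrival counts per visit stream for one session at one clinic.

    Static mode splits the annual target evenly (cumulative rounding, so
    the year sums exactly); dynamic mode draws Poisson(lambda) per
    stream.  Each arrival is one child (or TT contact) whose due doses
    are the stream's dose set.
    """
    if clinic_id not in demand.clinic_shares:
        raise KeyError(f"clinic {clinic_id!r} has no share weight")
    out: dict[str, int] = {}
    for stream in visit_streams(catalog):
        if demand.mode == "static":
            out[stream.name] = _static_count(
                demand.annual_stream_target(clinic_id, stream),
                session_index,
                demand.sessions_per_year,
            )
        else:
            out[stream.name] = int(rng.poisson(demand.session_lambda(clinic_id, stream)))
    return out
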