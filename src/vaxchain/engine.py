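"""Discrete-event core of the supply-chain simulator.

The simulated year advances day by day; within a day events run in a
fixed order (expiry sweep, clinic sessions, order placement, shipments)
so every replication is reproducible from its seed.  Vials are the unit
of account: stock at a location is a FIFO queue of *lots* — runs of
interchangeable vials sharing an arrival time and expiry — which is
semantically identical to tracking each vial as its own entity (vials
within a lot differ in no attribute) while keeping a national-scale
network fast.  Clinic sessions implement the WHO multi-dose vial policy:
doses are drawn from an already-open vial when one holds doses, else the
oldest sealed vial is opened; at session end open lyophilized vials are
discarded (remaining doses become open-vial wastage) while open liquid
vials persist up to 28 days after opening.

Ordering follows a (s, S) rule: when on-hand stock falls to 25% of a
location's order-up-to level the location orders the shortfall plus a
25% buffer; orders above what the vehicle can carry (or the origin can
supply) are backlogged to the next trip, and the ratio of ordered volume
to vehicle capacity is recorded as the demand-requested transport
utilization (it may exceed 100%; actual loading never does).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .catalog import Catalog, VaccinePresentation, substitute_presentation
from .demand import DemandModel, visit_streams
from .network import SupplyNetwork, Location, Route, storage_capacity

__all__ = [
    "Vial",
    "OpenVial",
    "Lot",
    "AntigenStock",
    "LocationState",
    "Shipment",
    "SessionStats",
    "SessionOutcome",
    "ScenarioConfig",
    "AntigenLedger",
    "RouteTrip",
    "StorageStat",
    "ReplicationResult",
    "SimulationResults",
    "ConsistencyError",
    "PreflightError",
    "update_inventory",
    "allocate_limited_space",
    "compute_order",
    "load_shipment",
    "apply_random_loss",
    "remove_expired",
    "run_session",
    "run_simulation",
]


class ConsistencyError(RuntimeError):
    """An internal invariant was violated (bug trap, not user error)."""


class PreflightError(ValueError):
    """The scenario is infeasible before simulation starts."""


@dataclass
class Vial:
    """A single vial entity (used by the per-vial code paths and the
    brute-force oracle; bulk stock uses :class:`Lot`)."""

    presentation: VaccinePresentation
    doses_remaining: int
    arrival_time: float = 0.0
    expiry_time: float = math.inf
    opened_time: float | None = None


@dataclass(slots=True)
class OpenVial:
    doses_remaining: int
    opened_time: float
    discard_time: float  # opened_time + open-vial lifetime (inf never occurs)


@dataclass(slots=True)
class Lot:
    """A run of interchangeable sealed vials."""

    count: int
    arrival_time: float
    expiry_time: float


class AntigenStock:
    """FIFO queue of sealed-vial lots for one antigen at one location."""

    __slots__ = ("lots", "vial_count")

    def __init__(self) -> None:
        self.lots: deque[Lot] = deque()
        self.vial_count: int = 0

    def add(self, count: int, arrival_time: float, expiry_time: float) -> None:
        if count <= 0:
            return
        tail = self.lots[-1] if self.lots else None
        if (
            tail is not None
            and tail.arrival_time == arrival_time
            and tail.expiry_time == expiry_time
        ):
            tail.count += count
        else:
            self.lots.append(Lot(count, arrival_time, expiry_time))
        self.vial_count += count

    def draw(self, n: int) -> list[Lot]:
        """Remove up to ``n`` vials, oldest arrivals first."""
        drawn: list[Lot] = []
        while n > 0 and self.lots:
            head = self.lots[0]
            take = min(n, head.count)
            if take == head.count:
                drawn.append(self.lots.popleft())
            else:
                head.count -= take
                drawn.append(Lot(take, head.arrival_time, head.expiry_time))
            self.vial_count -= take
            n -= take
        return drawn

    def pop_expired(self, now: float) -> int:
        """Remove lots whose expiry has passed; returns vials removed."""
        removed = 0
        keep: deque[Lot] = deque()
        while self.lots:
            lot = self.lots.popleft()
            if lot.expiry_time <= now:
                removed += lot.count
            else:
                keep.append(lot)
        self.lots = keep
        self.vial_count -= removed
        return removed


class LocationState:
    """Mutable per-location simulation state."""

    __slots__ = ("location", "stock", "open_vials", "capacity")

    def __init__(self, location: Location) -> None:
        self.location = location
        self.stock: dict[str, AntigenStock] = {}
        self.open_vials: dict[str, deque[OpenVial]] = {}
        self.capacity = {
            "refrigerated": storage_capacity(location, "refrigerated"),
            "frozen": storage_capacity(location, "frozen"),
        }

    def stock_for(self, antigen: str) -> AntigenStock:
        s = self.stock.get(antigen)
        if s is None:
            s = self.stock[antigen] = AntigenStock()
        return s

    def open_for(self, antigen: str) -> deque[OpenVial]:
        q = self.open_vials.get(antigen)
        if q is None:
            q = self.open_vials[antigen] = deque()
        return q

    def stored_volume(self, temperature_class: str, catalog: Catalog) -> float:
        vol = 0.0
        for antigen in catalog.antigens():
            p = catalog.active_presentation(antigen)
            if p.temperature_class != temperature_class:
                continue
            s = self.stock.get(antigen)
            if s:
                vol += s.vial_count * p.volume_per_vial
        return vol

    def free_volume(self, temperature_class: str, catalog: Catalog) -> float:
        return self.capacity[temperature_class] - self.stored_volume(
            temperature_class, catalog
        )


# ---------------------------------------------------------------------------
# elementary operations


def allocate_limited_space(
    incoming: dict[str, int], free_volume: float, catalog: Catalog
) -> tuple[dict[str, int], dict[str, int]]:
    """Admit incoming vials into limited space by balanced allocation.

    Complete regimens are prioritized over single antigens: admission
    proceeds in rounds, each round adding the vial mix that covers one
    further child's full schedule (per antigen, ``ceil(k * doses_per_person
    / doses_per_vial)`` vials after k rounds), until the next round no
    longer fits; remaining space is then topped up one vial at a time in
    catalog order.  Returns ``(accepted, rejected)`` vial counts.
    """
    if free_volume < 0:
        raise ValueError("free_volume must be >= 0")
    incoming = {a: int(n) for a, n in incoming.items() if n > 0}
    if not incoming:
        return {}, {}
    pres = {a: catalog.active_presentation(a) for a in incoming}

    def quota(k: int) -> dict[str, int]:
        return {
            a: min(n, math.ceil(k * pres[a].doses_per_person / pres[a].doses_per_vial))
            for a, n in incoming.items()
        }

    def volume(counts: dict[str, int]) -> float:
        return sum(pres[a].volume_per_vial * c for a, c in counts.items())

    k_max = max(
        math.ceil(n * pres[a].doses_per_vial / pres[a].doses_per_person)
        for a, n in incoming.items()
    )
    if volume(quota(k_max)) <= free_volume:
        accepted = dict(incoming)
    else:
        lo, hi = 0, k_max  # volume(quota(lo)) always fits; hi does not
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if volume(quota(mid)) <= free_volume:
                lo = mid
            else:
                hi = mid
        accepted = quota(lo)
        # top up leftover space one vial per antigen per pass, catalog order
        remaining = free_volume - volume(accepted)
        order = [a for a in catalog.antigens() if a in incoming]
        progress = True
        while progress:
            progress = False
            for a in order:
                if accepted[a] < incoming[a] and pres[a].volume_per_vial <= remaining:
                    accepted[a] += 1
                    remaining -= pres[a].volume_per_vial
                    progress = True
    rejected = {
        a: incoming[a] - accepted.get(a, 0)
        for a in incoming
        if incoming[a] > accepted.get(a, 0)
    }
    return {a: c for a, c in accepted.items() if c > 0}, rejected


def update_inventory(
    state: LocationState,
    arrivals: dict[str, list[Lot]],
    removals: dict[str, int],
    catalog: Catalog,
) -> dict[str, int]:
    """Daily inventory balance: stock + arrivals - removals, with arrivals
    admitted only up to free capacity per temperature class.

    ``removals`` are vial counts drawn FIFO; removing more vials than are
    on hand raises :class:`ConsistencyError` (bug trap, removals must be
    a subset of current inventory).  Returns rejected vial counts per
    antigen (excess over capacity).
    """
    for antigen, n in removals.items():
        s = state.stock_for(antigen)
        if n > s.vial_count:
            raise ConsistencyError(
                f"removing {n} {antigen} vials but only {s.vial_count} on hand"
            )
        s.draw(n)
    rejected_all: dict[str, int] = {}
    for tclass in ("refrigerated", "frozen"):
        incoming = {
            a: sum(l.count for l in lots)
            for a, lots in arrivals.items()
            if catalog.active_presentation(a).temperature_class == tclass
        }
        if not incoming:
            continue
        free = state.free_volume(tclass, catalog)
        accepted, rejected = allocate_limited_space(incoming, max(free, 0.0), catalog)
        for a, n_acc in accepted.items():
            s = state.stock_for(a)
            left = n_acc
            for lot in arrivals[a]:
                take = min(left, lot.count)
                if take > 0:
                    s.add(take, lot.arrival_time, lot.expiry_time)
                    left -= take
        rejected_all.update(rejected)
    return rejected_all


def compute_order(
    on_hand: dict[str, int],
    max_level: dict[str, int],
    catalog: Catalog,
    capacity: dict[str, float] | None = None,
    reorder_point_fraction: float = 0.25,
    buffer_fraction: float = 0.25,
) -> dict[str, int]:
    """(s, S) order rule: an antigen whose on-hand stock is at or below
    ``reorder_point_fraction`` of its order-up-to level orders the
    shortfall times ``1 + buffer_fraction`` (rounded up), capped so the
    post-delivery volume cannot exceed storage capacity."""
    order: dict[str, int] = {}
    for antigen, mx in max_level.items():
        oh = on_hand.get(antigen, 0)
        if mx > 0 and oh <= reorder_point_fraction * mx:
            qty = math.ceil((mx - oh) * (1.0 + buffer_fraction))
            if qty > 0:
                order[antigen] = qty
    if capacity is not None and order:
        for tclass in ("refrigerated", "frozen"):
            ants = [
                a
                for a in order
                if catalog.active_presentation(a).temperature_class == tclass
            ]
            if not ants:
                continue
            held = sum(
                on_hand.get(a, 0) * catalog.active_presentation(a).volume_per_vial
                for a in on_hand
                if catalog.active_presentation(a).temperature_class == tclass
            )
            free = capacity.get(tclass, math.inf) - held
            ovol = sum(
                order[a] * catalog.active_presentation(a).volume_per_vial for a in ants
            )
            if ovol > free:
                factor = max(free, 0.0) / ovol
                for a in ants:
                    order[a] = math.floor(order[a] * factor)
    return {a: q for a, q in order.items() if q > 0}


@dataclass
class Shipment:
    """One executed trip: what was asked for, what was loaded, what
    remains backlogged for the next trip."""

    route_id: str
    loaded: dict[str, list[Lot]]
    requested_volume: float
    actual_volume: float
    capacity: float
    backlog: dict[str, int]

    @property
    def demand_requested_utilization(self) -> float:
        return self.requested_volume / self.capacity

    @property
    def actual_utilization(self) -> float:
        return self.actual_volume / self.capacity


def load_shipment(
    requested: dict[str, int],
    origin: LocationState,
    vehicle_capacity: float,
    catalog: Catalog,
    destination_free: dict[str, float] | None = None,
    route_id: str = "",
) -> Shipment:
    """Load a vehicle against an order.

    Vials are drawn FIFO from origin stock up to
    ``min(requested, stock, vehicle capacity, destination free space)``;
    when the vehicle (or destination space) binds, the load is balanced
    across antigens by complete regimens.  The demand-requested
    utilization is the full ordered volume over vehicle capacity and may
    exceed 100%; the unshipped remainder is returned as backlog for the
    next trip.
    """
    if vehicle_capacity <= 0:
        raise ValueError("vehicle capacity must be > 0")
    requested = {a: int(n) for a, n in requested.items() if n > 0}
    req_vol = sum(
        n * catalog.active_presentation(a).volume_per_vial
        for a, n in requested.items()
    )
    available = {
        a: min(n, origin.stock_for(a).vial_count) for a, n in requested.items()
    }
    if destination_free is not None:
        clamped: dict[str, int] = {}
        for tclass in ("refrigerated", "frozen"):
            part = {
                a: n
                for a, n in available.items()
                if catalog.active_presentation(a).temperature_class == tclass
            }
            if part:
                acc, _ = allocate_limited_space(
                    part, max(destination_free.get(tclass, 0.0), 0.0), catalog
                )
                clamped.update(acc)
        available = clamped
    accepted, _ = allocate_limited_space(available, vehicle_capacity, catalog)
    loaded: dict[str, list[Lot]] = {}
    actual_vol = 0.0
    for a, n in accepted.items():
        lots = origin.stock_for(a).draw(n)
        loaded[a] = lots
        actual_vol += n * catalog.active_presentation(a).volume_per_vial
    backlog = {
        a: requested[a] - sum(l.count for l in loaded.get(a, []))
        for a in requested
        if requested[a] > sum(l.count for l in loaded.get(a, []))
    }
    return Shipment(
        route_id=route_id,
        loaded=loaded,
        requested_volume=req_vol,
        actual_volume=actual_vol,
        capacity=vehicle_capacity,
        backlog=backlog,
    )


def apply_random_loss(
    vials: Iterable[Vial] | AntigenStock | list[Lot],
    p: float,
    rng: np.random.Generator,
) -> list:
    """Destroy each vial independently with probability ``p``; returns the
    survivors.  Lot inputs use a binomial thinning per lot, which is
    distribution-identical to per-vial Bernoulli draws."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("loss probability must lie in [0, 1]")
    if isinstance(vials, AntigenStock):
        lost = _thin_lots(vials.lots, p, rng)
        vials.vial_count -= lost
        return list(vials.lots)
    vials = list(vials)
    if vials and isinstance(vials[0], Lot):
        _thin_lots(vials, p, rng)
        return [l for l in vials if l.count > 0]
    if p == 0.0:
        return vials
    keep = rng.random(len(vials)) >= p
    return [v for v, k in zip(vials, keep) if k]


def _thin_lots(lots, p: float, rng: np.random.Generator) -> int:
    if p == 0.0:
        return 0
    lost_total = 0
    for lot in list(lots):
        lost = int(rng.binomial(lot.count, p))
        lot.count -= lost
        lost_total += lost
        if lot.count == 0:
            lots.remove(lot)
    return lost_total


def remove_expired(
    state: LocationState, now: float, catalog: Catalog
) -> tuple[dict[str, int], dict[str, int]]:
    """Discard sealed vials past shelf life and open vials past their
    opened-vial lifetime.

    Returns ``(expired_doses, open_vial_waste_doses)`` per antigen —
    sealed expiry is counted separately from open-vial wastage (an open
    liquid vial past 28 days contributes its remaining doses to the
    latter)."""
    expired: dict[str, int] = {}
    open_waste: dict[str, int] = {}
    for antigen, s in state.stock.items():
        n = s.pop_expired(now)
        if n:
            dpv = catalog.active_presentation(antigen).doses_per_vial
            expired[antigen] = expired.get(antigen, 0) + n * dpv
    for antigen, q in state.open_vials.items():
        keep: deque[OpenVial] = deque()
        while q:
            ov = q.popleft()
            if ov.discard_time <= now:
                open_waste[antigen] = open_waste.get(antigen, 0) + ov.doses_remaining
            else:
                keep.append(ov)
        state.open_vials[antigen] = keep
    return expired, open_waste


@dataclass(slots=True)
class SessionStats:
    arrivals: int = 0
    administered: int = 0
    missed: int = 0
    vials_opened: int = 0
    open_vial_waste: int = 0


@dataclass
class SessionOutcome:
    """Per-antigen outcome of one immunization session."""

    per_antigen: dict[str, SessionStats] = field(default_factory=dict)

    def stats_for(self, antigen: str) -> SessionStats:
        st = self.per_antigen.get(antigen)
        if st is None:
            st = self.per_antigen[antigen] = SessionStats()
        return st


def run_session(
    state: LocationState,
    arrivals: dict[str, int],
    catalog: Catalog,
    now: float,
) -> SessionOutcome:
    """Run one clinic session under the multi-dose vial policy.

    For each arrival due an antigen: draw from an already-open vial if
    one holds doses, else open the oldest sealed vial, else record a
    miss.  At session end open lyophilized vials are discarded and their
    remaining doses counted as open-vial wastage; open liquid vials
    persist (they are discarded 28 days after opening by the expiry
    sweep or at a later session)."""
    outcome = SessionOutcome()
    for antigen in catalog.antigens():
        n = int(arrivals.get(antigen, 0))
        p = catalog.active_presentation(antigen)
        st = outcome.stats_for(antigen)
        st.arrivals = n
        open_q = state.open_for(antigen)
        # sweep open vials that lapsed since the previous session
        while open_q and open_q[0].discard_time <= now:
            st.open_vial_waste += open_q.popleft().doses_remaining
        while n > 0 and open_q:
            ov = open_q[0]
            take = min(n, ov.doses_remaining)
            ov.doses_remaining -= take
            st.administered += take
            n -= take
            if ov.doses_remaining == 0:
                open_q.popleft()
        stock = state.stock_for(antigen)
        while n > 0 and stock.vial_count > 0:
            stock.draw(1)
            st.vials_opened += 1
            take = min(n, p.doses_per_vial)
            st.administered += take
            n -= take
            leftover = p.doses_per_vial - take
            if leftover > 0:
                if p.formulation == "liquid":
                    open_q.append(
                        OpenVial(
                            doses_remaining=leftover,
                            opened_time=now,
                            discard_time=now + (p.open_vial_lifetime_days or 0.0),
                        )
                    )
                else:
                    st.open_vial_waste += leftover
        st.missed = n
        if p.formulation == "lyophilized":
            # session-end discard of anything still open (defensive: the
            # in-session path never leaves a lyophilized vial open)
            while open_q:
                st.open_vial_waste += open_q.popleft().doses_remaining
        if st.administered + st.missed != st.arrivals:
            raise ConsistencyError(f"{antigen}: administered+missed != arrivals")
    return outcome


# ---------------------------------------------------------------------------
# scenario configuration and results containers


@dataclass
class ScenarioConfig:
    """One experiment: a measles vial-size substitution under given
    demand and loss conditions."""

    name: str = "baseline"
    measles_doses_per_vial: int = 10
    target_fraction: float = 1.0
    demand_mode: str = "dynamic"  # static | dynamic
    inventory_loss_rate: float = 0.01  # annual, converted to monthly sweeps
    shipping_loss_rate: float = 0.01  # per trip, per vial
    sessions_per_month: int = 4
    replications: int = 10
    seed: int = 12345
    horizon_days: int = 365
    cover_multiple: float = 2.0  # order-up-to = cover * expected vials/interval


@dataclass
class AntigenLedger:
    """Exact national dose accounting for one antigen in one replication.

    Everything below the central store balances:
    ``initial_below + shipped_from_central ==
    administered + open_vial_waste + expiry_below + loss_below +
    residual_below``."""

    initial_below: int = 0
    shipped_from_central: int = 0
    administered: int = 0
    open_vial_waste: int = 0
    expiry_below: int = 0
    loss_below: int = 0
    residual_below: int = 0
    central_produced: int = 0
    central_initial: int = 0
    central_loss: int = 0
    central_expiry: int = 0

    def imbalance(self) -> int:
        return (self.initial_below + self.shipped_from_central) - (
            self.administered
            + self.open_vial_waste
            + self.expiry_below
            + self.loss_below
            + self.residual_below
        )


@dataclass(slots=True)
class RouteTrip:
    route_id: str
    day: int
    requested_volume: float
    actual_volume: float
    capacity: float


@dataclass(slots=True)
class StorageStat:
    sum_util: float = 0.0
    n_samples: int = 0
    max_util: float = 0.0

    def record(self, util: float) -> None:
        self.sum_util += util
        self.n_samples += 1
        if util > self.max_util:
            self.max_util = util

    @property
    def mean_util(self) -> float:
        return self.sum_util / self.n_samples if self.n_samples else math.nan


@dataclass
class ReplicationResult:
    replication: int
    clinic_stats: dict  # (clinic_id, antigen) -> SessionStats accumulators
    route_trips: list[RouteTrip]
    storage: dict  # (location_id, level, temperature_class) -> StorageStat
    ledgers: dict  # antigen -> AntigenLedger
    session_diluent_volume: float = 0.0


@dataclass
class SimulationResults:
    config: ScenarioConfig
    replications: list[ReplicationResult]

    def national_availability(self, antigen: str) -> list[float]:
        """Per-replication national availability for one antigen."""
        out = []
        for rep in self.replications:
            arr = sum(
                st.arrivals for (c, a), st in rep.clinic_stats.items() if a == antigen
            )
            adm = sum(
                st.administered
                for (c, a), st in rep.clinic_stats.items()
                if a == antigen
            )
            out.append(adm / arr if arr else math.nan)
        return out

    def national_open_vial_waste(self, antigen: str) -> list[int]:
        out = []
        for rep in self.replications:
            out.append(rep.ledgers[antigen].open_vial_waste)
        return out


# ---------------------------------------------------------------------------
# the orchestrator


def _expected_vials_per_session(lam: float, dpv: int) -> float:
    """E[ceil(N/dpv)] for N ~ Poisson(lam): expected vials a session opens
    when demand alone dictates openings (planning anticipates open-vial
    wastage)."""
    if lam <= 0:
        return 0.0
    hi = int(lam + 10.0 * math.sqrt(lam) + 20.0)
    n = np.arange(0, hi + 1)
    # stable Poisson pmf via log factorial
    logpmf = -lam + n * math.log(lam) - np.cumsum(
        np.concatenate(([0.0], np.log(np.maximum(n[1:], 1))))
    )
    pmf = np.exp(logpmf)
    return float(np.sum(pmf * np.ceil(n / dpv)))


class _Sim:
    """One scenario run: builds planning levels, then executes
    replications."""

    def __init__(
        self,
        network: SupplyNetwork,
        catalog: Catalog,
        demand: DemandModel,
        config: ScenarioConfig,
    ) -> None:
        network.validate()
        self.network = network
        self.catalog = substitute_presentation(
            catalog, "M", config.measles_doses_per_vial
        )
        self.config = config
        self.demand = replace(
            demand,
            target_fraction=config.target_fraction,
            mode=config.demand_mode,
            sessions_per_month=config.sessions_per_month,
        )
        self.streams = visit_streams(self.catalog)
        self.antigens = self.catalog.antigens()
        self.clinics = sorted(
            (l.location_id for l in network.by_level("clinic")),
        )
        self._preflight()
        self._plan()

    # -- planning -----------------------------------------------------------

    def _preflight(self) -> None:
        for clinic_id in self.clinics:
            loc = self.network.locations[clinic_id]
            for antigen in self.antigens:
                tclass = self.catalog.active_presentation(antigen).temperature_class
                if storage_capacity(loc, tclass) <= 0:
                    raise PreflightError(
                        f"clinic {clinic_id} has no {tclass} storage for {antigen}"
                    )
            if self.network.inbound_route(clinic_id) is None:
                raise PreflightError(f"clinic {clinic_id} has no inbound route")

    def _plan(self) -> None:
        cfg = self.config
        sessions = self.demand.sessions_per_year
        # per-clinic per-antigen session arrival rate
        self.clinic_lambda: dict[tuple[str, str], float] = {}
        for clinic in self.clinics:
            for antigen in self.antigens:
                lam = sum(
                    self.demand.session_lambda(clinic, s)
                    for s in self.streams
                    for a, _ in s.doses
                    if a == antigen
                )
                self.clinic_lambda[(clinic, antigen)] = lam
        # expected annual sealed-vial throughput per clinic
        self.clinic_annual_vials: dict[tuple[str, str], float] = {}
        for (clinic, antigen), lam in self.clinic_lambda.items():
            dpv = self.catalog.active_presentation(antigen).doses_per_vial
            self.clinic_annual_vials[(clinic, antigen)] = (
                sessions * _expected_vials_per_session(lam, dpv)
            )
        # order-up-to levels, bottom-up along the supply tree
        self.max_level: dict[str, dict[str, int]] = {}
        self.loc_annual_vials: dict[tuple[str, str], float] = {}
        subtree_cache: dict[str, list[str]] = {
            lid: self.network.subtree(lid) for lid in self.network.locations
        }
        for lid, loc in self.network.locations.items():
            if loc.level == "central":
                interval = 365.0 / 4.0  # quarterly manufacturer restock
            else:
                route = self.network.inbound_route(lid)
                if route is None:
                    self.max_level[lid] = {a: 0 for a in self.antigens}
                    continue
                interval = route.interval_days
            clinics_below = [
                c for c in subtree_cache[lid] if c in self.demand.clinic_shares
            ]
            levels: dict[str, int] = {}
            for antigen in self.antigens:
                annual = sum(
                    self.clinic_annual_vials[(c, antigen)] for c in clinics_below
                )
                self.loc_annual_vials[(lid, antigen)] = annual
                levels[antigen] = math.ceil(
                    annual * interval / 365.0 * cfg.cover_multiple
                )
            self.max_level[lid] = self._capacity_cap(loc, levels)

    def _capacity_cap(self, loc: Location, levels: dict[str, int]) -> dict[str, int]:
        """Scale order-up-to levels so they fit in 95% of each temperature
        class's storage (zero capacity => cross-dock, holds nothing)."""
        capped = dict(levels)
        for tclass in ("refrigerated", "frozen"):
            cap = storage_capacity(loc, tclass) * 0.95
            ants = [
                a
                for a in levels
                if self.catalog.active_presentation(a).temperature_class == tclass
            ]
            vol = sum(
                levels[a] * self.catalog.active_presentation(a).volume_per_vial
                for a in ants
            )
            if vol > cap:
                factor = cap / vol if vol > 0 else 0.0
                for a in ants:
                    capped[a] = math.floor(levels[a] * factor)
        return capped

    # -- execution ----------------------------------------------------------

    def run(self) -> SimulationResults:
        reps = [
            self._run_replication(r) for r in range(self.config.replications)
        ]
        return SimulationResults(config=self.config, replications=reps)

    def _session_days(self) -> list[int]:
        n = self.demand.sessions_per_year
        return sorted(
            {
                max(1, round((s + 0.5) * self.config.horizon_days / n))
                for s in range(n)
            }
        )

    def _trip_days(self, route_index: int, route: Route) -> list[int]:
        interval = max(1, round(route.interval_days))
        offset = 1 + (route_index % interval)
        return [
            d
            for d in range(1, self.config.horizon_days + 1)
            if (d - offset) % interval == 0
        ]

    def _run_replication(self, rep_index: int) -> ReplicationResult:
        cfg = self.config
        rng_demand, rng_loss = np.random.SeedSequence(
            [cfg.seed, rep_index]
        ).spawn(2)
        rng_demand = np.random.default_rng(rng_demand)
        rng_loss = np.random.default_rng(rng_loss)

        catalog = self.catalog
        net = self.network
        states = {lid: LocationState(loc) for lid, loc in net.locations.items()}
        ledgers = {a: AntigenLedger() for a in self.antigens}
        central_id = net.central.location_id

        routes_sorted = sorted(
            enumerate(net.routes),
            key=lambda ir: ("central", "regional", "district", "clinic").index(
                net.locations[ir[1].origin].level
            ),
        )
        trips_by_day: dict[int, list[tuple[int, Route]]] = {}
        for idx, route in routes_sorted:
            for d in self._trip_days(idx, route):
                trips_by_day.setdefault(d, []).append((idx, route))

        # initial stock: the chain starts fully stocked at its order-up-to
        # levels (an operating chain, not a cold start)
        for lid, state in states.items():
            for antigen, level in self.max_level[lid].items():
                if level <= 0:
                    continue
                p = catalog.active_presentation(antigen)
                state.stock_for(antigen).add(level, 0.0, p.shelf_life_days)
                doses = level * p.doses_per_vial
                if lid == central_id:
                    ledgers[antigen].central_initial += doses
                else:
                    ledgers[antigen].initial_below += doses

        # pre-draw session arrivals [clinic, session, stream]
        session_days = self._session_days()
        n_sessions = len(session_days)
        lam = np.array(
            [
                [self.demand.session_lambda(c, s) for s in self.streams]
                for c in self.clinics
            ]
        )
        if self.demand.mode == "dynamic":
            arrivals_array = rng_demand.poisson(
                lam[:, None, :], size=(len(self.clinics), n_sessions, len(self.streams))
            )
        else:
            annual = lam * self.demand.sessions_per_year
            cum = np.round(
                annual[:, None, :]
                * (np.arange(n_sessions + 1) / n_sessions)[None, :, None]
            )
            arrivals_array = (cum[:, 1:, :] - cum[:, :-1, :]).astype(int)
        stream_antigen = [
            [a for a, _ in s.doses] for s in self.streams
        ]

        clinic_stats: dict[tuple[str, str], SessionStats] = {
            (c, a): SessionStats() for c in self.clinics for a in self.antigens
        }
        route_trips: list[RouteTrip] = []
        storage: dict[tuple[str, str, str], StorageStat] = {}
        pending: dict[str, dict[str, int]] = {
            lid: {} for lid in net.locations if lid != central_id
        }
        session_diluent = 0.0

        session_day_set = set(session_days)
        session_counter = 0
        p_month = 1.0 - (1.0 - cfg.inventory_loss_rate) ** (30.0 / 365.0)

        for day in range(1, cfg.horizon_days + 1):
            monthly = day % 30 == 0
            # 1. expiry sweep (monthly everywhere; clinics also sweep open
            #    vials inside run_session)
            if monthly:
                for lid, state in states.items():
                    expired, open_waste = remove_expired(state, day, catalog)
                    for a, doses in expired.items():
                        if lid == central_id:
                            ledgers[a].central_expiry += doses
                        else:
                            ledgers[a].expiry_below += doses
                    for a, doses in open_waste.items():
                        ledgers[a].open_vial_waste += doses

            # 2. clinic sessions
            if day in session_day_set:
                s_idx = session_counter
                session_counter += 1
                for c_idx, clinic in enumerate(self.clinics):
                    counts = arrivals_array[c_idx, s_idx, :]
                    if not counts.any():
                        continue
                    arr: dict[str, int] = {}
                    for st_idx, ants in enumerate(stream_antigen):
                        n = int(counts[st_idx])
                        if n:
                            for a in ants:
                                arr[a] = arr.get(a, 0) + n
                    outcome = run_session(states[clinic], arr, catalog, float(day))
                    for a, st in outcome.per_antigen.items():
                        acc = clinic_stats[(clinic, a)]
                        acc.arrivals += st.arrivals
                        acc.administered += st.administered
                        acc.missed += st.missed
                        acc.vials_opened += st.vials_opened
                        acc.open_vial_waste += st.open_vial_waste
                        ledgers[a].administered += st.administered
                        ledgers[a].open_vial_waste += st.open_vial_waste
                        p = catalog.active_presentation(a)
                        session_diluent += (
                            st.vials_opened * p.diluent_volume_per_vial
                        )

            # 3-4. order placement and shipments (orders are evaluated at
            # collection time; stock is non-increasing between trips so the
            # trigger state at the trip equals the daily-check maximum)
            for idx, route in trips_by_day.get(day, []):
                origin_state = states[route.origin]
                remaining_capacity = route.transport.net_capacity
                trip_requested_vol = 0.0
                trip_actual_vol = 0.0
                loss_p = (
                    route.transport.loss_probability
                    if route.transport.loss_probability is not None
                    else cfg.shipping_loss_rate
                )
                for stop in route.stops:
                    stop_state = states[stop]
                    loc = net.locations[stop]
                    on_hand = {
                        a: stop_state.stock_for(a).vial_count for a in self.antigens
                    }
                    fresh = compute_order(
                        on_hand,
                        self.max_level[stop],
                        catalog,
                        capacity=stop_state.capacity,
                        reorder_point_fraction=loc.reorder_point_fraction,
                        buffer_fraction=loc.buffer_fraction,
                    )
                    req = dict(pending[stop])
                    for a, q in fresh.items():
                        req[a] = max(req.get(a, 0), q)
                    if not req:
                        pending[stop] = {}
                        continue
                    dest_free = {
                        t: stop_state.free_volume(t, catalog)
                        for t in ("refrigerated", "frozen")
                    }
                    shipment = load_shipment(
                        req,
                        origin_state,
                        max(remaining_capacity, 1e-9),
                        catalog,
                        destination_free=dest_free,
                        route_id=route.route_id,
                    )
                    trip_requested_vol += shipment.requested_volume
                    # shipping loss at departure, then same-day delivery
                    delivered: dict[str, list[Lot]] = {}
                    for a, lots in shipment.loaded.items():
                        doses_loaded = sum(l.count for l in lots) * catalog.active_presentation(a).doses_per_vial
                        if route.origin == central_id:
                            ledgers[a].shipped_from_central += doses_loaded
                        survivors = apply_random_loss(lots, loss_p, rng_loss)
                        lost_doses = doses_loaded - sum(
                            l.count for l in survivors
                        ) * catalog.active_presentation(a).doses_per_vial
                        ledgers[a].loss_below += lost_doses
                        delivered[a] = [
                            Lot(l.count, float(day), l.expiry_time) for l in survivors
                        ]
                    arrived_vol = sum(
                        sum(l.count for l in lots)
                        * catalog.active_presentation(a).volume_per_vial
                        for a, lots in delivered.items()
                    )
                    trip_actual_vol += shipment.actual_volume
                    remaining_capacity -= shipment.actual_volume
                    rejected = update_inventory(stop_state, delivered, {}, catalog)
                    if rejected:
                        raise ConsistencyError(
                            f"destination {stop} rejected pre-clamped delivery"
                        )
                    pending[stop] = dict(shipment.backlog)
                route_trips.append(
                    RouteTrip(
                        route_id=route.route_id,
                        day=day,
                        requested_volume=trip_requested_vol,
                        actual_volume=trip_actual_vol,
                        capacity=route.transport.net_capacity,
                    )
                )

            # 5. monthly storage loss sweep
            if monthly and cfg.inventory_loss_rate > 0:
                for lid, state in states.items():
                    for a in self.antigens:
                        s = state.stock.get(a)
                        if not s or s.vial_count == 0:
                            continue
                        before = s.vial_count
                        apply_random_loss(s, p_month, rng_loss)
                        lost = before - s.vial_count
                        if lost:
                            doses = lost * catalog.active_presentation(a).doses_per_vial
                            if lid == central_id:
                                ledgers[a].central_loss += doses
                            else:
                                ledgers[a].loss_below += doses

            # 6. quarterly manufacturer restock of the central store
            if (day - 1) % 91 == 0:
                central_state = states[central_id]
                for a, level in self.max_level[central_id].items():
                    s = central_state.stock_for(a)
                    top_up = level - s.vial_count
                    if top_up > 0:
                        p = catalog.active_presentation(a)
                        s.add(top_up, float(day), day + p.shelf_life_days)
                        ledgers[a].central_produced += top_up * p.doses_per_vial

            # 7. weekly storage-utilization sample
            if day % 7 == 0:
                for lid, state in states.items():
                    loc = net.locations[lid]
                    for tclass in ("refrigerated", "frozen"):
                        cap = state.capacity[tclass]
                        if cap <= 0:
                            continue
                        util = state.stored_volume(tclass, catalog) / cap
                        if util > 1.0 + 1e-9:
                            raise ConsistencyError(
                                f"{lid} {tclass} storage above capacity"
                            )
                        key = (lid, loc.level, tclass)
                        stat = storage.get(key)
                        if stat is None:
                            stat = storage[key] = StorageStat()
                        stat.record(util)

        # residual accounting
        for lid, state in states.items():
            if lid == central_id:
                continue
            for a in self.antigens:
                p = catalog.active_presentation(a)
                s = state.stock.get(a)
                if s:
                    ledgers[a].residual_below += s.vial_count * p.doses_per_vial
                for ov in state.open_vials.get(a, ()):
                    ledgers[a].residual_below += ov.doses_remaining

        return ReplicationResult(
            replication=rep_index,
            clinic_stats=clinic_stats,
            route_trips=route_trips,
            storage=storage,
            ledgers=ledgers,
            session_diluent_volume=session_diluent,
        )


def run_simulation(
    network: SupplyNetwork,
    catalog: Catalog,
    demand: DemandModel,
    config: ScenarioConfig,
) -> SimulationResults:
    """Simulate one scenario over the configured replications.

    Replication seeds derive from ``(config.seed, replication index)``
    only, so vial-size scenarios sharing a root seed see paired demand
    streams (common random numbers)."""
    return _Sim(network, catalog, demand, config).run()
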