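"""Four-tier supply-network representation.

Locations (central, regional, district, clinic) hold cold-storage
devices; routes connect them with a transport device, a shipping
frequency and a mode (delivery = origin pushes on its schedule,
collection = destination fetches).  Multi-stop delivery loops share one
vehicle's capacity across an ordered stop list.  After expanding loops
into origin->stop edges the graph must be a forest rooted at the central
store: every location has exactly one inbound supply route.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "StorageDevice",
    "TransportDevice",
    "Location",
    "Route",
    "SupplyNetwork",
    "TopologyError",
    "load_network",
    "save_network",
    "storage_capacity",
]

LEVELS = ("central", "regional", "district", "clinic")

STORAGE_KINDS = ("cold_room", "refrigerator", "freezer")
TRANSPORT_KINDS = ("cold_truck", "four_by_four", "cold_box", "vaccine_carrier")


class TopologyError(ValueError):
    """The network description is not a forest reachable from central."""


@dataclass
class StorageDevice:
    device_id: str
    kind: str  # cold_room | refrigerator | freezer
    net_capacity: float  # cm3
    temperature_class: str = ""  # refrigerated | frozen

    def __post_init__(self) -> None:
        if self.kind not in STORAGE_KINDS:
            raise ValueError(f"unknown storage device kind {self.kind!r}")
        if self.net_capacity <= 0:
            raise ValueError(f"{self.device_id}: net_capacity must be > 0")
        if not self.temperature_class:
            self.temperature_class = (
                "frozen" if self.kind == "freezer" else "refrigerated"
            )


@dataclass
class TransportDevice:
    device_id: str
    kind: str  # cold_truck | four_by_four | cold_box | vaccine_carrier
    net_capacity: float  # cm3
    loss_probability: float | None = None  # per-trip per-vial; None -> scenario rate

    def __post_init__(self) -> None:
        if self.kind not in TRANSPORT_KINDS:
            raise ValueError(f"unknown transport device kind {self.kind!r}")
        if self.net_capacity <= 0:
            raise ValueError(f"{self.device_id}: net_capacity must be > 0")


@dataclass
class Location:
    location_id: str
    level: str
    devices: list[StorageDevice] = field(default_factory=list)
    reorder_point_fraction: float = 0.25
    buffer_fraction: float = 0.25
    birth_share: float | None = None  # clinics only: share of national births

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")


@dataclass
class Route:
    route_id: str
    origin: str
    stops: list[str]  # ordered; >1 entry = multi-stop loop
    transport: TransportDevice
    trips_per_year: float
    mode: str = "collection"  # delivery | collection

    @property
    def interval_days(self) -> float:
        return 365.0 / self.trips_per_year


@dataclass
class SupplyNetwork:
    locations: dict[str, Location]
    routes: list[Route]

    @property
    def central(self) -> Location:
        for loc in self.locations.values():
            if loc.level == "central":
                return loc
        raise TopologyError("network has no central store")

    def inbound_route(self, location_id: str) -> Route | None:
        for r in self.routes:
            if location_id in r.stops:
                return r
        return None

    def by_level(self, level: str) -> list[Location]:
        return [l for l in self.locations.values() if l.level == level]

    def children(self, location_id: str) -> list[str]:
        out: list[str] = []
        for r in self.routes:
            if r.origin == location_id:
                out.extend(r.stops)
        return out

    def subtree(self, location_id: str) -> list[str]:
        """All locations supplied (transitively) from ``location_id``,
        including itself."""
        seen = [location_id]
        frontier = [location_id]
        while frontier:
            nxt: list[str] = []
            for loc in frontier:
                for child in self.children(loc):
                    if child not in seen:
                        seen.append(child)
                        nxt.append(child)
            frontier = nxt
        return seen

    def validate(self) -> None:
        """Check referential integrity, reachability from central and the
        one-inbound-route (forest) property."""
        central = self.central  # raises if absent
        for r in self.routes:
            if r.origin not in self.locations:
                raise TopologyError(
                    f"route {r.route_id}: unknown origin {r.origin!r}"
                )
            for s in r.stops:
                if s not in self.locations:
                    raise TopologyError(
                        f"route {r.route_id}: unknown stop {s!r}"
                    )
        inbound: dict[str, str] = {}
        for r in self.routes:
            for s in r.stops:
                if s in inbound:
                    raise TopologyError(
                        f"{s} has two inbound routes ({inbound[s]}, {r.route_id}); "
                        "the supply graph must be a forest"
                    )
                inbound[s] = r.route_id
        reachable = set(self.subtree(central.location_id))
        orphans = sorted(set(self.locations) - reachable)
        if orphans:
            raise TopologyError(
                f"locations unreachable from the central store: {orphans}"
            )


def storage_capacity(location: Location, temperature_class: str) -> float:
    """Total net cm3 of the location's devices in a temperature class
    (0 for the storage-less district store)."""
    return sum(
        d.net_capacity
        for d in location.devices
        if d.temperature_class == temperature_class
    )


def _network_to_obj(net: SupplyNetwork) -> dict:
    return {
        "locations": [
            {
                "location_id": l.location_id,
                "level": l.level,
                "reorder_point_fraction": l.reorder_point_fraction,
                "buffer_fraction": l.buffer_fraction,
                "birth_share": l.birth_share,
                "devices": [
                    {
                        "device_id": d.device_id,
                        "kind": d.kind,
                        "net_capacity": d.net_capacity,
                        "temperature_class": d.temperature_class,
                    }
                    for d in l.devices
                ],
            }
            for l in net.locations.values()
        ],
        "routes": [
            {
                "route_id": r.route_id,
                "origin": r.origin,
                "stops": list(r.stops),
                "trips_per_year": r.trips_per_year,
                "mode": r.mode,
                "transport": {
                    "device_id": r.transport.device_id,
                    "kind": r.transport.kind,
                    "net_capacity": r.transport.net_capacity,
                    "loss_probability": r.transport.loss_probability,
                },
            }
            for r in net.routes
        ],
    }


def _obj_to_network(obj: dict) -> SupplyNetwork:
    locations = {}
    for l in obj["locations"]:
        locations[l["location_id"]] = Location(
            location_id=l["location_id"],
            level=l["level"],
            devices=[
                StorageDevice(
                    device_id=d["device_id"],
                    kind=d["kind"],
                    net_capacity=d["net_capacity"],
                    temperature_class=d.get("temperature_class", ""),
                )
                for d in l.get("devices", [])
            ],
            reorder_point_fraction=l.get("reorder_point_fraction", 0.25),
            buffer_fraction=l.get("buffer_fraction", 0.25),
            birth_share=l.get("birth_share"),
        )
    routes = [
        Route(
            route_id=r["route_id"],
            origin=r["origin"],
            stops=list(r["stops"]),
            transport=TransportDevice(
                device_id=r["transport"]["device_id"],
                kind=r["transport"]["kind"],
                net_capacity=r["transport"]["net_capacity"],
                loss_probability=r["transport"].get("loss_probability"),
            ),
            trips_per_year=r["trips_per_year"],
            mode=r.get("mode", "collection"),
        )
        for r in obj["routes"]
    ]
    return SupplyNetwork(locations=locations, routes=routes)


def load_network(path: str | Path) -> SupplyNetwork:
    """Load and validate a network from JSON or YAML (by suffix)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        obj = yaml.safe_load(text)
    else:
        obj = json.loads(text)
    net = _obj_to_network(obj)
    net.validate()
    return net


def save_network(net: SupplyNetwork, path: str | Path) -> None:
    path = Path(path)
    obj = _network_to_obj(net)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=1))
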