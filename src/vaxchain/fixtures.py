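"""Synthetic national-scale fixtures.

The real equipment inventory and route list behind the four-tier
national chain are unpublished, so experiments run on a synthetic
network that reproduces the published *structure* — one central store,
7 regional stores served by two multi-stop cold-truck loops, 42 district
stores of which 7 procure directly from the central store and one has no
cold storage at all, and 695 clinics — with device capacities chosen so
the baseline (10-dose measles) scenario sits in the published operating
regime: district refrigerators around two-thirds full, many clinic
vaccine carriers above 100% demand-requested utilization, regional cold
rooms lightly loaded.  All capacity constants below are documented
calibration choices, not measurements; everything is regenerated
deterministically from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import Catalog, default_catalog
from .demand import DemandModel, visit_streams
from .engine import ScenarioConfig, _expected_vials_per_session
from .network import (
    Location,
    Route,
    StorageDevice,
    SupplyNetwork,
    TransportDevice,
)

__all__ = [
    "FixtureParams",
    "miniature_params",
    "generate_network",
    "default_demand",
    "generate_scenario_suite",
    "PRINTED_ANNUAL_BIRTHS",
]

# the published projected national birth cohort for the simulated year
PRINTED_ANNUAL_BIRTHS = 586_880

# ---------------------------------------------------------------------------
# calibration constants (synthetic; chosen so the baseline scenario lands in
# the published qualitative regime, see docs/methods.md)

CENTRAL_CAPACITY_FACTOR = 2.3    # x quarterly national throughput volume
REGIONAL_CAPACITY_FACTOR = 12.5  # x quarterly subtree throughput volume
DISTRICT_CAPACITY_FACTOR = 2.3   # x monthly subtree throughput volume
CLINIC_CAPACITY_FACTOR = 4.4     # x monthly clinic throughput volume
COLD_TRUCK_FACTOR = 2.0          # x quarterly loop delivery volume
FOUR_BY_FOUR_FACTOR = 3.5        # x mean monthly district volume (x3 for
                                 #   the quarterly self-procuring routes)
CARRIER_FACTOR = 4.5             # x mean monthly clinic volume
STORAGE_JITTER = (0.7, 1.3)      # per-device heterogeneity multiplier
SHARE_SIGMA = 1.0                # log-normal spread of clinic birth shares


@dataclass
class FixtureParams:
    """Shape of the generated network."""

    n_regional: int = 7
    n_district: int = 42
    n_clinics: int = 695
    n_self_procuring: int = 7  # districts supplied straight from central
    n_loops: int = 2           # cold-truck delivery loops over the regionals
    storage_less_district: bool = True
    annual_births: int = PRINTED_ANNUAL_BIRTHS
    sessions_per_month: int = 4
    share_sigma: float = SHARE_SIGMA
    capacity_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.n_regional, self.n_district, self.n_clinics) < 1:
            raise ValueError("level counts must be >= 1")
        if self.n_self_procuring >= self.n_district:
            raise ValueError("n_self_procuring must leave regional districts")

    def scale(self, level: str) -> float:
        return self.capacity_scale.get(level, 1.0)


def miniature_params(n_clinics: int = 10, n_district: int = 2) -> FixtureParams:
    """A small network for unit tests and quick runs (no self-procuring
    districts, no storage-less district, one loop)."""
    return FixtureParams(
        n_regional=1,
        n_district=n_district,
        n_clinics=n_clinics,
        n_self_procuring=0,
        n_loops=1,
        storage_less_district=False,
    )


def _clinic_monthly_volumes(
    params: FixtureParams, shares: np.ndarray, catalog: Catalog
) -> tuple[np.ndarray, np.ndarray]:
    """Expected monthly sealed-vial throughput volume per clinic,
    (refrigerated, frozen), including expected open-vial wastage (vials
    opened, not just doses demanded)."""
    streams = visit_streams(catalog)
    sessions = params.sessions_per_month * 12
    refr = np.zeros(len(shares))
    froz = np.zeros(len(shares))
    for antigen in catalog.antigens():
        p = catalog.active_presentation(antigen)
        per_birth = sum(
            s.arrivals_per_birth for s in streams for a, _ in s.doses if a == antigen
        )
        lam = params.annual_births * shares * per_birth / sessions
        vols = np.array(
            [
                _expected_vials_per_session(l, p.doses_per_vial) * p.volume_per_vial
                for l in lam
            ]
        )
        monthly = vols * sessions / 12.0
        if p.temperature_class == "frozen":
            froz += monthly
        else:
            refr += monthly
    return refr, froz


def generate_network(
    params: FixtureParams,
    seed: int,
    catalog: Catalog | None = None,
) -> SupplyNetwork:
    """Generate the synthetic four-tier network; bit-stable per seed.

    Clinic birth shares are drawn log-normally (small sessions must
    exist for vial-size effects on open-vial wastage to be visible) and
    stored on the clinic locations so :func:`default_demand` can rebuild
    the demand model from the network alone.
    """
    if catalog is None:
        catalog = default_catalog()
    rng = np.random.default_rng(seed)

    shares = rng.lognormal(mean=0.0, sigma=params.share_sigma, size=params.n_clinics)
    shares = shares / shares.sum()
    clinic_refr, clinic_froz = _clinic_monthly_volumes(params, shares, catalog)

    locations: dict[str, Location] = {}
    routes: list[Route] = []

    # district composition
    n_reg_districts = params.n_district - params.n_self_procuring
    district_ids = [f"D{i + 1:02d}" for i in range(params.n_district)]
    self_procuring = district_ids[n_reg_districts:]
    regional_districts = district_ids[:n_reg_districts]
    district_region = {
        d: f"R{(i % params.n_regional) + 1}" for i, d in enumerate(regional_districts)
    }
    crossdock = regional_districts[-1] if params.storage_less_district else None

    # clinics round-robin over districts
    clinic_ids = [f"C{i + 1:03d}" for i in range(params.n_clinics)]
    clinic_district = {
        c: district_ids[i % params.n_district] for i, c in enumerate(clinic_ids)
    }

    district_refr = {d: 0.0 for d in district_ids}
    district_froz = {d: 0.0 for d in district_ids}
    for i, c in enumerate(clinic_ids):
        district_refr[clinic_district[c]] += clinic_refr[i]
        district_froz[clinic_district[c]] += clinic_froz[i]
    region_refr = {f"R{r + 1}": 0.0 for r in range(params.n_regional)}
    region_froz = {f"R{r + 1}": 0.0 for r in range(params.n_regional)}
    for d in regional_districts:
        region_refr[district_region[d]] += district_refr[d]
        region_froz[district_region[d]] += district_froz[d]
    national_refr = sum(district_refr.values())
    national_froz = sum(district_froz.values())

    def jitter() -> float:
        return float(rng.uniform(*STORAGE_JITTER))

    # central store
    sc = params.scale("central")
    locations["CENTRAL"] = Location(
        location_id="CENTRAL",
        level="central",
        devices=[
            StorageDevice(
                "CENTRAL-coldroom",
                "cold_room",
                CENTRAL_CAPACITY_FACTOR * national_refr * 3.0 * sc,
            ),
            StorageDevice(
                "CENTRAL-freezer",
                "freezer",
                max(CENTRAL_CAPACITY_FACTOR * national_froz * 3.0 * sc, 1.0),
            ),
        ],
    )

    # regional stores
    sr = params.scale("regional")
    for r in range(params.n_regional):
        rid = f"R{r + 1}"
        locations[rid] = Location(
            location_id=rid,
            level="regional",
            devices=[
                StorageDevice(
                    f"{rid}-coldroom",
                    "cold_room",
                    max(
                        REGIONAL_CAPACITY_FACTOR * region_refr[rid] * 3.0 * sr * jitter(),
                        1.0,
                    ),
                ),
                StorageDevice(
                    f"{rid}-freezer",
                    "freezer",
                    max(
                        REGIONAL_CAPACITY_FACTOR * region_froz[rid] * 3.0 * sr * jitter(),
                        1.0,
                    ),
                ),
            ],
        )

    # district stores
    sd = params.scale("district")
    for d in district_ids:
        if d == crossdock:
            locations[d] = Location(location_id=d, level="district", devices=[])
            continue
        locations[d] = Location(
            location_id=d,
            level="district",
            devices=[
                StorageDevice(
                    f"{d}-fridge",
                    "refrigerator",
                    max(
                        DISTRICT_CAPACITY_FACTOR * district_refr[d] * sd * jitter(),
                        1.0,
                    ),
                ),
                StorageDevice(
                    f"{d}-freezer",
                    "freezer",
                    max(
                        DISTRICT_CAPACITY_FACTOR * district_froz[d] * sd * jitter(),
                        1.0,
                    ),
                ),
            ],
        )

    # clinics
    scl = params.scale("clinic")
    for i, c in enumerate(clinic_ids):
        locations[c] = Location(
            location_id=c,
            level="clinic",
            devices=[
                StorageDevice(
                    f"{c}-fridge",
                    "refrigerator",
                    max(CLINIC_CAPACITY_FACTOR * clinic_refr[i] * scl * jitter(), 1.0),
                ),
                StorageDevice(
                    f"{c}-freezer",
                    "freezer",
                    max(CLINIC_CAPACITY_FACTOR * clinic_froz[i] * scl * jitter(), 1.0),
                ),
            ],
            birth_share=float(shares[i]),
        )

    # routes: cold-truck loops central -> regionals, quarterly deliveries
    region_ids = [f"R{r + 1}" for r in range(params.n_regional)]
    loop_size = math.ceil(params.n_regional / params.n_loops)
    for k in range(params.n_loops):
        stops = region_ids[k * loop_size : (k + 1) * loop_size]
        if not stops:
            continue
        loop_quarterly = sum(
            (region_refr[r] + region_froz[r]) * 3.0 for r in stops
        )
        routes.append(
            Route(
                route_id=f"central-regional-loop{k + 1}",
                origin="CENTRAL",
                stops=stops,
                transport=TransportDevice(
                    f"coldtruck{k + 1}",
                    "cold_truck",
                    max(COLD_TRUCK_FACTOR * loop_quarterly, 1.0),
                ),
                trips_per_year=4,
                mode="delivery",
            )
        )

    mean_district_monthly = (
        (national_refr + national_froz) / params.n_district
    )
    # self-procuring districts: quarterly 4x4 collection from central
    for d in self_procuring:
        routes.append(
            Route(
                route_id=f"central-district-{d}",
                origin="CENTRAL",
                stops=[d],
                transport=TransportDevice(
                    f"4x4-{d}",
                    "four_by_four",
                    max(FOUR_BY_FOUR_FACTOR * 3.0 * mean_district_monthly, 1.0),
                ),
                trips_per_year=4,
                mode="collection",
            )
        )
    # regional -> district: monthly 4x4 collection (the storage-less
    # cross-dock district keeps its route but never orders)
    for d in regional_districts:
        routes.append(
            Route(
                route_id=f"regional-district-{district_region[d]}-{d}",
                origin=district_region[d],
                stops=[d],
                transport=TransportDevice(
                    f"4x4-{d}",
                    "four_by_four",
                    max(FOUR_BY_FOUR_FACTOR * mean_district_monthly, 1.0),
                ),
                trips_per_year=12,
                mode="collection",
            )
        )
    # district -> clinic: monthly vaccine-carrier collection; clinics of the
    # storage-less cross-dock district collect straight from its region
    mean_clinic_monthly = (national_refr + national_froz) / params.n_clinics
    carrier_capacity = max(CARRIER_FACTOR * mean_clinic_monthly, 1.0)
    for c in clinic_ids:
        d = clinic_district[c]
        if d == crossdock:
            origin = district_region[d]
            rid = f"regional-clinic-{origin}-{c}"
        elif d in self_procuring:
            origin = d
            rid = f"district-clinic-{d}-{c}"
        else:
            origin = d
            rid = f"district-clinic-{d}-{c}"
        routes.append(
            Route(
                route_id=rid,
                origin=origin,
                stops=[c],
                transport=TransportDevice(
                    f"carrier-{c}", "vaccine_carrier", carrier_capacity
                ),
                trips_per_year=12,
                mode="collection",
            )
        )

    net = SupplyNetwork(locations=locations, routes=routes)
    net.validate()
    return net


def default_demand(
    network: SupplyNetwork,
    annual_births: int = PRINTED_ANNUAL_BIRTHS,
    target_fraction: float = 1.0,
    mode: str = "dynamic",
    sessions_per_month: int = 4,
) -> DemandModel:
    """Build the demand model from the clinic birth shares stored on a
    generated network."""
    shares = {
        l.location_id: l.birth_share
        for l in network.by_level("clinic")
        if l.birth_share is not None
    }
    total = sum(shares.values())
    shares = {c: s / total for c, s in shares.items()}
    return DemandModel(
        annual_births=annual_births,
        clinic_shares=shares,
        target_fraction=target_fraction,
        mode=mode,
        sessions_per_month=sessions_per_month,
    )


def generate_scenario_suite(
    vial_sizes: tuple[int, ...] = (10, 5, 2, 1),
    target_fractions: tuple[float, ...] = (1.0, 0.8, 0.6),
    seed: int = 12345,
    replications: int = 10,
    sensitivity: bool = False,
) -> list[ScenarioConfig]:
    """The experiment grid: vial sizes x target-population fractions,
    all under the baseline conditions (dynamic monthly demand, 1%
    inventory and shipping loss).  ``sensitivity=True`` appends the
    loss-rate (0% and 2%) and static-demand axes around the baseline."""
    suite = [
        ScenarioConfig(
            name=f"measles{v}dose_target{int(t * 100)}",
            measles_doses_per_vial=v,
            target_fraction=t,
            seed=seed,
            replications=replications,
        )
        for v in vial_sizes
        for t in target_fractions
    ]
    if sensitivity:
        for rate in (0.0, 0.02):
            suite.append(
                ScenarioConfig(
                    name=f"loss{int(rate * 100)}pct",
                    inventory_loss_rate=rate,
                    shipping_loss_rate=rate,
                    seed=seed,
                    replications=replications,
                )
            )
        suite.append(
            ScenarioConfig(
                name="static_demand",
                demand_mode="static",
                seed=seed,
                replications=replications,
            )
        )
    return suite
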