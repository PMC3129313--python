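# Methods

## The model

`vaxchain` is a discrete-event simulation of a national four-tier
vaccine cold chain: a central store supplies regional stores (multi-stop
cold-truck delivery loops), regional stores supply district stores (4×4
truck collections), and district stores supply clinics (vaccine-carrier
collections), where children arrive at immunization sessions and
receive the doses due at their visit.  The simulated commodity is the
vaccine *vial*: each vial has an antigen, doses per vial, packaged
volume, storage temperature class, formulation and shelf life.  The
experiment of interest swaps the measles presentation between 10-, 5-,
2- and 1-dose vials and measures the knock-on effects on availability,
storage and transport utilization, open-vial wastage and cost.

The year advances in days.  Within a day, events run in a fixed order —
expiry sweep, clinic sessions, order placement, shipments, loss sweep,
central restock — so each replication is exactly reproducible from its
seed.

### Inventory and vial accounting

Stock is held as FIFO queues of *lots*: runs of interchangeable vials
sharing an arrival time and expiry.  Vials within a lot differ in no
attribute, so lot bookkeeping (binomial thinning for breakage, count
arithmetic for draws) is distribution-identical to simulating each vial
as a separate entity while letting a 745-location network run in
seconds per replication.  A brute-force per-vial, per-dose replay of
the session rules serves as an independent oracle in the test suite.

Storage is capacity-constrained per temperature class (refrigerated
2–8 °C; frozen −15 to −25 °C, used by OPV only).  Arrivals are admitted
only up to free space; when space binds, admission is balanced by
complete child regimens — rounds that each add the vial mix covering one
further child's full schedule — rather than first-come-first-served by
antigen.  The same balanced allocation is used when a vehicle's capacity
binds.  Stored volume never exceeds a device's net capacity (asserted
after every event).  Diluent volume is excluded from storage and
transport capacity; it occupies clinic space only around administration
and is reported separately.

### Ordering

Each location runs a (s, S) policy: S is an order-up-to level per
antigen, computed as expected sealed-vial throughput per resupply
interval times a cover multiple (default 2 intervals); s is 25 % of S;
orders are the shortfall times a 25 % buffer, capped so the
post-delivery volume fits in storage.  Expected throughput uses the
Poisson expectation E⌈N/d⌉ of vials opened per session, so planning
anticipates open-vial wastage (small, irregular sessions open more
vials per dose).  Orders are evaluated at collection time; because
stock is non-increasing between replenishments this is equivalent to a
daily check of the reorder trigger.  Unfilled order portions are
backlogged to the next trip.  The ratio ordered-volume/vehicle-capacity
is recorded as the *demand-requested* transport utilization and may
exceed 100 %; actual loading is capped at 100 %.

The chain starts the year stocked at its order-up-to levels.  (An
alternative initialization at the reorder point, phase-aligned with
each location's first collection, was tried and rejected: it makes the
whole system restock towards its stationary level at once, and the
resulting transient depresses availability by several points.)

### Sessions and the multi-dose vial policy

Clinics hold sessions (default four per month).  Arrivals are generated
per visit stream — birth, 6, 10, 14 weeks, 9 months, plus an aggregate
tetanus-toxoid contact stream at five contacts per birth — either as a
deterministic equal split of the annual target (static mode) or as
Poisson draws (dynamic mode).  A child finding a vaccine out of stock
is a missed vaccination opportunity and does not re-queue.

Doses are drawn from an already-open vial when one holds doses,
otherwise the oldest sealed vial is opened.  At session end, open
lyophilized vials (measles, BCG, yellow fever) are discarded and their
remaining doses counted as open-vial wastage; open liquid vials (OPV,
TT, DTP-HepB-Hib) persist up to 28 days after opening.  A 1-dose vial
can never be partially used, so its open-vial wastage is identically
zero.

### Losses and expiry

Breakage is Bernoulli per vial: at trip departure with the shipping
loss rate (default 1 % per trip) and monthly in storage with the annual
inventory loss rate (default 1 %/year, converted to a monthly
probability).  Sealed vials past shelf life are discarded as expiry
wastage, counted separately from open-vial wastage.

### Exact conservation

Per antigen and replication, integer dose accounting balances exactly:

    initial stock below central + doses shipped from central
      = administered + open-vial waste + expiry + breakage losses
        + residual inventory (sealed and open) below central

This identity is asserted for every replication in the tests.

## Costing

Three components per scenario, applied to replication-averaged counts:

* administration = doses × (price/dose + injection-syringe cost) + one
  reconstitution syringe per opened vial (lyophilized only; oral OPV
  consumes no syringe);
* wasted doses = open-vial wasted doses × price/dose;
* disposal = safety-box cost per administered dose (no published value;
  defaults to 0 with a warning) + 0.0069 USD/g × mass of discarded
  vials and syringes (empty-vial masses; residue mass is not
  published).

Cost per injection = total / doses administered.  The 2-dose measles
price and empty-vial mass are unpublished; they are stored as
explicitly missing and any computation touching them raises instead of
imputing.  Two printed component figures in the source material are
internally inconsistent (the 10-dose wasted-dose cost does not equal
wasted doses × price; the 1-dose administration cost equals the 1-dose
total); the implementation follows the stated equations.

## The synthetic network

The real equipment inventory, route list and per-district populations
are unpublished.  `fixtures.generate_network` reproduces the published
structure — 1 central store, 7 regional stores on two cold-truck loops,
42 districts (7 self-procuring directly from central, 1 with no cold
storage acting as a cross-dock whose clinics collect from the regional
store), 695 clinics — and draws clinic birth shares log-normally
(σ = 1) so that small sessions exist; vial-size effects on open-vial
wastage are only visible with heterogeneous session sizes.  The annual
birth cohort is the published 586,880 (the published projection
557,381 × 1.0104⁵ evaluates to 586,974; the printed total is kept as
the input).

Device capacities are calibration constants (multiples of expected
throughput volume per resupply interval, with ±30 % per-device jitter),
chosen once so the baseline 10-dose scenario lands in the published
operating regime and then left alone:

| constant | value | meaning |
|---|---|---|
| `CENTRAL_CAPACITY_FACTOR` | 2.3 | × quarterly national volume |
| `REGIONAL_CAPACITY_FACTOR` | 12.5 | × quarterly subtree volume |
| `DISTRICT_CAPACITY_FACTOR` | 2.3 | × monthly subtree volume |
| `CLINIC_CAPACITY_FACTOR` | 4.4 | × monthly clinic volume |
| `COLD_TRUCK_FACTOR` | 2.0 | × quarterly loop volume |
| `FOUR_BY_FOUR_FACTOR` | 3.5 | × mean monthly district volume |
| `CARRIER_FACTOR` | 4.5 | × mean monthly clinic volume |

Under these constants the baseline run gives national measles
availability ≈ 0.89, regional cold rooms ≈ 12 % full, district
refrigerators ≈ 53–57 % full (median), and the largest-session clinics'
carriers above 100 % demand-requested utilization, with all of these
worsening as the vial size shrinks.

Two published regime features are *not* reproduced, deliberately:

* median district refrigerator utilization is ~0.55 rather than
  0.63–0.65 — under a (s, S) sawtooth whose order-up-to level must fit
  in storage, mean stock is about half the level, bounding mean
  utilization near 50 %; squeezing capacity further only caps the
  order-up-to level and costs availability;
* the median carrier demand-requested utilization is well below the
  published 149 % — monthly fixed-frequency collections at >100 %
  requested for the *median* clinic are arithmetically incompatible
  with ~90 % availability, so with the fixed monthly collection design
  only the upper tail of clinics exceeds 100 %.

What passing tests on this fixture show is the *mechanism* — volume-
driven crowding of storage and transport as doses get bulkier, and the
wastage/price trade-off — not the magnitudes of any real country's
chain.  Exact published table cells and histograms depend on the real
network data and are out of reach by construction.

## Numerical and design choices

* Replication seeds derive from (root seed, replication index) only, so
  vial-size scenarios with the same root seed see paired demand streams
  (common random numbers); scenario comparisons are paired.
* Tie-breaks in balanced allocation fall back to catalog order
  (BCG, DTP-HepB-Hib, YF, OPV, TT, M), one vial per antigen per pass.
* Multi-stop loops unload stops in list order while the shared truck
  capacity lasts.
* Shipments are instantaneous (no travel times are modelled); the
  in-transit term of the conservation identity is therefore zero.
* Static-mode session counts use cumulative rounding, so annual totals
  are exact.
* Availability with zero arrivals, storage utilization of a zero-
  capacity store, and cost per injection with zero administered doses
  are reported as missing (NaN), never as 0 or an error.
* Sealed shelf life is set to 730 days for all presentations (a
  documented stand-in; the source gives none), so sealed expiry is rare
  within the one-year horizon — expiry accounting is nonetheless
  implemented and tested with short-lived lots.

## Limitations

* No emergency orders between scheduled trips; stock-outs are bridged
  by backlog only.
* No temperature excursions, vial monitors, campaign demand pulses,
  seasonality or migration.
* Opened-vial volume is not charged against storage capacity.
* The maternal tetanus-toxoid population is folded into a birth-
  proportional aggregate stream rather than modelled separately.
* Cold-chain capital, energy, fuel and staff costs are out of scope of
  the costing (as in the source equations).
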