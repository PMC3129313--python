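# vaxchain

Discrete-event simulation of a national, four-tier vaccine cold chain —
central store → regional stores → district stores → clinics — for
studying how a vaccine's *vial size* (doses per vial) ripples through
storage, transport, wastage and cost.  It is written for immunization
programme analysts and supply-chain operations researchers who want to
ask questions like: *if we swap the 10-dose measles vial for 1-dose
vials, what happens to availability at the clinic door, to the cold
rooms and vaccine carriers in between, and to the cost per injection?*

The core trade-off: smaller vials eliminate open-vial wastage (a
partially used multi-dose vial must be discarded under the WHO
multi-dose vial policy — at session end for lyophilized vaccines, after
28 days for liquid ones) but occupy far more cold-chain volume per dose
and cost more per dose, so they can crowd out vaccines downstream and
*lower* availability.

## What it models

* Vial-level inventory with FIFO removal, shelf-life expiry, and
  Bernoulli breakage in storage and transport.
* Capacity-constrained cold storage (refrigerated / frozen) and
  transport, with balanced allocation by complete child regimens when
  space binds.
* (s, S) reordering: reorder point at 25 % of an order-up-to level, a
  25 % order buffer, and backlog of unfilled order portions to the next
  trip.  Ordered volume above vehicle capacity is reported as
  demand-requested utilization (> 100 % possible; actual loading caps
  at 100 %).
* Clinic sessions driven by a birth-cohort demand model (static or
  Poisson), with per-visit dose schedules for the six EPI antigens
  (BCG, DTP-HepB-Hib, YF, OPV, TT, measles).
* The three performance metrics — vaccine availability, transport
  capacity utilization, storage utilization — and the three cost
  equations (administration, wasted doses, disposal), giving cost per
  injection.

A synthetic, national-scale network generator (`vaxchain.fixtures`)
reproduces the published structure of a real four-tier chain (7
regional stores on two cold-truck loops, 42 districts, 695 clinics,
586,880 annual births) with documented calibration constants; see
`docs/methods.md` for what it does and does not claim to reproduce.

## Worked example

```python
import numpy as np
import vaxchain as vx

catalog = vx.default_catalog()                       # six EPI antigens, four measles vial sizes
network = vx.generate_network(vx.miniature_params(), seed=3)   # 1 region, 2 districts, 10 clinics
demand  = vx.default_demand(network)

for size in (10, 5, 2, 1):
    config = vx.ScenarioConfig(measles_doses_per_vial=size, replications=10, seed=1)
    res = vx.run_simulation(network, catalog, demand, config)
    print(size, round(float(np.mean(res.national_availability("M"))), 3),
          round(float(np.mean(res.national_open_vial_waste("M")))))
```

prints (availability of measles for arriving children, then mean
open-vial wasted measles doses per year):

```
10 0.827 1923
5 0.813 854
2 0.767 211
1 0.723 0
```

Shrinking the vial drives open-vial wastage to zero but, because the
packaged volume per dose rises from 2.6 to 26.1 cm³, the same storage
and transport now move fewer doses and availability falls.  Costing the
same runs (`vaxchain.costing.scenario_cost`) gives a cost per injection
rising from $0.38 (10-dose) to $1.18 (1-dose) on this miniature
network; the 2-dose scenario has no published price per dose and the
cost functions refuse to impute one.

The command line mirrors this: `vaxchain validate` checks catalog and
network files, `vaxchain run` executes one scenario and writes tidy and
summary CSVs plus a reproducibility manifest, and `vaxchain suite` runs
the full 4 vial-sizes × 3 target-population grid.

```bash
vaxchain run --miniature --vial-size 1 --replications 10 --seed 1 --out out/
vaxchain suite --miniature --seed 1 --out suite/
```

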