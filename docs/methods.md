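# Methods

This note documents the models behind `vaxfootprint`, the defaults they
ship with, and what the synthetic study conditions do and do not represent.

## 1. Emissions ledger

### Model

A scenario is a declarative list of line items evaluated against an
emission-factor registry. Item kinds and their formulas (all values in
kg CO₂e for `N` doses):

| kind       | formula                                             | example default |
|------------|-----------------------------------------------------|-----------------|
| transport  | `distance_km × factor × payload_kg / 1000`          | air 6200 km × 2.3 |
| material   | `mass_per_dose_kg × factor × N`                     | glass 1 g/dose × 0.72 |
| storage    | `days × per_day_factor`                             | 180 d × 8 kg/d |
| dry_ice    | `refreshes × charge_kg × N/doses_per_unit × factor` | 2 × 23 kg × N/5850 × 0.15 |
| waste      | `N × mass_per_dose_kg × (gross − credit)`           | 2 g/dose × (2.41 − 0.65) |
| travel     | `N × km_per_person × per_km_factor`                 | 1 km × 0.1 kg/km |
| fixed      | a pinned value                                      | last mile 566 kg |

The transport payload mass comes from the presentation's packaging
arithmetic (`mass_for_doses`), rounded to whole kg by default so that
reported lines match the precision of the reference figures (6154 kg per
10⁶ doses for the dry-ice presentation, 2517 kg for the palletized one).

### Uncertainty

Per-line relative errors are inputs (defaults range from 3% for dry ice to
500% for the order-of-magnitude mRNA-synthesis line). Lines are treated as
independent and first-order: absolute errors combine as root-sum-of-squares
within the transport group and the non-transport group, and the two group
errors combine the same way — algebraically identical to one global
quadrature, but the split exposes how completely transport dominates the
budget (the non-transport quadrature is ~0.7% of the transport one in the
dry-ice scenario). Reported per-dose values are rounded half-even at three
decimals; absolute errors are rounded **up** at the same precision, the
conservative convention for uncertainty bounds. No Monte-Carlo propagation
is attempted; with one dominant, symmetric error term, quadrature is
adequate and auditable.

### Deliberate reconciliations

Reference figures for the built-in scenarios contain a few internal
inconsistencies; the package resolves them as follows and keeps everything
configurable:

* **Payload mass of the dry-ice presentation.** One carton = 5850 doses at
  36 kg gives exactly 6154 kg per 10⁶ doses. The 23 kg dry-ice charge and
  3 kg container packaging physically travel with the carton but are *not*
  added to the ledger's payload mass: the dry ice has its own production
  line (1180 kg), and adding ~46 kg/carton to the freight mass would double
  count a refrigerant that is also consumed en route. The container extras
  are retained as spec metadata.
* **Truck line of scenario B.** The formula `1000 km × 0.2 × 2517 kg / 1000`
  evaluates to 503.4 kg; the builder uses the formula (a commonly cited
  printed value of 403 kg is inconsistent with it). The per-dose total is
  unaffected at three decimals.
* **Refrigerator line.** The reference tabulation carries 10 kg although
  `10 d × 0.1 kg/d` evaluates to 1 kg; the built-in scenarios pin the
  tabulated 10 kg (the alternative changes no reported digit). The pinning
  is recorded in the item's formula trace.
* **Liquid volume of the palletized presentation.** 54 L of vaccine per
  115,200-dose pallet gives 468.75 L per 10⁶ doses (reported as 469 L); the
  nominal 5 mL per ten-dose vial would give 500 L. The built-in spec uses
  the pallet volume and records the nominal value as metadata.
* **Steam factor.** The registry stores the literature compilation's
  136 kg CO₂e/kg as printed but flags it `suspect` (three orders of
  magnitude above comparable goods); no built-in scenario uses it.

## 2. Synthetic geography

The simulation needs realistic spatial structure, but real hub, pharmacy
and practice locations are proprietary. The generator therefore emulates a
Germany-scale network statistically on a planar 630 × 570 km rectangle
(since the downstream distance model is straight-line × road factor, a
projected plane is exact, not an approximation):

* **Pharmacies (15,000) and GP practices (35,000)** are drawn i.i.d. from a
  mixture: with probability 0.7 from one of 12 Gaussian "metro" clusters
  (σ = 25 km, centres uniform with a margin), else uniform background.
  Draws outside the region are rejected and redrawn. The 0.7/12/25 km
  defaults were chosen once so that tier distances land at the order of
  magnitude of a month of real German distribution (~1.2 M km); they are
  configuration, not constants.
* **Hubs (41 receipt + 69 intermediary)** are k-means centroids of the
  pharmacy cloud, so hub coverage follows demand density.
* **Wholesalers.** Ten wholesalers share the pharmacies: five nationwide
  (market shares 17/15/13/11/9%) and five regional at 7% each, restricted
  to west/east/north/south halves and a central box. Assignment uses exact
  largest-remainder counts, regional zones filled first, so empirical
  shares match targets to within one pharmacy.
* **GP→pharmacy mapping** is nearest-neighbour (ties to the lowest index).

All stages draw from sub-streams derived from one master seed (stage index
appended to the seed), so adding a stage never perturbs earlier ones and
every run is bit-reproducible.

What the generator does **not** emulate: real road topology (a single 1.3
road factor stands in), borders and coastlines, population-weighted metro
sizes, hub ownership by specific wholesalers, and opening-hour or
time-window effects. Passing tests therefore demonstrate the *statistical*
behaviour of the delivery model, not predictions for any real wholesaler.

## 3. Last-mile simulation

One month of distribution at reference settings: 4 delivery waves,
1,050,000 vials (6.3 M doses) at 40 g shipped mass per vial (36.9 g vial +
cryo-case share 112 g/49 vials, rounded), i.e. 42 t of payload.

* **Grouping.** Pharmacies attach to their nearest hub per wholesaler. A
  hub serving fewer than ⌈min_cluster/2⌉ = 8 of a wholesaler's pharmacies
  is consolidated: its pharmacies are re-served from the next-nearest hub.
  This mirrors depot consolidation of low-volume territory and is the same
  half-cluster threshold the remainder-merge rule uses. At reference scale
  it yields ~830–840 delivery clusters of mean size ~18.
* **Clustering.** Within a (wholesaler, hub) group, pharmacies are sorted
  by angle around the hub (radius breaks ties) and cut into consecutive
  arcs of target size `round(n / ceil(n / 30))`; a trailing arc smaller
  than 7.5 merges into its neighbour, so at most one under- (or slightly
  over-) sized remainder survives per group.
* **Tours.** Cluster and GP tours are closed TSP tours: nearest-neighbour
  construction (ties to the lowest stop index) refined by first-improvement
  2-opt until no strict gain remains. 2-opt never worsens the construction
  tour; exhaustive enumeration (≤ 9 stops) provides the exact optimum in
  tests. Network-tier service is modelled as two-way star legs between each
  active intermediary hub and its nearest receipt hub rather than a TSP
  over hubs — hub topology is wholesaler-owned and the reference accounting
  treats it as a fixed two-way leg.
* **Durations.** `distance/speed × 60 + stops × per_stop + fixed` with
  90/60/40 km/h per tier, 10 min per pharmacy or GP stop, 20 min hub
  loading, 10 min intermediary reload, 30 min pharmacy preparation. The
  printed reference durations for a model tour cannot be reconstructed
  exactly from the printed legs and speeds, so durations are reported but
  not pinned to any reference value; all constants are configuration.
* **Waves.** Clusters are fixed for the month by default, so one wave is
  computed and scaled by the wave count; `recluster_per_wave` rotates the
  angular sweep per wave instead.

### Emission accounting

Two modes, differing by what is charged:

* *most likely* — the vaccine rides existing wholesale tours; only its
  freight units count: `loading_mass (t) × representative_km × 0.1 kg/t·km`.
  `representative_km` is the mean distance the payload is carried per wave
  (network leg + half the cluster tour), accumulated over waves. For the
  reference monthly inputs (42 t carried ~849 km) this is ~3.6 t CO₂e/month.
* *worst case* — dedicated vaccine tours; every driven km is charged at
  0.3 kg/vehicle-km. For a dedicated-tour month (~1.2–1.4 M km) this is
  ~370–430 t CO₂e/month, about two orders of magnitude above the
  additional-load mode — the quantitative core of the "additional load
  only" argument.

The factor pair (0.1 kg/t·km, 0.3 kg/vehicle-km) is the only dimensional
reading of the reference accounting that reproduces its printed monthly
totals; the captions there ("100 g/1000 km") are dimensionally inconsistent
as printed.

## 4. Numerical and design choices

* Angular sweep clustering is deterministic; `round()` uses banker's
  rounding (`n = 31` splits 16 + 15).
* 2-opt accepts improvements greater than 1e-12 only, guaranteeing
  termination; brute force breaks ties toward the lexicographically
  earliest order.
* k-means (scikit-learn, `n_init=4`) is seeded from the master seed; with
  fewer demand points than hubs, hub placement falls back to uniform
  sampling.
* Degenerate inputs: zero stops produce a zero-length tour; zero deliveries
  produce an all-zero month; empty scenarios total zero; division-style
  operations (per-vial, E-factor, car-km) reject non-positive denominators.
* Problem sizes in the test suite: the reference-scale simulation (15,000
  pharmacies, 35,000 GPs, ~3,300 tours) runs once as a shared fixture in a
  few seconds; unit-level properties use a 600-pharmacy model.

## 5. Known limitations

* Factors are user-supplied constants, not a life-cycle database; results
  inherit their (large) uncertainties, which is why the ledger carries
  per-line errors as first-class data.
* No vehicle capacities, time windows, traffic, or multi-day inventory
  dynamics; no vial-expiry waste.
* The simulated tier distances match the reference month only at the order
  of magnitude — exact reproduction would require the unpublished real
  locations. Checks on the simulation are therefore property-based
  (distance band, cluster structure, determinism, scaling homogeneity,
  TSP-oracle bounds) rather than value-pinned.
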