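# Methods

This note documents the model, its parameters and defaults, the
synthetic input generators, and the design choices made where the
design was genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Scope and purpose

`beescape` links residues of a systemic insecticide in pollen from a
single treated cornfield to colony-level outcomes. Exposure occurs
exclusively through consumption of pollen: corn produces no nectar, and
for a soil-applied or seed-treatment compound, contact exposure of
foragers is negligible. Sublethal effects are not simulated. The
simulation horizon is 480 days — a full calendar year plus 115 days of
the following spring, reusing year-1 landscape and weather inputs — so
that colony strength can be censused both before overwintering (21
October, simulation day 294) and in early spring (1 April of year 2,
day 456, on the 365-day calendar used throughout). Colonies are never
killed by a winter size threshold; runs always complete, keeping
spring censuses comparable across treatments.

## The exposure-effects chain

### Pollen storage as daily cohorts

All pollen brought into the hive on one day is assumed completely
mixed: the age-0 cohort's concentration is the mass-weighted mean of
the day's loads. Cohorts age daily; pollen older than 7 days is pooled
into a single old cohort (again mass-weighted). Pollen is never eaten
on its collection day; consumers draw from age 1 upward, freshest
first, shifting to older cohorts only as younger ones are exhausted.
Mass and residue mass are conserved exactly by construction, and the
package tracks cumulative deposit/ingestion tallies so that the balance
can be audited to 1e-9 relative over a full run.

### Consumption rates and dose ledgers

Daily pollen consumption is uniform within each life stage (pollen
serves as the protein proxy; larvae are modelled as eating pollen
directly rather than via jelly, with the jelly-to-pollen conversion
already folded into the rate):

| class              | g pollen / bee / day |
|--------------------|----------------------|
| worker larva       | 0.00653 |
| in-hive worker     | 0.0065  |
| forager            | 0.000041 |
| drone larva        | 0.0057  |
| adult drone        | 0.0000002 |

Every class eats from the same daily withdrawal mix (the store does not
resolve who gets which cohort; preference is by age only), so the
per-capita dose of a class on a day is its drawn mass times the blended
concentration divided by its head count. When the store cannot cover
total demand, all classes are shorted pro rata and the shortfall is
reported (it feeds a brood-survival penalty, see below).

Per-capita daily doses are recorded in dose ledgers. Because doses are
identical across cohorts within a class, the engine keeps one ledger
per class and reconstructs any cohort's personal window (e.g. an adult
that switched from in-hive to forager duty mid-window) from its
stage-by-age history; this is observationally equivalent to a ledger
per cohort and lets the adult population update vectorize.

### Dose–response curves

Quantal mortality uses the two standard benchmark-dose families:
log-logistic `P(d) = γ + (1−γ)/(1+exp(−α−β ln d))` (with `P(0)=γ` and a
1e-12 dose floor to avoid `ln 0`) and Weibull
`P(d) = γ + (1−γ)(1−exp(−β d^α))`. Doses are cumulative ng active
ingredient per bee over the curve's window. `fit_curve` maximizes the
binomial log-likelihood (Nelder–Mead on transformed parameters,
heuristic starts from a regression on the linearized form) and reports
log-likelihood and AIC so families can be compared; non-convergence and
boundary data (all dead / all alive) are flagged, never silent.
`lc(curve, p)` inverts on the *corrected* mortality scale
`(P−γ)/(1−γ) = p` (closed form in both families).

The three default curves ship anchored to published dietary endpoints,
because the full fitted parameter sets of the underlying laboratory
studies are not public. Concentration→dose conversion is consumption
rate × window days:

* **larval chronic** (log-logistic, 6-d window): LC50 at dietary
  2800 ng/g, i.e. 2800 × 0.00653 × 6 ≈ 109.7 ng/bee; slope β = 2. The
  21-d laboratory exposure is mapped onto the model's 6-d larval
  consumption window (configurable).
* **adult acute** (Weibull, 2-d window): corrected mortality 0.999 at
  dietary 200 ng/g over 2 days at the in-hive rate (2.6 ng/bee);
  shape α = 4. This reproduces "near-total mortality at the dietary
  LC100" while keeping low-dose acute mortality negligible.
* **adult chronic** (Weibull, 10-d window): LC50 at dietary 50 ng/g
  over 10 days (3.25 ng/bee); shape α = 3. No published summary pins
  this curve; the default places the cumulative 10-d LC50 at ~2.2× the
  acute 2-d LC50, i.e. chronic exposure is more toxic per unit daily
  intake but less than the same total dose delivered acutely —
  consistent with the time-reinforced chronic toxicity reported for
  neonicotinoids. All three curves use γ = 0 (laboratory control
  mortality is not re-applied in the colony, which has its own
  background rates); every parameter is overridable via the curves
  YAML.

### Applying mortality without double counting

Larval cohorts are judged once, at pupation, on their cumulative 6-day
dose. Adults are judged daily on rolling 2-d and 10-d window doses.
Because consecutive windows overlap, applying `P(window dose)` naively
every day would re-kill the same bees. Each endpoint therefore keeps
the maximum mortality already applied, `P*`, and applies only the
conditional increment `max(0, (P_t − P*)/(1 − P*))`; the two endpoints
combine multiplicatively on survival. Under constant exposure the
increments telescope so total applied mortality equals the curve value
at the full-window dose, and after a transient exposure the cumulative
applied mortality can never exceed the curve at the largest window
dose observed (both properties are tested, including against a
per-bee Monte-Carlo oracle at 100 000 bees). How the original study
combined the two adult endpoints is not public; multiplicative
combination was chosen because it is order-independent and consistent
with independent endpoint hazards. Worker and drone cohorts, larval
and adult, pass through identical machinery.

Cohort counts are real-valued with expected-value mortality by
default; a seeded binomial mode (used by the experiment runner)
provides stochastic replicates. When an increment is exactly zero no
random numbers are drawn, which makes a zero-residue run bit-identical
to a run with the exposure module disabled under the same seed.

## Colony engine

A deliberately compact cohort engine drives the exposure module:

* **Development**: egg 3 d → larva 6 d → pupa 12 d for workers
  (3/7/14 for drones); adults switch from in-hive duty to foraging at
  age 21 d. An egg laid on day *t* emerges on day *t*+21.
* **Egg laying**: a half-sine over days 60–270 peaking at 1600
  eggs/day, capped by nurse capacity (0.12 eggs per adult worker);
  4% drone eggs during days 100–240.
* **Background mortality** (daily): egg 0.03, larva 0.01, pupa 0.001,
  in-hive adult 0.004, forager 0.08 on flight days (0.004 otherwise),
  adult drone 0.05; maximum adult age 290 d. These give a summer adult
  lifespan of roughly five weeks, long-lived winter bees, a peak
  colony of ~45 000 adults and an October strength near 20 000 in the
  baseline scenario — plausible for a strong temperate colony.
* **Energetics**: honey demand per bee per day (in-hive 12 mg, flying
  forager 35 mg, larva 60 mg incl. nursing overhead, drone 20 mg);
  nectar sugar converts to honey at 1/0.8; store cap 60 kg. Unmet
  honey demand applies a starvation mortality proportional to the
  deficit. Unmet pollen demand penalizes larval survival
  (0.3 × shortfall fraction per day).
* **Daily order**: (1) pollen store ages, (2) laying, (3) foraging and
  deposition, (4) consumption + dose recording + beekeeping,
  (5) adult exposure mortality, (6) development (larval exposure
  mortality at pupation), (7) background mortality, (8) record.
  Deposits precede next-day edibility by construction.

The run record (one row per day) reports adults, brood stages, honey,
pollen store, pollen collected in total and from the test field, the
pollen shortfall, and the per-class daily doses.

## Foraging

Flight happens only on days with no precipitation and maximum
temperature ≥ 15 °C, for the full astronomical day length. Available
forager-seconds are split between pollen and nectar trips and across
patches deterministically:

* The **pollen share** of effort tracks demand: desired collection is
  1.05 × the day's consumption plus 20%/day of the deficit to a
  reserve target (7 days of demand, floored at 2 kg and capped at 6 kg
  of comb space). Tracking consumption keeps the colony eating
  *recent* pollen — as bees do — rather than digging into the old
  pooled cohort whenever the reserve happens to be full; without this,
  residue trapped in the pooled cohort would keep dosing the colony
  for months after the flowering window.
* The **allocation weight** of a patch is
  `attractiveness × min(availability, saturation) / trip_time × D̄`,
  where `D̄` is the mean of `(1 + d/250 m)^-3` over the patch's pixels
  and trip time uses the centroid distance
  (`2d/6.5 m s⁻¹ + gathering + 300 s handling`). Averaging the distance
  discount over pixels, not the centroid, matters: a large field is
  foraged where its area actually lies, and a wrap-around patch whose
  centroid happens to fall near the hive gains no spurious advantage.
  The saturation (50 kg pollen / 200 L nectar per day) stops a vast
  corn block from absorbing the entire foraging force by area alone.
  Attractiveness is 1.0 for semi-natural covers and alfalfa/buckwheat,
  0.5 for soybeans and beans/peas, 0.25 for corn and sorghum/millet
  (wind-pollinated, low-attractiveness crops).
* Loads are 0.015 g pollen or 50 µL nectar per trip; collection from a
  patch is capped by its daily availability, and each deposit carries
  its source patch's residue concentration for the day.

This replaces the parent model's individual dance-recruitment foragers
with a two-knob abstraction (distance discount, availability
saturation) that preserves the distance/gathering-time/availability
trade-offs; its fidelity is asserted only through the qualitative
landscape relationship (below), not trip-level behaviour.

## Scenarios and experiment design

* **baseline**: no mites, no beekeeping; gathering times 600 s
  (pollen) / 1200 s (nectar) everywhere.
* **stress**: semi-natural gathering times doubled (1200/2400 s),
  honey harvested down to 10 kg on day 240, feeding to 5 kg whenever
  stores drop below 2 kg, and a mite/virus burden approximated by
  elevated background mortality (+0.008/d in-hive, +0.012/d brood).
  The proxy reproduces the intended outcome — markedly weaker
  colonies (October control strength roughly 60% of baseline) — not
  mite mechanics.

The standard design crosses 2 scenarios × 4 synthetic landscapes
(20/40/60/80% semi-natural) × 6 residue levels
{0, 12.2, 19, 39.9, 200, 2800} ng/g × N repetitions over 480 days.
Each repetition's colony seed is a hash of (base seed, scenario, site,
rep) — *not* the residue level — so exposed runs share every stochastic
draw with their control and the colony-level effect metric
(100 × exposed adults / control adults at a census day) pairs exactly.
Weather is seeded per site; landscapes per site. Cells are fully
seed-isolated, so execution order cannot affect results, and runs
already on disk are skipped on resume.

Problem sizes: the in-package acceptance suite runs the full design at
10 repetitions (~480 simulations, about a minute); the acceptance
script uses 5 repetitions. Both are the package's standard desk-scale
configurations; repetitions are a free parameter of `Design`.

## Synthetic inputs

* **Landscapes** emulate corn-belt compositions on a 101 × 101 grid of
  30-m pixels with the colony at the centre of a contiguous central
  cornfield (default 10 ha ≈ 111 pixels). Target category fractions
  (semi-natural → 55% pasture / 45% deciduous forest; other crop →
  50% corn / 50% soybeans; alfalfa/buckwheat → alfalfa) are realized
  by a seeded ring-mosaic: each annulus around the hive is cut into
  contiguous arcs proportional to each class's remaining quota, with
  random rotation and class order per ring. Field-sized clustered
  regions result, every class gets the same radial profile in
  proportion to its cover, and the measured composition lands within
  ±3% of target (verified, with retries, at generation time).
  Remaining area is "developed" (excluded). What this generator does
  *not* emulate: real field-boundary geometry, roads and linear
  features, spatial autocorrelation of cover types, or between-site
  idiosyncrasy of real landscapes — so passing the landscape tests
  shows the composition→collection mechanism works, not that any real
  site's numbers are reproduced.
* **Crop parameters** (per-flower production, densities, windows,
  sugar) are package defaults of literature magnitude — e.g. corn
  sheds 16 mg pollen/m²/day over days 203–216 (≈ 22 kg/ha per season),
  soybeans 7.5 mg/m²/day plus modest nectar over days 182–235 — with
  beans/peas and sorghum/millet each pooled to one parameter set.
  Semi-natural covers use monthly per-m² levels (March–October
  profile peaking in May) scaled by a low/medium/high category factor
  (0.4/1.0/1.6).
* **Weather** is a sinusoidal daily maximum temperature (mean 12.5 °C,
  amplitude 16 °C, warmest near day 200, N(0, 3 °C) noise), Bernoulli
  wet days (p = 0.3) with gamma amounts, and day length from solar
  declination at 44° N. It emulates an upper-Midwest season's foraging
  gate (frequency of flyable days), not any station record.

## Numerical and degenerate-input choices

* 4-connectivity defines patch adjacency (switchable to 8); patches
  under 1 ha are dropped by default (configurable); pixel membership
  in the 1.5-km radius is by pixel centre; composition percentages use
  the pixelated circle as denominator, so categories plus exclusions
  sum to ≤ 100%.
* Doses below 1e-12 ng are treated as zero in the log-logistic form.
* Withdrawal from an emptied pollen cohort resets its concentration to
  zero; an empty store yields zero dose and full shortfall, never an
  error.
* The trip allocator redistributes seconds from availability-capped
  patches to open ones in a single pass; residual effort after that
  pass is dropped rather than iterated to convergence.
* Stochastic mortality draws binomial deaths on the integer part of a
  cohort and applies the expectation to the fractional remainder.
* Effect metrics raise (rather than return a number) when the control
  colony has no adults on a census day; the pollen share returns NaN
  when nothing was collected in the window.

## Known limitations

* The colony engine is a compact stand-in for the full published
  colony model: no dance recruitment, no explicit mite/virus
  epidemiology, no comb geometry, no queen failure or swarming.
  Absolute colony sizes are plausible but not calibrated to any field
  dataset.
* In this implementation the stress scenario *increases* the share of
  pollen taken from the central field (semi-natural patches become
  slower to exploit) and consequently shows stronger proportional
  effects at the extreme residue level than the baseline scenario.
  The reference behaviour of the full model is the opposite on both
  counts; the package asserts only the control-run landscape
  relationship (less test-field pollen with more semi-natural cover)
  and the residue-level ordering, which hold here.
* Larvae eat store pollen directly; nurse-jelly transfer lag is not
  modelled.
* Only the pollen route is implemented: no nectar, water, or contact
  exposure, and no sublethal endpoints.
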