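# Methods

`enercomm` simulates a community of small herbivorous mammals as
individual agents with explicit daily energy budgets, foraging on a
gridded landscape whose resources are seasonally renewed and can be
suppressed by drought events.  This note documents the model, its
assumptions, the parameterisation, and what the simulated conditions do
and do not represent.

## Model structure

### Landscape

The world is a square lattice of 10 m x 10 m cells (toroidal by default,
to avoid edge artefacts).  A fixed fraction of cells (default 0.3) is
habitat; only habitat holds resources.  Every habitat cell is renewed
each morning to a common daily cap that follows a sinusoid,

    cap(day) = mean_cap * (1 + A * sin(2*pi*(day - peak + 91.25)/365)),

with `mean_cap = 14 kJ`, amplitude `A = 0.3` and the peak at mid-year
(day 182).  Renewal fully resets cells; there is no carry-over or
logistic regrowth (the simplest reading of daily renewal, switchable in
principle by replacing `renew_and_force`).

Fragmentation is varied *per se*: the habitat amount never changes, only
its arrangement.  The generator grows habitat from seed cells by random
frontier accretion; the fragmentation level sets the number of seeds
(low: ~1 per 1000 habitat cells -> one or two large blocks; medium: ~1
per 125 -> several separated patches; high: every cell placed
independently -> single-cell scatter).  Seeds are placed with a minimum
separation (rejection sampling) so medium-level patches rarely coalesce;
mean 4-neighbour patch size then decreases strictly from low to high for
effectively all seeds, which is the property the experiments rely on.
Any neutral-landscape generator with that property would serve.

### Species

Ten species are characterised solely by adult body mass, log-spaced over
10-100 g.  All physiology derives from mass `M` (grams):

| trait | form | default | note |
|---|---|---|---|
| maintenance | `b0 * m^0.75` kJ/d | `b0 = 1.2` | near-basal; see calibration |
| postural cost | `0.01 * m_tot^0.75` kJ/h, 4 h active | | charged on foraging days |
| incremental cost | `0.05 * m_tot^0.68` kJ/km | | `m_tot` includes carried fat |
| max home-range area | `16000 * M^0.24` m^2 | | ceiling -> radius in cells |
| food share per visit | 0.9 | | fraction of a cell's standing crop |
| storage capacity | `0.45 * m * 39.3` kJ | | catabolizable reserve |
| growth (postnatal) | von Bertalanffy, `k = 0.075 * M^-0.25`/d | | cube-root form |
| growth (embryo) | Gompertz to birth mass (8 % of adult) | | continuous at birth |
| gestation / lactation | `8*M^0.25` / `10*M^0.2` d | | ~2-4 weeks |
| maturity / lifespan | `30*M^0.25` / `548*(M/10)^0.25` d | | |
| assimilation | 0.8 efficiency, 0.1 digestive loss | | intake x 0.72 usable |

### Daily schedule

Each simulated day: (1) renew resources under the drought multiplier;
(2) draw a fresh foraging order, weighted by `mass^0.5 / (1 + local
conspecific count)^2` via Gumbel keys — a slight size advantage plus a
persistent advantage for individuals in sparse neighbourhoods; (3) each
individual forages in turn around its core cell, near to far, taking its
food share of each cell until its aim is met, its maximum radius is
reached, or it can no longer pay for travel; cells are depleted in
place, which is the only interaction between individuals; (4) intake is
assimilated and allocated by strict priority: maintenance and
locomotion (storage covers deficits; an unpayable survival cost is
death), then offspring demand for reproducing females (never funded from
storage), then own growth, then storage top-up, with surplus beyond the
cap discarded; (5) reproductive transitions (conception when a mature
female's store exceeds 60 % of capacity; birth after gestation; weaning
after lactation, when juveniles become independent, disperse near the
natal core and must establish a home range within ten trials or die);
(6) ageing, lifespan mortality, and metric recording.

Two foraging refinements matter for drought dynamics.  First, each
harvested cell costs a round trip (twice the centre distance) whose
marginal cost is added to the day's remaining aim, and an individual
stops expanding when cumulative travel can no longer be paid from storage
plus the day's assimilate.  Second, an individual skips cells whose
assimilable yield cannot repay the trip (optimal central-place foraging);
skipped cells still count toward the searched range, so under scarcity
the *realised home range widens* while harvesting stays economic.  The
home-range size reported daily is the searched disc in cells; the 7-day
memory of these sizes defines the cap used by the `maintain` drought
strategy.

### Drought forcing and behavioural strategies

A drought multiplies all resource caps by `1 - m` (m = 0.8, 0.9, 0.95,
0.98 by default) for `L` days (3, 9, 22, 57), with 1-day linear
transitions on both ends (a 3-day event is ramp / plateau / ramp; the
single transition day sits at the midpoint `1 - m/2`).  Droughts start
mid-summer, when caps peak.  Observed-series droughts are obtained by
run-length-encoding the days on which a soil-moisture index falls below
a percentile threshold; the threshold maps to the magnitude (2 % -> 0.98
etc.), and 1-2-day events drop the plateau but still bottom at `1 - m`.
A synthetic index generator (Gaussian-copula AR(1), uniform marginal)
provides percentile-scaled series with realistic multi-day runs for
tests and demonstrations.

During drought days individuals follow one of three strategies:
`increase` (default: unchanged aims, so search effort rises), `maintain`
(aims unchanged but the searched disc is capped at the pre-drought 7-day
mean home-range size), or `decrease` (forage only for unmet survival
costs, which can mean no foraging at all while storage lasts).

### Individual variation

Each individual draws a persistent body-condition multiplier, uniform
within +/-60 %, applied to its storage capacity.  Without it, all
members of a species hit zero reserves on nearly the same drought day
and severe-drought die-offs overshoot to extinction even where a
sustainable survivor density exists; the jitter spreads starvation times
so the crash resolves to the survivor cohort the resource supply can
carry.  It is the model's stand-in for the many unmodelled sources of
inter-individual heterogeneity (condition, dominance, microhabitat).

## Parameterisation and calibration

The allometric exponents are literature-standard (3/4-power metabolism,
~0.7 locomotion mass exponent).  The coefficients are calibration
inputs: they were chosen once so that, on the reference world (50 x 50
cells, habitat fraction 0.3), the model produces (i) a persistent
10-species community over multi-year horizons with populations in the
low hundreds; (ii) starvation endurance of one to a few weeks, so the
22-day drought is survivable largely on reserves while the 57-day
drought is not; (iii) a severity gradient in which 80-90 % reductions
are absorbed, 95 % causes partial richness loss, and 98 % for 57 days
kills roughly half the community rather than all of it, with small
species (cheap travel, low absolute needs) the likely survivors and
large species failing on long droughts despite larger reserves.  After
this calibration the defaults were frozen; all experiments in the tests
and the acceptance script run the frozen defaults.

Two defaults deserve honesty.  The reserve capacity (45 % of body mass
at fat energy density) is generous for small mammals if read as adipose
tissue alone; it is better read as total catabolizable reserve plus the
unmodelled behavioural slack (torpor, cached food) that lets real
populations persist through multi-week shortages.  The incremental
locomotion coefficient is about half the classical treadmill value,
reflecting that foraging movement is not sustained running.  Both are
single config fields (`AllometryConfig.storage_frac`,
`AllometryConfig.incremental_coeff`).

## Simulated conditions and problem sizes

The experiment grid follows the study protocol: community runs of 10
years with one drought starting mid-summer of year 5, single-species
runs of 3 years with the drought in year 2, 20 replicates per scenario,
crossing three fragmentation levels, four magnitudes, four lengths and
three behavioural strategies (2,880 drought runs plus controls at full
scale).  The package's own headline experiments (tests and
`scripts/acceptance.py`) run a reduced world — 50 x 50 cells, 5 years
with the drought in year 3, 10 replicates — chosen so the full
computation completes on one desktop CPU in minutes while preserving
the community patterns; richness is evaluated one year after the
drought ends against paired no-drought controls.

## What the synthetic conditions do not show

The landscape is neutral and binary, resources are generic and spatially
uniform within habitat, and drought forcing is spatially homogeneous;
there is no thermoregulation, water budget, torpor, predation, or
interference competition beyond resource depletion and foraging order.
Passing tests therefore demonstrate the internal consistency of the
energy bookkeeping and the qualitative community phenomenology
(fragmentation-dependent drought impacts, storage-mediated survival),
not quantitative predictions for any real landscape or species.  The
10 % richness-pattern tolerances in the acceptance suite reflect
replicate stochasticity at the reduced scale.

## Numerical choices

Cells are visited in strictly increasing centre distance with row-major
tie-breaking, so every foraging walk is deterministic given the order;
the daily order is the only stochastic element of foraging.  One
`numpy.random.Generator` per run is drawn in a fixed documented order
(initialisation, daily order, offspring sexes, dispersal candidates), so
runs are bitwise reproducible from the config seed and independent of
worker count in sweeps.  The ledger identity `assimilated + shortfall =
maintenance + locomotion + repro + growth + storage_delta + overflow` is
asserted to ~1e-13 in audit mode for every individual-day, along with
storage bounds and community intake <= daily supply.  Degenerate inputs
(all-matrix worlds, empty event lists, zero-amplitude seasons, litters
of zero) are exercised in the unit tests.

## Known limitations

Establishment evaluates candidate ranges against survival needs only
(not storage refill), so marginal ranges can be accepted that later
force daily storage draws.  Lactating mothers never draw storage for
offspring (a conservative reading; the alternative is a one-line change
in `allocate_arrays` usage).  The "competitors per foraging patch"
metric counts all species within the searched disc, not conspecifics
only.  Weaned litters convert to independent juveniles instantaneously;
there is no partial independence.  At 50 x 50 cells the severe-drought
survivor cohort is small (~10-20 individuals), so species-level survival
at 98 % x 57 d has high replicate variance — a genuine small-world
effect, not numerical noise.
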