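# enercomm

An individual-based, metabolically explicit community model of small
herbivorous mammals, built to study how **habitat fragmentation** and
**drought-induced resource shortage** jointly shape individual energy
dynamics, population persistence and species coexistence.

It is aimed at ecological modellers who want a fast, reproducible,
fully-scriptable implementation of a daily-timestep energy-budget
community simulation: ten species defined only by body mass (10-100 g),
foraging as central-place foragers on a gridded neutral landscape,
competing by depleting shared resources, and allocating assimilated
energy down a survival-first priority ladder.

## The model in brief

Each species' physiology derives allometrically from adult mass *M*:
maintenance `b0·m^0.75`, locomotion split into postural (per active
hour) and incremental (per km, mass-dependent) costs, a maximum daily
home-range radius from an area-mass relation, a per-visit food share,
and a fat store capped at a fixed fraction of body mass.  Daily intake
is discounted by assimilation efficiency and digestive loss, then
allocated in strict priority

    maintenance -> locomotion -> reproduction -> growth -> storage,

with fat reserves covering survival deficits; an unpayable survival cost
is death, and every individual-day closes the ledger identity

    assimilated + shortfall =
        maintenance + locomotion + repro + growth + Δstorage + overflow.

Embryos grow along a Gompertz curve, postnatal animals along a von
Bertalanffy curve; mothers who cannot pay offspring demand abort the
litter (pregnancy) or lose juveniles one by one (lactation).

Droughts multiply all resource caps by `1 − m` for `L` days (magnitudes
0.98/0.95/0.90/0.80, lengths 3/9/22/57, 1-day linear ramps), either as
designed events or thresholded from a soil-moisture-index series (a 2 %
threshold maps to a 98 % reduction).  During droughts individuals follow
one of three strategies: `increase` search effort (default), `maintain`
the pre-drought home-range size (7-day memory), or `decrease` activity
to survival needs only.  See `docs/methods.md` for the full model
description and parameter table.

## Worked example

A 50×50-cell medium-fragmentation community, 3 years, with a severe
9-day drought (95 % resource reduction) starting mid-summer of year 2:

```python
from enercomm import ScenarioConfig, DroughtEvent, run_simulation
from enercomm.scenarios import mid_year_day

start = mid_year_day(2)                      # day 547: mid-summer, year 2
cfg = ScenarioConfig(side_cells=50, years=3, fragmentation="medium",
                     events=[DroughtEvent(start, 9, 0.95)], seed=42)
res = run_simulation(cfg)
print(res.summary().to_string(index=False))
print("richness one year after the drought:", res.richness(start + 365))
```

which prints (abridged to five species):

```
 species  adult_mass  final_population  mean_lrs  recovery_time  resistance
       1   10.000000                19  3.504425          290.0    0.389948
       2   12.915497                20  4.508929            0.0    0.513514
       5   27.825594                36  5.472527            0.0    0.457143
       8   59.948425                34  7.014286          268.0    0.726073
      10  100.000000                30  3.883117            NaN    0.553846
richness one year after the drought: 10
```

Populations dip during the drought (`resistance` = minimum population
over the drought and its aftermath relative to the 30-day pre-drought
mean — the seasonal winter trough contributes to it), most species
regain their baseline immediately or within the following year
(`recovery_time` in days after drought end; `NaN` means censored within
the run), `mean_lrs` is the mean number of offspring raised to
independence per individual, and no species is lost: a 9-day drought is
bridged by fat reserves.  Long severe droughts (98 % for 57 days) are
not bridgeable by storage and remove roughly half the community, with
small-bodied species — cheap travel, low absolute needs — the typical
survivors.

`res.daily()` returns the per-day, per-species table (population, mean
home-range size, energy balance, storage, competitors per foraging
patch) behind the figures such plots are made from.

## Command line

```bash
enercomm generate-landscape --side 100 --habitat-frac 0.3 \
    --fragmentation medium --seed 1 --out landscape.txt
enercomm run --config scenario.yaml --out results/
enercomm sweep --mode community --replicates 20 --out sweep/
enercomm droughts-from-smi --smi site.csv --threshold 0.02 --out forcing.csv
```

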