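"""Allometric derivation of species traits from adult body mass.

Every trait of a simulated species is a deterministic function of its adult
body mass ``M`` (grams) and a table of allometric constants.  The community
is characterised purely by a body-mass axis (default ten species log-spaced
over 10-100 g), so this module is the single source of physiological
parameters for the rest of the model:

* maintenance metabolism ``b0 * m**b1`` (metabolic scaling, default
  exponent 0.75),
* locomotion costs split into postural costs per active hour and
  incremental costs per km travelled, both mass-dependent; carrying stored
  fat increases the mass entering these costs,
* the maximum daily home-range radius implied by an allometric
  area-mass relation and the landscape cell size,
* an allometric share of a cell's resources accessible per visit,
* fat-storage capacity as a fraction of body mass times fat energy density,
* growth curves (Gompertz before birth, von Bertalanffy afterwards) and the
  reproduction schedule (gestation, lactation, maturity, litter size).

The exact coefficient values are calibration inputs, exposed on
:class:`AllometryConfig` with defaults in the range standard for small
terrestrial herbivores; see ``docs/methods.md`` for the calibration
rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AllometryConfig",
    "SpeciesTraits",
    "default_community",
    "derive_traits",
    "maintenance_rate",
    "locomotion_cost",
    "max_home_range_radius",
    "growth_mass",
    "fat_mass",
    "traits_to_frame",
    "write_trait_table",
    "read_trait_table",
]


@dataclass(frozen=True)
class AllometryConfig:
    """Allometric constants shared by all species.

    Units: masses in g, energies in kJ, times in days, distances in km
    unless noted.  ``*_exp`` fields are exponents on adult (or current)
    body mass in grams.
    """

    # maintenance: b0 * m**b1  [kJ/day], near-basal coefficient
    b0: float = 1.2
    b1: float = 0.75
    # postural cost of activity: coeff * m**exp  [kJ/hour active]
    postural_coeff: float = 0.01
    postural_exp: float = 0.75
    active_hours: float = 4.0
    # incremental locomotion: coeff * m**exp  [kJ/km]
    incremental_coeff: float = 0.05
    incremental_exp: float = 0.68
    # maximum home-range area: coeff * M**exp  [m^2]
    hr_area_coeff: float = 16000.0
    hr_area_exp: float = 0.24
    # share of a cell's standing resource accessible per visit
    food_share_coeff: float = 0.9
    food_share_exp: float = 0.0
    # fat storage
    storage_frac: float = 0.45            # catabolizable reserve / adult mass
    fat_energy_density: float = 39.3      # kJ per g fat
    # tissue synthesis
    tissue_energy_density: float = 7.0    # kJ per g wet mass
    flesh_synthesis_cost: float = 6.0     # kJ per g newly synthesised
    # digestion
    assim_eff: float = 0.8
    digest_loss: float = 0.1
    # growth
    birth_mass_frac: float = 0.08         # birth mass / adult mass
    growth_rate_coeff: float = 0.075      # von Bertalanffy k = coeff * M**-0.25 [1/day]
    gompertz_shape: float = 6.0           # embryonic curve steepness (dimensionless)
    conception_mass_frac: float = 0.01    # embryo mass at conception / birth mass
    # reproduction schedule
    litter_size: int = 4
    gestation_coeff: float = 8.0          # days = coeff * M**0.25
    lactation_coeff: float = 10.0         # days = coeff * M**0.2
    maturity_coeff: float = 30.0          # days = coeff * M**0.25
    # longevity: days = coeff * (M/10)**0.25
    lifespan_coeff: float = 548.0
    cell_area_m2: float = 100.0


@dataclass(frozen=True)
class SpeciesTraits:
    """Derived trait set of one species; pure function of (adult_mass, config)."""

    species_id: int
    adult_mass: float          # g
    birth_mass: float          # g
    max_hr_radius: int         # cells
    food_share: float          # proportion per visit
    storage_cap: float         # kJ at adult mass
    growth_rate: float         # von Bertalanffy k [1/day]
    litter_size: int
    gestation_days: int
    lactation_days: int
    maturity_days: int
    lifespan_days: int
    config: AllometryConfig = field(repr=False, default_factory=AllometryConfig)


def derive_traits(species_id: int, adult_mass: float,
                  config: AllometryConfig | None = None) -> SpeciesTraits:
    """Build the full trait set for a species of given adult mass."""
    if adult_mass <= 0:
        raise ValueError(f"adult_mass must be positive, got {adult_mass}")
    cfg = config or AllometryConfig()
    m = adult_mass
    return SpeciesTraits(
        species_id=species_id,
        adult_mass=m,
        birth_mass=cfg.birth_mass_frac * m,
        max_hr_radius=_hr_radius_cells(m, cfg),
        food_share=min(1.0, cfg.food_share_coeff * m ** cfg.food_share_exp),
        storage_cap=cfg.storage_frac * m * cfg.fat_energy_density,
        growth_rate=cfg.growth_rate_coeff * m ** -0.25,
        litter_size=cfg.litter_size,
        gestation_days=max(1, round(cfg.gestation_coeff * m ** 0.25)),
        lactation_days=max(1, round(cfg.lactation_coeff * m ** 0.2)),
        maturity_days=max(1, round(cfg.maturity_coeff * m ** 0.25)),
        lifespan_days=max(1, round(cfg.lifespan_coeff * (m / 10.0) ** 0.25)),
        config=cfg,
    )


def default_community(n_species: int = 10, mass_min: float = 10.0,
                      mass_max: float = 100.0,
                      config: AllometryConfig | None = None,
                      spacing: str = "log") -> list[SpeciesTraits]:
    """Trait sets for a community spanning ``mass_min``-``mass_max`` grams.

    Adult masses are log-spaced (default) or linearly spaced, inclusive of
    both endpoints; ``species_id`` runs 1..n ascending with mass.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if mass_min <= 0 or mass_max <= 0 or mass_min > mass_max:
        raise ValueError("need 0 < mass_min <= mass_max")
    if n_species == 1:
        masses = np.array([mass_min])
    elif spacing == "log":
        masses = np.geomspace(mass_min, mass_max, n_species)
    elif spacing == "linear":
        masses = np.linspace(mass_min, mass_max, n_species)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return [derive_traits(i + 1, float(m), config) for i, m in enumerate(masses)]


def maintenance_rate(traits: SpeciesTraits, current_mass: float) -> float:
    """Daily maintenance metabolism [kJ/day] at the given structural mass."""
    if current_mass <= 0:
        raise ValueError("current_mass must be positive")
    cfg = traits.config
    return cfg.b0 * current_mass ** cfg.b1


def locomotion_cost(traits: SpeciesTraits, total_mass: float,
                    distance_km: float, active_hours: float) -> float:
    """Locomotion cost [kJ] = postural * hours + incremental * distance.

    ``total_mass`` includes carried fat, so a fatter animal pays more for
    the same distance.
    """
    if distance_km < 0:
        raise ValueError("distance_km must be non-negative")
    if active_hours < 0:
        raise ValueError("active_hours must be non-negative")
    cfg = traits.config
    postural = cfg.postural_coeff * total_mass ** cfg.postural_exp
    incremental = cfg.incremental_coeff * total_mass ** cfg.incremental_exp
    return postural * active_hours + incremental * distance_km


def _hr_radius_cells(adult_mass: float, cfg: AllometryConfig) -> int:
    area_m2 = cfg.hr_area_coeff * adult_mass ** cfg.hr_area_exp
    return max(1, math.ceil(math.sqrt(area_m2 / (math.pi * cfg.cell_area_m2))))


def max_home_range_radius(traits: SpeciesTraits) -> int:
    """Maximum daily home-range radius in cells (ceiling of the allometric disc)."""
    return _hr_radius_cells(traits.adult_mass, traits.config)


def fat_mass(traits: SpeciesTraits, storage_kj: float) -> float:
    """Fat mass [g] currently carried for a given storage level [kJ]."""
    return storage_kj / traits.config.fat_energy_density


def growth_mass(traits: SpeciesTraits, age_days: float) -> float:
    """Body mass [g] on the reference growth trajectory at a given age.

    Negative ages index embryonic days (age ``-gestation_days`` is
    conception).  A Gompertz curve runs from a small conception mass to
    ``birth_mass`` at age 0; a von Bertalaffy curve (cube-root form)
    continues from birth mass toward ``adult_mass``.  The two pieces meet
    continuously at age 0 and the whole trajectory is non-decreasing.
    """
    cfg = traits.config
    G = traits.gestation_days
    if age_days < -G:
        raise ValueError(f"age {age_days} precedes conception (-{G} days)")
    if age_days < 0:
        # Gompertz, normalised to hit birth_mass exactly at age 0
        s = age_days + G            # days since conception, in [0, G)
        b = -math.log(cfg.conception_mass_frac)
        c = cfg.gompertz_shape / G
        raw = math.exp(-b * math.exp(-c * s))
        raw_birth = math.exp(-b * math.exp(-c * G))
        return traits.birth_mass * raw / raw_birth
    a13 = traits.adult_mass ** (1.0 / 3.0)
    m013 = traits.birth_mass ** (1.0 / 3.0)
    k = traits.growth_rate
    return (a13 - (a13 - m013) * math.exp(-k * age_days)) ** 3


def vb_daily_increment(traits: SpeciesTraits, current_mass: float) -> float:
    """One-day von Bertalanffy mass increment from the current mass [g/day].

    State-based form of the postnatal curve: individuals that missed growth
    (energy shortage) resume from their actual mass rather than the
    age-indexed trajectory, so stunting persists.
    """
    a13 = traits.adult_mass ** (1.0 / 3.0)
    m13 = min(current_mass, traits.adult_mass) ** (1.0 / 3.0)
    k = traits.growth_rate
    nxt = (a13 - (a13 - m13) * math.exp(-k)) ** 3
    return max(0.0, nxt - current_mass)


def with_config(traits: SpeciesTraits, **overrides) -> SpeciesTraits:
    """Re-derive a trait set with some config fields overridden."""
    cfg = replace(traits.config, **overrides)
    return derive_traits(traits.species_id, traits.adult_mass, cfg)


_TRAIT_COLUMNS = ("species_id", "adult_mass", "birth_mass", "max_hr_radius",
                  "food_share", "storage_cap", "growth_rate", "litter_size",
                  "gestation_days", "lactation_days", "maturity_days",
                  "lifespan_days")


def traits_to_frame(species: list[SpeciesTraits]):
    """One row per species, one column per derived trait."""
    import pandas as pd

    return pd.DataFrame([{c: getattr(t, c) for c in _TRAIT_COLUMNS}
                         for t in species])


def write_trait_table(species: list[SpeciesTraits], path) -> None:
    traits_to_frame(species).to_csv(path, index=False)


def read_trait_table(path, config: AllometryConfig | None = None) -> list[SpeciesTraits]:
    """Rebuild trait sets from a CSV written by :func:`write_trait_table`.

    Traits are re-derived from each row's adult mass under ``config``, so
    the table is a record of the mass axis, not an independent source of
    trait values.
    """
    import pandas as pd

    df = pd.read_csv(path)
    return [derive_traits(int(r.species_id), float(r.adult_mass), config)
            for r in df.itertuples()]
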