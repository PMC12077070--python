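"""The daily per-individual energy ledger.

Ingested energy is discounted by assimilation efficiency and digestive
loss, then allocated down a strict priority ladder:

1. maintenance and locomotion (survival tier — deficits draw on fat
   storage; an unpayable survival cost kills the individual the same day),
2. offspring demand for pregnant/lactating females (paid from remaining
   assimilate only, never from storage; any shortfall triggers abortion or
   sequential juvenile loss),
3. the individual's own structural growth,
4. storage top-up to the fat cap; surplus beyond the cap is discarded.

Every day closes with the conservation identity

    assimilated + shortfall
        = maintenance + locomotion + repro_cost + growth_cost
          + storage_delta + overflow

where ``shortfall`` (unpaid survival cost) is positive only on the death
day and ``overflow`` is energy discarded at a full store.  The identity is
asserted in the engine's audit mode for every individual-day.

The allocation core is vectorised over individuals; the per-individual
operations used in tests and exposed in the public API are thin scalar
wrappers over the same arrays, so there is a single allocation code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .allometry import SpeciesTraits, growth_mass

__all__ = [
    "Individual",
    "DailyEnergyLedger",
    "ReproState",
    "assimilate",
    "allocate_arrays",
    "allocate_day",
    "reproduction_demand",
    "apply_repro_shortfall",
]

# repro_state codes
class ReproState:
    NONE = 0
    PREGNANT = 1
    LACTATING = 2


@dataclass
class Individual:
    """Scalar agent state (mirrors one row of the engine's array state)."""

    id: int
    species_id: int
    sex: int = 0                   # 0 female, 1 male
    age_days: int = 0
    structural_mass: float = 0.0   # g
    storage: float = 0.0           # kJ
    core_cell: tuple[int, int] = (0, 0)
    current_radius: int = 0
    hr_memory: list[float] = field(default_factory=list)  # last 7 daily HR sizes
    repro_state: int = ReproState.NONE
    stage_day: int = 0             # days into pregnancy / lactation
    litter_count: int = 0
    alive: bool = True
    lrs: int = 0                   # offspring raised to independence


@dataclass
class DailyEnergyLedger:
    ingested: float = 0.0
    assimilated: float = 0.0
    maintenance: float = 0.0
    locomotion: float = 0.0
    growth_cost: float = 0.0
    repro_cost: float = 0.0
    storage_delta: float = 0.0
    shortfall: float = 0.0
    overflow: float = 0.0

    @property
    def balance(self) -> float:
        """Assimilated energy minus all expenditures (ingested vs expended)."""
        return self.assimilated - (self.maintenance + self.locomotion
                                   + self.repro_cost + self.growth_cost)

    def conservation_residual(self) -> float:
        return (self.assimilated + self.shortfall
                - (self.maintenance + self.locomotion + self.repro_cost
                   + self.growth_cost + self.storage_delta + self.overflow))


def assimilate(ingested: float, assim_eff: float, digest_loss: float) -> float:
    """Usable energy from ingested energy: ingested * eff * (1 - loss)."""
    if np.any(np.asarray(ingested) < 0):
        raise ValueError("ingested energy must be non-negative")
    if not (0 < assim_eff <= 1 and 0 <= digest_loss < 1):
        raise ValueError("efficiencies must be proportions")
    return ingested * assim_eff * (1.0 - digest_loss)


def allocate_arrays(assimilated, maintenance, locomotion, repro_demand,
                    growth_cost_desired, storage, storage_cap):
    """Vectorised priority allocation over individuals.

    All inputs are broadcastable float arrays [kJ].  Returns a dict of
    arrays: paid repro/growth costs, new storage, storage_delta, shortfall,
    overflow, and a boolean ``died`` mask (survival tier unpayable).
    Storage funds survival only.
    """
    assimilated = np.asarray(assimilated, dtype=float)
    survival = maintenance + locomotion
    paid = np.minimum(assimilated, survival)
    remaining = assimilated - paid
    deficit = survival - paid
    draw = np.minimum(storage, deficit)
    storage_after = storage - draw
    shortfall = deficit - draw
    died = shortfall > 1e-9
    repro_paid = np.minimum(remaining, repro_demand)
    remaining = remaining - repro_paid
    growth_paid = np.minimum(remaining, growth_cost_desired)
    remaining = remaining - growth_paid
    headroom = np.maximum(0.0, storage_cap - storage_after)
    topup = np.minimum(remaining, headroom)
    overflow = remaining - topup
    new_storage = storage_after + topup
    return {
        "repro_paid": repro_paid,
        "growth_paid": growth_paid,
        "storage": new_storage,
        "storage_delta": new_storage - storage,
        "shortfall": shortfall,
        "overflow": overflow,
        "died": died,
    }


def allocate_day(individual: Individual, traits: SpeciesTraits,
                 assimilated: float, locomotion_due: float,
                 growth_cost_desired: float = 0.0,
                 ingested: float = 0.0) -> DailyEnergyLedger:
    """Run one individual's daily allocation and update its state in place.

    Returns the closed ledger.  Reproduction demand is computed from the
    individual's reproductive state; any unmet demand must then be applied
    via :func:`apply_repro_shortfall` (the engine does this immediately).
    """
    if not individual.alive:
        raise RuntimeError("allocate_day called on a dead individual")
    if assimilated < 0:
        raise ValueError("assimilated must be non-negative")
    from .allometry import maintenance_rate

    maint = maintenance_rate(traits, individual.structural_mass)
    demand = (reproduction_demand(individual, traits)
              if individual.repro_state != ReproState.NONE else 0.0)
    out = allocate_arrays(np.array([assimilated]), np.array([maint]),
                          np.array([locomotion_due]), np.array([demand]),
                          np.array([growth_cost_desired]),
                          np.array([individual.storage]),
                          np.array([traits.storage_cap]))
    individual.storage = float(out["storage"][0])
    if bool(out["died"][0]):
        individual.alive = False
    ledger = DailyEnergyLedger(
        ingested=ingested, assimilated=assimilated, maintenance=maint,
        locomotion=locomotion_due, growth_cost=float(out["growth_paid"][0]),
        repro_cost=float(out["repro_paid"][0]),
        storage_delta=float(out["storage_delta"][0]),
        shortfall=float(out["shortfall"][0]),
        overflow=float(out["overflow"][0]))
    unmet = demand - ledger.repro_cost
    if unmet > 1e-12 and individual.alive:
        apply_repro_shortfall(individual, unmet)
    return ledger


def reproduction_demand(mother: Individual, traits: SpeciesTraits) -> float:
    """Today's offspring energy demand [kJ] for a pregnant or lactating female.

    Demand is the litter's daily growth-mass increment times the cost of
    new flesh (tissue energy content plus synthesis overhead).  During
    pregnancy the increment follows the embryonic Gompertz curve; during
    lactation it follows the early postnatal von Bertalanffy curve.
    """
    if mother.repro_state == ReproState.NONE:
        raise RuntimeError("reproduction_demand on a non-reproducing female")
    cfg = traits.config
    if mother.repro_state == ReproState.PREGNANT:
        age_today = mother.stage_day - traits.gestation_days   # negative = embryonic
        age_prev = age_today - 1
    else:
        age_today = mother.stage_day
        age_prev = mother.stage_day - 1
    dm = growth_mass(traits, age_today) - growth_mass(traits, max(age_prev, -traits.gestation_days))
    dm = max(0.0, dm)
    per_g = cfg.tissue_energy_density + cfg.flesh_synthesis_cost
    return mother.litter_count * dm * per_g


def apply_repro_shortfall(mother: Individual, unmet: float) -> Individual:
    """Consequences of unmet offspring demand.

    Pregnant: the whole litter is aborted.  Lactating: one juvenile is lost
    per shortfall day until the litter is empty.  ``unmet == 0`` is a no-op.
    """
    if unmet < 0:
        raise ValueError("unmet must be >= 0")
    if unmet <= 1e-12:
        return mother
    if mother.repro_state == ReproState.PREGNANT:
        mother.litter_count = 0
        mother.repro_state = ReproState.NONE
        mother.stage_day = 0
    elif mother.repro_state == ReproState.LACTATING:
        mother.litter_count -= 1
        if mother.litter_count <= 0:
            mother.litter_count = 0
            mother.repro_state = ReproState.NONE
            mother.stage_day = 0
    return mother
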