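"""Central-place foraging behaviour, competition ordering and drought strategies.

Individuals are central-place foragers: they hold a core cell and exploit
cells around it near-to-far, depleting what they ingest (exploitation
competition).  The day's foraging *aim* depends on the active strategy:

``increase`` (default, and the only behaviour outside droughts)
    forage until maintenance, locomotion, reproduction and growth costs
    are covered and the fat store is topped up to its cap.
``maintain`` (drought only)
    same aim, but the search radius is capped so the home range does not
    exceed the mean size realised over the 7 days before the drought.
``decrease`` (drought only)
    forage only until survival costs are covered; if storage already
    covers them the individual does not forage at all that day.

Foraging order is redrawn daily at random with a slight advantage to
heavier individuals and a persistent advantage to those with few
conspecifics nearby (weight = mass**alpha / (1 + conspecific count)**beta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import _kernels
from .allometry import SpeciesTraits, maintenance_rate, max_home_range_radius
from .energetics import Individual
from .landscape import Landscape

__all__ = [
    "Strategy",
    "ForagingOutcome",
    "foraging_order",
    "conspecific_counts",
    "daily_aims",
    "forage_day",
    "establish_home_range",
    "disperse_juvenile",
]


class Strategy(str, Enum):
    """Behavioural strategy during drought days."""

    INCREASE = "increase"
    MAINTAIN = "maintain"
    DECREASE = "decrease"


@dataclass
class ForagingOutcome:
    cells_visited: list = field(default_factory=list)  # (row, col) with intake
    distance_moved: float = 0.0      # cell units (round trips)
    ingested: float = 0.0            # kJ
    final_radius: float = 0.0        # cells
    hr_size: int = 0                 # disc cells scanned (home-range size)
    aim_met: bool = False


def conspecific_counts(species: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                       side: int, radius: float, toroidal: bool = True) -> np.ndarray:
    """Number of same-species individuals within ``radius`` cells of each core."""
    counts = np.zeros(species.shape[0], dtype=np.int64)
    _kernels.conspecific_census(np.ascontiguousarray(species),
                                np.ascontiguousarray(rows),
                                np.ascontiguousarray(cols),
                                int(side), float(radius), bool(toroidal),
                                counts)
    return counts


def foraging_order(masses: np.ndarray, conspecifics: np.ndarray,
                   rng: np.random.Generator, alpha: float = 0.5,
                   beta: float = 2.0) -> np.ndarray:
    """Random daily foraging permutation with a size/density bias.

    Sampling without replacement with weight
    ``mass**alpha / (1 + local conspecific count)**beta``, implemented via
    Gumbel keys; a fresh draw every call.  The mass advantage is slight
    (``alpha`` = 0.5); the low-density advantage is persistent in space,
    so individuals in sparse neighbourhoods keep foraging early --- the
    model's lightweight stand-in for site dominance.
    """
    masses = np.asarray(masses, dtype=float)
    if masses.size == 0:
        return np.array([], dtype=np.int64)
    w = (masses ** alpha
         / (1.0 + np.asarray(conspecifics, dtype=float)) ** beta)
    keys = np.log(w) + rng.gumbel(size=masses.size)
    return np.argsort(-keys, kind="stable").astype(np.int64)


def daily_aims(strategy: Strategy, in_drought: bool,
               maintenance: np.ndarray, postural: np.ndarray,
               repro_demand: np.ndarray, growth_cost: np.ndarray,
               storage: np.ndarray, storage_cap: np.ndarray,
               max_off_full: np.ndarray, hr_mem_mean: np.ndarray,
               intake_factor: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised foraging aims (ingestion units, kJ) and disc-size caps.

    Returns ``(aim, max_off, active)``: the remaining ingestion target,
    the per-individual cap on disc cells scanned, and whether the
    individual goes out at all (postural costs are charged only then).
    """
    strategy = Strategy(strategy)
    full_costs = maintenance + postural + repro_demand + growth_cost
    headroom = np.maximum(0.0, storage_cap - storage)
    aim = (full_costs + headroom) / intake_factor
    max_off = max_off_full.astype(np.int64).copy()
    if in_drought and strategy is Strategy.MAINTAIN:
        mem = np.where(np.isnan(hr_mem_mean), max_off_full, hr_mem_mean)
        max_off = np.minimum(max_off, np.maximum(1, np.floor(mem))).astype(np.int64)
    elif in_drought and strategy is Strategy.DECREASE:
        deficit = maintenance - storage
        aim = np.where(deficit <= 0.0, 0.0, (deficit + postural) / intake_factor)
    active = aim > 0.0
    return aim, max_off, active


def _postural_per_day(traits: SpeciesTraits, total_mass: float) -> float:
    cfg = traits.config
    return cfg.postural_coeff * total_mass ** cfg.postural_exp * cfg.active_hours


def _intake_factor(traits: SpeciesTraits) -> float:
    cfg = traits.config
    return cfg.assim_eff * (1.0 - cfg.digest_loss)


def forage_day(individual: Individual, traits: SpeciesTraits,
               landscape: Landscape, strategy: Strategy | str = Strategy.INCREASE,
               in_drought: bool = False,
               rng: np.random.Generator | None = None) -> ForagingOutcome:
    """One individual's daily foraging bout (depletes the landscape in place)."""
    strategy = Strategy(strategy)
    if not individual.alive:
        raise RuntimeError("forage_day called on a dead individual")
    cfg = traits.config
    r_max = max_home_range_radius(traits)
    off_dr, off_dc, off_dist, disc_end = _kernels.ring_offsets(max(r_max, 1))
    total_mass = individual.structural_mass + individual.storage / cfg.fat_energy_density
    maint = maintenance_rate(traits, individual.structural_mass)
    postural = _postural_per_day(traits, total_mass)
    from .energetics import ReproState, reproduction_demand

    demand = (reproduction_demand(individual, traits)
              if individual.repro_state != ReproState.NONE else 0.0)
    mem = individual.hr_memory[-7:]
    mem_mean = np.array([np.mean(mem) if mem else np.nan])
    aim, max_off, _ = daily_aims(
        strategy, in_drought,
        np.array([maint]), np.array([postural]), np.array([demand]),
        np.array([0.0]), np.array([individual.storage]),
        np.array([traits.storage_cap]),
        np.array([disc_end[r_max]]), mem_mean, _intake_factor(traits))
    ingested = np.zeros(1)
    distance = np.zeros(1)
    scan_end = np.zeros(1, dtype=np.int64)
    own = np.zeros(1, dtype=np.int64)
    fcount = np.zeros_like(landscape.resource, dtype=np.int64)
    visits = np.zeros(int(disc_end[r_max]), dtype=np.int64)
    vstart = np.zeros(1, dtype=np.int64)
    vend = np.zeros(1, dtype=np.int64)
    _kernels.forage_all(
        landscape.resource, landscape.habitat_mask, landscape.toroidal,
        np.array([0], dtype=np.int64),
        np.array([individual.core_cell[0]], dtype=np.int64),
        np.array([individual.core_cell[1]], dtype=np.int64),
        np.array([traits.food_share]), aim, max_off,
        np.array([individual.storage]),
        np.array([cfg.incremental_coeff * total_mass ** cfg.incremental_exp]),
        landscape.cell_size_m / 1000.0, _intake_factor(traits),
        off_dr, off_dc, off_dist, ingested, distance, scan_end, own, fcount,
        visits, vstart, vend)
    cells = [(int(r), int(c)) for r, c in zip(*np.nonzero(fcount))]
    n_scanned = int(scan_end[0])
    final_radius = float(off_dist[n_scanned - 1]) if n_scanned > 0 else 0.0
    individual.current_radius = math.ceil(final_radius)
    return ForagingOutcome(
        cells_visited=cells, distance_moved=float(distance[0]),
        ingested=float(ingested[0]), final_radius=final_radius,
        hr_size=n_scanned,
        aim_met=bool(ingested[0] >= aim[0] - 1e-9))


def _establishment_need(traits: SpeciesTraits, mass: float, storage: float) -> float:
    """Daily survival need in ingestion units used to judge a candidate range."""
    total_mass = mass + storage / traits.config.fat_energy_density
    return ((maintenance_rate(traits, mass) + _postural_per_day(traits, total_mass))
            / _intake_factor(traits))


def _try_candidates(individual: Individual, traits: SpeciesTraits,
                    landscape: Landscape, candidates) -> bool:
    cfg = traits.config
    r_max = max_home_range_radius(traits)
    off_dr, off_dc, off_dist, disc_end = _kernels.ring_offsets(max(r_max, 1))
    need = _establishment_need(traits, individual.structural_mass, individual.storage)
    total_mass = individual.structural_mass + individual.storage / cfg.fat_energy_density
    incr = cfg.incremental_coeff * total_mass ** cfg.incremental_exp
    for (r0, c0) in candidates:
        if not landscape.habitat_mask[r0, c0]:
            continue  # a matrix core consumes the trial but cannot succeed
        scan = _kernels.evaluate_core(
            landscape.resource, landscape.habitat_mask, landscape.toroidal,
            int(r0), int(c0), traits.food_share, need,
            int(disc_end[r_max]), individual.storage, incr,
            landscape.cell_size_m / 1000.0, _intake_factor(traits),
            off_dr, off_dc, off_dist)
        if scan >= 0:
            individual.core_cell = (int(r0), int(c0))
            individual.current_radius = math.ceil(float(off_dist[scan - 1])) if scan > 0 else 0
            individual.alive = True
            return True
    individual.alive = False
    return False


def establish_home_range(individual: Individual, traits: SpeciesTraits,
                         landscape: Landscape, occupancy=None,
                         max_trials: int = 10,
                         rng: np.random.Generator | None = None) -> bool:
    """Search for a viable home range; remove the individual after failures.

    Candidate cores are drawn uniformly from habitat cells (uniformly from
    all cells if the landscape has none, so a barren world consumes
    exactly ``max_trials`` candidates).  Each candidate is grown radius by
    radius until accessible energy covers the daily survival need, the
    allometric maximum radius is reached, or movement energy is exhausted;
    the first sufficient candidate is accepted.
    """
    if max_trials < 1:
        raise ValueError("max_trials must be >= 1")
    rng = rng or np.random.default_rng()
    hab = np.argwhere(landscape.habitat_mask)
    if hab.shape[0] > 0:
        picks = hab[rng.integers(hab.shape[0], size=max_trials)]
    else:
        side = landscape.side_cells
        picks = np.column_stack([rng.integers(side, size=max_trials),
                                 rng.integers(side, size=max_trials)])
    return _try_candidates(individual, traits, landscape,
                           [tuple(p) for p in picks])


def disperse_juvenile(juvenile: Individual, traits: SpeciesTraits,
                      landscape: Landscape, occupancy=None,
                      natal_core: tuple[int, int] | None = None,
                      max_trials: int = 10,
                      dispersal_factor: float = 3.0,
                      rng: np.random.Generator | None = None) -> bool:
    """Establish a newly independent juvenile near its natal core.

    Candidate cores are sampled uniformly within an allometric dispersal
    radius (``dispersal_factor`` times the species' maximum home-range
    radius) of the natal core; matrix candidates consume a trial.  The
    usual establishment rules then apply.
    """
    rng = rng or np.random.default_rng()
    natal = natal_core or juvenile.core_cell
    disp_r = max(1, round(dispersal_factor * max_home_range_radius(traits)))
    off_dr, off_dc, _, disc_end = _kernels.ring_offsets(disp_r)
    side = landscape.side_cells
    n_disc = int(disc_end[disp_r])
    js = rng.integers(n_disc, size=max_trials)
    cands = []
    for j in js:
        r0 = natal[0] + int(off_dr[j])
        c0 = natal[1] + int(off_dc[j])
        if landscape.toroidal:
            r0 %= side
            c0 %= side
        elif not (0 <= r0 < side and 0 <= c0 < side):
            r0, c0 = -1, -1  # off-grid candidate: wasted trial
        cands.append((max(r0, 0) if r0 >= 0 else 0, max(c0, 0) if c0 >= 0 else 0)
                     if r0 >= 0 else None)
    cands = [c for c in cands if c is not None]
    if not cands:
        juvenile.alive = False
        return False
    return _try_candidates(juvenile, traits, landscape, cands)
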