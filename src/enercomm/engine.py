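"""The daily scheduler binding landscape, allometry, energetics and behaviour.

One simulated day runs, in fixed order: resource renewal with drought
forcing -> a fresh weighted-random foraging order -> sequential foraging
(depleting resources) -> assimilation and priority energy allocation ->
reproduction bookkeeping (conception, birth, weaning, abortion) -> growth
and ageing -> dispersal and home-range establishment of newly independent
juveniles -> metric recording.  All randomness flows through one
``numpy.random.Generator`` seeded from the scenario config and drawn in
that documented order, so a run is bitwise reproducible from its seed.

Individual state lives in flat numpy arrays (one row per living
individual, compacted after deaths); the expensive spatial loops are the
numba kernels in :mod:`enercomm._kernels`, and energy allocation is the
same vectorised core the per-individual API uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .allometry import SpeciesTraits, default_community, growth_mass
from .behaviour import Strategy, conspecific_counts, daily_aims, foraging_order
from .energetics import allocate_arrays
from .landscape import Landscape, generate_landscape, renew_and_force, \
    seasonal_cap
from .scenarios import ScenarioConfig

__all__ = ["SimResult", "run_simulation"]

_FEMALE, _MALE = 0, 1
_NONE, _PREGNANT, _LACTATING = 0, 1, 2


@dataclass
class SimResult:
    """Daily per-species metrics plus per-run summaries for one simulation."""

    config: ScenarioConfig
    species: list[SpeciesTraits]
    population: np.ndarray        # (days, S) living individuals
    mean_hr: np.ndarray           # (days, S) mean home-range size [cells]
    mean_balance: np.ndarray      # (days, S) mean daily energy balance [kJ]
    mean_storage: np.ndarray      # (days, S) mean fat store [kJ]
    competitors: np.ndarray       # (days, S) mean competitors per foraging patch
    lrs_mean: np.ndarray          # (S,) mean lifetime reproductive success
    audit: dict = field(default_factory=dict)

    @property
    def n_days(self) -> int:
        return self.population.shape[0]

    def richness(self, day: int | None = None) -> int:
        pop = self.population[day if day is not None else -1]
        return int((pop > 0).sum())

    def daily(self) -> pd.DataFrame:
        """Long-format per-day per-species metrics table."""
        days, S = self.population.shape
        day_idx = np.repeat(np.arange(days), S)
        sp_idx = np.tile([t.species_id for t in self.species], days)
        return pd.DataFrame({
            "day": day_idx,
            "species": sp_idx,
            "population": self.population.ravel(),
            "mean_hr": self.mean_hr.ravel(),
            "mean_balance": self.mean_balance.ravel(),
            "mean_storage": self.mean_storage.ravel(),
            "competitors_per_patch": self.competitors.ravel(),
        })

    def summary(self) -> pd.DataFrame:
        """Per-species end-of-run summary (population, LRS, recovery, resistance)."""
        from .metrics import recovery_time, resistance

        rows = []
        ev = self.config.events[0] if self.config.events else None
        for s, traits in enumerate(self.species):
            pop = self.population[:, s]
            rec = res = None
            if ev is not None:
                baseline = pop[max(0, ev.start_day - 30):ev.start_day].mean()
                if baseline > 0:
                    rec = recovery_time(pop, ev.end_day, 30,
                                        drought_start_day=ev.start_day)
                    res = resistance(pop, (ev.start_day, ev.end_day), baseline)
            rows.append({
                "species": traits.species_id,
                "adult_mass": traits.adult_mass,
                "final_population": int(pop[-1]),
                "mean_lrs": self.lrs_mean[s],
                "recovery_time": rec,
                "resistance": res,
            })
        return pd.DataFrame(rows)


class _Community:
    """Precomputed per-species constant arrays."""

    def __init__(self, species: list[SpeciesTraits], cell_size_m: float):
        cfg = species[0].config
        self.traits = species
        self.cfg = cfg
        self.S = len(species)
        self.adult_mass = np.array([t.adult_mass for t in species])
        self.birth_mass = np.array([t.birth_mass for t in species])
        self.share = np.array([t.food_share for t in species])
        self.k_growth = np.array([t.growth_rate for t in species])
        self.a13 = self.adult_mass ** (1.0 / 3.0)
        self.gestation = np.array([t.gestation_days for t in species], dtype=np.int64)
        self.lactation = np.array([t.lactation_days for t in species], dtype=np.int64)
        self.maturity = np.array([t.maturity_days for t in species], dtype=np.int64)
        self.lifespan = np.array([t.lifespan_days for t in species], dtype=np.int64)
        self.litter = np.array([t.litter_size for t in species], dtype=np.int64)
        self.max_radius = np.array([t.max_hr_radius for t in species], dtype=np.int64)
        r_needed = int(self.max_radius.max())
        self.off_dr, self.off_dc, self.off_dist, self.disc_end = \
            _kernels.ring_offsets(max(r_needed, 1))
        self.max_off = self.disc_end[self.max_radius]
        self.cell_km = cell_size_m / 1000.0
        self.intake_factor = cfg.assim_eff * (1.0 - cfg.digest_loss)
        self.per_g = cfg.tissue_energy_density + cfg.flesh_synthesis_cost
        self.wean_mass = np.array([growth_mass(t, t.lactation_days) for t in species])
        # per-offspring daily demand tables, indexed by stage day (1-based)
        Gmax, Lmax = int(self.gestation.max()), int(self.lactation.max())
        self.preg_demand = np.zeros((self.S, Gmax + 1))
        self.lact_demand = np.zeros((self.S, Lmax + 1))
        for s, t in enumerate(species):
            G = t.gestation_days
            for d in range(1, G + 1):
                dm = growth_mass(t, d - G) - growth_mass(t, d - 1 - G)
                self.preg_demand[s, d] = max(0.0, dm) * self.per_g
            for d in range(1, t.lactation_days + 1):
                dm = growth_mass(t, d) - growth_mass(t, d - 1)
                self.lact_demand[s, d] = max(0.0, dm) * self.per_g

    def storage_cap(self, mass: np.ndarray) -> np.ndarray:
        """Fat cap [kJ] scales with current structural mass (<= adult cap)."""
        return self.cfg.storage_frac * mass * self.cfg.fat_energy_density


class _State:
    """Struct-of-arrays individual state, compacted after deaths."""

    FIELDS = ("uid", "sp", "sex", "age", "mass", "storage", "core_r", "core_c",
              "repro", "stage", "litter", "lrs", "mem_len", "cap_mult")

    def __init__(self):
        self.uid = np.zeros(0, dtype=np.int64)      # persistent individual id
        self.sp = np.zeros(0, dtype=np.int64)       # species index 0..S-1
        self.sex = np.zeros(0, dtype=np.int64)
        self.age = np.zeros(0, dtype=np.int64)
        self.mass = np.zeros(0)
        self.storage = np.zeros(0)
        self.core_r = np.zeros(0, dtype=np.int64)
        self.core_c = np.zeros(0, dtype=np.int64)
        self.repro = np.zeros(0, dtype=np.int64)
        self.stage = np.zeros(0, dtype=np.int64)
        self.litter = np.zeros(0, dtype=np.int64)
        self.lrs = np.zeros(0, dtype=np.int64)
        self.mem_len = np.zeros(0, dtype=np.int64)
        self.cap_mult = np.ones(0)
        self.hr_mem = np.zeros((0, 7))

    @property
    def n(self) -> int:
        return self.sp.shape[0]

    def keep(self, mask: np.ndarray) -> None:
        for f in self.FIELDS:
            setattr(self, f, getattr(self, f)[mask])
        self.hr_mem = self.hr_mem[mask]

    def append(self, **kw) -> None:
        m = len(kw["sp"])
        for f in self.FIELDS:
            arr = getattr(self, f)
            fill = np.ones(m, dtype=arr.dtype) if f == "cap_mult" \
                else np.zeros(m, dtype=arr.dtype)
            new = np.asarray(kw.get(f, fill), dtype=arr.dtype)
            setattr(self, f, np.concatenate([arr, new]))
        self.hr_mem = np.concatenate([self.hr_mem, np.zeros((m, 7))])


def _build_species(config: ScenarioConfig) -> list[SpeciesTraits]:
    comm = default_community(config.n_species, config.mass_min, config.mass_max,
                             config.allometry)
    if config.single_species is not None:
        by_id = {t.species_id: t for t in comm}
        if config.single_species not in by_id:
            raise ValueError(f"unknown species_id {config.single_species}")
        return [by_id[config.single_species]]
    return comm


def _establish(com: _Community, ls: Landscape, s: int, mass: float,
               storage: float, candidates) -> tuple[int, int] | None:
    cfg = com.cfg
    total_mass = mass + storage / cfg.fat_energy_density
    maint = cfg.b0 * mass ** cfg.b1
    postural = cfg.postural_coeff * total_mass ** cfg.postural_exp * cfg.active_hours
    need = (maint + postural) / com.intake_factor
    incr = cfg.incremental_coeff * total_mass ** cfg.incremental_exp
    for (r0, c0) in candidates:
        if not ls.habitat_mask[r0, c0]:
            continue
        scan = _kernels.evaluate_core(
            ls.resource, ls.habitat_mask, ls.toroidal, int(r0), int(c0),
            com.share[s], need, int(com.max_off[s]), storage, incr,
            com.cell_km, com.intake_factor,
            com.off_dr, com.off_dc, com.off_dist)
        if scan >= 0:
            return int(r0), int(c0)
    return None


def run_simulation(config: ScenarioConfig, audit: bool = False,
                   ledger_path=None) -> SimResult:
    """Run one scenario to completion and return its metrics.

    With ``audit=True`` the result carries the global energy checks: the
    maximum per-individual-day ledger conservation residual, the maximum
    community intake overshoot versus daily supply, and the worst storage
    bound violation (all should be ~0).  With ``ledger_path`` set, every
    individual-day ledger is dumped to that CSV (verbose; small runs only).
    """
    if config.years < 1:
        raise ValueError("years must be >= 1")
    strategy = Strategy(config.behaviour)
    species = _build_species(config)
    com = _Community(species, cell_size_m=10.0)
    cfg = com.cfg
    eng = config.engine
    rng = np.random.default_rng(config.seed)
    ls = generate_landscape(config.side_cells, config.habitat_frac,
                            config.fragmentation, seed=config.seed,
                            season=config.season)
    forcing = config.forcing()
    n_days = config.horizon_days
    S = com.S
    hab_cells = np.argwhere(ls.habitat_mask)
    n_hab = hab_cells.shape[0]

    st = _State()
    next_uid = 0
    ledger_rows = [] if ledger_path is not None else None
    # --- initialisation: adults with established ranges ----------------
    renew_and_force(ls, 0, 1.0)
    init = {f: [] for f in _State.FIELDS}
    for s in range(S):
        cap_adult = com.storage_cap(com.adult_mass[s])
        for _ in range(eng.n0_per_species):
            age0 = int(rng.integers(com.maturity[s], max(com.maturity[s] + 1,
                                                         com.lifespan[s] // 2)))
            sex = int(rng.integers(2))
            jit = 1.0 + eng.condition_jitter * float(rng.uniform(-1.0, 1.0))
            store0 = eng.init_storage_frac * cap_adult * jit
            picks = hab_cells[rng.integers(n_hab, size=eng.max_trials)] \
                if n_hab else np.zeros((0, 2), dtype=int)
            core = _establish(com, ls, s, com.adult_mass[s], store0,
                              [tuple(p) for p in picks])
            if core is None:
                continue
            init["uid"].append(next_uid); next_uid += 1
            init["sp"].append(s); init["sex"].append(sex); init["age"].append(age0)
            init["mass"].append(com.adult_mass[s]); init["storage"].append(store0)
            init["core_r"].append(core[0]); init["core_c"].append(core[1])
            init["repro"].append(_NONE); init["stage"].append(0)
            init["litter"].append(0); init["lrs"].append(0); init["mem_len"].append(0)
            init["cap_mult"].append(jit)
    st.append(**{k: np.asarray(v) for k, v in init.items()})

    pop_out = np.zeros((n_days, S), dtype=np.int64)
    hr_out = np.zeros((n_days, S))
    bal_out = np.zeros((n_days, S))
    stor_out = np.zeros((n_days, S))
    comp_out = np.zeros((n_days, S))
    lrs_sum = np.zeros(S)
    lrs_n = np.zeros(S, dtype=np.int64)
    max_residual = 0.0
    max_over_intake = 0.0
    max_storage_violation = 0.0
    fcount = np.zeros_like(ls.resource, dtype=np.int64)
    visits_buf = np.zeros(4096, dtype=np.int64)

    for day in range(n_days):
        mult = forcing[day]
        renew_and_force(ls, day, mult)
        in_drought = mult < 1.0
        n = st.n
        if n == 0:
            continue
        supply = n_hab * seasonal_cap(ls, day) * mult

        # --- per-individual rates -------------------------------------
        total_mass = st.mass + st.storage / cfg.fat_energy_density
        maint = cfg.b0 * st.mass ** cfg.b1
        postural = (cfg.postural_coeff * total_mass ** cfg.postural_exp
                    * cfg.active_hours)
        incr = cfg.incremental_coeff * total_mass ** cfg.incremental_exp
        cap_now = com.storage_cap(st.mass) * st.cap_mult

        # reproduction stage advances at day start; demand follows the stage
        active_repro = st.repro > 0
        st.stage[active_repro] += 1
        demand = np.zeros(n)
        preg = st.repro == _PREGNANT
        lact = st.repro == _LACTATING
        if preg.any():
            demand[preg] = (com.preg_demand[st.sp[preg], st.stage[preg]]
                            * st.litter[preg])
        if lact.any():
            demand[lact] = (com.lact_demand[st.sp[lact], st.stage[lact]]
                            * st.litter[lact])

        # own growth toward the adult mass
        m13 = np.minimum(st.mass, com.adult_mass[st.sp]) ** (1.0 / 3.0)
        a13 = com.a13[st.sp]
        next_mass = (a13 - (a13 - m13) * np.exp(-com.k_growth[st.sp])) ** 3
        dm_desired = np.maximum(0.0, next_mass - st.mass)
        growth_cost = dm_desired * com.per_g

        mem_mean = np.where(st.mem_len > 0,
                            st.hr_mem.sum(axis=1) / np.maximum(st.mem_len, 1),
                            np.nan)
        aim, max_off, active = daily_aims(
            strategy, in_drought, maint, postural, demand, growth_cost,
            st.storage, cap_now, com.max_off[st.sp], mem_mean,
            com.intake_factor)

        # --- foraging in weighted random order ------------------------
        consp = conspecific_counts(st.sp, st.core_r, st.core_c, ls.side_cells,
                                   eng.density_radius, ls.toroidal)
        order = foraging_order(st.mass, consp, rng, eng.order_alpha,
                               eng.order_beta)
        ingested = np.zeros(n)
        distance = np.zeros(n)
        scan_end = np.zeros(n, dtype=np.int64)
        own_cells = np.zeros(n, dtype=np.int64)
        visit_start = np.zeros(n, dtype=np.int64)
        visit_end = np.zeros(n, dtype=np.int64)
        if visits_buf.shape[0] < n * int(com.max_off.max()):
            visits_buf = np.zeros(n * int(com.max_off.max()), dtype=np.int64)
        fcount[:] = 0
        _kernels.forage_all(
            ls.resource, ls.habitat_mask, ls.toroidal, order,
            st.core_r, st.core_c, com.share[st.sp], aim, max_off,
            st.storage, incr, com.cell_km, com.intake_factor,
            com.off_dr, com.off_dc, com.off_dist,
            ingested, distance, scan_end, own_cells, fcount,
            visits_buf, visit_start, visit_end)

        # --- assimilation and allocation ------------------------------
        assimilated = ingested * com.intake_factor
        went_out = active & (scan_end > 0)
        locomotion = (np.where(went_out, postural, 0.0)
                      + incr * distance * com.cell_km)
        out = allocate_arrays(assimilated, maint, locomotion, demand,
                              growth_cost, st.storage, cap_now)
        st.storage = out["storage"]
        st.mass = np.minimum(com.adult_mass[st.sp],
                             st.mass + out["growth_paid"] / com.per_g)
        starved = out["died"]
        balance = assimilated - (maint + locomotion + out["repro_paid"]
                                 + out["growth_paid"])

        if ledger_rows is not None:
            for i in range(n):
                ledger_rows.append((
                    day, int(st.uid[i]), int(st.sp[i]) + 1,
                    float(ingested[i]), float(assimilated[i]), float(maint[i]),
                    float(locomotion[i]), float(out["growth_paid"][i]),
                    float(out["repro_paid"][i]), float(out["storage_delta"][i]),
                    float(out["shortfall"][i]), float(balance[i])))

        if audit:
            residual = np.abs(assimilated + out["shortfall"]
                              - (maint + locomotion + out["repro_paid"]
                                 + out["growth_paid"] + out["storage_delta"]
                                 + out["overflow"]))
            max_residual = max(max_residual, float(residual.max(initial=0.0)))
            max_over_intake = max(max_over_intake,
                                  float(ingested.sum() - supply))
            max_storage_violation = max(
                max_storage_violation,
                float(np.maximum(st.storage - cap_now, 0.0).max(initial=0.0)),
                float(np.maximum(-st.storage, 0.0).max(initial=0.0)))

        # --- reproduction shortfalls (abortion / juvenile loss) -------
        unmet = demand - out["repro_paid"]
        shortfall_repro = (unmet > 1e-9) & ~starved
        abort = shortfall_repro & preg
        st.litter[abort] = 0
        st.repro[abort] = _NONE
        st.stage[abort] = 0
        lose = shortfall_repro & lact
        st.litter[lose] -= 1
        done = lose & (st.litter <= 0)
        st.litter[done] = 0
        st.repro[done] = _NONE
        st.stage[done] = 0

        # --- births and weaning ---------------------------------------
        births = preg & ~starved & (st.repro == _PREGNANT) \
            & (st.stage >= com.gestation[st.sp])
        st.repro[births] = _LACTATING
        st.stage[births] = 0
        weaned = lact & ~starved & (st.repro == _LACTATING) \
            & (st.stage >= com.lactation[st.sp])
        weaned_idx = np.flatnonzero(weaned)

        # --- conception ------------------------------------------------
        eligible = ((st.sex == _FEMALE) & (st.repro == _NONE) & ~starved
                    & (st.age >= com.maturity[st.sp])
                    & (st.storage >= eng.conception_storage_frac * cap_now))
        # females that just weaned may conceive again from the next day on
        eligible &= ~weaned
        st.repro[eligible] = _PREGNANT
        st.stage[eligible] = 0
        st.litter[eligible] = com.litter[st.sp[eligible]]

        # --- ageing and deaths ----------------------------------------
        st.age += 1
        died = starved | (st.age > com.lifespan[st.sp])
        if died.any():
            np.add.at(lrs_sum, st.sp[died], st.lrs[died])
            np.add.at(lrs_n, st.sp[died], 1)

        # --- home-range memory (pre-drought window only) --------------
        if not in_drought:
            slot = day % 7
            st.hr_mem[:, slot] = scan_end
            st.mem_len = np.minimum(st.mem_len + 1, 7)

        # --- metrics ---------------------------------------------------
        alive = ~died
        comp = np.zeros(n)
        _kernels.competitor_census(fcount.ravel(), visits_buf,
                                   visit_start, visit_end, comp)
        sp_alive = st.sp[alive]
        counts = np.bincount(sp_alive, minlength=S)
        pop_out[day] = counts
        nz = counts > 0
        safe = np.maximum(counts, 1)
        hr_out[day, nz] = (np.bincount(sp_alive, scan_end[alive], S) / safe)[nz]
        bal_out[day, nz] = (np.bincount(sp_alive, balance[alive], S) / safe)[nz]
        stor_out[day, nz] = (np.bincount(sp_alive, st.storage[alive], S) / safe)[nz]
        comp_out[day, nz] = (np.bincount(sp_alive, comp[alive], S) / safe)[nz]

        # --- spawn and disperse weaned juveniles ----------------------
        new = {f: [] for f in _State.FIELDS}
        for i in weaned_idx:
            if died[i]:
                continue
            s = int(st.sp[i])
            litter_n = int(st.litter[i])
            st.lrs[i] += litter_n
            st.repro[i] = _NONE
            st.stage[i] = 0
            st.litter[i] = 0
            natal = (int(st.core_r[i]), int(st.core_c[i]))
            for _ in range(litter_n):
                if st.n + len(new["sp"]) >= eng.max_population:
                    break
                sex = int(rng.integers(2))
                jit = 1.0 + eng.condition_jitter * float(rng.uniform(-1.0, 1.0))
                mass_j = com.wean_mass[s]
                store_j = eng.juvenile_storage_frac * com.storage_cap(mass_j) * jit
                disp_r = max(1, round(eng.dispersal_factor * com.max_radius[s]))
                ddr, ddc, _, ddisc = _kernels.ring_offsets(disp_r)
                picks = []
                for j in rng.integers(int(ddisc[disp_r]), size=eng.max_trials):
                    r0 = (natal[0] + int(ddr[j])) % ls.side_cells
                    c0 = (natal[1] + int(ddc[j])) % ls.side_cells
                    picks.append((r0, c0))
                core = _establish(com, ls, s, mass_j, store_j, picks)
                if core is None:
                    continue
                new["uid"].append(next_uid); next_uid += 1
                new["sp"].append(s); new["sex"].append(sex)
                new["age"].append(int(com.lactation[s]))
                new["mass"].append(mass_j); new["storage"].append(store_j)
                new["core_r"].append(core[0]); new["core_c"].append(core[1])
                new["repro"].append(_NONE); new["stage"].append(0)
                new["litter"].append(0); new["lrs"].append(0)
                new["mem_len"].append(0); new["cap_mult"].append(jit)

        if died.any():
            st.keep(alive)
        if new["sp"]:
            st.append(**{k: np.asarray(v) for k, v in new.items()})

    # survivors contribute their LRS at the end of the run
    if st.n:
        np.add.at(lrs_sum, st.sp, st.lrs)
        np.add.at(lrs_n, st.sp, 1)
    lrs_mean = np.divide(lrs_sum, lrs_n, out=np.zeros(S), where=lrs_n > 0)

    if ledger_rows is not None:
        pd.DataFrame(ledger_rows, columns=[
            "day", "individual", "species", "ingested", "assimilated",
            "maintenance", "locomotion", "growth_cost", "repro_cost",
            "storage_delta", "shortfall", "balance"]).to_csv(
                ledger_path, index=False)

    audit_out = {}
    if audit:
        audit_out = {"max_ledger_residual": max_residual,
                     "max_intake_minus_supply": max_over_intake,
                     "max_storage_violation": max_storage_violation}
    return SimResult(config=config, species=species, population=pop_out,
                     mean_hr=hr_out, mean_balance=bal_out,
                     mean_storage=stor_out, competitors=comp_out,
                     lrs_mean=lrs_mean, audit=audit_out)
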