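"""Home-range establishment, foraging order, daily foraging, drought strategies."""

import itertools
import math

import numpy as np
import pytest

from enercomm.allometry import derive_traits, maintenance_rate
from enercomm.behaviour import (Strategy, disperse_juvenile,
                                establish_home_range, forage_day,
                                foraging_order)
from enercomm.energetics import Individual
from enercomm.landscape import Landscape, SeasonParams, renew_and_force


def uniform_landscape(side=15, cap=20.0, habitat=True):
    mask = np.full((side, side), habitat, dtype=bool)
    ls = Landscape(side, 10.0, mask, np.zeros((side, side)),
                   SeasonParams(cap, 0.0), toroidal=True)
    if habitat:
        renew_and_force(ls, 0, 1.0)
    return ls


def make_individual(traits, storage=None):
    return Individual(id=1, species_id=traits.species_id,
                      structural_mass=traits.adult_mass,
                      storage=traits.storage_cap if storage is None else storage,
                      age_days=traits.maturity_days)


class TestEstablishment:
    def test_accepted_radius_matches_brute_force_minimum(self, frictionless_config):
        """With zero travel cost the minimal viable radius has a closed form."""
        traits = derive_traits(1, 10.0, frictionless_config)
        cap = 1.2  # lean cells force a multi-ring range
        ls = uniform_landscape(side=21, cap=cap)
        ind = make_individual(traits, storage=5.0)
        assert establish_home_range(ind, traits, ls,
                                    rng=np.random.default_rng(0))
        need = (maintenance_rate(traits, traits.adult_mass)
                / (traits.config.assim_eff * (1 - traits.config.digest_loss)))
        # oracle: independent near-to-far accumulation over explicit offsets
        offs = sorted((math.hypot(dr, dc), dr, dc)
                      for dr in range(-10, 11) for dc in range(-10, 11)
                      if math.hypot(dr, dc) <= traits.max_hr_radius + 1e-9)
        acc, oracle_radius = 0.0, None
        for d, dr, dc in offs:
            acc += cap * traits.food_share
            if acc >= need - 1e-9:
                oracle_radius = math.ceil(d)
                break
        assert oracle_radius is not None
        assert ind.current_radius == oracle_radius

    def test_all_matrix_world_removes_individual(self, small_traits):
        ls = uniform_landscape(habitat=False)
        ind = make_individual(small_traits)
        ok = establish_home_range(ind, small_traits, ls, max_trials=5,
                                  rng=np.random.default_rng(1))
        assert not ok
        assert not ind.alive

    def test_max_trials_validated(self, small_traits):
        with pytest.raises(ValueError):
            establish_home_range(make_individual(small_traits),
                                 small_traits, uniform_landscape(),
                                 max_trials=0)


class TestForagingOrder:
    def test_singleton(self, rng):
        assert foraging_order(np.array([25.0]), np.array([0]), rng).tolist() == [0]

    def test_symmetric_individuals_draw_uniform_orders(self):
        rng = np.random.default_rng(7)
        masses = np.array([20.0, 20.0, 20.0])
        consp = np.zeros(3, dtype=int)
        counts = {p: 0 for p in itertools.permutations(range(3))}
        n = 10_000
        for _ in range(n):
            counts[tuple(foraging_order(masses, consp, rng))] += 1
        expected = n / 6
        chi2 = sum((c - expected) ** 2 / expected for c in counts.values())
        assert chi2 < 16.75  # chi-square df=5, p=0.005

    def test_large_individual_has_slight_advantage(self):
        rng = np.random.default_rng(11)
        masses = np.array([100.0, 10.0])
        consp = np.zeros(2, dtype=int)
        first = sum(foraging_order(masses, consp, rng)[0] == 0
                    for _ in range(10_000))
        assert 0.55 < first / 10_000 < 0.95

    def test_crowded_individual_forages_later_on_average(self):
        rng = np.random.default_rng(13)
        masses = np.array([20.0, 20.0])
        consp = np.array([8, 0])
        first = sum(foraging_order(masses, consp, rng)[0] == 1
                    for _ in range(4_000))
        assert first / 4_000 > 0.8


class TestForageDay:
    def test_satiation_at_core(self, small_traits):
        ls = uniform_landscape(cap=50.0)
        ind = make_individual(small_traits)            # storage at cap
        ind.core_cell = (7, 7)
        out = forage_day(ind, small_traits, ls)
        assert out.aim_met
        assert out.distance_moved == 0.0
        assert out.final_radius == 0.0
        assert out.cells_visited == [(7, 7)]

    def test_maintain_caps_range_at_memory_mean(self, small_traits):
        ls = uniform_landscape(cap=0.4)                # scarce: wants to expand
        ind = make_individual(small_traits, storage=0.0)
        ind.core_cell = (7, 7)
        ind.hr_memory = [12.0] * 7
        out = forage_day(ind, small_traits, ls, strategy=Strategy.MAINTAIN,
                         in_drought=True)
        assert out.hr_size <= 12
        unconstrained = forage_day(make_individual(small_traits, storage=0.0),
                                   small_traits, uniform_landscape(cap=0.4),
                                   strategy=Strategy.INCREASE, in_drought=True)
        assert unconstrained.hr_size > 12

    def test_decrease_skips_foraging_while_storage_covers_survival(self, small_traits):
        ls = uniform_landscape(cap=20.0)
        ind = make_individual(small_traits)            # full storage
        out = forage_day(ind, small_traits, ls, strategy=Strategy.DECREASE,
                         in_drought=True)
        assert out.ingested == 0.0
        assert out.cells_visited == []
        # once storage is gone the survival aim kicks in
        hungry = make_individual(small_traits, storage=0.0)
        out2 = forage_day(hungry, small_traits, ls, strategy=Strategy.DECREASE,
                          in_drought=True)
        assert out2.ingested > 0.0

    def test_unknown_strategy_rejected(self, small_traits):
        with pytest.raises(ValueError):
            forage_day(make_individual(small_traits), small_traits,
                       uniform_landscape(), strategy="hibernate")

    def test_sequential_depletion_conserves_resources(self, community):
        ls = uniform_landscape(side=12, cap=6.0)
        total_before = ls.resource.sum()
        ingested = 0.0
        for i, traits in enumerate(community[:5]):
            ind = make_individual(traits, storage=0.0)
            ind.core_cell = (6, 6)
            ingested += forage_day(ind, traits, ls).ingested
        assert ls.resource.min() >= 0.0
        assert ingested <= total_before + 1e-9
        assert ls.resource.sum() == pytest.approx(total_before - ingested)


class TestDispersal:
    def test_establishment_succeeds_on_rich_empty_landscape(self, small_traits):
        successes = 0
        for seed in range(100):
            ls = uniform_landscape(cap=30.0)
            juv = make_individual(small_traits, storage=10.0)
            juv.core_cell = (7, 7)
            if disperse_juvenile(juv, small_traits, ls, natal_core=(7, 7),
                                 rng=np.random.default_rng(seed)):
                successes += 1
        assert successes >= 99

    def test_dispersal_distance_within_radius(self, small_traits):
        factor = 3.0
        limit = factor * small_traits.max_hr_radius
        side = 15
        for seed in range(30):
            ls = uniform_landscape(side=side, cap=30.0)
            juv = make_individual(small_traits, storage=10.0)
            assert disperse_juvenile(juv, small_traits, ls, natal_core=(7, 7),
                                     dispersal_factor=factor,
                                     rng=np.random.default_rng(seed))
            dr = min(abs(juv.core_cell[0] - 7), side - abs(juv.core_cell[0] - 7))
            dc = min(abs(juv.core_cell[1] - 7), side - abs(juv.core_cell[1] - 7))
            assert math.hypot(dr, dc) <= limit + 1e-9
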