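"""Caterpillar agents: leaf choice, feeding law, development, pupation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fspherb import architecture as arch
from fspherb.fixtures import caterpillar_oracle
from fspherb.herbivory import (Herbivore, choose_leaf, feed_and_grow, infest,
                               selection_weight, step_herbivore)
from fspherb.params import HerbivoreParameters, PlantParameters


def plant_with_leaves(rng, ages, area=0.02):
    p = PlantParameters()
    plant = arch.new_plant(0, (0.0, 0.0, 0.0), p, rng)
    arch.produce_phytomers(plant, 12.0 * (len(ages) + 1))
    for ph, age in zip(plant.main.phytomers, ages):
        ph.age = age
        ph.leaf.grown_mass = area * p.lma
    for ph in plant.main.phytomers[len(ages):]:
        ph.leaf.grown_mass = 0.0
    return plant


def fresh_herbivore(h=0.5, **kw):
    params = HerbivoreParameters(h=h, **kw)
    return Herbivore(id=0, params=params, host_plant=0, weight=params.w0)


class TestSelectionWeight:
    def test_indifferent_preference_is_flat(self, herb_params):
        from dataclasses import replace
        p = replace(herb_params, h=0.5)
        vals = [selection_weight(a, p) for a in (0.0, 50.0, 150.0, 400.0)]
        assert all(v == pytest.approx(p.rp_max / 2) for v in vals)

    def test_midpoint_age_is_half_max_for_any_preference(self, herb_params):
        from dataclasses import replace
        for h in (0.0, 0.2, 0.8, 1.0):
            p = replace(herb_params, h=h)
            assert selection_weight(p.m, p) == pytest.approx(p.rp_max / 2)

    @given(st.floats(0, 600), st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_complementary_preferences_sum_to_max(self, age, h):
        from dataclasses import replace
        base = HerbivoreParameters()
        a = selection_weight(age, replace(base, h=h))
        b = selection_weight(age, replace(base, h=1 - h))
        assert a + b == pytest.approx(base.rp_max, rel=1e-9)

    def test_young_leaf_feeder_prefers_young(self, herb_params):
        from dataclasses import replace
        p = replace(herb_params, h=0.8)
        assert selection_weight(50.0, p) > selection_weight(400.0, p)


class TestChooseLeaf:
    def test_single_leaf_always_chosen(self, rng):
        plant = plant_with_leaves(rng, [100.0])
        herb = fresh_herbivore()
        ref = choose_leaf(plant, herb, rng)
        assert ref == (0, 0)

    def test_equal_ages_uniform_choice(self, rng):
        plant = plant_with_leaves(rng, [100.0, 100.0])
        counts = np.zeros(2)
        herb = fresh_herbivore()
        for _ in range(4000):
            counts[choose_leaf(plant, herb, rng)[1]] += 1
        # chi-square against uniform at alpha ~ 1e-4
        chi2 = ((counts - 2000.0) ** 2 / 2000.0).sum()
        assert chi2 < 15.0

    def test_empirical_ratio_matches_selection_curve(self, rng):
        plant = plant_with_leaves(rng, [50.0, 400.0])
        herb = fresh_herbivore(h=0.8)
        n = 10_000
        counts = np.zeros(2)
        for _ in range(n):
            counts[choose_leaf(plant, herb, rng)[1]] += 1
        w = [selection_weight(a, herb.params) for a in (50.0, 400.0)]
        p_young = w[0] / sum(w)
        se = math.sqrt(p_young * (1 - p_young) / n)
        assert counts[0] / n == pytest.approx(p_young, abs=3.5 * se)

    def test_no_live_leaves_starvation_pupation(self, rng):
        plant = plant_with_leaves(rng, [])
        herb = fresh_herbivore()
        assert choose_leaf(plant, herb, rng) is None
        assert herb.state == "pupated"
        assert herb.pupation_cause == "starved"


class TestFeeding:
    def test_daily_demand_is_linear_in_weight(self, rng):
        plant = plant_with_leaves(rng, [100.0], area=1.0)
        herb = fresh_herbivore()
        herb.weight = 0.1
        leaf = plant.main.phytomers[0]
        removed = feed_and_grow(herb, plant, leaf, 1.0)
        assert removed == pytest.approx(7.68e-4 * 0.1)

    def test_weight_follows_power_law_of_consumed_area(self, rng):
        plant = plant_with_leaves(rng, [100.0], area=1.0)
        herb = fresh_herbivore()
        p = herb.params
        for _ in range(60):
            feed_and_grow(herb, plant, plant.main.phytomers[0], 5.0)
        expected = min(p.w_max, max(p.w0, p.a_w * herb.cum_area ** p.b))
        assert herb.weight == pytest.approx(expected, rel=1e-12)

    def test_weight_ceiling_inverts_to_51_cm2(self):
        # 0.178 = 10.61 * A^0.7747 solved for A by an independent root-find
        p = HerbivoreParameters()
        area = (p.w_max / p.a_w) ** (1 / p.b)
        assert area == pytest.approx(5.109862505223561e-3, rel=1e-9)

    def test_exhausted_leaf_flags_shortfall(self, rng):
        plant = plant_with_leaves(rng, [100.0], area=1e-9)
        herb = fresh_herbivore()
        herb.weight = 0.1
        leaf = plant.main.phytomers[0]
        feed_and_grow(herb, plant, leaf, 1.0)
        assert leaf.leaf.live_area(plant.params.lma) == pytest.approx(0.0)
        assert "shortfall" in herb.events

    def test_leaf_area_ledger_balances(self, rng):
        plant = plant_with_leaves(rng, [50.0, 200.0], area=0.004)
        herb = fresh_herbivore()
        herb.weight = 0.05
        lma = plant.params.lma
        gross = sum(ph.leaf.grown_area(lma) for _, ph in plant.phytomer_iter())
        for _ in range(30):
            step_herbivore(herb, plant, 2.0, rng)
        live = sum(ph.leaf.live_area(lma) for _, ph in plant.phytomer_iter())
        assert herb.cum_area + live == pytest.approx(gross, abs=1e-12)


class TestDevelopment:
    def test_instar_progression(self):
        herb = fresh_herbivore()
        p = herb.params
        assert 1 + int(4 * 0.0 / p.lifespan) == 1
        assert 1 + int(4 * 105.0 / p.lifespan) == 3

    def test_pupation_by_age(self, rng):
        plant = plant_with_leaves(rng, [100.0], area=1.0)
        herb = fresh_herbivore(a_f=1e-9)  # barely feeds: age rule must fire
        herb.age = 209.0
        choose_leaf(plant, herb, rng)
        step_herbivore(herb, plant, 2.0, rng)
        assert herb.state == "pupated"
        assert herb.pupation_cause == "age"

    def test_pupation_by_weight_matches_oracle(self, rng):
        # engine stepping at 1 gdd vs the 0.01-gdd oracle: same binding rule,
        # pupation weight exactly at the ceiling, time within 1 %
        oracle = caterpillar_oracle()
        assert oracle.rule == "weight"
        plant = plant_with_leaves(rng, [100.0], area=10.0)
        herb = fresh_herbivore()
        choose_leaf(plant, herb, rng)
        while herb.state == "feeding":
            step_herbivore(herb, plant, 1.0, rng)
        assert herb.pupation_cause == "weight"
        assert herb.weight == pytest.approx(0.178)
        assert herb.age == pytest.approx(oracle.time_to_pupation, rel=0.01)

    def test_moult_triggers_movement(self, rng):
        plant = plant_with_leaves(rng, [100.0] * 8, area=1.0)
        herb = fresh_herbivore()
        choose_leaf(plant, herb, rng)
        start = herb.current_leaf
        moved = False
        for _ in range(300):
            before = herb.current_leaf
            step_herbivore(herb, plant, 1.0, rng)
            if herb.state != "feeding":
                break
            if herb.current_leaf != before:
                moved = True
        assert moved


class TestInfest:
    def _plants(self, rng, n):
        return [arch.new_plant(i, (0.1 * i, 0.0, 0.0),
                               PlantParameters(), rng) for i in range(n)]

    def _feed_leaves(self, plants):
        for pl in plants:
            for ph in pl.main.phytomers:
                ph.leaf.grown_mass = 0.2

    def test_homogeneous_counts(self, rng):
        plants = self._plants(rng, 4)
        self._feed_leaves(plants)
        cohort = infest(plants, "homogeneous", 5, 2, rng, homogeneous_h=0.8)
        assert len(cohort) == 20
        assert {h.params.h for h in cohort} == {0.8}

    def test_heterogeneous_checkerboard(self, rng):
        plants = self._plants(rng, 16)
        self._feed_leaves(plants)
        cohort = infest(plants, "heterogeneous", 5, 4, rng, homogeneous_h=0.8)
        infested = {h.host_plant for h in cohort}
        assert len(infested) == 8
        assert len(cohort) == 40

    def test_alternating_preferences(self, rng):
        plants = self._plants(rng, 16)
        self._feed_leaves(plants)
        cohort = infest(plants, "alternating", 5, 4, rng)
        by_h = {}
        for h in cohort:
            by_h.setdefault(h.params.h, set()).add(h.host_plant)
        assert len(by_h[0.8]) == 8
        assert len(by_h[0.2]) == 8

    def test_odd_grid_rejected_for_checkerboards(self, rng):
        plants = self._plants(rng, 9)
        self._feed_leaves(plants)
        with pytest.raises(ValueError):
            infest(plants, "alternating", 5, 3, rng)

    def test_unknown_pattern_rejected(self, rng):
        with pytest.raises(ValueError):
            infest([], "striped", 5, 2, rng)
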