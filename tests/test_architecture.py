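"""Phytomer production, branching rules, senescence and the pipe model."""

import math

import numpy as np
import pytest

from fspherb import architecture as arch
from fspherb.params import PlantParameters


def make_plant(rng, **overrides):
    p = PlantParameters(**overrides)
    return arch.new_plant(0, (0.0, 0.0, 0.0), p, rng)


class TestProducePhytomers:
    def test_two_phyllochrons_give_two_phytomers(self, rng):
        plant = make_plant(rng)
        n0 = len(plant.main.phytomers)
        arch.produce_phytomers(plant, 24.0)
        assert len(plant.main.phytomers) == n0 + 2

    def test_no_thermal_time_no_change(self, rng):
        plant = make_plant(rng)
        n0 = len(plant.main.phytomers)
        arch.produce_phytomers(plant, 0.0)
        assert len(plant.main.phytomers) == n0

    def test_flowering_at_phytomer_target(self, rng):
        plant = make_plant(rng)
        target = plant.target_n
        arch.produce_phytomers(plant, target * 12.0 + 1)
        assert len(plant.main.phytomers) == target
        assert plant.main.flowering
        assert plant.main.seed is not None
        # flowering is terminal: no more vegetative phytomers
        arch.produce_phytomers(plant, 120.0)
        assert len(plant.main.phytomers) == target

    def test_ranks_consecutive(self, rng):
        plant = make_plant(rng)
        arch.produce_phytomers(plant, 200.0)
        ranks = [ph.rank for ph in plant.main.phytomers]
        assert ranks == list(range(len(ranks)))


class TestBranching:
    def _grown_plant(self, rng, n=10):
        plant = make_plant(rng)
        arch.produce_phytomers(plant, n * 12.0)
        for ph in plant.main.phytomers:
            ph.age = 80.0            # past apical-dominance release
            ph.leaf.grown_mass = 0.3
            ph.tip_rfr = 1.2
        return plant

    def test_no_surplus_no_break(self, rng):
        plant = self._grown_plant(rng)
        plant.last_satisfaction = 0.0
        arch.update_branching(plant, surplus=0.0)
        assert plant.branch_count() == 0

    def test_staggered_breaks_with_surplus(self, rng):
        plant = self._grown_plant(rng)
        for _ in range(4):
            arch.update_branching(plant, surplus=1.0)
        assert plant.branch_count() == 4  # one bud per favourable day

    def test_low_rfr_blocks_initiation(self, rng):
        plant = self._grown_plant(rng)
        for ph in plant.main.phytomers:
            ph.tip_rfr = 0.5         # below the 0.65 abortion threshold
        arch.update_branching(plant, surplus=1.0)
        assert plant.branch_count() == 0

    def test_basal_axils_stay_dormant(self, rng):
        plant = self._grown_plant(rng)
        for _ in range(30):
            arch.update_branching(plant, surplus=1.0)
        p = plant.params
        for ph in plant.main.phytomers[:p.basal_dormant_ranks]:
            assert ph.meristem.state == "dormant"

    def test_sustained_low_rfr_aborts_immature_branch(self, rng):
        plant = self._grown_plant(rng)
        arch.update_branching(plant, surplus=1.0)
        assert plant.branch_count() == 1
        branch = plant.axes[1]
        plant.last_satisfaction = 0.0    # unfavourable: no further breaks
        for ph in plant.main.phytomers:
            ph.tip_rfr = 0.60            # below the abortion threshold
        for _ in range(plant.params.abort_days):
            arch.update_branching(plant, surplus=0.0)
        assert plant.axes[1].aborted
        assert plant.branch_count() == 0
        # abortion is terminal even if the light recovers
        for ph in plant.main.phytomers:
            ph.tip_rfr = 1.2
        arch.update_branching(plant, surplus=1.0)
        assert plant.axes[1].aborted

    def test_single_low_day_does_not_abort(self, rng):
        plant = self._grown_plant(rng)
        arch.update_branching(plant, surplus=1.0)
        bearer = plant.main.phytomers[plant.axes[1].parent_rank]
        plant.last_satisfaction = 0.0
        bearer.tip_rfr = 0.60
        arch.update_branching(plant, surplus=0.0)
        bearer.tip_rfr = 1.2
        for _ in range(10):
            arch.update_branching(plant, surplus=0.0)
        assert not plant.axes[1].aborted

    def test_starvation_aborts_youngest_branch(self, rng):
        plant = self._grown_plant(rng)
        for _ in range(3):
            arch.update_branching(plant, surplus=1.0)
        plant.starve_days = plant.params.n_starve
        arch.update_branching(plant, surplus=0.0)
        aborted = [a for a in plant.axes[1:] if a.aborted]
        assert len(aborted) == 1
        assert aborted[0].created_gdd == max(a.created_gdd for a in plant.axes[1:])


class TestSenescence:
    def test_age_rule(self, rng):
        plant = make_plant(rng)
        ph = plant.main.phytomers[0]
        ph.leaf.grown_mass = 0.5
        ph.age = plant.params.senes_age + 1
        arch.senesce_leaves(plant)
        assert ph.leaf.senesced
        assert plant.litter_mass == pytest.approx(0.5)

    def test_young_lit_leaf_survives(self, rng):
        plant = make_plant(rng)
        ph = plant.main.phytomers[0]
        ph.leaf.grown_mass = 0.5
        ph.age = 100.0
        ph.leaf.rel_light = 1.0
        arch.senesce_leaves(plant)
        assert not ph.leaf.senesced

    def test_sustained_deep_shade_kills_old_leaf(self, rng):
        plant = make_plant(rng)
        ph = plant.main.phytomers[0]
        ph.leaf.grown_mass = 0.5
        ph.age = 200.0
        ph.leaf.rel_light = 0.0
        for _ in range(plant.params.senes_light_days):
            arch.senesce_leaves(plant)
        assert ph.leaf.senesced

    def test_senescence_is_monotone(self, rng):
        plant = make_plant(rng)
        ph = plant.main.phytomers[0]
        ph.leaf.grown_mass = 0.5
        ph.age = plant.params.senes_age + 1
        arch.senesce_leaves(plant)
        litter = plant.litter_mass
        ph.leaf.rel_light = 1.0
        arch.senesce_leaves(plant)
        assert ph.leaf.senesced
        assert plant.litter_mass == litter


class TestPipeModel:
    def test_unbranched_stem_uniform_initial_radius(self, rng):
        plant = make_plant(rng)
        arch.produce_phytomers(plant, 120.0)
        arch.pipe_model(plant)
        r0 = plant.params.r0
        for ph in plant.main.phytomers:
            assert ph.internode.radius == pytest.approx(r0)

    def test_two_terminal_daughters_sum_areas(self, rng):
        # an internode carrying the apex plus one single-phytomer branch has
        # cross-section 2 * pi * r0^2, i.e. radius r0 * sqrt(2)
        plant = make_plant(rng, basal_dormant_ranks=0, dominance_age=0.0)
        arch.produce_phytomers(plant, 24.0)
        for ph in plant.main.phytomers:
            ph.age = 50.0
            ph.tip_rfr = 1.2
        arch.update_branching(plant, surplus=1.0)
        branch = plant.axes[1]
        branch.phytomers.append(arch._make_phytomer(plant, branch, 0, 1.2))
        arch.pipe_model(plant)
        r0 = plant.params.r0
        bearer_rank = branch.parent_rank
        below = plant.main.phytomers[bearer_rank]
        assert below.internode.radius == pytest.approx(r0 * math.sqrt(2))

    def test_cross_sections_add_exactly_at_junctions(self, rng):
        plant = make_plant(rng, basal_dormant_ranks=0, dominance_age=0.0)
        arch.produce_phytomers(plant, 120.0)
        for ph in plant.main.phytomers:
            ph.age = 80.0
            ph.tip_rfr = 1.2
        for _ in range(4):
            arch.update_branching(plant, surplus=1.0)
        for axis in plant.axes[1:]:
            axis.phytomers.append(arch._make_phytomer(plant, axis, 0, 1.2))
        arch.pipe_model(plant)
        a = lambda ph: math.pi * ph.internode.radius ** 2
        main = plant.main.phytomers
        r0sq = math.pi * plant.params.r0 ** 2
        for i, ph in enumerate(main[:-1]):
            expected = a(main[i + 1])
            if ph.meristem.branch_axis >= 0:
                expected += a(plant.axes[ph.meristem.branch_axis].phytomers[0])
            assert a(ph) == pytest.approx(expected, rel=1e-9)

    def test_radii_never_shrink(self, rng):
        plant = make_plant(rng)
        arch.produce_phytomers(plant, 60.0)
        arch.pipe_model(plant)
        plant.main.phytomers[0].internode.radius = 0.005
        arch.pipe_model(plant)
        assert plant.main.phytomers[0].internode.radius == 0.005

    def test_distal_counts(self, rng):
        plant = make_plant(rng)
        arch.produce_phytomers(plant, 60.0)
        arch.pipe_model(plant)
        n = len(plant.main.phytomers)
        for i, ph in enumerate(plant.main.phytomers):
            assert ph.internode.n_distal == n - i


class TestGrowthClosure:
    def test_leaf_area_follows_mass_over_lma(self, rng):
        # LMA converts allocated mass to one-sided blade area
        plant = make_plant(rng)
        leaf = plant.main.phytomers[0].leaf
        lma = plant.params.lma
        m0 = leaf.grown_mass
        leaf.grown_mass += lma * 0.01
        assert leaf.grown_area(lma) == pytest.approx(m0 / lma + 0.01)

    def test_internode_extension_volume_identity(self, rng):
        # delta mass of wood_density * pi * r0^2 * L extends by L at r0
        plant = make_plant(rng)
        inter = plant.main.phytomers[0].internode
        p = plant.params
        inter.len_acc = 0.05
        inter.mass = p.wood_density * math.pi * p.r0 ** 2 * 0.01
        inter.extend(p.wood_density, p.r0)
        assert inter.length(p.wood_density) == pytest.approx(0.01)
        # extension is capped by the accumulated potential length
        inter.mass *= 100
        inter.extend(p.wood_density, p.r0)
        assert inter.length(p.wood_density) == pytest.approx(0.05)

    def test_height_is_main_stem_length_plus_raceme(self, rng):
        plant = make_plant(rng)
        p = plant.params
        for ph in plant.main.phytomers:
            ph.internode.len_acc = 0.05
            ph.internode.mass = p.wood_density * math.pi * p.r0 ** 2 * 0.05
            ph.internode.extend(p.wood_density, p.r0)
        assert plant.height() == pytest.approx(0.05 * len(plant.main.phytomers))
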