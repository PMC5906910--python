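"""Beta growth curve, photosynthesis, maintenance and allocation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fspherb.physiology import (CarbonPool, SinkRecord, allocate, beta_mass,
                                leaf_photosynthesis, maintenance_cost)


class TestBetaMass:
    def test_endpoint_reaches_wmax(self):
        assert beta_mass(234.0, 234.0, 167.0, 2.5) == 2.5
        assert beta_mass(500.0, 234.0, 167.0, 2.5) == 2.5

    def test_starts_at_zero(self):
        assert beta_mass(0.0, 234.0, 167.0, 2.5) == 0.0

    def test_midpoint_value_against_closed_form(self):
        # w(117; te=234, tm=167) = (1 + 117/67) * (0.5)^(234/67), evaluated
        # independently before implementation
        assert beta_mass(117.0, 234.0, 167.0, 1.0) == pytest.approx(
            0.2439970232426993, rel=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            beta_mass(10.0, 100.0, 150.0, 1.0)
        with pytest.raises(ValueError):
            beta_mass(-1.0, 200.0, 100.0, 1.0)

    @given(st.floats(1, 500), st.floats(1, 500))
    @settings(max_examples=100, deadline=None)
    def test_nondecreasing(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert beta_mass(hi, 234.0, 167.0, 1.0) >= beta_mass(lo, 234.0, 167.0, 1.0)

    def test_increment_maximal_near_tm(self):
        incs = {t: beta_mass(t + 1, 234.0, 167.0, 1.0) - beta_mass(t, 234.0, 167.0, 1.0)
                for t in range(0, 234)}
        t_peak = max(incs, key=incs.get)
        assert abs(t_peak - 167) <= 2


class TestPhotosynthesis:
    def test_no_light_no_carbon(self):
        assert leaf_photosynthesis(0.0, 1.0, 50000.0) == 0.0

    def test_saturates_at_base_capacity(self):
        # I -> infinity at full relative light approaches Amax = 30
        daily = leaf_photosynthesis(1e4, 1.0, 50000.0, amax_base=30.0)
        assert daily == pytest.approx(30.0 * 50000.0 * 30e-6, rel=1e-6)

    def test_concave_and_monotone_in_light(self):
        xs = np.linspace(1, 60, 40)
        ys = [leaf_photosynthesis(x, 1.0, 50000.0) for x in xs]
        diffs = np.diff(ys)
        assert np.all(diffs > 0)
        assert np.all(np.diff(diffs) < 1e-12)

    def test_shade_acclimation_lowers_capacity(self):
        bright = leaf_photosynthesis(50.0, 1.0, 50000.0)
        shaded = leaf_photosynthesis(50.0, 0.1, 50000.0)
        assert shaded < bright


class TestMaintenance:
    def test_zero_mass_zero_cost(self):
        assert maintenance_cost(0.0, 20.0) == 0.0

    def test_reference_rate_at_20C(self):
        assert maintenance_cost(10.0, 20.0, m_coef=0.015) == pytest.approx(0.15)

    def test_q10_doubles_per_10_degrees(self):
        c20 = maintenance_cost(10.0, 20.0)
        c30 = maintenance_cost(10.0, 30.0)
        assert c30 == pytest.approx(2 * c20)


class TestAllocate:
    def make_pool(self, assim, reserves=0.0):
        pool = CarbonPool(assimilates_today=assim, reserves=reserves)
        return pool

    def sinks(self, *growths, grf=1.39):
        return [SinkRecord(i, g, g * grf) for i, g in enumerate(growths)]

    def test_no_sinks_everything_to_reserves(self):
        pool = self.make_pool(5.0)
        res = allocate(pool, [], maintenance=1.0)
        assert pool.reserves == pytest.approx(4.0)
        assert res.surplus == pytest.approx(4.0)

    def test_equal_sinks_share_equally_when_short(self):
        pool = self.make_pool(1.39)  # half the total demand of 2 x 1 g
        res = allocate(pool, self.sinks(1.0, 1.0), maintenance=0.0)
        assert res.growth[0] == pytest.approx(0.5)
        assert res.growth[1] == pytest.approx(0.5)
        assert pool.reserves == 0.0

    def test_proportional_shares_1_2_3(self):
        # demands 1:2:3 (g CH2O) with 3 g available -> structural growth
        # shares 0.5 : 1.0 : 1.5 divided by the growth respiration factor
        grf = 1.39
        sinks = [SinkRecord(i, d / grf, d) for i, d in enumerate((1.0, 2.0, 3.0))]
        pool = self.make_pool(3.0)
        res = allocate(pool, sinks, maintenance=0.0, grf=grf)
        assert res.growth == pytest.approx([x / grf for x in (0.5, 1.0, 1.5)])

    def test_full_demand_met_leaves_surplus(self):
        pool = self.make_pool(5.0)
        res = allocate(pool, self.sinks(1.0), maintenance=0.0)
        assert res.growth[0] == pytest.approx(1.0)
        assert res.surplus == pytest.approx(5.0 - 1.39)

    def test_maintenance_shortfall_recorded(self):
        pool = self.make_pool(0.5, reserves=0.2)
        res = allocate(pool, [], maintenance=1.0)
        assert res.shortfall
        assert pool.stress_days == 1
        assert pool.reserves == 0.0

    def test_negative_demand_rejected(self):
        pool = self.make_pool(1.0)
        with pytest.raises(ValueError):
            allocate(pool, [SinkRecord(0, -1.0, -1.39)], 0.0)

    @given(st.floats(0, 20), st.floats(0, 5),
           st.lists(st.floats(0, 3), min_size=0, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_carbon_conserved(self, assim, maint, growths):
        grf = 1.39
        pool = self.make_pool(assim)
        res = allocate(pool, self.sinks(*growths, grf=grf), maint, grf)
        spent = res.maintenance_paid + grf * sum(res.growth) + pool.reserves
        assert spent == pytest.approx(assim, abs=1e-9)
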