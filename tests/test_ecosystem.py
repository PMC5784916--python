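"""Simulator mechanics: mortality closed forms, predation structure,
growth/starvation, recruitment scaling, migration conservation, fishing
closures, flux balance, nitrogen accounting and the fine-step oracle."""

import numpy as np
import pytest

import spillweb as sw
from spillweb.ecosystem import DAYS_PER_YEAR, Ecosystem, SimulationError
from spillweb.foodweb import FLEETS
from spillweb.forcings import ClosureSchedule, LarvalLossTable

from conftest import make_eco, make_predprey_groups, make_solo_groups


class TestInitState:
    def test_same_seed_gives_identical_state(self, small_geometry, demo_groups):
        eco = make_eco(demo_groups, small_geometry)
        a = eco.init_state(seed=3)
        b = eco.init_state(seed=3)
        assert np.array_equal(a.numbers, b.numbers)
        assert np.array_equal(a.rN, b.rN)

    def test_pelagic_groups_have_no_sediment_presence(self, small_geometry,
                                                      demo_groups):
        eco = make_eco(demo_groups, small_geometry)
        i = eco.index["small pelagic fish"]
        assert np.all(eco.profile[i, :, -1] == 0)  # sediment layer empty
        j = eco.index["benthic_invertebrates"]
        assert np.all(eco.profile[j, :, -1] > 0)

    def test_state_positive_in_occupied_cells(self, small_geometry,
                                              demo_groups):
        eco = make_eco(demo_groups, small_geometry)
        state = eco.init_state(seed=0)
        fish = np.nonzero(eco.is_fish)[0]
        for i in fish:
            n = eco.n_ages[i]
            assert np.all(state.numbers[i, :n, :] > 0)
            assert np.all(state.sN[i, :n] > 0)


class TestMortality:
    def test_pure_linear_mortality_matches_exponential(self, solo_eco):
        eco, state = solo_eco
        Z = eco.groups[0].turnover
        n0 = state.numbers[0].sum()
        for _ in range(720):  # 360 days, before any year boundary
            eco.step(state, dt=0.5)
        expected = n0 * np.exp(-Z * 360 / DAYS_PER_YEAR)
        assert state.numbers[0].sum() == pytest.approx(expected, rel=1e-3)

    def test_oil_mortality_strictly_lowers_survival(self, solo_eco):
        eco, state = solo_eco
        clean = state.copy()
        oiled = state.copy()
        P, G = eco.P, eco.G
        m_oil = np.full((P, G), 0.01)
        eco.step(clean, dt=0.5, modifiers=(np.zeros((P, G)), np.ones((P, G))))
        eco.step(oiled, dt=0.5, modifiers=(m_oil, np.ones((P, G))))
        assert oiled.numbers[0].sum() < clean.numbers[0].sum()

    def test_quadratic_term_raises_per_capita_mortality_with_density(
            self, small_geometry):
        eco = make_eco(make_solo_groups(), small_geometry, k_maint=0.0,
                       spawn_fraction=0.0, mq_share=0.3)
        lo = eco.init_state(seed=0, density_jitter=0.0)
        hi = lo.copy()
        hi.numbers *= 2.0
        d_lo = eco.natural_mortality(lo, dt=0.5)
        d_hi = eco.natural_mortality(hi, dt=0.5)
        # more than proportional loss: per-capita mortality rose with density
        assert d_hi[0].sum() > 2.0 * d_lo[0].sum()


class TestPredation:
    def test_zero_availability_means_zero_consumption(self, small_geometry):
        groups = make_predprey_groups()
        groups[0].diet_row = {}
        eco = make_eco(groups, small_geometry)
        state = eco.init_state(seed=0)
        loss, percap, _ = eco.predation_fluxes(state)
        assert np.all(loss[0] == 0) and np.all(loss[1] == 0)

    def test_per_capita_intake_saturates_at_cmax(self, small_geometry):
        groups = make_predprey_groups()
        eco = make_eco(groups, small_geometry)
        state = eco.init_state(seed=0)
        state.numbers[1, 0] *= 1e6  # prey to (near) infinity
        _, percap, _ = eco.predation_fluxes(state)
        i = eco.index["pred"]
        n = eco.n_ages[i]
        assert np.all(percap[i, :n, :] <= eco.cmax[i, :n, None] + 1e-12)
        sat = percap[i, :n, :] / eco.cmax[i, :n, None]
        assert np.all(sat > 0.999)

    def test_identical_prey_consumed_equally(self, small_geometry):
        groups = make_predprey_groups()
        prey2 = __import__("copy").deepcopy(groups[1])
        prey2.name = "forage2"
        groups.insert(2, prey2)
        groups[0].diet_row = {"forage": 0.3, "forage2": 0.3}
        eco = make_eco(groups, small_geometry)
        state = eco.init_state(seed=0, density_jitter=0.0)
        loss, _, _ = eco.predation_fluxes(state)
        i, j = eco.index["forage"], eco.index["forage2"]
        assert np.allclose(loss[i], loss[j], rtol=1e-9)

    def test_predation_never_exceeds_available_prey(self, small_geometry,
                                                    demo_groups):
        eco = make_eco(demo_groups, small_geometry)
        state = eco.init_state(seed=0)
        state.numbers *= 0.01  # scarce prey: caps must engage cleanly
        for _ in range(20):
            eco.step(state, dt=0.5)  # validate() inside raises on negatives
        assert np.all(state.numbers >= 0)


class TestGrowth:
    def test_zero_growth_multiplier_stops_weight_gain(self, small_geometry):
        groups = make_predprey_groups()
        eco = make_eco(groups, small_geometry, k_maint=0.0, spawn_fraction=0.0)
        state = eco.init_state(seed=0)
        P, G = eco.P, eco.G
        sN0, rN0 = state.sN.copy(), state.rN.copy()
        eco.step(state, dt=0.5, modifiers=(np.zeros((P, G)),
                                           np.zeros((P, G))))  # g_mult = 0
        i = eco.index["pred"]
        assert np.all(state.sN[i] == sN0[i])
        assert np.all(state.rN[i] <= rN0[i] + 1e-12)

    def test_unit_multiplier_is_bitwise_baseline(self, small_geometry,
                                                 demo_groups):
        eco = make_eco(demo_groups, small_geometry)
        a = eco.init_state(seed=0)
        b = a.copy()
        P, G = eco.P, eco.G
        eco.step(a, dt=0.5, modifiers=None)
        eco.step(b, dt=0.5, modifiers=(np.zeros((P, G)), np.ones((P, G))))
        assert np.array_equal(a.numbers, b.numbers)
        assert np.array_equal(a.rN, b.rN)

    def test_starvation_draws_reserve_not_structure(self, small_geometry):
        groups = make_predprey_groups()
        eco = make_eco(groups, small_geometry)
        state = eco.init_state(seed=0)
        state.numbers[1, 0] *= 1e-6  # remove the prey field
        i = eco.index["pred"]
        sN0, rN0 = state.sN[i].copy(), state.rN[i].copy()
        for _ in range(60):
            eco.step(state, dt=0.5)
        n = eco.n_ages[i]
        assert np.all(state.rN[i, :n] < rN0[:n])
        assert np.all(state.sN[i, :n] <= sN0[:n] + 1e-9)


class TestRecruitment:
    def _run_year(self, eco, state, loss_table):
        for _ in range(732):
            rec = eco.step(state, dt=0.5, larval_loss=loss_table,
                           spill_year=0)
            if rec.recruits is not None:
                return rec.recruits
        raise AssertionError("no year boundary reached")

    def test_larval_loss_scales_recruits(self, small_geometry):
        results = {}
        for loss in (0.0, 0.058, 1.0):
            eco = make_eco(make_predprey_groups(), small_geometry)
            state = eco.init_state(seed=0, density_jitter=0.0)
            table = LarvalLossTable({"pred": loss})
            results[loss] = self._run_year(eco, state, table)[
                eco.index["pred"]]
        assert results[1.0] == 0.0
        assert results[0.058] == pytest.approx(0.942 * results[0.0], rel=1e-9)

    def test_no_table_equals_zero_loss(self, small_geometry):
        eco = make_eco(make_predprey_groups(), small_geometry)
        a = eco.init_state(seed=0)
        b = a.copy()
        ra = self._run_year(eco, a, None)
        eco2 = make_eco(make_predprey_groups(), small_geometry)
        eco2.init_state(seed=0)  # calibrate
        rb = self._run_year(eco2, b, LarvalLossTable({"pred": 0.0}))
        assert np.allclose(ra, rb)

    def test_invalid_loss_rejected(self):
        with pytest.raises(ValueError):
            LarvalLossTable({"pred": -0.2})


class TestMigration:
    def test_no_schedule_is_identity(self, small_geometry):
        eco = make_eco(make_solo_groups(), small_geometry,
                       k_maint=0.0, spawn_fraction=0.0)
        state = eco.init_state(seed=0)
        before = state.numbers.copy()
        eco.migration_fluxes(state, day=100.0, dt=0.5)
        assert np.array_equal(state.numbers, before)

    def test_full_out_and_back_conserves_numbers(self, small_geometry):
        groups = make_solo_groups()
        groups[0].migration_schedule = {"out_start": 10, "out_end": 40,
                                        "out_fraction": 1.0,
                                        "in_start": 60, "in_end": 90}
        eco = make_eco(groups, small_geometry, k_maint=0.0, spawn_fraction=0.0)
        state = eco.init_state(seed=0)
        total0 = state.numbers[0].sum() + state.external[0].sum()
        for day2 in range(0, 2 * 100):
            eco.migration_fluxes(state, day=day2 / 2, dt=0.5)
        assert state.external[0].sum() == pytest.approx(0.0, abs=1e-6 * total0)
        assert state.numbers[0].sum() + state.external[0].sum() == \
            pytest.approx(total0, rel=1e-9)

    def test_diffusion_reduces_density_gap(self):
        geom = sw.gen_geometry(n_polygons=2, grid_resolution=0.5, seed=1)
        groups = make_solo_groups()
        groups[0].diffusion = 0.05
        eco = make_eco(groups, geom, k_maint=0.0, spawn_fraction=0.0)
        state = eco.init_state(seed=0, density_jitter=0.0)
        state.numbers[0, :, 1] = 0.0  # empty one polygon
        dens = lambda: state.numbers[0, 0, :] / geom.areas
        gap0 = abs(dens()[0] - dens()[1])
        total0 = state.numbers[0].sum()
        eco.migration_fluxes(state, day=5.0, dt=0.5)
        gap1 = abs(dens()[0] - dens()[1])
        assert gap1 < gap0
        assert state.numbers[0].sum() == pytest.approx(total0, rel=1e-12)


class TestFishing:
    def _closures(self, eco, frac):
        closed = np.full((10, eco.P, len(FLEETS)), frac)
        return ClosureSchedule(start_day=0, closed=closed)

    def test_full_closure_stops_catch(self, small_geometry):
        eco = make_eco(make_solo_groups(fishing=0.3), small_geometry)
        state = eco.init_state(seed=0)
        catch = eco.fishing_fluxes(state, self._closures(eco, 1.0), day=2.0)
        assert np.all(catch == 0)

    def test_partial_closure_scales_catch(self, small_geometry):
        eco = make_eco(make_solo_groups(fishing=0.3), small_geometry)
        state = eco.init_state(seed=0)
        open_catch = eco.fishing_fluxes(state.copy(), None, day=2.0)
        part_catch = eco.fishing_fluxes(state.copy(),
                                        self._closures(eco, 0.4), day=2.0)
        # the closure scales F itself; catch = N(1 - exp(-F dt)) follows
        # to first order in F dt
        assert part_catch.sum() == pytest.approx(0.6 * open_catch.sum(),
                                                 rel=1e-3)

    def test_no_reallocation_of_effort(self, small_geometry):
        eco = make_eco(make_solo_groups(fishing=0.3), small_geometry)
        state = eco.init_state(seed=0)
        closed = np.zeros((10, eco.P, len(FLEETS)))
        closed[:, 0, :] = 1.0  # close polygon 0 only
        sched = ClosureSchedule(start_day=0, closed=closed)
        open_catch = eco.fishing_fluxes(state.copy(), None, day=2.0)
        part_catch = eco.fishing_fluxes(state.copy(), sched, day=2.0)
        assert np.all(part_catch[:, :, 0] == 0)
        assert np.allclose(part_catch[:, :, 1:], open_catch[:, :, 1:])


class TestConservation:
    def test_flux_record_closes_biomass_budget(self, small_geometry,
                                               demo_groups):
        eco = make_eco(demo_groups, small_geometry)
        state = eco.init_state(seed=0)
        scale = state.biomass().sum()
        for k in range(40):
            rec = eco.step(state, dt=0.5)
            err = np.abs(rec.imbalance()).max()
            assert err < 1e-8 * scale

    def test_nitrogen_conserved_without_fishing_or_migration(
            self, small_geometry):
        groups = sw.gen_food_web(seed=0)
        for g in groups:
            g.fishing_mortality = 0.0
            g.migration_schedule = None
        eco = make_eco(groups, small_geometry)
        state = eco.init_state(seed=0)
        n0 = eco.total_nitrogen(state)
        for _ in range(730):  # one simulated year at 12-h steps
            eco.step(state, dt=0.5)
        n1 = eco.total_nitrogen(state)
        assert abs(n1 - n0) / n0 < 1e-6

    def test_fishing_exports_nitrogen(self, small_geometry):
        eco = make_eco(make_solo_groups(fishing=0.5), small_geometry)
        state = eco.init_state(seed=0)
        n0 = eco.total_nitrogen(state)
        for _ in range(100):
            eco.step(state, dt=0.5)
        assert eco.total_nitrogen(state) < n0

    def test_nan_state_aborts_with_diagnostic(self, solo_eco):
        eco, state = solo_eco
        state.numbers[0, 0, 0] = np.nan
        with pytest.raises(SimulationError):
            eco.step(state, dt=0.5)


class TestIntegrationAccuracy:
    def test_fine_step_oracle_on_predator_prey_subsystem(self, small_geometry):
        results = {}
        for dt in (0.5, 0.005):
            eco = make_eco(make_predprey_groups(), small_geometry)
            state = eco.init_state(seed=0, density_jitter=0.0)
            state.numbers[1, 0] *= 0.5  # perturb prey: transient dynamics
            n_steps = int(round(360 / dt))
            for _ in range(n_steps):
                eco.step(state, dt=dt)
            results[dt] = state.biomass().sum(axis=1)
        pred = results[0.5][0] / results[0.005][0]
        prey = results[0.5][1] / results[0.005][1]
        assert abs(pred - 1) < 0.01
        assert abs(prey - 1) < 0.01
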