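"""Dose-response and exposure pipeline: hockey-stick properties, the
uptake-depuration recursion, polygon aggregation and the modifier series."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spillweb as sw
from spillweb.toxicology import DoseResponseParams, polygon_modifier_series

P = DoseResponseParams()

HSET = settings(derandomize=True, max_examples=60, deadline=None)


class TestBodyBurden:
    def test_99_percent_clearance_in_20_days(self):
        phi = 1.0
        for _ in range(20):
            phi = sw.update_body_burden(phi, 0.0, mu=0.1, rho=P.rho)
        assert phi <= 0.01  # rho = 0.2424 clears >= 99% in 20 days

    def test_zero_uptake_is_pure_exponential_decay(self):
        phi = 5.0
        for t in range(1, 15):
            phi = sw.update_body_burden(phi, 3.0, mu=0.0, rho=P.rho)
            assert phi == pytest.approx(5.0 * np.exp(-P.rho * t))

    def test_constant_forcing_converges_to_geometric_series_limit(self):
        c, mu = 2.5, 1.0
        phi = 0.0
        for _ in range(300):
            phi = sw.update_body_burden(phi, c, mu=mu, rho=P.rho)
        # closed form: mu*c * sum_k exp(-rho k) = mu*c / (1 - exp(-rho))
        assert phi == pytest.approx(mu * c / (1 - np.exp(-P.rho)), rel=1e-10)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            sw.update_body_burden(-1.0, 0.0, mu=1.0, rho=0.2)
        with pytest.raises(ValueError):
            sw.update_body_burden(1.0, -2.0, mu=1.0, rho=0.2)

    @HSET
    @given(st.lists(st.floats(0, 50), min_size=1, max_size=60))
    def test_burden_nonnegative_and_bounded_under_bounded_forcing(self, series):
        phi = 0.0
        bound = max(series) * P.mu_benthic / (1 - np.exp(-P.rho)) + 1e-9
        for o in series:
            phi = sw.update_body_burden(phi, o, mu=P.mu_benthic, rho=P.rho)
            assert 0.0 <= phi <= bound


class TestHockeyStick:
    def test_zero_below_and_at_mortality_threshold(self):
        assert sw.mortality_effect(P.beta / (2 * P.K), P) == 0.0
        assert sw.mortality_effect(P.beta / P.K, P) == 0.0

    def test_mortality_slope_one_efold_above_threshold(self):
        # K phi = beta e  =>  alpha * ln(e) / omega = 0.2885 / 15
        phi = P.beta * np.e / P.K
        assert sw.mortality_effect(phi, P) == pytest.approx(0.2885 / 15.0,
                                                            rel=1e-12)

    def test_growth_effect_values_and_clamps(self):
        g, mult = sw.growth_effect(0.0, P)
        assert g == 0.0 and mult == 1.0
        g, _ = sw.growth_effect(P.delta * np.e / P.K, P)
        assert g == pytest.approx(0.0531 / 15.0, rel=1e-12)
        # the log-slope is shallow: g_t reaches 1 only at K phi / delta
        # ~ e^(omega/gamma) ~ e^282; past that the multiplier clamps at 0
        _, mult = sw.growth_effect(1e130, P)
        assert mult == 0.0
        _, mult = sw.growth_effect(1e12, P)
        assert 0.0 <= mult < 1.0

    @HSET
    @given(st.floats(1e-6, 1e7))
    def test_effect_continuous_nonnegative_and_increasing(self, phi):
        eps = phi * 1e-6
        lo = sw.mortality_effect(phi, P)
        hi = sw.mortality_effect(phi + eps, P)
        assert 0.0 <= lo <= hi
        # continuity at the knot: effect vanishes as K phi -> beta+
        knot = sw.mortality_effect(P.beta / P.K * (1 + 1e-12), P)
        assert knot < 1e-10

    def test_concave_above_threshold(self):
        phi = np.geomspace(P.beta / P.K * 1.01, P.beta / P.K * 100, 200)
        eff = sw.mortality_effect(phi, P)
        d2 = np.diff(np.diff(eff))
        assert np.all(d2 <= 1e-12)

    @HSET
    @given(st.floats(1e-3, 1e5), st.floats(400, 1000), st.floats(500, 1500))
    def test_monotone_in_K_and_antitone_in_beta(self, phi, K_lo, beta):
        K_hi = K_lo * 1.5
        p_lo = DoseResponseParams(K=K_lo, beta=beta)
        p_hi = DoseResponseParams(K=K_hi, beta=beta)
        assert sw.mortality_effect(phi, p_lo) <= sw.mortality_effect(phi, p_hi)
        p_b_lo = DoseResponseParams(K=K_lo, beta=beta * 0.6)
        assert sw.mortality_effect(phi, p_lo) <= sw.mortality_effect(phi, p_b_lo)


class TestCombination:
    def test_endpoint_and_midpoint_weights(self):
        assert sw.combine_modifiers(0.02, 0.04, 0.0) == pytest.approx(0.02)
        assert sw.combine_modifiers(0.02, 0.04, 1.0) == pytest.approx(0.04)
        assert sw.combine_modifiers(0.02, 0.04, 0.5) == pytest.approx(0.03)

    @HSET
    @given(st.floats(0, 1), st.floats(0, 0.5), st.floats(0, 0.5))
    def test_output_lies_between_inputs(self, b, pel, ben):
        out = sw.combine_modifiers(pel, ben, b)
        assert min(pel, ben) - 1e-15 <= out <= max(pel, ben) + 1e-15

    def test_all_zero_diet_row_gives_zero_fraction(self):
        assert sw.benthic_diet_fraction({}, {}) == 0.0
        assert sw.benthic_diet_fraction({"a": 0.3}, {"a": False}) == 0.0
        assert sw.benthic_diet_fraction(
            {"a": 0.21, "b": 0.49}, {"a": True, "b": False}
        ) == pytest.approx(0.3)


class TestAggregation:
    def test_uniform_field_aggregates_to_itself(self, small_geometry):
        geom = small_geometry
        field = sw.gen_oil_field(geom, release_days=1, track_days=2, seed=0)
        field.conc[:] = 3.5
        series = sw.aggregate_to_polygons(field, geom)
        assert np.allclose(series.water_conc, 3.5)
        assert np.allclose(series.oiled_cell_fraction, 1.0)

    def test_half_oiled_polygon_means_and_fraction(self):
        geom = sw.gen_geometry(n_polygons=1, grid_resolution=0.5, seed=0)
        field = sw.gen_oil_field(geom, release_days=1, track_days=1, seed=0)
        field.conc[:] = 0.0
        ny = geom.lat.size
        half = (ny // 2) * geom.lon.size
        flat = field.conc[0, 0].ravel()
        flat[:2 * (half // 2)][::2] = 0.0  # no-op, keep structure obvious
        field.conc[0, 0, :ny // 2, :] = 2.0
        series = sw.aggregate_to_polygons(field, geom)
        frac = series.oiled_cell_fraction[0, 0]
        # area weighting: the oiled half is the southern half (larger cells)
        assert 0.4 < frac < 0.6
        assert series.water_conc[0, 0, 0] == pytest.approx(2.0 * frac)

    def test_matches_brute_force_cell_average(self, small_geometry):
        geom = small_geometry
        rng = np.random.default_rng(7)
        field = sw.gen_oil_field(geom, release_days=1, track_days=3, seed=0)
        field.conc = rng.uniform(0, 5, field.conc.shape)
        field.conc[field.conc < 2.0] = 0.0
        series = sw.aggregate_to_polygons(field, geom)
        for p in range(geom.n_polygons):
            m = geom.cell_polygon == p
            w = geom.cell_area[m] / geom.cell_area[m].sum()
            for t in (0, 2):
                for l in range(geom.n_water_layers):
                    expected = float(field.conc[t, l][m] @ w)
                    assert series.water_conc[t, p, l] == pytest.approx(expected)
                oiled = (field.conc[t].max(axis=0) > 0)[m] @ w
                assert series.oiled_cell_fraction[t, p] == pytest.approx(
                    min(oiled, 1.0))

    def test_mismatched_grids_rejected(self, small_geometry):
        other = sw.gen_geometry(n_polygons=4, grid_resolution=0.25, seed=0)
        field = sw.gen_oil_field(other, release_days=1, track_days=2, seed=0)
        with pytest.raises(ValueError):
            sw.aggregate_to_polygons(field, small_geometry)


class TestModifierSeries:
    def test_zero_oil_means_zero_effects(self, small_geometry, demo_groups):
        geom = small_geometry
        field = sw.gen_oil_field(geom, release_days=1, track_days=5, seed=0)
        field.conc[:] = 0.0
        series = sw.aggregate_to_polygons(field, geom)
        mods = polygon_modifier_series(series, geom, demo_groups, P)
        assert np.all(mods.m_oil == 0)
        assert np.all(mods.g_mult == 1)

    def test_unoiled_cell_fraction_halves_the_effect(self, demo_groups):
        geom = sw.gen_geometry(n_polygons=1, grid_resolution=0.5, seed=0)
        conc = 5.0
        for frac_rows in (None,):
            field = sw.gen_oil_field(geom, release_days=1, track_days=1, seed=0)
            field.conc[:] = 0.0
            ny = geom.lat.size
            field.conc[0, :, :ny // 2, :] = conc  # uniform dose, half the cells
            series = sw.aggregate_to_polygons(field, geom)
            half = polygon_modifier_series(series, geom, demo_groups, P)
            field.conc[0, :, :, :] = conc  # same dose everywhere
            series_full = sw.aggregate_to_polygons(field, geom)
            full = polygon_modifier_series(series_full, geom, demo_groups, P)
        frac = series.oiled_cell_fraction[0, 0]
        assert half.m_benthic[0, 0] == pytest.approx(
            frac * full.m_benthic[0, 0], rel=1e-9)

    def test_effects_decay_to_zero_after_forcing_ends(self, small_geometry,
                                                      demo_groups):
        geom = small_geometry
        field = sw.gen_oil_field(geom, release_days=10, track_days=15, seed=0,
                                 source_strength=100.0)
        series = sw.aggregate_to_polygons(field, geom)
        mods = polygon_modifier_series(series, geom, demo_groups, P,
                                       n_days=120)
        peak = mods.m_oil.max(axis=(1, 2))
        tail = peak[15:]
        assert np.all(np.diff(tail) <= 1e-15)  # monotone decay
        assert tail[-1] == 0.0
        # burden envelope follows exp(-rho t) once forcing is over
        phi = mods.phi_benthic.max(axis=1)
        ratio = phi[20:40] / phi[19:39]
        assert np.allclose(ratio, np.exp(-P.rho), rtol=1e-9)

    def test_nonfish_groups_never_receive_effects(self, small_geometry,
                                                  demo_groups):
        geom = small_geometry
        field = sw.gen_oil_field(geom, release_days=5, track_days=8, seed=0,
                                 source_strength=500.0)
        series = sw.aggregate_to_polygons(field, geom)
        mods = polygon_modifier_series(series, geom, demo_groups, P)
        nonfish = [i for i, g in enumerate(demo_groups) if not g.is_fish]
        assert np.all(mods.m_oil[:, :, nonfish] == 0)
        assert np.all(mods.g_mult[:, :, nonfish] == 1)
        assert mods.m_oil.max() > 0  # the forcing itself is live
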