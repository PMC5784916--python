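"""Shared fixtures: small geometries for unit tests, and one session-scoped
sensitivity grid that the acceptance tests share (the worst-case member of
the grid doubles as the demo impacted run)."""

from __future__ import annotations

import numpy as np
import pytest

import spillweb as sw
from spillweb.ecosystem import EcoConfig, Ecosystem
from spillweb.foodweb import FunctionalGroup


@pytest.fixture(scope="session")
def small_geometry():
    return sw.gen_geometry(n_polygons=4, depth_cuts=(10.0, 50.0, 200.0),
                           grid_resolution=0.5, seed=0)


@pytest.fixture(scope="session")
def demo_groups():
    return sw.gen_food_web(seed=0)


@pytest.fixture(scope="session")
def demo_config():
    return sw.ScenarioConfig(horizon_years=10, seed=1)


@pytest.fixture(scope="session")
def demo_inputs(demo_config):
    return sw.generate_inputs(demo_config)


@pytest.fixture(scope="session")
def demo_grid(demo_config, demo_inputs):
    """Baseline + 16 K x beta runs at demo scale (the heavyweight fixture)."""
    return sw.run_sensitivity_grid(demo_config, demo_inputs)


@pytest.fixture(scope="session")
def demo_pair(demo_grid):
    """(worst-case impacted, baseline) pair from the shared grid."""
    worst = [k for k in demo_grid if "363" in k and "K1000" in k]
    return demo_grid[worst[0]], demo_grid["baseline"]


def make_solo_groups(turnover=0.4, n_ages=3, fishing=0.0):
    """One diet-less fish group plus detritus: isolates mortality terms."""
    fish = FunctionalGroup(
        name="solo", guild="snappers", habitat="pelagic", n_age_classes=n_ages,
        maturity_age=max(1, n_ages - 1), turnover=turnover, growth_k=0.3,
        sN_inf=1000.0, diet_row={}, fleet="demersal" if fishing else None,
        fishing_mortality=fishing, density=1e6, diffusion=0.0,
        trophic_level=3.0, benthic_frac=0.0)
    det = FunctionalGroup(name="detritus", guild="detritus", habitat="benthic",
                          is_fish=False, is_detritus=True, benthic_prey=True,
                          density=1e8, trophic_level=1.0, benthic_frac=0.0)
    return [fish, det]


def make_predprey_groups():
    """Predator fish + forage pool + detritus: a two-species subsystem."""
    pred = FunctionalGroup(
        name="pred", guild="groupers", habitat="demersal", n_age_classes=3,
        maturity_age=2, turnover=0.4, growth_k=0.3, sN_inf=10_000.0,
        diet_row={"forage": 0.6}, density=5e6, diffusion=0.0,
        trophic_level=3.0, benthic_frac=0.0)
    prey = FunctionalGroup(
        name="forage", guild="benthos", habitat="benthic", is_fish=False,
        benthic_prey=True, diet_row={"detritus": 0.6}, density=2e8,
        pool_mortality=0.002, trophic_level=2.0, benthic_frac=1.0)
    det = FunctionalGroup(name="detritus", guild="detritus", habitat="benthic",
                          is_fish=False, is_detritus=True, benthic_prey=True,
                          density=1e9, trophic_level=1.0, benthic_frac=0.0)
    return [pred, prey, det]


def make_eco(groups, geometry, **cfg_kwargs):
    defaults = dict(burn_in_years=0)
    defaults.update(cfg_kwargs)
    return Ecosystem(groups, geometry, config=EcoConfig(**defaults))


@pytest.fixture()
def solo_eco(small_geometry):
    eco = make_eco(make_solo_groups(), small_geometry,
                   k_maint=0.0, spawn_fraction=0.0, mq_share=0.0)
    state = eco.init_state(seed=0, density_jitter=0.0)
    return eco, state
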