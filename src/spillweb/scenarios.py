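"""Scenario composition and execution.

A scenario toggles four forcings on a shared baseline — oil mortality, oil
growth impairment, fishery closures, spill-year larval losses — and scales
the sensitivity dials K (sediment:water concentration factor) and beta
(mortality threshold) by reductions from {0, 20, 40, 60}%.  Simulations
run a spin-up with no forcings, the oil-forcing window, and a multi-year
projection during which body burdens depurate.  The 4 x 4 K-beta grid and
the single-factor (closures-only, recruitment-only) runs reproduce the
study design at a reduced scale.

Calendar: day 0 is 1 January of the spill year; the spill opens on day 110
(20 April) after a 100-day spin-up.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .ecosystem import DAYS_PER_YEAR, EcoConfig, Ecosystem, ModelState
from .foodweb import FLEETS, FunctionalGroup, gen_food_web
from .forcings import ClosureSchedule, LarvalLossTable, gen_closures, gen_larval_loss
from .geometry import PolygonGeometry, gen_geometry
from .oilfield import DEFAULT_RELEASE_SITE, OilFieldGrid, gen_oil_field
from .toxicology import (DoseResponseParams, PolygonOilSeries, ToxModifiers,
                         aggregate_to_polygons, polygon_modifier_series)

VALID_REDUCTIONS = (0, 20, 40, 60)

#: Demo-scale depth cuts: 4 water layers + sediment.
DEMO_DEPTH_CUTS = (10.0, 50.0, 200.0)


@dataclass
class ScenarioConfig:
    """Switches and dials for one simulation.

    ``K_reduction`` and ``beta_reduction`` are percent reductions from the
    baseline K and beta and must come from {0, 20, 40, 60}.
    """

    oil_mortality: bool = True
    oil_growth: bool = True
    closures: bool = False
    recruitment: bool = False
    K_reduction: int = 0
    beta_reduction: int = 0
    spin_up_days: int = 100
    spill_day: int = 110
    forcing_days: int = 167
    horizon_years: int = 10
    seed: int = 0
    n_polygons: int = 16
    depth_cuts: tuple = DEMO_DEPTH_CUTS
    grid_resolution: float = 0.25
    dt: float = 0.5

    def __post_init__(self):
        if self.K_reduction not in VALID_REDUCTIONS or \
                self.beta_reduction not in VALID_REDUCTIONS:
            raise ValueError(f"reductions must be one of {VALID_REDUCTIONS}")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")

    @property
    def total_days(self) -> int:
        return int(self.horizon_years * DAYS_PER_YEAR)

    @property
    def spill_year(self) -> int:
        return int(self.spill_day // DAYS_PER_YEAR)


@dataclass
class ScenarioInputs:
    """Shared synthetic inputs for a family of scenarios."""

    geometry: PolygonGeometry
    groups: list
    oil_field: OilFieldGrid
    oil_series: PolygonOilSeries
    closures: ClosureSchedule
    larval_loss: LarvalLossTable
    params: DoseResponseParams
    settled_cache: dict = field(default_factory=dict)


def generate_inputs(config: ScenarioConfig,
                    params: DoseResponseParams | None = None) -> ScenarioInputs:
    """Generate every synthetic input a scenario family needs, seeded."""
    seed = config.seed
    geometry = gen_geometry(n_polygons=config.n_polygons,
                            depth_cuts=config.depth_cuts,
                            grid_resolution=config.grid_resolution,
                            seed=seed)
    groups = gen_food_web(seed=seed + 1)
    oil_field = gen_oil_field(geometry, release_days=87,
                              track_days=config.forcing_days, seed=seed + 2)
    oil_series = aggregate_to_polygons(oil_field, geometry)
    closures = gen_closures(geometry, start_day=config.spill_day,
                            duration_days=365, seed=seed + 3)
    larval = gen_larval_loss(groups, seed=seed + 4)
    return ScenarioInputs(geometry=geometry, groups=groups,
                          oil_field=oil_field, oil_series=oil_series,
                          closures=closures, larval_loss=larval,
                          params=params or DoseResponseParams())


def group_metadata(groups: list[FunctionalGroup]) -> dict:
    """Per-group flags and traits used by the analysis layer.

    Piscivores take >= 30% of their availability row from fish prey;
    planktivores take >= 20% from plankton pools.
    """
    fish_names = {g.name for g in groups if g.is_fish}
    plankton_names = {g.name for g in groups if g.guild == "plankton"}

    def share(g, names):
        total = g.diet_sum()
        if total == 0:
            return 0.0
        return sum(v for k, v in g.diet_row.items() if k in names) / total

    return {
        "is_fish": np.array([g.is_fish for g in groups]),
        "is_detritus": np.array([g.is_detritus for g in groups]),
        "trophic_level": np.array([g.trophic_level for g in groups]),
        "habitat": [g.habitat for g in groups],
        "maturity_age": np.array([g.maturity_age for g in groups]),
        "benthic_frac": np.array([0.0 if np.isnan(g.benthic_frac)
                                  else g.benthic_frac for g in groups]),
        "turnover": np.array([g.turnover for g in groups]),
        "piscivore": np.array([g.is_fish and share(g, fish_names) >= 0.3
                               for g in groups]),
        "planktivore": np.array([g.is_fish and share(g, plankton_names) >= 0.2
                                 for g in groups]),
    }


@dataclass
class Scenario:
    """A fully resolved scenario: forcings + simulator, ready to run."""

    label: str
    config: ScenarioConfig
    inputs: ScenarioInputs
    ecosystem: Ecosystem
    params: DoseResponseParams
    modifiers: ToxModifiers | None  # daily, indexed from spill_day
    closures: ClosureSchedule | None
    larval_loss: LarvalLossTable | None


@dataclass
class RunOutput:
    """Recorded output of one simulation run.

    Monthly snapshots (month = 365/12 days): numbers per (month, group,
    age, polygon), reserve/structural weights per (month, group, age), and
    consumption per (month, predator, prey, polygon).  Catch and recruits
    are annual.
    """

    label: str
    config: ScenarioConfig
    group_names: list
    guilds: list
    spill_day: int
    snapshot_days: np.ndarray
    numbers: np.ndarray  # (M, G, A, P)
    rN: np.ndarray  # (M, G, A)
    sN: np.ndarray  # (M, G, A)
    consumption: np.ndarray  # (M, G, G, P) biomass eaten in the month
    catch_annual: np.ndarray  # (Y, n_fleets, G)
    recruits_annual: np.ndarray  # (Y, G)
    modifiers: ToxModifiers | None = None
    flux_monthly: dict = field(default_factory=dict)  # name -> (M, G)
    group_meta: dict = field(default_factory=dict)

    @property
    def n_months(self) -> int:
        return self.snapshot_days.size

    def weight(self) -> np.ndarray:
        """(M, G, A) individual weight."""
        return self.rN + self.sN

    def biomass(self) -> np.ndarray:
        """(M, G, P) biomass."""
        return (self.numbers * self.weight()[:, :, :, None]).sum(axis=2)

    def guild_biomass(self, polygons=None) -> dict:
        """Guild name -> (M,) biomass series, optionally over a subset."""
        b = self.biomass()
        if polygons is not None:
            b = b[:, :, polygons]
        tot = b.sum(axis=2)
        out: dict = {}
        for i, g in enumerate(self.guilds):
            out.setdefault(g, np.zeros(self.n_months))
            out[g] = out[g] + tot[:, i]
        return out

    def month_of_day(self, day: float) -> int:
        return int(np.searchsorted(self.snapshot_days, day, side="right") - 1)


def scenario_label(params: DoseResponseParams, config: ScenarioConfig) -> str:
    K = params.K * (1 - config.K_reduction / 100)
    beta = params.beta * (1 - config.beta_reduction / 100)
    return f"[K{K:g} β{beta:.0f}]"


def build_scenario(config: ScenarioConfig,
                   inputs: ScenarioInputs | None = None,
                   eco_config: EcoConfig | None = None) -> Scenario:
    """Resolve a config into a runnable scenario.

    K and beta are scaled by their percent reductions; the toxicological
    modifier series is precomputed for the forcing window plus a
    depuration tail (effects vanish within weeks of the last oiled day).
    """
    if inputs is None:
        inputs = generate_inputs(config)
    params = dataclasses.replace(
        inputs.params,
        K=inputs.params.K * (1 - config.K_reduction / 100),
        beta=inputs.params.beta * (1 - config.beta_reduction / 100),
    )
    label = scenario_label(inputs.params, config)
    if not (config.oil_mortality or config.oil_growth or config.closures
            or config.recruitment):
        label = "baseline"
    eco = Ecosystem(inputs.groups, inputs.geometry, config=eco_config)

    modifiers = None
    if config.oil_mortality or config.oil_growth:
        tail = int(min(config.total_days - config.spill_day,
                       config.forcing_days + 120))
        modifiers = polygon_modifier_series(
            inputs.oil_series, inputs.geometry, inputs.groups, params,
            n_days=tail)
        if not config.oil_mortality:
            modifiers.m_oil[:] = 0.0
        if not config.oil_growth:
            modifiers.g_mult[:] = 1.0
    return Scenario(
        label=label, config=config, inputs=inputs, ecosystem=eco,
        params=params, modifiers=modifiers,
        closures=inputs.closures if config.closures else None,
        larval_loss=inputs.larval_loss if config.recruitment else None,
    )


def run(scenario: Scenario, record_modifiers: bool = True) -> RunOutput:
    """Run a scenario from a seeded initial state to its horizon.

    Deterministic given the scenario seed: the only randomness is in the
    generated inputs and the seeded initial state.
    """
    cfg = scenario.config
    eco = scenario.ecosystem
    geom = scenario.inputs.geometry
    G, A, P = eco.G, eco.A, eco.P
    state = eco.init_state(seed=cfg.seed,
                           cache=scenario.inputs.settled_cache)

    n_days = cfg.total_days
    month_len = DAYS_PER_YEAR / 12.0
    n_months = int(np.ceil(n_days / month_len))
    n_years = cfg.horizon_years
    nF = len(FLEETS)

    snap_days = np.full(n_months, np.nan)
    numbers = np.zeros((n_months, G, A, P))
    rN = np.zeros((n_months, G, A))
    sN = np.zeros((n_months, G, A))
    cons = np.zeros((n_months, G, G, P))
    catch_annual = np.zeros((n_years, nF, G))
    recruits_annual = np.zeros((n_years, G))
    flux_monthly: dict = {}

    zeros_m = np.zeros((P, G))
    ones_g = np.ones((P, G))
    mods = scenario.modifiers
    n_steps = int(round(n_days / cfg.dt))
    last_month = -1
    for k in range(n_steps):
        day = state.day
        month = min(int(day / month_len), n_months - 1)
        if month != last_month:
            snap_days[month] = day
            numbers[month] = state.numbers
            rN[month] = state.rN
            sN[month] = state.sN
            last_month = month
        di = int(day) - cfg.spill_day
        if mods is not None and 0 <= di < mods.m_oil.shape[0]:
            step_mods = (mods.m_oil[di], mods.g_mult[di])
        else:
            step_mods = (zeros_m, ones_g)
        rec = eco.step(state, dt=cfg.dt, modifiers=step_mods,
                       closures=scenario.closures,
                       larval_loss=scenario.larval_loss,
                       spill_year=cfg.spill_year)
        cons[month] += rec.consumption
        year = min(int(day / DAYS_PER_YEAR), n_years - 1)
        if rec.catch is not None:
            catch_annual[year] += rec.catch.sum(axis=2)
        if rec.recruits is not None:
            recruits_annual[year] += rec.recruits
        for name, val in rec.fluxes.items():
            if name not in flux_monthly:
                flux_monthly[name] = np.zeros((n_months, G))
            flux_monthly[name][month] += val.sum(axis=1)

    return RunOutput(
        label=scenario.label, config=cfg,
        group_names=list(eco.names),
        guilds=[g.guild for g in scenario.inputs.groups],
        spill_day=cfg.spill_day, snapshot_days=snap_days,
        numbers=numbers, rN=rN, sN=sN, consumption=cons,
        catch_annual=catch_annual, recruits_annual=recruits_annual,
        modifiers=mods if record_modifiers else None,
        flux_monthly=flux_monthly,
        group_meta=group_metadata(scenario.inputs.groups),
    )


def baseline_config(config: ScenarioConfig) -> ScenarioConfig:
    """The matching no-forcing baseline of a scenario config."""
    return dataclasses.replace(config, oil_mortality=False, oil_growth=False,
                               closures=False, recruitment=False,
                               K_reduction=0, beta_reduction=0)


def run_sensitivity_grid(base_config: ScenarioConfig,
                         inputs: ScenarioInputs | None = None,
                         K_reductions=VALID_REDUCTIONS,
                         beta_reductions=VALID_REDUCTIONS) -> dict:
    """Run the K x beta factorial plus one shared baseline.

    Inputs (geometry, oil fields, food web) are generated once and shared,
    so the grid varies only K and beta.  Returns a dict mapping scenario
    labels to RunOutput, with the no-oil run under 'baseline'.
    """
    if inputs is None:
        inputs = generate_inputs(base_config)
    out: dict = {}
    base = baseline_config(base_config)
    out["baseline"] = run(build_scenario(base, inputs), record_modifiers=False)
    for rk in K_reductions:
        for rb in beta_reductions:
            cfg = dataclasses.replace(base_config, oil_mortality=True,
                                      oil_growth=True, closures=False,
                                      recruitment=False, K_reduction=rk,
                                      beta_reduction=rb)
            sc = build_scenario(cfg, inputs)
            out[sc.label] = run(sc, record_modifiers=False)
    return out


def single_factor_runs(base_config: ScenarioConfig,
                       inputs: ScenarioInputs | None = None) -> dict:
    """Closures-only and recruitment-only runs, paired with a baseline."""
    if inputs is None:
        inputs = generate_inputs(base_config)
    base = baseline_config(base_config)
    out = {"baseline": run(build_scenario(base, inputs))}
    clo = dataclasses.replace(base, closures=True)
    sc = build_scenario(clo, inputs)
    sc_label = "closures-only"
    sc = dataclasses.replace(sc, label=sc_label)
    out[sc_label] = run(sc)
    recr = dataclasses.replace(base, recruitment=True)
    sc = dataclasses.replace(build_scenario(recr, inputs),
                             label="recruitment-only")
    out["recruitment-only"] = run(sc)
    return out
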