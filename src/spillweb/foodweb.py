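"""Functional-group parameter tables and the synthetic food-web generator.

The demo web holds the eight exploited-fish guilds reported in Gulf of
Mexico ecosystem analyses (snappers, groupers, sciaenids, elasmobranchs,
large pelagic, small pelagic, small demersal & reef forage, large demersal)
plus two plankton pools, a benthic-invertebrate forage pool, and detritus.
Fish are age-structured; pools are single biomass compartments.

All nitrogen masses are in mg N; rates are per day unless noted.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

FISH_GUILDS = (
    "snappers",
    "groupers",
    "sciaenids",
    "elasmobranchs",
    "large pelagic fish",
    "small pelagic fish",
    "small demersal and reef fish",
    "large demersal fish",
)

#: Fleet indices.
FLEETS = ("demersal", "pelagic")


@dataclass
class FunctionalGroup:
    """Life-history and interaction parameters for one model group.

    ``diet_row`` holds availability fractions over prey (by group name);
    the row sum must be <= 1 (a substochastic availability vector, not the
    realised diet, which also depends on prey biomass and co-occurrence).
    ``turnover`` is the design total mortality Z (1/yr) used to build a
    stationary age structure; the linear mortality coefficient is calibrated
    at initialisation as the residual of Z after predation and fishing.
    """

    name: str
    guild: str
    habitat: str  # 'pelagic' | 'demersal' | 'benthic'
    is_fish: bool = True
    is_producer: bool = False
    is_detritus: bool = False
    benthic_prey: bool = False  # counts as benthic prey in diet weighting
    n_age_classes: int = 1
    maturity_age: int = 1
    turnover: float = 0.5  # design total mortality Z, 1/yr
    growth_k: float = 0.3  # von Bertalanffy-like growth coefficient, 1/yr
    sN_inf: float = 1.0  # asymptotic structural weight, mg N
    assimilation_efficiency: float = 0.5
    diet_row: dict = field(default_factory=dict)
    gape: tuple = (5.0, 1.0e5)  # predator:prey individual weight ratio window
    fleet: str | None = None
    fishing_mortality: float = 0.0  # base F, 1/yr
    density: float = 1.0  # initial biomass density, mg N / km^2
    diffusion: float = 0.0  # density-dependent exchange rate, 1/day
    migration_schedule: dict | None = None
    pool_mortality: float = 0.0  # linear loss for pools, 1/day
    trophic_level: float = np.nan  # filled by gen_food_web
    benthic_frac: float = np.nan  # filled by gen_food_web

    def diet_sum(self) -> float:
        return float(sum(self.diet_row.values()))


def _template() -> list[FunctionalGroup]:
    g = FunctionalGroup
    return [
        g("phytoplankton", "plankton", "pelagic", is_fish=False, is_producer=True,
          density=5.0e7, pool_mortality=0.001),
        g("zooplankton", "plankton", "pelagic", is_fish=False,
          diet_row={"phytoplankton": 0.8}, density=2.0e8, pool_mortality=0.005),
        g("benthic_invertebrates", "benthos", "benthic", is_fish=False,
          benthic_prey=True,
          diet_row={"detritus": 0.6, "phytoplankton": 0.2},
          density=2.5e8, pool_mortality=0.002),
        g("detritus", "detritus", "benthic", is_fish=False, is_detritus=True,
          benthic_prey=True, density=1.2e10),
        g("snappers", "snappers", "demersal", n_age_classes=10, maturity_age=3,
          turnover=0.45, growth_k=0.25, sN_inf=15_000.0,
          diet_row={"small demersal and reef fish": 0.30,
                    "benthic_invertebrates": 0.15,
                    "small pelagic fish": 0.25, "zooplankton": 0.05},
          fleet="demersal", fishing_mortality=0.20, density=1.0e7,
          diffusion=0.02),
        g("groupers", "groupers", "demersal", n_age_classes=10, maturity_age=5,
          turnover=0.30, growth_k=0.15, sN_inf=70_000.0,
          diet_row={"small demersal and reef fish": 0.28,
                    "benthic_invertebrates": 0.14,
                    "small pelagic fish": 0.23, "sciaenids": 0.05,
                    "snappers": 0.05},
          fleet="demersal", fishing_mortality=0.12, density=8.0e6,
          diffusion=0.01),
        g("sciaenids", "sciaenids", "demersal", n_age_classes=8, maturity_age=2,
          turnover=0.60, growth_k=0.35, sN_inf=7_000.0,
          diet_row={"benthic_invertebrates": 0.30,
                    "small demersal and reef fish": 0.15,
                    "zooplankton": 0.10, "small pelagic fish": 0.20},
          fleet="demersal", fishing_mortality=0.25, density=1.5e7,
          diffusion=0.02),
        g("elasmobranchs", "elasmobranchs", "demersal", n_age_classes=10,
          maturity_age=6, turnover=0.20, growth_k=0.12, sN_inf=2.0e5,
          diet_row={"small demersal and reef fish": 0.20,
                    "benthic_invertebrates": 0.15,
                    "small pelagic fish": 0.20, "sciaenids": 0.10,
                    "snappers": 0.05, "large demersal fish": 0.05},
          fleet="demersal", fishing_mortality=0.05, density=5.0e6,
          diffusion=0.03),
        g("large pelagic fish", "large pelagic fish", "pelagic",
          n_age_classes=10, maturity_age=4, turnover=0.35, growth_k=0.20,
          sN_inf=3.5e5,
          diet_row={"small pelagic fish": 0.50, "zooplankton": 0.10,
                    "small demersal and reef fish": 0.10},
          fleet="pelagic", fishing_mortality=0.18, density=1.0e7,
          diffusion=0.05,
          migration_schedule={"out_start": 330, "out_end": 360,
                              "out_fraction": 0.10, "in_start": 60,
                              "in_end": 90}),
        g("small pelagic fish", "small pelagic fish", "pelagic",
          n_age_classes=5, maturity_age=1, turnover=1.20, growth_k=0.60,
          sN_inf=220.0,
          diet_row={"zooplankton": 0.70, "phytoplankton": 0.10},
          fleet="pelagic", fishing_mortality=0.40, density=5.0e7,
          diffusion=0.05),
        g("small demersal and reef fish", "small demersal and reef fish",
          "demersal", benthic_prey=True, n_age_classes=5, maturity_age=1,
          turnover=1.10, growth_k=0.60, sN_inf=150.0,
          diet_row={"benthic_invertebrates": 0.47, "detritus": 0.20,
                    "zooplankton": 0.18},
          fleet="demersal", fishing_mortality=0.05, density=8.0e7,
          diffusion=0.02),
        g("large demersal fish", "large demersal fish", "demersal",
          n_age_classes=10, maturity_age=4, turnover=0.35, growth_k=0.20,
          sN_inf=35_000.0,
          diet_row={"benthic_invertebrates": 0.25,
                    "small demersal and reef fish": 0.20,
                    "small pelagic fish": 0.20, "sciaenids": 0.05,
                    "zooplankton": 0.05},
          fleet="demersal", fishing_mortality=0.15, density=1.0e7,
          diffusion=0.02),
    ]


def default_template() -> list[FunctionalGroup]:
    """A fresh copy of the packaged 12-group demo template."""
    return copy.deepcopy(_template())


def compute_trophic_levels(groups: list[FunctionalGroup]) -> np.ndarray:
    """Solve TL_i = 1 + sum_j d_ij TL_j with row-normalised diets.

    Producers and detritus are fixed at TL = 1.  Consumer rows are
    normalised to sum to 1 before taking the prey-TL average, so a pure
    herbivore lands exactly at TL 2.
    """
    names = [g.name for g in groups]
    idx = {n: i for i, n in enumerate(names)}
    n = len(groups)
    D = np.zeros((n, n))
    basal = np.zeros(n, dtype=bool)
    for i, g in enumerate(groups):
        if g.is_producer or g.is_detritus or not g.diet_row:
            basal[i] = True
            continue
        s = g.diet_sum()
        for prey, frac in g.diet_row.items():
            D[i, idx[prey]] = frac / s
    A = np.eye(n) - D
    for i in np.nonzero(basal)[0]:
        A[i] = 0.0
        A[i, i] = 1.0
    tl = np.linalg.solve(A, np.ones(n))
    return tl


def benthic_diet_fraction_of(group: FunctionalGroup,
                             groups: list[FunctionalGroup]) -> float:
    """Share of the availability row falling on benthic-flagged prey."""
    flags = {g.name: g.benthic_prey for g in groups}
    total = group.diet_sum()
    if total == 0:
        return 0.0
    benthic = sum(v for k, v in group.diet_row.items() if flags.get(k, False))
    return benthic / total


def gen_food_web(
    template: list[FunctionalGroup] | None = None,
    n_age_classes: int | None = None,
    jitter: float = 0.03,
    seed: int = 0,
) -> list[FunctionalGroup]:
    """Generate a seeded functional-group set from a guild template.

    The template must contain the eight fish guilds plus at least two
    plankton/forage pools and a detritus group.  Life-history rates and
    diet availabilities receive a small multiplicative lognormal jitter
    (diet row sums are preserved), then trophic levels and benthic diet
    fractions are computed.

    Raises ``ValueError`` if any diet row sums above 1.
    """
    groups = copy.deepcopy(template) if template is not None else _template()
    rng = np.random.default_rng(seed)

    guilds = {g.guild for g in groups}
    missing = set(FISH_GUILDS) - guilds
    if missing:
        raise ValueError(f"template is missing fish guilds: {sorted(missing)}")
    n_pools = sum(1 for g in groups if not g.is_fish and not g.is_detritus)
    if n_pools < 2 or not any(g.is_detritus for g in groups):
        raise ValueError("template needs >= 2 plankton/forage pools and detritus")

    for g in groups:
        if g.diet_sum() > 1 + 1e-9:
            raise ValueError(f"diet row of {g.name!r} sums above 1")
        if n_age_classes is not None and g.is_fish:
            g.n_age_classes = n_age_classes
            g.maturity_age = min(g.maturity_age, max(1, n_age_classes - 1))
        if jitter > 0:
            j = lambda: float(np.exp(rng.normal(0.0, jitter)))
            g.turnover *= j()
            g.growth_k *= j()
            g.sN_inf *= j()
            g.density *= j()
            if g.diet_row:
                keys = list(g.diet_row)
                vals = np.array([g.diet_row[k] for k in keys])
                total = vals.sum()
                vals = vals * np.exp(rng.normal(0.0, jitter, vals.size))
                vals *= total / vals.sum()  # preserve the row sum
                g.diet_row = dict(zip(keys, vals.tolist()))

    tl = compute_trophic_levels(groups)
    for g, t in zip(groups, tl):
        g.trophic_level = float(t)
        g.benthic_frac = benthic_diet_fraction_of(g, groups)
    return groups


def structural_weight_at_age(group: FunctionalGroup) -> np.ndarray:
    """Target structural weight (mg N) per age class, von Bertalanffy cubed."""
    a = np.arange(group.n_age_classes + 1, dtype=float)
    w = group.sN_inf * (1.0 - np.exp(-group.growth_k * (a + 0.8))) ** 3
    return w
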