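# Methods

`spillweb` couples three layers: synthetic drivers (geometry, gridded PAH
fields, a functional-group food web, fishery closures, larval losses), a
toxicology layer that turns oil concentrations into daily mortality and
growth modifiers, and a reduced spatial ecosystem simulator whose paired
(impacted, baseline) runs feed the analysis metrics.  This note records the
model equations, the defaults and why they hold their values, the numerical
choices, and what the synthetic setting can and cannot show.

## Spatial template

The domain is a rectangle (25–30.75°N, 93–84°W) of grid cells at a
configurable resolution (0.25° by default), tiled into contiguous polygons
by nearest-seed regions around seeded random points.  Water columns are cut
at fixed depths into layers (defaults 10/20/50/200/2000 m, i.e. up to six
water layers; the packaged demo uses 10/50/200 m, four layers) with one
sediment layer beneath the deepest occupied water layer.  Bottom depth
deepens from the northern shelf toward the southern basin, so shelf
polygons hold few layers and basin polygons hold all of them.  The demo
scale is 16 polygons; polygon count, cuts and resolution are configurable.

## Oil fields

The transport surrogate is deliberately simple: daily injection of a fixed
mass at the release cell, split between the surface layer (slick) and the
layer containing the release depth (deep plume), followed each day by a
Gaussian spreading kernel, a uniform per-layer drift (surface pushed NE,
plume SW, with seeded day-to-day jitter), and first-order decay.  The
release runs 87 days and the field is tracked 167 days at daily resolution.
A per-day ledger closes the mass budget (injected − decayed − transported
out = change in residual) to better than 1e-6 relative.

Defaults: decay 0.03 d⁻¹, spreading 0.12°·d⁻¹, source strength 15
ppb·cell·d⁻¹ split 35/65 surface/deep.  The source strength was fixed once
so that plume water-column PAH peaks at roughly 1–2 ppb — the order of
magnitude of transport-model water-column concentrations for a deep
blowout — which, through the sediment concentration factor, yields
worst-case guild declines in the 30–70 % band.  No droplet physics,
dissolution or evaporation fractionation is represented; only the output
contract (daily layered ppb grids) matters downstream.

## Toxicology

Body burden follows the first-order uptake–depuration recursion

φ_t = φ_{t−1}·e^(−ρ) + μ·O_t,

with depuration ρ = 0.2424 d⁻¹ (99 % clearance in 20 days) and uptake
constants μ = 1 (benthic) and μ = 0.1 (pelagic).  The printed source form
of this recursion contains undefined symbols; the implementation uses the
standard recursion above, which reproduces every stated property
(single combined uptake process, exponential clearance).

Effects are clamped log-linear ("hockey stick") responses with MLE-fitted
constants: added daily mortality m_t = α·ln(K·φ_t/β)/ω above the threshold
β and zero below it (α = 0.2885, β = 907.4306 ppb), and a growth effect
g_t = γ·ln(K·φ_t/δ)/ω (γ = 0.0531, δ = 28.422 ppb), both divided by the
mean experimental exposure time ω = 15 d.  Natural log is used; with the
clamp, the base choice is a pure rescaling of α and γ.  The growth
multiplier applied to assimilation is max(0, 1 − g_t) — the minimal map
from effect size to a multiplicative modifier.  K is the assumed
sediment:water concentration factor (default 1000, reducible by 20/40/60 %
in sensitivity runs, as is β).  As printed, K sits inside both the benthic
and the pelagic dose; a config switch (`apply_K_pelagic`) restricts it to
the benthic dose if desired.  The benthic/pelagic contrast is otherwise
carried by μ and by which concentration series drives each burden: layer
water concentrations drive the pelagic burden, the deepest occupied
layer's concentration drives the benthic burden.

Per polygon, the dose is the conditional mean over oiled member cells, and
effects are weighted by the oiled-cell fraction, so a polygon half covered
by a uniform dose receives half the effect.  Because dose–response is
computed from a persistent body burden, the exposed-population weight is a
ratchet w_t = max(oiled_frac_t, w_{t−1}·e^(−ρ)): after the last oiled day
effects decay smoothly with depuration instead of vanishing with the
field.  Each fish group's modifier is the convex combination of the
pelagic and benthic environment effects weighted by its benthic diet
fraction (the share of its availability row on benthic-flagged prey), a
proxy for sediment association.  Invertebrates, plankton and detritus
never receive oil effects.

## Ecosystem simulator

State is numbers per (group, age, polygon) with reserve (rN) and
structural (sN) nitrogen per individual tracked per (group, age)
stock-wide; biomass is numbers × (rN + sN), all in mg N.  Vertical
structure is a static habitat profile per (group, polygon, layer):
pelagic groups span the water column weighted toward the surface, demersal
groups sit in the deepest one or two water layers, benthic groups straddle
the sediment and the deepest water layer.  Tracking weights stock-wide
(with intake pooled across polygons, weighted by the local growth
multiplier) is the main reduction relative to a fully spatial
formulation; local biomass dynamics remain polygon-resolved through
numbers.

Each 12-h step applies, in order: predation → primary production → growth
→ natural + oil mortality → fishing → migration → (at year boundaries)
spawning, recruitment and aging.  The ordering is a fixed convention;
survival terms use exact exponentials so the linear-mortality limit is
exact at any step size, and a two-group predator–prey subsystem stepped at
12 h agrees with a 100× finer integration within 1 % over a year.

* **Predation** is Holling type II: per-capita intake
  C_max·E/(E + H) where E is the availability-, gape- and
  co-occurrence-weighted prey field.  Gape limits (predator:prey weight
  ratio 5–10⁵) apply between fish; plankton and benthos pools are exempt.
  A per-step cap prevents removing more than 90 % of any prey pool.
* **Growth**: assimilated intake (efficiency 0.5, scaled by the oil growth
  multiplier) pays maintenance (0.3 % of body N·d⁻¹) first, then splits
  toward structural N at the fixed target reserve:structural ratio 2.65,
  with reserve absorbing surplus and deficit first.  Structural N never
  shrinks; starvation drains reserve, and when rN falls below half its
  target an extra starvation mortality of 0.02 d⁻¹ applies.
* **Mortality**: M1 = m_l + m_q·B + m_oil (+ starvation), applied as
  exp(−M1·dt).  Dead biomass, egestion, respiration and spawning products
  all flow to detritus.
* **Fishing**: two fleets (demersal, pelagic) with logistic age
  selectivity; closures scale local F by the open fraction per
  (day, polygon, fleet) with no effort reallocation.
* **Migration**: an optional seasonal exchange with an external pool
  (large pelagics winter outside the domain) plus density-dependent
  diffusion between adjacent polygons.
* **Recruitment** is annual Beverton–Holt on mature stock biomass, scaled
  by (1 − larval loss) in the spill year only; cohorts promote one age
  class per year with a plus group merged by numbers-weighted averaging of
  individual weights.  Recruit biomass is drawn from detritus, and primary
  production is detritus-limited, closing the nitrogen budget: with
  fishing and migration off, total N is conserved to 1e-6 per simulated
  year (fishing is an explicit export).

### Self-calibration and burn-in

The demo web (8 fish guilds — snappers, groupers, sciaenids,
elasmobranchs, large and small pelagics, small demersal/reef forage, large
demersals — plus phytoplankton, zooplankton, benthic invertebrates and
detritus) is not a fitted model; it is a synthetic calibration.  At
initialisation each fish group receives a stable age structure under its
design total mortality Z (0.2 yr⁻¹ for elasmobranchs up to ~1.2 yr⁻¹ for
forage fish), and the solver then fixes: maximum consumption so realised
intake at the seeded state equals the ration (maintenance + growth +
spawning allowance); half-saturation at the seeded prey field;
residual linear mortality as Z minus realised predation, fishing and
quadratic mortality; Beverton–Holt coefficients so recruits exactly
replace deaths at the seeded spawning biomass; and primary production to
match grazing.  Stabilising feedbacks — a quadratic mortality term
carrying 15 % of Z, a recruitment asymptote 1.3× the stationary recruit
count, and quadratic density dependence on pool mortality — damp
multi-year predator–prey cycles.  Finally the web runs unforced for four
years inside `init_state` (cached per input family) so every experiment
starts on the settled annual cycle.  Under these defaults the unforced
baseline holds every fish guild within ±15 % of its initial annual-mean
biomass over 50 simulated years.

## Scenarios and analysis

Day 0 is 1 January of the spill year; after a 100-day spin-up the spill
opens on day 110 and oil forcing lasts 167 days, with depuration-only
decay afterwards.  Closures run 365 days from the spill day.  The
sensitivity design crosses K ∈ {1000, 800, 600, 400} with β ∈ {907, 726,
544, 363} — 16 oil runs against one shared baseline; closures-only and
recruitment-only runs isolate those forcings.  Runs are deterministic
given the seed.

Analysis reproduces the study's reporting: relative guild biomass over the
heavily impacted polygons (top 25 % by proportional fish-biomass change;
the fraction is configurable), biomass minima and months-after-spill
timing, recovery as the first month after the minimum from which the
ratio holds ≥ 99 % of baseline for 12 consecutive months (the sustained
window suppresses oscillation artifacts; never reaching it within the
horizon returns a did-not-recover sentinel), age composition and
mature:immature ratios, biomass-weighted condition factor (rN/sN),
per-capita consumption matrices, ecosystem indicators (biomass-weighted
mean trophic level, Shannon diversity over living-group shares,
pelagic:demersal and piscivore:planktivore fish ratios) and annual catch
ratios per fleet.  Guild biomass is depth-integrated.

## What the synthetic setting shows — and what it does not

The demo web has ~12 groups on 16 polygons; the real system this emulates
has 91 groups on 64 polygons with assimilated hydrodynamics and a
droplet-tracking oil model.  Absolute biomass trajectories, percentage
declines and recovery years at demo scale are therefore not comparable to
the full system; what is preserved — and what the acceptance suite checks —
is the structure of the results: monotone ordering of guild minima across
the K × β grid, the forage guild taking the deepest minimum, decline depth
increasing with benthic diet association, indicator directions during the
impact year (pelagic:demersal up, Shannon and mean trophic level down),
faster recovery in high-turnover groups, post-spill catch reductions, and
the weakness of closure and recruitment forcings relative to direct
toxicity.  The generators also omit hydrodynamic realism (kernel advection
only), invertebrate toxicity, oiled-marine-snow pathways, avoidance
behaviour and effort reallocation — all out of scope by design.

## Numerical conventions

Explicit stepping at dt = 0.5 d with exact-exponential survival; per-step
predation caps at 90 % of a prey pool; biomass-budget closure of every
step's flux record to 1e-8 relative (each operator records the change it
applies); ties in the biomass minimum break to the earliest month; a zero
diet row has benthic fraction 0; divisions guard with small floors rather
than exceptions wherever a zero denominator has a natural limit.  Demo
problem sizes (16 polygons, 10-year grid horizons, 4-year burn-in) are the
packaged defaults for the study-design runs; all are configurable.
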