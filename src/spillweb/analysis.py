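"""Paired impacted-vs-baseline run analysis.

Implements the reporting metrics of the study design: relative guild
biomass over heavily impacted polygons, biomass minima and their timing,
time to 99% recovery (with a did-not-recover sentinel), age-structure and
condition-factor series, per-capita consumption matrices, ecosystem
indicators (biomass-weighted mean trophic level, Shannon diversity,
pelagic:demersal and piscivore:planktivore fish biomass ratios) and annual
catch ratios per fleet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .scenarios import RunOutput

#: Sentinel for 'did not recover within the horizon'.
DNR = np.inf


def _check_paired(impacted: RunOutput, baseline: RunOutput) -> None:
    if impacted.numbers.shape != baseline.numbers.shape or \
            impacted.spill_day != baseline.spill_day:
        raise ValueError("runs are not paired (mismatched calendar/geometry)")


def heavily_impacted_polygons(impacted: RunOutput, baseline: RunOutput,
                              frac: float = 0.25) -> np.ndarray:
    """Polygons with the greatest proportional fish-biomass change.

    Ranks polygons by the largest deviation of the fish-summed biomass
    ratio from 1 after the spill and returns the top ``frac`` share
    (at least one polygon).
    """
    _check_paired(impacted, baseline)
    fish = np.asarray(impacted.group_meta["is_fish"])
    bi = impacted.biomass()[:, fish, :].sum(axis=1)  # (M, P)
    bb = baseline.biomass()[:, fish, :].sum(axis=1)
    m0 = impacted.month_of_day(impacted.spill_day)
    ratio = bi[m0:] / np.maximum(bb[m0:], 1e-300)
    impact = np.abs(1.0 - ratio).max(axis=0)  # (P,)
    k = max(1, int(round(frac * impact.size)))
    return np.sort(np.argsort(impact)[::-1][:k])


def relative_biomass(impacted: RunOutput, baseline: RunOutput,
                     polygon_subset=None, level: str = "guild",
                     top_frac: float = 0.25) -> dict:
    """Relative (impacted / baseline) biomass series.

    ``polygon_subset`` may be an explicit polygon index array, None for
    the whole domain, or the string 'auto' for the heavily-impacted rule.
    ``level`` is 'guild' (summed across member groups) or 'group'.
    """
    _check_paired(impacted, baseline)
    if isinstance(polygon_subset, str):
        if polygon_subset != "auto":
            raise ValueError("polygon_subset must be indices, None or 'auto'")
        polygon_subset = heavily_impacted_polygons(impacted, baseline,
                                                   frac=top_frac)
    bi = impacted.biomass()
    bb = baseline.biomass()
    if polygon_subset is not None:
        bi = bi[:, :, polygon_subset]
        bb = bb[:, :, polygon_subset]
    bi = bi.sum(axis=2)
    bb = bb.sum(axis=2)
    keys = impacted.guilds if level == "guild" else impacted.group_names
    out: dict = {}
    for i, key in enumerate(keys):
        out.setdefault(key, [np.zeros(bi.shape[0]), np.zeros(bi.shape[0])])
        out[key][0] = out[key][0] + bi[:, i]
        out[key][1] = out[key][1] + bb[:, i]
    return {k: num / np.maximum(den, 1e-300) for k, (num, den) in out.items()}


def biomass_minimum(series: np.ndarray, spill_month: int) -> tuple:
    """(minimum ratio, months after spill) of a relative series.

    Searches from the spill month onward; ties break to the earliest
    month.  A series that never leaves 1 returns (1.0, None).
    """
    s = np.asarray(series)[spill_month:]
    i = int(np.argmin(s))
    if s[i] >= 1.0:
        return 1.0, None
    return float(s[i]), i


def recovery_time(series: np.ndarray, spill_month: int,
                  threshold: float = 0.99, horizon_years: float = 50.0,
                  sustain_months: int = 12) -> float:
    """Years from spill to sustained recovery, or DNR (inf).

    Recovery is the first month at/after the post-spill minimum from which
    the relative series stays >= ``threshold`` for ``sustain_months``
    consecutive months (or through the end of the series if fewer months
    remain).  A series that never dips below the threshold recovers at 0.
    """
    s = np.asarray(series)[spill_month:]
    n = min(s.size, int(round(horizon_years * 12)))
    s = s[:n]
    if np.all(s >= threshold):
        return 0.0
    imin = int(np.argmin(s))
    ok = s >= threshold
    for m in range(imin, n):
        if ok[m:min(m + sustain_months, n)].all():
            return m / 12.0
    return DNR


def age_structure_metrics(run: RunOutput, polygons=None) -> dict:
    """Age composition and mature:immature numbers ratio.

    Returns ``{'proportions': (M, G, A), 'mature_immature': (M, G)}``,
    numbers-based, over the whole domain or a polygon subset.
    """
    n = run.numbers if polygons is None else run.numbers[:, :, :, polygons]
    n = n.sum(axis=3)  # (M, G, A)
    tot = np.maximum(n.sum(axis=2, keepdims=True), 1e-300)
    prop = n / tot
    mat = np.asarray(run.group_meta["maturity_age"])
    A = n.shape[2]
    mature = np.arange(A)[None, None, :] >= mat[None, :, None]
    n_mat = (n * mature).sum(axis=2)
    n_imm = (n * ~mature).sum(axis=2)
    ratio = n_mat / np.maximum(n_imm, 1e-300)
    return {"proportions": prop, "mature_immature": ratio}


def condition_factor(run: RunOutput, polygons=None) -> dict:
    """Biomass-weighted mean reserve:structural N ratio per guild (M,)."""
    cond = run.rN / np.maximum(run.sN, 1e-300)  # (M, G, A)
    b = run.numbers if polygons is None else run.numbers[:, :, :, polygons]
    b = (b * run.weight()[:, :, :, None]).sum(axis=3)  # (M, G, A)
    fish = np.asarray(run.group_meta["is_fish"])
    out: dict = {}
    for guild in dict.fromkeys(run.guilds):
        members = [i for i, g in enumerate(run.guilds)
                   if g == guild and fish[i]]
        if not members:
            continue
        bw = b[:, members, :]
        cw = cond[:, members, :]
        out[guild] = (bw * cw).sum(axis=(1, 2)) / \
            np.maximum(bw.sum(axis=(1, 2)), 1e-300)
    return out


def consumption_matrix(run: RunOutput, months, polygons=None) -> dict:
    """Per-capita consumption (mg N per predator per day) by guild pair.

    Averages the recorded monthly consumption over ``months`` (an index
    or slice), dividing by predator numbers and days.  Also returns each
    predator guild's pelagic share of fish+pool prey intake.
    """
    months = np.atleast_1d(months)
    cons = run.consumption[months]  # (m, G, G, P)
    if polygons is not None:
        cons = cons[:, :, :, polygons]
        pred_n = run.numbers[months][:, :, :, polygons].sum(axis=(2, 3))
    else:
        pred_n = run.numbers[months].sum(axis=(2, 3))
    cons = cons.sum(axis=(0, 3))  # (G, G) total over months
    days = months.size * 365.0 / 12.0
    percap = cons / np.maximum(pred_n.mean(axis=0)[:, None], 1e-300) / days

    guilds = run.guilds
    uniq = list(dict.fromkeys(guilds))
    gi = {g: k for k, g in enumerate(uniq)}
    mat = np.zeros((len(uniq), len(uniq)))
    for i, gp in enumerate(guilds):
        for j, gq in enumerate(guilds):
            mat[gi[gp], gi[gq]] += percap[i, j]
    habitat = run.group_meta["habitat"]
    pel = np.array([h == "pelagic" for h in habitat])
    pel_share = cons[:, pel].sum(axis=1) / np.maximum(cons.sum(axis=1), 1e-300)
    return {"guilds": uniq, "per_capita": mat, "pelagic_prey_share": pel_share}


@dataclass
class IndicatorSeries:
    """Ecosystem structure indicators, monthly."""

    mean_trophic_level: np.ndarray
    shannon: np.ndarray
    pelagic_demersal: np.ndarray
    piscivore_planktivore: np.ndarray


def ecosystem_indicators(run: RunOutput, polygons=None) -> IndicatorSeries:
    """Indicators over living groups (detritus excluded).

    mean TL = sum B_i TL_i / sum B_i; Shannon = -sum p_i ln p_i over
    biomass shares; pelagic:demersal and piscivore:planktivore ratios are
    fish-only.  Raises on zero total biomass.
    """
    b = run.biomass() if polygons is None else run.biomass()[:, :, polygons]
    b = b.sum(axis=2)  # (M, G)
    meta = run.group_meta
    living = ~np.asarray(meta["is_detritus"])
    tl = np.asarray(meta["trophic_level"])
    bl = b[:, living]
    tot = bl.sum(axis=1)
    if np.any(tot <= 0):
        raise ValueError("zero total biomass in indicator computation")
    mean_tl = (bl * tl[living]).sum(axis=1) / tot
    p = bl / tot[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = -(np.where(p > 0, p * np.log(p), 0.0)).sum(axis=1)

    fish = np.asarray(meta["is_fish"])
    habitat = meta["habitat"]
    pel = fish & np.array([h == "pelagic" for h in habitat])
    dem = fish & np.array([h != "pelagic" for h in habitat])
    pd = b[:, pel].sum(axis=1) / np.maximum(b[:, dem].sum(axis=1), 1e-300)
    pisc = fish & np.asarray(meta["piscivore"])
    plank = fish & np.asarray(meta["planktivore"])
    pp = b[:, pisc].sum(axis=1) / np.maximum(b[:, plank].sum(axis=1), 1e-300)
    return IndicatorSeries(mean_trophic_level=mean_tl, shannon=shannon,
                           pelagic_demersal=pd, piscivore_planktivore=pp)


def catch_delta(impacted: RunOutput, baseline: RunOutput) -> np.ndarray:
    """Annual whole-domain catch ratio per (year, fleet); NaN where the
    baseline catch is zero."""
    _check_paired(impacted, baseline)
    ci = impacted.catch_annual.sum(axis=2)  # (Y, F)
    cb = baseline.catch_annual.sum(axis=2)
    return np.where(cb > 0, ci / np.maximum(cb, 1e-300), np.nan)


def spearman_permutation(x, y, n_perm: int = 2000, seed: int = 0,
                         alternative: str = "less") -> tuple:
    """Spearman rank correlation with a permutation p-value.

    ``alternative='less'`` tests for negative correlation.  Returns
    (rho, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = stats.spearmanr(x, y).statistic
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for k in range(n_perm):
        perm[k] = stats.spearmanr(x, rng.permutation(y)).statistic
    if alternative == "less":
        p = (np.sum(perm <= rho) + 1) / (n_perm + 1)
    else:
        p = (np.sum(perm >= rho) + 1) / (n_perm + 1)
    return float(rho), float(p)


@dataclass
class RunComparison:
    """All paired metrics for one (impacted, baseline) pair."""

    polygons: np.ndarray
    guild_ratio: dict
    group_ratio: dict
    minima: dict  # guild -> (min ratio, months after spill)
    recovery_years: dict  # group -> years or DNR
    indicators_impacted: IndicatorSeries
    indicators_baseline: IndicatorSeries
    catch_ratio: np.ndarray
    spill_month: int


def compare_runs(impacted: RunOutput, baseline: RunOutput,
                 polygon_subset="auto", top_frac: float = 0.25,
                 threshold: float = 0.99) -> RunComparison:
    """Compute the full paired-metric set for a scenario/baseline pair."""
    if isinstance(polygon_subset, str):
        polygon_subset = heavily_impacted_polygons(impacted, baseline,
                                                   frac=top_frac)
    spill_month = impacted.month_of_day(impacted.spill_day)
    guild_ratio = relative_biomass(impacted, baseline, polygon_subset,
                                   level="guild")
    group_ratio = relative_biomass(impacted, baseline, polygon_subset,
                                   level="group")
    fish_guilds = {g for g, f in zip(impacted.guilds,
                                     impacted.group_meta["is_fish"]) if f}
    minima = {g: biomass_minimum(s, spill_month)
              for g, s in guild_ratio.items() if g in fish_guilds}
    horizon = impacted.config.horizon_years
    fish_groups = {n for n, f in zip(impacted.group_names,
                                     impacted.group_meta["is_fish"]) if f}
    recovery = {g: recovery_time(s, spill_month, threshold=threshold,
                                 horizon_years=horizon)
                for g, s in group_ratio.items() if g in fish_groups}
    return RunComparison(
        polygons=np.asarray(polygon_subset),
        guild_ratio=guild_ratio, group_ratio=group_ratio, minima=minima,
        recovery_years=recovery,
        indicators_impacted=ecosystem_indicators(impacted, polygon_subset),
        indicators_baseline=ecosystem_indicators(baseline, polygon_subset),
        catch_ratio=catch_delta(impacted, baseline),
        spill_month=spill_month,
    )
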