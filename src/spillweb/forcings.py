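"""Fishery-closure schedules and larval-loss tables.

The closure generator emulates the spatiotemporal footprint of emergency
fishery closures: a closed region that grows around the spill-site polygon,
peaks, and shrinks back within the closure window, expressed as a closed
fraction per (day, polygon, fleet).  Larval losses are per-group fractions
of the spill-year recruitment drawn from a truncated normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .foodweb import FLEETS, FunctionalGroup
from .geometry import PolygonGeometry


@dataclass
class ClosureSchedule:
    """Closed fraction in [0, 1] per (day, polygon, fleet).

    ``closed`` covers only the closure window; :meth:`closed_fraction`
    returns zeros outside it.
    """

    start_day: int
    closed: np.ndarray  # (duration_days, n_polygons, n_fleets)

    @property
    def duration_days(self) -> int:
        return self.closed.shape[0]

    def closed_fraction(self, day: int) -> np.ndarray:
        """(n_polygons, n_fleets) closed fraction on an absolute day."""
        i = day - self.start_day
        if 0 <= i < self.duration_days:
            return self.closed[i]
        return np.zeros_like(self.closed[0])

    def closed_area(self, geometry: PolygonGeometry) -> np.ndarray:
        """Fleet-mean closed area (km^2) per window day."""
        return (self.closed.mean(axis=2) * geometry.areas[None, :]).sum(axis=1)


@dataclass
class LarvalLossTable:
    """Fraction of spill-year larval production lost, per group name."""

    loss_fraction: dict

    def __post_init__(self):
        for k, v in self.loss_fraction.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"loss fraction for {k!r} outside [0, 1]")

    def get(self, name: str) -> float:
        return float(self.loss_fraction.get(name, 0.0))


def gen_closures(
    geometry: PolygonGeometry,
    start_day: int = 110,
    duration_days: int = 365,
    peak_fraction: float = 0.9,
    center_polygon: int | None = None,
    release_site: tuple[float, float] = (-88.37, 28.74),
    growth_fraction: float = 0.3,
    max_radius_deg: float = 4.0,
    seed: int = 0,
) -> ClosureSchedule:
    """Generate a grow-then-shrink closure footprint around the spill site.

    The closed fraction of a polygon on a given day falls off linearly with
    the distance of its centroid from the spill-site polygon, inside a
    radius that grows linearly to ``max_radius_deg`` over the first
    ``growth_fraction`` of the window and then shrinks to zero at the end.
    ``peak_fraction`` is the closed fraction at the centre at peak extent.
    """
    if duration_days < 1:
        raise ValueError("duration_days must be >= 1")
    if not (0.0 <= peak_fraction <= 1.0):
        raise ValueError("peak_fraction must lie in [0, 1]")
    if center_polygon is None:
        center_polygon = geometry.polygon_of(*release_site)
    cents = geometry.centroids()
    dist = np.hypot(cents[:, 0] - cents[center_polygon, 0],
                    cents[:, 1] - cents[center_polygon, 1])

    peak_day = max(1, int(round(growth_fraction * duration_days)))
    closed = np.zeros((duration_days, geometry.n_polygons, len(FLEETS)))
    for d in range(duration_days):
        if d <= peak_day:
            r = max_radius_deg * d / peak_day
        else:
            r = max_radius_deg * (duration_days - 1 - d) / (duration_days - 1 - peak_day)
        r = max(r, 0.0)
        if r <= 0:
            continue
        frac = peak_fraction * np.clip(1.0 - dist / r, 0.0, None)
        closed[d] = frac[:, None]
    return ClosureSchedule(start_day=int(start_day), closed=closed)


def gen_larval_loss(
    groups: list[FunctionalGroup],
    mean: float = 0.058,
    sd: float = 0.045,
    seed: int = 0,
) -> LarvalLossTable:
    """Draw per-fish-group larval loss fractions.

    Draws come from a normal with the stated pre-truncation moments,
    truncated to [0, 1]; with ``sd == 0`` every group receives exactly
    ``mean``.  Non-fish groups receive 0.
    """
    if mean < 0 or sd < 0:
        raise ValueError("mean and sd must be >= 0")
    rng = np.random.default_rng(seed)
    fish = [g.name for g in groups if g.is_fish]
    if sd == 0:
        draws = np.full(len(fish), np.clip(mean, 0.0, 1.0))
    else:
        a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
        draws = stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                    size=len(fish), random_state=rng)
    table = {name: float(v) for name, v in zip(fish, draws)}
    for g in groups:
        if not g.is_fish:
            table[g.name] = 0.0
    return LarvalLossTable(loss_fraction=table)
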