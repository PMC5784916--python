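"""Synthetic gridded PAH concentration fields.

A kernel-advection surrogate for a droplet-tracking oil transport model:
mass is injected daily at a point source into a surface layer (the slick)
and a deep layer (the subsurface plume), then spread by a Gaussian kernel,
displaced by a uniform per-layer drift, and removed by first-order decay.
Only the output contract matters downstream: daily, layered, gridded ppb
PAH snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import PolygonGeometry

#: Default release site (lon, lat, depth m): deep blowout in the central domain.
DEFAULT_RELEASE_SITE = (-88.37, 28.74, 1200.0)

#: Per-layer uniform drift (deg/day): surface slick pushed NE, plume SW.
DEFAULT_DRIFT = {"surface": (0.05, 0.02), "deep": (-0.04, -0.012)}


@dataclass
class OilFieldGrid:
    """Daily layered PAH concentration snapshots (ppb).

    ``conc`` has shape ``(track_days, n_layers, n_lat, n_lon)``.  Day 0 is
    the first day of the release; no new mass enters after ``release_days``.
    ``budget`` is a per-day mass ledger (injected, decayed, transported out
    of the domain, residual mass) in ppb * cell units.
    """

    conc: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    depth_cuts: np.ndarray
    release_site: tuple[float, float, float]
    release_days: int
    track_days: int
    budget: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_layers(self) -> int:
        return self.conc.shape[1]

    def total_mass(self) -> np.ndarray:
        """Total field mass per day (ppb * cell units)."""
        return self.conc.sum(axis=(1, 2, 3))


def deep_layer_index(depth_cuts: np.ndarray, depth: float) -> int:
    """Water layer containing the given depth."""
    return int(np.searchsorted(np.asarray(depth_cuts, dtype=float), depth))


def gen_oil_field(
    geometry: PolygonGeometry,
    release_site=DEFAULT_RELEASE_SITE,
    release_days: int = 87,
    track_days: int = 167,
    surface_and_deep_fractions=(0.35, 0.65),
    decay_rate: float = 0.03,
    source_strength: float = 15.0,
    spread_sigma_deg: float = 0.12,
    drift=None,
    seed: int = 0,
) -> OilFieldGrid:
    """Emulate a point-source release tracked as daily layered ppb fields.

    Parameters
    ----------
    release_days, track_days
        Days of active release and total days tracked (track >= release).
    surface_and_deep_fractions
        Partition of the daily source mass between the surface layer and the
        deep layer at the release depth; must sum to <= 1 (the remainder is
        treated as never entering the modelled fraction).
    decay_rate
        First-order loss rate (1/day) summarising degradation, evaporation
        and dissolution out of the toxic fraction.  Must be >= 0.
    source_strength
        Daily injected mass in ppb * cell units.
    spread_sigma_deg
        Daily Gaussian spreading scale (degrees).
    drift
        Mapping with 'surface' and 'deep' (dlon, dlat) deg/day entries;
        defaults to a NE surface drift and a SW deep drift.
    seed
        Seeds day-to-day jitter of the drift direction.
    """
    if track_days < release_days:
        raise ValueError("track_days must be >= release_days")
    if decay_rate < 0:
        raise ValueError("decay_rate must be >= 0")
    fs, fd = surface_and_deep_fractions
    if fs < 0 or fd < 0 or fs + fd > 1 + 1e-12:
        raise ValueError("surface/deep fractions must be >= 0 and sum to <= 1")
    drift = dict(DEFAULT_DRIFT if drift is None else drift)
    rng = np.random.default_rng(seed)

    lon, lat = geometry.lon, geometry.lat
    res = float(lon[1] - lon[0]) if lon.size > 1 else 1.0
    n_layers = geometry.n_water_layers
    ny, nx = lat.size, lon.size

    slon, slat, sdepth = release_site
    ix = int(np.argmin(np.abs(lon - slon)))
    iy = int(np.argmin(np.abs(lat - slat)))
    deep = deep_layer_index(geometry.depth_cuts, sdepth)
    deep = min(deep, n_layers - 1)

    sigma_cells = spread_sigma_deg / res
    layer_drift = np.zeros((n_layers, 2))
    layer_drift[0] = drift["surface"]
    layer_drift[deep] = drift["deep"]

    conc = np.zeros((track_days, n_layers, ny, nx))
    cur = np.zeros((n_layers, ny, nx))
    ledger = []
    survive = np.exp(-decay_rate)
    for t in range(track_days):
        transported_out = 0.0
        if t > 0:
            jitter = 1.0 + 0.15 * rng.standard_normal(2)
            for l in (0, deep):
                before = cur[l].sum()
                dlon, dlat = layer_drift[l] * jitter
                shifted = ndimage.shift(
                    cur[l], (dlat / res, dlon / res), order=1, mode="constant", cval=0.0
                )
                blurred = ndimage.gaussian_filter(
                    shifted, sigma=sigma_cells, mode="constant", cval=0.0
                )
                transported_out += before - blurred.sum()
                cur[l] = blurred
        before_decay = cur.sum()
        cur *= survive
        decayed = before_decay - cur.sum()
        injected = 0.0
        if t < release_days:
            injected = (fs + fd) * source_strength
            cur[0, iy, ix] += fs * source_strength
            cur[deep, iy, ix] += fd * source_strength
        np.clip(cur, 0.0, None, out=cur)
        conc[t] = cur
        ledger.append((t, injected, decayed, transported_out, cur.sum()))

    budget = pd.DataFrame(
        ledger, columns=["day", "injected", "decayed", "transported_out", "mass"]
    )
    return OilFieldGrid(
        conc=conc, lon=lon.copy(), lat=lat.copy(),
        depth_cuts=np.asarray(geometry.depth_cuts, dtype=float),
        release_site=tuple(release_site), release_days=int(release_days),
        track_days=int(track_days), budget=budget,
    )
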