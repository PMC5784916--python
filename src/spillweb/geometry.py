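"""Polygonal model geometry on a regular lon/lat grid.

The spatial domain is a rectangle of grid cells tiled into contiguous
polygons (nearest-seed Voronoi regions over cell centres).  Each polygon
carries an area, a bottom depth, and a set of water-column layers cut at
fixed depths; a sediment layer sits below the deepest occupied water layer.
This mirrors the box-geometry convention of spatially explicit ecosystem
models (boxes x depth layers), at a reduced, configurable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default domain (lon_min, lon_max, lat_min, lat_max), northern Gulf of Mexico.
DEFAULT_EXTENT = (-93.0, -84.0, 25.0, 30.75)

#: Default water-column layer cuts (m).  Six water layers result.
DEFAULT_DEPTH_CUTS = (10.0, 20.0, 50.0, 200.0, 2000.0)

_KM_PER_DEG = 111.32


@dataclass
class PolygonGeometry:
    """Tiling of a rectangular lon/lat grid into contiguous polygons.

    Attributes
    ----------
    lon, lat
        Cell-centre coordinates (1-D, degrees).
    cell_polygon
        Integer polygon id per cell, shape ``(n_lat, n_lon)``.
    depth_cuts
        Strictly increasing water-column partition depths (m).  There are
        ``len(depth_cuts) + 1`` water layers; layer 0 is the surface layer.
    bottom_depth
        Seafloor depth per polygon (m).
    areas
        Polygon areas (km^2).
    adjacency
        Set of unordered polygon-id pairs sharing a grid edge.
    """

    lon: np.ndarray
    lat: np.ndarray
    cell_polygon: np.ndarray
    depth_cuts: np.ndarray
    bottom_depth: np.ndarray
    areas: np.ndarray
    cell_area: np.ndarray
    adjacency: set = field(default_factory=set)

    @property
    def n_polygons(self) -> int:
        return int(self.areas.size)

    @property
    def n_water_layers(self) -> int:
        return int(self.depth_cuts.size) + 1

    @property
    def sediment_layer(self) -> int:
        """Index of the sediment layer (below all water layers)."""
        return self.n_water_layers

    def layer_bounds(self) -> np.ndarray:
        """Upper/lower depth of each water layer, shape (n_water_layers, 2)."""
        tops = np.concatenate([[0.0], self.depth_cuts])
        bots = np.concatenate([self.depth_cuts, [np.inf]])
        return np.column_stack([tops, bots])

    def n_occupied_layers(self, polygon: int) -> int:
        """Number of water layers whose top lies above the polygon's bottom."""
        tops = np.concatenate([[0.0], self.depth_cuts])
        return int(np.sum(tops < self.bottom_depth[polygon]))

    def occupied_layer_mask(self) -> np.ndarray:
        """Boolean (n_polygons, n_water_layers): layer exists in polygon."""
        tops = np.concatenate([[0.0], self.depth_cuts])
        return tops[None, :] < self.bottom_depth[:, None]

    def layer_thickness(self) -> np.ndarray:
        """Occupied thickness (m) per (polygon, water layer); 0 if absent."""
        bounds = self.layer_bounds()
        bot = np.minimum(bounds[None, :, 1], self.bottom_depth[:, None])
        thick = np.clip(bot - bounds[None, :, 0], 0.0, None)
        return thick

    def deepest_layer(self) -> np.ndarray:
        """Index of the deepest occupied water layer per polygon."""
        return self.occupied_layer_mask().sum(axis=1) - 1

    def membership_weights(self) -> dict[int, list[tuple[tuple[int, int], float]]]:
        """Per polygon: list of ((iy, ix), area weight); weights sum to 1."""
        out: dict[int, list[tuple[tuple[int, int], float]]] = {}
        for p in range(self.n_polygons):
            iy, ix = np.nonzero(self.cell_polygon == p)
            w = self.cell_area[iy, ix]
            w = w / w.sum()
            out[p] = [((int(y), int(x)), float(v)) for y, x, v in zip(iy, ix, w)]
        return out

    def polygon_of(self, lon: float, lat: float) -> int:
        """Polygon containing the given point (nearest cell centre)."""
        ix = int(np.argmin(np.abs(self.lon - lon)))
        iy = int(np.argmin(np.abs(self.lat - lat)))
        return int(self.cell_polygon[iy, ix])

    def centroids(self) -> np.ndarray:
        """Area-weighted polygon centroids, shape (n_polygons, 2) lon/lat."""
        cx = np.empty(self.n_polygons)
        cy = np.empty(self.n_polygons)
        lon2, lat2 = np.meshgrid(self.lon, self.lat)
        for p in range(self.n_polygons):
            m = self.cell_polygon == p
            w = self.cell_area[m]
            cx[p] = np.average(lon2[m], weights=w)
            cy[p] = np.average(lat2[m], weights=w)
        return np.column_stack([cx, cy])


def _validate_depth_cuts(depth_cuts) -> np.ndarray:
    cuts = np.asarray(depth_cuts, dtype=float)
    if cuts.size == 0:
        raise ValueError("depth_cuts must be nonempty")
    if np.any(np.diff(cuts) <= 0) or cuts[0] <= 0:
        raise ValueError("depth_cuts must be strictly increasing and positive")
    return cuts


def gen_geometry(
    n_polygons: int = 16,
    depth_cuts=DEFAULT_DEPTH_CUTS,
    grid_resolution: float = 0.25,
    extent=DEFAULT_EXTENT,
    max_depth: float = 3500.0,
    seed: int = 0,
) -> PolygonGeometry:
    """Generate a contiguous polygon tiling of a rectangular domain.

    Polygons are nearest-seed regions around random seed points, so they are
    contiguous and roughly convex.  Bottom depth deepens from the northern
    (shelf) edge toward the southern edge of the domain, so northern polygons
    hold few water layers and southern ones hold them all.

    Parameters
    ----------
    n_polygons
        Number of polygons (>= 2, or 1 for the trivial single-region case).
    depth_cuts
        Strictly increasing layer partition depths in metres.
    grid_resolution
        Cell size in degrees.
    seed
        Seed for the polygon seed-point draw; identical seeds give identical
        geometry.
    """
    if n_polygons < 1:
        raise ValueError("n_polygons must be >= 1")
    cuts = _validate_depth_cuts(depth_cuts)
    lon0, lon1, lat0, lat1 = extent
    rng = np.random.default_rng(seed)

    lon = np.arange(lon0 + grid_resolution / 2, lon1, grid_resolution)
    lat = np.arange(lat0 + grid_resolution / 2, lat1, grid_resolution)
    lon2, lat2 = np.meshgrid(lon, lat)

    if n_polygons == 1:
        cell_polygon = np.zeros(lon2.shape, dtype=int)
    else:
        for _ in range(50):
            sx = rng.uniform(lon0, lon1, n_polygons)
            sy = rng.uniform(lat0, lat1, n_polygons)
            d2 = (lon2[..., None] - sx) ** 2 + (lat2[..., None] - sy) ** 2
            cell_polygon = np.argmin(d2, axis=-1)
            if np.unique(cell_polygon).size == n_polygons:
                break
        else:  # pragma: no cover - vanishingly unlikely at sane sizes
            raise RuntimeError("could not draw a tiling with all polygons non-empty")

    # Cell areas (km^2), latitude-corrected.
    dy = _KM_PER_DEG * grid_resolution
    dx = _KM_PER_DEG * grid_resolution * np.cos(np.deg2rad(lat2))
    cell_area = dx * dy

    # Depth field: shallow shelf in the north, deep basin southward.
    frac = (lat1 - lat2) / (lat1 - lat0)
    depth_cell = 8.0 + max_depth * frac**1.2
    depth_cell *= np.exp(rng.normal(0.0, 0.08, depth_cell.shape))

    areas = np.zeros(n_polygons)
    bottom = np.zeros(n_polygons)
    for p in range(n_polygons):
        m = cell_polygon == p
        areas[p] = cell_area[m].sum()
        bottom[p] = np.average(depth_cell[m], weights=cell_area[m])

    adjacency: set = set()
    for a, b in ((cell_polygon[:, :-1], cell_polygon[:, 1:]),
                 (cell_polygon[:-1, :], cell_polygon[1:, :])):
        diff = a != b
        for i, j in zip(a[diff].ravel(), b[diff].ravel()):
            adjacency.add((int(min(i, j)), int(max(i, j))))

    return PolygonGeometry(
        lon=lon, lat=lat, cell_polygon=cell_polygon, depth_cuts=cuts,
        bottom_depth=bottom, areas=areas, cell_area=cell_area,
        adjacency=adjacency,
    )
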