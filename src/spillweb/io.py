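"""Serialisation of inputs and outputs.

Oil fields travel as netCDF (dims time/layer/lat/lon, units 'ppb PAH');
geometry as GeoJSON polygons plus a CSV layer table; food webs, closures
and larval losses as CSV; run outputs as a directory of CSVs with a JSON
metadata sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .foodweb import FLEETS, FunctionalGroup
from .forcings import ClosureSchedule, LarvalLossTable
from .geometry import PolygonGeometry
from .oilfield import OilFieldGrid
from .scenarios import RunOutput
from .toxicology import PolygonOilSeries


def oil_field_to_dataset(field: OilFieldGrid) -> xr.Dataset:
    da = xr.DataArray(
        field.conc, dims=("time", "layer", "lat", "lon"),
        coords={"time": np.arange(field.track_days),
                "layer": np.arange(field.conc.shape[1]),
                "lat": field.lat, "lon": field.lon},
        name="pah", attrs={"units": "ppb PAH"},
    )
    ds = da.to_dataset()
    ds.attrs.update({
        "release_lon": field.release_site[0],
        "release_lat": field.release_site[1],
        "release_depth_m": field.release_site[2],
        "release_days": field.release_days,
        "track_days": field.track_days,
    })
    return ds


def write_oil_field(field: OilFieldGrid, path) -> None:
    """Write a netCDF-3 oil field (scipy engine, no external libs)."""
    oil_field_to_dataset(field).to_netcdf(path, engine="scipy")


def read_oil_field(path, depth_cuts) -> OilFieldGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    return OilFieldGrid(
        conc=ds["pah"].values, lon=ds["lon"].values, lat=ds["lat"].values,
        depth_cuts=np.asarray(depth_cuts, dtype=float),
        release_site=(float(ds.attrs["release_lon"]),
                      float(ds.attrs["release_lat"]),
                      float(ds.attrs["release_depth_m"])),
        release_days=int(ds.attrs["release_days"]),
        track_days=int(ds.attrs["track_days"]),
    )


def geometry_to_geojson(geometry: PolygonGeometry) -> dict:
    """GeoJSON FeatureCollection of polygon outlines (cell unions)."""
    from shapely import unary_union
    from shapely.geometry import box, mapping

    res_lon = float(geometry.lon[1] - geometry.lon[0]) \
        if geometry.lon.size > 1 else 1.0
    res_lat = float(geometry.lat[1] - geometry.lat[0]) \
        if geometry.lat.size > 1 else 1.0
    features = []
    for p in range(geometry.n_polygons):
        iy, ix = np.nonzero(geometry.cell_polygon == p)
        cells = [box(geometry.lon[x] - res_lon / 2, geometry.lat[y] - res_lat / 2,
                     geometry.lon[x] + res_lon / 2, geometry.lat[y] + res_lat / 2)
                 for y, x in zip(iy, ix)]
        shape = unary_union(cells)
        features.append({
            "type": "Feature",
            "geometry": mapping(shape),
            "properties": {"polygon_id": p,
                           "area_km2": float(geometry.areas[p]),
                           "bottom_depth_m": float(geometry.bottom_depth[p])},
        })
    return {"type": "FeatureCollection", "features": features}


def write_geometry(geometry: PolygonGeometry, geojson_path, layers_csv_path) -> None:
    Path(geojson_path).write_text(json.dumps(geometry_to_geojson(geometry)))
    bounds = geometry.layer_bounds()
    rows = []
    for p in range(geometry.n_polygons):
        for l in range(geometry.n_water_layers):
            if bounds[l, 0] < geometry.bottom_depth[p]:
                rows.append((p, l, bounds[l, 0],
                             min(bounds[l, 1], geometry.bottom_depth[p])))
    pd.DataFrame(rows, columns=["polygon", "layer", "top_m", "bottom_m"]) \
        .to_csv(layers_csv_path, index=False)


def food_web_to_frame(groups: list[FunctionalGroup]) -> pd.DataFrame:
    rows = []
    for g in groups:
        d = dataclasses.asdict(g)
        d["diet_row"] = json.dumps(d["diet_row"])
        d["migration_schedule"] = json.dumps(d["migration_schedule"])
        d["gape_min"], d["gape_max"] = d.pop("gape")
        rows.append(d)
    return pd.DataFrame(rows)


def write_food_web(groups: list[FunctionalGroup], path) -> None:
    food_web_to_frame(groups).to_csv(path, index=False)


def read_food_web(path) -> list[FunctionalGroup]:
    df = pd.read_csv(path)
    groups = []
    for _, row in df.iterrows():
        d = row.to_dict()
        d["diet_row"] = json.loads(d["diet_row"])
        mig = d["migration_schedule"]
        d["migration_schedule"] = None if (not isinstance(mig, str)
                                           or mig == "null") \
            else json.loads(mig)
        d["gape"] = (d.pop("gape_min"), d.pop("gape_max"))
        if not isinstance(d["fleet"], str):
            d["fleet"] = None
        groups.append(FunctionalGroup(**d))
    return groups


def write_closures(schedule: ClosureSchedule, path) -> None:
    d, p, f = np.nonzero(schedule.closed)
    pd.DataFrame({
        "day": d + schedule.start_day, "polygon": p,
        "fleet": [FLEETS[i] for i in f],
        "closed_fraction": schedule.closed[d, p, f],
    }).to_csv(path, index=False)


def write_larval_loss(table: LarvalLossTable, path) -> None:
    pd.DataFrame(sorted(table.loss_fraction.items()),
                 columns=["group", "loss_fraction"]).to_csv(path, index=False)


def read_larval_loss(path) -> LarvalLossTable:
    df = pd.read_csv(path)
    return LarvalLossTable(dict(zip(df["group"], df["loss_fraction"])))


def polygon_series_to_frame(series: PolygonOilSeries) -> pd.DataFrame:
    """Long-format (day, polygon, layer, ppb) of nonzero concentrations."""
    d, p, l = np.nonzero(series.water_conc)
    return pd.DataFrame({"day": d, "polygon": p, "layer": l,
                         "ppb": series.water_conc[d, p, l]})


def write_polygon_series(series: PolygonOilSeries, path) -> None:
    polygon_series_to_frame(series).to_csv(path, index=False)


def modifiers_to_frame(mods, group_names) -> pd.DataFrame:
    """Long-format daily modifiers: (day, polygon, group, m_oil, g_mult)."""
    d, p, g = np.nonzero(mods.m_oil)
    return pd.DataFrame({
        "day": d, "polygon": p,
        "group": np.asarray(group_names)[g],
        "m_oil_per_day": mods.m_oil[d, p, g],
        "g_mult": mods.g_mult[d, p, g],
    })


def write_modifiers(mods, group_names, path) -> None:
    modifiers_to_frame(mods, group_names).to_csv(path, index=False)


def dose_response_to_dict(params) -> dict:
    """JSON/YAML-ready dose-response parameter block."""
    return dataclasses.asdict(params)


def write_dose_response(params, path) -> None:
    import yaml
    Path(path).write_text(yaml.safe_dump(dose_response_to_dict(params),
                                         sort_keys=False))


def read_dose_response(path):
    import yaml
    from .toxicology import DoseResponseParams
    return DoseResponseParams(**yaml.safe_load(Path(path).read_text()))


def write_run_output(run: RunOutput, directory) -> None:
    """Write a run as CSV tables + JSON metadata under a directory."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    b = run.biomass()  # (M, G, P)
    m, g, p = np.indices(b.shape)
    pd.DataFrame({
        "month": m.ravel(), "group": np.array(run.group_names)[g.ravel()],
        "polygon": p.ravel(), "biomass_mgN": b.ravel(),
    }).to_csv(out / "biomass.csv", index=False)
    y, f, g2 = np.indices(run.catch_annual.shape)
    pd.DataFrame({
        "year": y.ravel(), "fleet": np.array(FLEETS)[f.ravel()],
        "group": np.array(run.group_names)[g2.ravel()],
        "catch_mgN": run.catch_annual.ravel(),
    }).to_csv(out / "catch.csv", index=False)
    meta = {
        "label": run.label, "spill_day": run.spill_day,
        "group_names": run.group_names, "guilds": run.guilds,
        "config": dataclasses.asdict(run.config),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
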