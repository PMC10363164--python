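"""Geospatial products: attribute schema, areas, vector/raster text I/O.

Outputs use the package's fixed attribute schema — ID,
Biome, Country, Prc_Pln/Prc_P_U/Prc_P_L (percent planted per bound, NaN on
national-map cells), Type/Typ_Upp/Typ_Lwr, Genus/Gns_Upp/Gns_Lwr (NaN on
natural cells), Area_m2 — with one square 0.009° polygon per forest cell.
Vector output is GeoJSON (WGS84); rasters are ESRI ASCII grids with a JSON
sidecar legend for categorical fields.  Cell areas use a spherical Earth
with the authalic radius (error < 0.3% at mid latitudes).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping, shape

from .grid import Grid

EARTH_RADIUS_M = 6_371_008.8  # authalic radius

OUTPUT_COLUMNS = (
    "ID", "Biome", "Country", "Prc_Pln", "Prc_P_U", "Prc_P_L",
    "Type", "Typ_Upp", "Typ_Lwr", "Genus", "Gns_Upp", "Gns_Lwr", "Area_m2",
)
OPTIONAL_COLUMNS = ("Besnard_Yr", "Du_Yr")  # passthrough only, never computed
NODATA = -9999.0


def cell_area_m2(centroid_lat: float, cell_size_deg: float) -> float:
    """Spherical area of one grid cell: (R·Δφ)·(R·cosφ·Δλ)."""
    if not -90.0 < centroid_lat < 90.0:
        raise ValueError(f"latitude {centroid_lat} out of range (-90, 90)")
    dphi = math.radians(cell_size_deg)
    dlam = math.radians(cell_size_deg)
    return (EARTH_RADIUS_M * dphi) * (EARTH_RADIUS_M * math.cos(math.radians(centroid_lat)) * dlam)


def build_output_records(
    cells: pd.DataFrame,
    records: pd.DataFrame,
    genus: Mapping[str, pd.Series],
) -> pd.DataFrame:
    """Assemble the exported attribute table.

    ``cells`` (indexed by cell_id) supplies Biome (biome_group), Country
    and centroid_lat; ``records`` the percent/type fields from the
    classifier; ``genus`` maps bound name ("mean", "upper", "lower") to a
    cell_id -> genus Series.  Genus is blanked wherever the corresponding
    type is Natural.
    """
    idx = records.index
    out = pd.DataFrame(index=idx)
    out["ID"] = idx
    out["Biome"] = cells.loc[idx, "biome_group"]
    out["Country"] = cells.loc[idx, "country"]
    out["Prc_Pln"] = records["p_mean"]
    out["Prc_P_U"] = records["p_upper"]
    out["Prc_P_L"] = records["p_lower"]
    for src, dst in (("type", "Type"), ("type_upper", "Typ_Upp"), ("type_lower", "Typ_Lwr")):
        out[dst] = records[src].map({"planted": "Planted", "natural": "Natural"})
    for bound, col, typ in (("mean", "Genus", "Type"), ("upper", "Gns_Upp", "Typ_Upp"),
                            ("lower", "Gns_Lwr", "Typ_Lwr")):
        g = genus.get(bound, pd.Series(dtype=object)).reindex(idx)
        g[out[typ] == "Natural"] = np.nan
        out[col] = g
    lat = cells.loc[idx, "centroid_lat"].to_numpy()
    size = cells.attrs.get("cell_size_deg", 0.009)
    out["Area_m2"] = [cell_area_m2(float(v), size) for v in lat]
    return out.loc[:, list(OUTPUT_COLUMNS)]


# --------------------------------------------------------------------------
# Vector I/O (GeoJSON)

def write_vector(records: pd.DataFrame, grid: Grid, path: str | Path) -> Path:
    """Write the attribute table as GeoJSON with one square cell polygon
    per record (WGS84).  NaN attributes become JSON nulls."""
    path = Path(path)
    features = []
    for cell_id, row in records.iterrows():
        r, c = int(cell_id) // grid.n_cols, int(cell_id) % grid.n_cols
        geom = box(*grid.cell_bounds(r, c))
        props = {}
        for k, v in row.items():
            if isinstance(v, float) and math.isnan(v):
                props[k] = None
            elif isinstance(v, (np.integer,)):
                props[k] = int(v)
            elif isinstance(v, (np.floating,)):
                props[k] = float(v)
            else:
                props[k] = None if v is None or (isinstance(v, float) and math.isnan(v)) else v
        features.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": "urn:ogc:def:crs:OGC:1.3:CRS84"}},
        "features": features,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))
    return path


def read_vector(path: str | Path) -> tuple[pd.DataFrame, list]:
    """Read a GeoJSON written by :func:`write_vector`; returns (attribute
    table indexed by ID, list of shapely geometries)."""
    doc = json.loads(Path(path).read_text())
    rows, geoms = [], []
    for feat in doc["features"]:
        rows.append(feat["properties"])
        geoms.append(shape(feat["geometry"]))
    df = pd.DataFrame(rows)
    if "ID" in df.columns:
        df = df.set_index(df["ID"].to_numpy())
    return df, geoms


# --------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid + JSON legend sidecar)

def write_raster(
    field: pd.Series,
    grid: Grid,
    path: str | Path,
    legend: Mapping[str, int] | None = None,
) -> Path:
    """Write a per-cell field as an ESRI ASCII grid aligned to the grid.

    ``field`` is indexed by cell_id; absent cells and NaN become the
    nodata value.  Categorical fields pass a ``legend`` (category -> int
    code) and are encoded through it, with the legend written to
    ``<path>.legend.json``.
    """
    path = Path(path)
    full = np.full(grid.n_cells, NODATA)
    vals = field.dropna()
    bad = ~pd.Index(vals.index).isin(range(grid.n_cells))
    if bad.any():
        raise ValueError("field misaligned with grid: cell_ids outside the grid")
    if legend is not None:
        coded = vals.map(legend)
        if coded.isna().any():
            missing = sorted(set(vals[coded.isna()]))
            raise ValueError(f"legend lacks codes for {missing}")
        full[vals.index.to_numpy()] = coded.to_numpy(dtype=float)
    else:
        full[vals.index.to_numpy()] = vals.to_numpy(dtype=float)
    arr = full.reshape(grid.n_rows, grid.n_cols)  # row 0 = north, as stored
    s = grid.cell_size_deg
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_lon!r}\n"
        f"yllcorner {grid.origin_lat - grid.n_rows * s!r}\n"
        f"cellsize {s!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.7g")
    if legend is not None:
        Path(str(path) + ".legend.json").write_text(json.dumps(dict(legend)))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, Grid, dict | None]:
    """Read an ESRI ASCII grid back as (array, grid, legend-or-None);
    nodata becomes NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    nodata = header["nodata_value"]
    arr[arr == nodata] = np.nan
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    s = header["cellsize"]
    grid = Grid(
        n_rows=n_rows, n_cols=n_cols,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * s,
        cell_size_deg=s,
    )
    legend_path = Path(str(path) + ".legend.json")
    legend = json.loads(legend_path.read_text()) if legend_path.exists() else None
    return arr, grid, legend


# --------------------------------------------------------------------------
# Area summaries

def planted_area_summary(output: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-country, per-genus x country) planted-area tables in km².

    Both tables sum to the same total over the same planted-cell set, with
    percent-share columns per country.
    """
    planted = output.loc[output["Type"] == "Planted"]
    km2 = planted["Area_m2"] / 1e6
    by_country = km2.groupby(planted["Country"]).sum().rename("area_km2").reset_index()
    total = float(km2.sum())
    by_country["share_pct"] = 100.0 * by_country["area_km2"] / total if total else 0.0
    by_genus = (
        km2.groupby([planted["Genus"], planted["Country"]]).sum().rename("area_km2").reset_index()
        .rename(columns={"level_0": "Genus"})
    )
    return by_country, by_genus
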