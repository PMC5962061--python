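"""Readers and writers for the exchanged plain-text formats.

Rasters travel as ASCII-grid text (ncols/nrows/xllcorner/yllcorner/
cellsize header then rows, north row first, as GIS tools write them),
flight paths and coastlines as GeoJSON LineStrings, records and segment
tables as CSV, fitted models and run summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, mapping, shape

from .synthetic import Landscape

__all__ = [
    "write_ascii_grid", "read_ascii_grid", "write_linestrings",
    "read_linestrings", "write_records", "read_records",
    "write_landscape", "read_landscape", "write_segments", "read_segments",
]


def write_ascii_grid(path, array: np.ndarray, origin_xy, cell_size: float) -> None:
    """Write a raster as ASCII grid; row 0 of ``array`` is the south row,
    but the file stores north first per the format convention."""
    arr = np.asarray(array, dtype=float)
    nrows, ncols = arr.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin_xy[0]:.6f}\n")
        fh.write(f"yllcorner {origin_xy[1]:.6f}\n")
        fh.write(f"cellsize {cell_size:.6f}\n")
        fh.write("NODATA_value -9999\n")
        for row in arr[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path):
    """Read an ASCII-grid raster; returns (array south-row-first,
    origin_xy, cell_size)."""
    header = {}
    data_rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                data_rows.append([float(v) for v in parts])
    arr = np.asarray(data_rows)[::-1]
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {arr.shape} does not match header")
    return arr, (header["xllcorner"], header["yllcorner"]), header["cellsize"]


def write_linestrings(path, lines: list[LineString], names=None) -> None:
    feats = []
    for i, ln in enumerate(lines):
        feats.append({
            "type": "Feature",
            "properties": {"name": (names[i] if names else f"line{i}")},
            "geometry": mapping(ln),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def read_linestrings(path) -> list[LineString]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [shape(gj["geometry"])]
    else:
        geoms = [shape(gj)]
    out = []
    for g in geoms:
        if g.geom_type != "LineString":
            raise ValueError(f"expected LineString geometries, got {g.geom_type}")
        out.append(g)
    return out


def write_records(path, records: pd.DataFrame) -> None:
    cols = [c for c in ("x", "y", "group_size", "t", "survey", "season",
                        "effort_km") if c in records.columns]
    records[cols].to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    rec = pd.read_csv(path)
    for col in ("x", "y", "group_size"):
        if col not in rec.columns:
            raise ValueError(f"record CSV lacks required column '{col}'")
    return rec


def write_segments(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_landscape(directory, landscape: Landscape) -> None:
    """Write a landscape as two ASCII grids plus a GeoJSON coastline."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(d / "elevation.asc", landscape.elevation,
                     landscape.origin_xy, landscape.cell_size)
    write_ascii_grid(d / "forest.asc", landscape.forest_fraction,
                     landscape.origin_xy, landscape.cell_size)
    write_linestrings(d / "coastline.geojson", [landscape.coastline],
                      names=["coastline"])


def read_landscape(directory) -> Landscape:
    d = Path(directory)
    elev, origin, cs = read_ascii_grid(d / "elevation.asc")
    forest, origin2, cs2 = read_ascii_grid(d / "forest.asc")
    if origin != origin2 or cs != cs2:
        raise ValueError("elevation and forest rasters are not aligned")
    coast = read_linestrings(d / "coastline.geojson")[0]
    return Landscape(origin_xy=origin, cell_size=cs, n_cols=elev.shape[1],
                     n_rows=elev.shape[0], elevation=elev,
                     forest_fraction=np.clip(forest, 0.0, 1.0), coastline=coast)
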