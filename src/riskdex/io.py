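"""Readers and writers for the pipeline's on-disk formats.

Rasters are stored as ESRI ASCII grids (.asc) with a .prj sidecar naming the
CRS; polygons as GeoJSON; occurrences, traits and ledgers as CSV with
declared column schemas.  Reads validate grid alignment and CRS so silently
mis-registered layers cannot enter the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .grids import WGS84, GridSpec, RasterGrid
from .vulnerability import DEFAULT_TRAIT_RISK, SENSITIVITY_TRAITS

NODATA = -9999.0

OCCURRENCE_COLUMNS = ["species_id", "lon", "lat"]
TRAIT_COLUMNS = ["species_id", *SENSITIVITY_TRAITS,
                 "order_label", "trophic_group", "body_size_class",
                 "locomotion_group"]


class CrsError(ValueError):
    pass


def write_ascii_grid(path: str | Path, raster: RasterGrid,
                     nodata: float = NODATA) -> None:
    path = Path(path)
    spec = raster.spec
    vals = np.asarray(raster.values, dtype=float).copy()
    vals[~np.isfinite(vals)] = nodata
    header = (f"ncols {spec.n_cols}\n"
              f"nrows {spec.n_rows}\n"
              f"xllcorner {spec.lon_min!r}\n"
              f"yllcorner {spec.lat_min!r}\n"
              f"cellsize {spec.resolution!r}\n"
              f"NODATA_value {nodata!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")
    path.with_suffix(".prj").write_text(spec.crs + "\n")


def read_ascii_grid(path: str | Path,
                    expected_crs: str | None = WGS84,
                    expected_spec: GridSpec | None = None) -> RasterGrid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    prj = path.with_suffix(".prj")
    if not prj.exists():
        raise CrsError(f"{path}: CRS sidecar missing (expected {expected_crs})")
    crs = prj.read_text().strip()
    if expected_crs is not None and crs != expected_crs:
        raise CrsError(f"{path}: CRS {crs!r} != expected {expected_crs!r}")
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    res = header["cellsize"]
    spec = GridSpec(lon_min=header["xllcorner"],
                    lat_max=header["yllcorner"] + n_rows * res,
                    resolution=res, n_rows=n_rows, n_cols=n_cols, crs=crs)
    vals = np.atleast_2d(vals)
    vals[vals == header["nodata_value"]] = np.nan
    if expected_spec is not None and spec != expected_spec:
        from .grids import GridMismatchError
        raise GridMismatchError(f"{path}: grid {spec} != expected {expected_spec}")
    return RasterGrid(spec, vals)


def write_geojson(path: str | Path,
                  features: list[tuple[object, dict]]) -> None:
    """Write (geometry, properties) pairs as a GeoJSON FeatureCollection."""
    fc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": WGS84}},
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> list[tuple[object, dict]]:
    fc = json.loads(Path(path).read_text())
    return [(shape(f["geometry"]), f.get("properties") or {})
            for f in fc["features"]]


def write_occurrences_csv(path: str | Path, records: dict[str, np.ndarray]) -> None:
    frames = [pd.DataFrame({"species_id": sid, "lon": pts[:, 0],
                            "lat": pts[:, 1]})
              for sid, pts in records.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_occurrences_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    missing = set(OCCURRENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns {sorted(missing)}")
    return {str(sid): sub[["lon", "lat"]].to_numpy()
            for sid, sub in df.groupby("species_id")}


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    """Schema/enum validation for a trait table; errors name the first bad row."""
    missing = set(TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trait CSV missing columns {sorted(missing)}")
    for trait, table in DEFAULT_TRAIT_RISK.items():
        allowed = set(table)
        col = df[trait]
        if all(isinstance(k, bool) for k in allowed):
            col = col.astype(bool)
        bad = ~col.isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"trait {trait!r}: unknown value {df[trait].iloc[row]!r} "
                f"in row {row} (species {df['species_id'].iloc[row]!r})")
    if (df["n_ecoregions"] < 1).any():
        row = int(np.flatnonzero((df["n_ecoregions"] < 1).to_numpy())[0])
        raise ValueError(f"n_ecoregions < 1 in row {row}")
    return df


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    return validate_traits(pd.read_csv(path))
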