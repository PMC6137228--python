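"""Raster and cube I/O.

Rasters are stored as single-variable NetCDF files with CF-style ``lat`` /
``lon`` centre coordinates plus explicit grid-geometry attributes, written
through xarray's scipy backend.  float64 payloads round-trip bit-exactly and
the geometry attributes round-trip exactly, so read(write(x)) == x.

A soil property cube (one element, seven layers, six statistics per layer)
is stored as one raster per (variable, layer, statistic) named
``<element>_<var>_<layer>_<mean|std>.nc`` next to a YAML manifest listing
layer boundaries and units.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import xarray as xr
import yaml

from .errors import GeoreferencingError, UnitError
from .grid import GeoGrid, RasterField

_GEOM_ATTRS = ("n_rows", "n_cols", "lat_origin", "lon_origin", "cell_size", "nodata")


def write_raster(field: RasterField, path: str | os.PathLike) -> Path:
    """Write one raster to NetCDF; returns the path written."""
    g = field.grid
    da = xr.DataArray(
        field.values,
        dims=("lat", "lon"),
        coords={"lat": g.lat_centers, "lon": g.lon_centers},
        name=field.name or "value",
        attrs={"units": field.units},
    )
    ds = da.to_dataset()
    ds.attrs.update(
        n_rows=g.n_rows, n_cols=g.n_cols, lat_origin=g.lat_origin,
        lon_origin=g.lon_origin, cell_size=g.cell_size, nodata=g.nodata,
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine="scipy")
    return path


def read_raster(path: str | os.PathLike, expected_units: str | None = None) -> RasterField:
    """Read one raster; fails if georeferencing attrs are missing or units mismatch."""
    path = Path(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    missing = [a for a in _GEOM_ATTRS if a not in ds.attrs]
    if missing:
        raise GeoreferencingError(f"{path}: missing georeferencing attributes {missing}")
    data_vars = list(ds.data_vars)
    if len(data_vars) != 1:
        raise GeoreferencingError(f"{path}: expected exactly one variable, found {data_vars}")
    da = ds[data_vars[0]]
    units = str(da.attrs.get("units", ""))
    if expected_units is not None and units != expected_units:
        raise UnitError(f"{path}: units {units!r}, expected {expected_units!r}")
    grid = GeoGrid(
        n_rows=int(ds.attrs["n_rows"]), n_cols=int(ds.attrs["n_cols"]),
        lat_origin=float(ds.attrs["lat_origin"]), lon_origin=float(ds.attrs["lon_origin"]),
        cell_size=float(ds.attrs["cell_size"]), nodata=float(ds.attrs["nodata"]),
    )
    return RasterField(grid, np.asarray(da.values, dtype=float), units, data_vars[0])


# -- soil cube on disk ----------------------------------------------------

_CUBE_VARS = ("conc", "conc_std", "bulk", "bulk_std", "cfrag", "cfrag_std")
_CUBE_UNITS = {"conc": "g kg-1", "bulk": "g cm-3", "cfrag": "%"}


def write_cube(cube, outdir: str | os.PathLike) -> Path:
    """Write a SoilCube as one raster per (variable, layer, statistic) + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for i, lf in enumerate(cube.fields):
        for var in _CUBE_VARS:
            fname = f"{cube.element}_{var.replace('_std', '')}_{i}_{'std' if var.endswith('_std') else 'mean'}.nc"
            write_raster(getattr(lf, var), outdir / fname)
            files[f"{var}_{i}"] = fname
    manifest = {
        "element": cube.element,
        "layer_boundaries_m": [cube.layers[0].top] + [l.bottom for l in cube.layers],
        "units": dict(_CUBE_UNITS),
        "files": files,
    }
    mpath = outdir / f"{cube.element}_manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return mpath


def read_cube(manifest_path: str | os.PathLike):
    """Read a SoilCube written by :func:`write_cube`."""
    from .stocks import LayerFields, SoilCube, SoilLayerSpec

    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    bounds = manifest["layer_boundaries_m"]
    layers = [SoilLayerSpec(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    fields = []
    for i in range(len(layers)):
        kwargs = {}
        for var in _CUBE_VARS:
            base = var.replace("_std", "")
            expected = _CUBE_UNITS[base]
            kwargs[var] = read_raster(
                manifest_path.parent / manifest["files"][f"{var}_{i}"], expected
            )
        fields.append(LayerFields(**kwargs))
    return SoilCube(element=manifest["element"], layers=layers, fields=fields)
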