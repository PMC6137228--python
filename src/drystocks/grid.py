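"""Regular latitude-longitude raster geometry, cell areas and block aggregation.

All spatial layers in the package live on a :class:`GeoGrid`: a regular
lat/lon grid addressed row-major from the northwest corner, rows running
north to south, with a single numeric nodata sentinel per raster.  Cell
values are cell-centre samples.

Cell areas are computed analytically on an authalic sphere rather than by
projecting to an equal-area CRS: for a cell bounded by latitudes
``(phi1, phi2)`` and spanning ``dlon`` radians of longitude the exact
spherical area is ``R^2 * dlon * (sin phi2 - sin phi1)``.  Equal-area
projections preserve exactly these areas, so the closed form is both faster
and testable against the full-sphere total ``4 pi R^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, ValidationError

#: Radius (km) of the sphere with the same surface area as the WGS84 ellipsoid.
AUTHALIC_RADIUS_KM = 6371.0072

_GEOMETRY_FIELDS = ("n_rows", "n_cols", "lat_origin", "lon_origin", "cell_size")
_EXTENT_TOL = 1e-9


@dataclass(frozen=True)
class GeoGrid:
    """Geometry of a regular lat/lon raster.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; rows are ordered north to south.
    lat_origin
        Latitude of the *north* edge of the first row, degrees.
    lon_origin
        Longitude of the *west* edge of the first column, degrees.
    cell_size
        Square cell size in degrees.
    nodata
        Numeric sentinel marking missing cells in any raster on this grid.
    """

    n_rows: int
    n_cols: int
    lat_origin: float = 90.0
    lon_origin: float = -180.0
    cell_size: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise GeometryError("grid must have at least one row and one column")
        if not (self.cell_size > 0):
            raise GeometryError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows * self.cell_size > 180.0 + _EXTENT_TOL:
            raise GeometryError("grid spans more than 180 degrees of latitude")
        if self.n_cols * self.cell_size > 360.0 + _EXTENT_TOL:
            raise GeometryError("grid spans more than 360 degrees of longitude")
        if self.lat_origin > 90.0 + _EXTENT_TOL:
            raise GeometryError("northern edge lies above 90 N")
        if self.lat_origin - self.n_rows * self.cell_size < -90.0 - _EXTENT_TOL:
            raise GeometryError("southern edge lies below 90 S")

    # -- derived geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lat_edges(self) -> np.ndarray:
        """Latitudes of row edges, north to south, length n_rows + 1."""
        return self.lat_origin - np.arange(self.n_rows + 1) * self.cell_size

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon_origin + np.arange(self.n_cols + 1) * self.cell_size

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @classmethod
    def global_grid(cls, cell_size: float, nodata: float = -9999.0) -> "GeoGrid":
        """The full-globe grid at a given resolution (must divide 180)."""
        n_rows = round(180.0 / cell_size)
        n_cols = round(360.0 / cell_size)
        if not (
            math.isclose(n_rows * cell_size, 180.0)
            and math.isclose(n_cols * cell_size, 360.0)
        ):
            raise GeometryError(f"cell_size {cell_size} does not tile the globe")
        return cls(n_rows, n_cols, 90.0, -180.0, cell_size, nodata)

    def aligned_with(self, other: "GeoGrid") -> bool:
        """Two grids are aligned iff all five geometry fields are equal."""
        return all(
            getattr(self, f) == getattr(other, f) for f in _GEOMETRY_FIELDS
        )

    def geometry_mismatches(self, other: "GeoGrid") -> list[str]:
        return [f for f in _GEOMETRY_FIELDS if getattr(self, f) != getattr(other, f)]


@dataclass
class RasterField:
    """A single-variable raster: values on a :class:`GeoGrid` plus a units tag."""

    grid: GeoGrid
    values: np.ndarray
    units: str
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GeometryError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not self.units:
            raise ValidationError("units tag must be non-empty")
        bad = ~np.isfinite(self.values) & (self.values != self.grid.nodata)
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} non-finite cells that are not the nodata sentinel"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.grid.nodata

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterField":
        return RasterField(self.grid, values, self.units, self.name if name is None else name)


@dataclass
class CellAreaField:
    """Per-cell spherical areas in km^2; constant within a latitude row."""

    grid: GeoGrid
    areas: np.ndarray
    radius_km: float

    @property
    def areas_m2(self) -> np.ndarray:
        return self.areas * 1e6


@dataclass
class AlignmentReport:
    """Result of checking that a set of rasters share one grid."""

    passed: bool
    mismatched_fields: list[str] = field(default_factory=list)
    n_fields: int = 0
    misuse: bool = False

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def cell_areas(grid: GeoGrid, radius_km: float = AUTHALIC_RADIUS_KM) -> CellAreaField:
    """Exact spherical cell areas (km^2) for every cell of *grid*.

    The area of a cell in the row bounded by latitudes ``(phi1, phi2)`` with
    longitudinal width ``dlon`` radians is ``R^2 * dlon * (sin phi2 - sin phi1)``;
    it is constant along the row.  Over a full global grid the row bands
    telescope to ``4 pi R^2``.
    """
    if not (radius_km > 0):
        raise GeometryError(f"radius must be positive, got {radius_km}")
    phi = np.radians(grid.lat_edges)
    sin_phi = np.sin(phi)
    band = sin_phi[:-1] - sin_phi[1:]  # north minus south, positive
    if np.any(band <= 0):
        raise GeometryError("degenerate latitude band (cell_size rounds to zero width)")
    dlon = math.radians(grid.cell_size)
    row_area = radius_km**2 * dlon * band
    areas = np.repeat(row_area[:, None], grid.n_cols, axis=1)
    return CellAreaField(grid, areas, radius_km)


def validate_alignment(fields: list) -> AlignmentReport:
    """Check that every raster in *fields* shares the first one's geometry.

    Report-returning: never raises.  An empty list is flagged as misuse.
    Accepts RasterField, CellAreaField or anything with a ``.grid`` attribute.
    """
    if not fields:
        return AlignmentReport(passed=False, mismatched_fields=["<empty input>"],
                               n_fields=0, misuse=True)
    ref = fields[0].grid
    mismatched: list[str] = []
    for f in fields[1:]:
        for name in ref.geometry_mismatches(f.grid):
            if name not in mismatched:
                mismatched.append(name)
    return AlignmentReport(passed=not mismatched, mismatched_fields=mismatched,
                           n_fields=len(fields))


def require_alignment(fields: list) -> None:
    from .errors import AlignmentError

    report = validate_alignment(fields)
    if not report.passed:
        raise AlignmentError(
            f"rasters are not aligned; mismatched geometry fields: {report.mismatched_fields}"
        )


def block_aggregate(
    field: RasterField,
    factor: int,
    mode: str = "mean",
    radius_km: float = AUTHALIC_RADIUS_KM,
) -> RasterField:
    """Coarsen a raster by an integer factor, ignoring nodata cells.

    ``mode='mean'`` is the plain mean of the valid fine cells of each block;
    ``mode='area_weighted_mean'`` weights them by spherical cell area, which
    conserves the block total of value x area exactly.  An all-nodata block
    becomes nodata.
    """
    if factor < 1 or int(factor) != factor:
        raise ValidationError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    grid = field.grid
    if grid.n_rows % factor or grid.n_cols % factor:
        raise ValidationError(
            f"factor {factor} does not divide grid shape {grid.shape}"
        )
    if mode not in ("mean", "area_weighted_mean"):
        raise ValidationError(f"unknown mode {mode!r}")

    valid = field.valid_mask
    v = np.where(valid, field.values, 0.0)
    if mode == "area_weighted_mean":
        w = cell_areas(grid, radius_km).areas * valid
    else:
        w = valid.astype(float)

    nr, nc = grid.n_rows // factor, grid.n_cols // factor

    def blocks(a: np.ndarray) -> np.ndarray:
        return a.reshape(nr, factor, nc, factor).sum(axis=(1, 3))

    wsum = blocks(w)
    vsum = blocks(v * w)
    out = np.where(wsum > 0, np.divide(vsum, wsum, out=np.zeros_like(vsum),
                                       where=wsum > 0), grid.nodata)
    coarse = replace(grid, n_rows=nr, n_cols=nc, cell_size=grid.cell_size * factor)
    return RasterField(coarse, out, field.units, field.name)
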