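"""Per-cell soil element stocks with first-order uncertainty propagation.

The fine-earth areal stock of an element in one soil layer is

    STOCK = HOT * CN * BULK * (1 - CFRAG/100)        [kg m-2]

with layer thickness HOT (m), element concentration CN (g kg-1), bulk
density BULK (g cm-3) and coarse-fragment (gravel) volume CFRAG (%).  The
unit identity (g kg-1)(g cm-3)(m) = kg m-2 holds with no extra factor.

Its standard deviation follows by first-order (Taylor / delta-method)
propagation of the three input standard deviations, treating the inputs as
independent:

    STOCK_std = HOT * sqrt( CN_std^2 * BULK^2   * (1 - CFRAG/100)^2
                          + CN^2    * BULK_std^2 * (1 - CFRAG/100)^2
                          + CN^2    * BULK^2    * (CFRAG_std/100)^2 )

Layers are combined to a depth target pro-rata (the layer straddling the
target contributes in proportion to the depth slice used, assuming uniform
density within the layer).  Layer errors combine either in quadrature
(``independent``, the default) or additively (``correlated``); the data do
not determine which is right, so both are exposed.

Map units composed of several soil components are composited as the
fraction-weighted mean of component stocks; the default variance rule is the
fraction-weighted mean of component variances, treating component stds as
measurement uncertainty rather than compositional spread (the full mixture
variance is available as ``variance_mode='mixture'``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CompositionError, DepthError, ValidationError
from .grid import GeoGrid, RasterField, require_alignment

_FRACTION_TOL = 1e-6


@dataclass(frozen=True)
class SoilLayerSpec:
    """One depth layer: [top, bottom) in metres below the surface."""

    top: float
    bottom: float

    def __post_init__(self):
        if not (self.bottom > self.top >= 0):
            raise ValidationError(f"need bottom > top >= 0, got [{self.top}, {self.bottom})")

    @property
    def thickness(self) -> float:
        return self.bottom - self.top


def layers_from_boundaries(bounds: Sequence[float]) -> list[SoilLayerSpec]:
    """Contiguous layers from a strictly increasing boundary list starting at 0."""
    b = list(bounds)
    if b[0] != 0:
        raise ValidationError("layer boundaries must start at 0")
    return [SoilLayerSpec(b[i], b[i + 1]) for i in range(len(b) - 1)]


# -- scalar / ufunc core ---------------------------------------------------


def layer_stock(cn, bulk, cfrag, hot):
    """Fine-earth areal stock (kg m-2) of one layer; broadcasts like a ufunc."""
    cn, bulk, cfrag, hot = (np.asarray(x, dtype=float) for x in (cn, bulk, cfrag, hot))
    _check_domain(cn, bulk, cfrag, hot)
    out = hot * cn * bulk * (1.0 - cfrag / 100.0)
    return out if out.ndim else float(out)


def layer_stock_std(cn, cn_std, bulk, bulk_std, cfrag, cfrag_std, hot):
    """First-order standard deviation (kg m-2) of :func:`layer_stock`."""
    arrs = [np.asarray(x, dtype=float)
            for x in (cn, cn_std, bulk, bulk_std, cfrag, cfrag_std, hot)]
    cn, cn_std, bulk, bulk_std, cfrag, cfrag_std, hot = arrs
    _check_domain(cn, bulk, cfrag, hot)
    for name, s in (("CN_std", cn_std), ("BULK_std", bulk_std), ("CFRAG_std", cfrag_std)):
        if np.any(s < 0):
            raise ValidationError(f"{name} must be non-negative")
    g = 1.0 - cfrag / 100.0
    var = (cn_std**2 * bulk**2 * g**2
           + cn**2 * bulk_std**2 * g**2
           + cn**2 * bulk**2 * (cfrag_std / 100.0) ** 2)
    out = hot * np.sqrt(var)
    return out if out.ndim else float(out)


def _check_domain(cn, bulk, cfrag, hot):
    if np.any(cn < 0):
        raise ValidationError("CN must be non-negative")
    if np.any(bulk <= 0):
        raise ValidationError("BULK must be positive")
    if np.any((cfrag < 0) | (cfrag > 100)):
        raise ValidationError("CFRAG must lie in [0, 100]")
    if np.any(hot <= 0):
        raise ValidationError("layer thickness must be positive")


def _layer_fractions(layers: Sequence[SoilLayerSpec], depth_target: float) -> np.ndarray:
    """Pro-rata fraction of each layer lying above *depth_target*."""
    if depth_target <= 0:
        raise DepthError(f"depth target must be positive, got {depth_target}")
    bottom = layers[-1].bottom
    if depth_target > bottom + 1e-12:
        raise DepthError(f"depth target {depth_target} m exceeds profile depth {bottom} m")
    return np.array([
        np.clip((depth_target - l.top) / l.thickness, 0.0, 1.0) for l in layers
    ])


# -- per-cell profiles -----------------------------------------------------


@dataclass
class CellProfile:
    """All six per-layer statistics for a single cell."""

    layers: list[SoilLayerSpec]
    cn: np.ndarray
    cn_std: np.ndarray
    bulk: np.ndarray
    bulk_std: np.ndarray
    cfrag: np.ndarray
    cfrag_std: np.ndarray

    def __post_init__(self):
        n = len(self.layers)
        for name in ("cn", "cn_std", "bulk", "bulk_std", "cfrag", "cfrag_std"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have one value per layer")
            setattr(self, name, arr)


def profile_stock(
    profile: CellProfile, depth_target: float, layer_mode: str = "independent"
) -> tuple[float, float]:
    """Stock mean and std (kg m-2) of one cell down to *depth_target* metres."""
    f = _layer_fractions(profile.layers, depth_target)
    hot = np.array([l.thickness for l in profile.layers])
    means = layer_stock(profile.cn, profile.bulk, profile.cfrag, hot)
    stds = layer_stock_std(profile.cn, profile.cn_std, profile.bulk, profile.bulk_std,
                           profile.cfrag, profile.cfrag_std, hot)
    mean = float(np.sum(f * means))
    std = _combine_layer_stds(f * stds, layer_mode)
    return mean, std


def _combine_layer_stds(scaled_stds: np.ndarray, layer_mode: str, axis=None) -> float:
    if layer_mode == "independent":
        return float(np.sqrt(np.sum(scaled_stds**2, axis=axis))) if axis is None \
            else np.sqrt(np.sum(scaled_stds**2, axis=axis))
    if layer_mode == "correlated":
        return float(np.sum(scaled_stds, axis=axis)) if axis is None \
            else np.sum(scaled_stds, axis=axis)
    raise ValidationError(f"unknown layer_mode {layer_mode!r}")


def composite_cell(
    components: Sequence[tuple[float, CellProfile]],
    depth_target: float,
    layer_mode: str = "independent",
    variance_mode: str = "mean_of_variances",
) -> tuple[float, float]:
    """Composite a map unit's soil components into one (mean, std) stock.

    *components* is a sequence of ``(area_fraction, CellProfile)``; fractions
    must sum to 1 within 1e-6.
    """
    fracs = np.array([f for f, _ in components], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > _FRACTION_TOL:
        raise CompositionError(
            f"component fractions must be >= 0 and sum to 1 (got sum {fracs.sum()!r})"
        )
    means, stds = zip(*(profile_stock(p, depth_target, layer_mode) for _, p in components))
    means, stds = np.array(means), np.array(stds)
    mean = float(np.sum(fracs * means))
    if variance_mode == "mean_of_variances":
        var = float(np.sum(fracs * stds**2))
    elif variance_mode == "mixture":
        var = float(np.sum(fracs * (stds**2 + means**2)) - mean**2)
    else:
        raise ValidationError(f"unknown variance_mode {variance_mode!r}")
    return mean, float(np.sqrt(max(var, 0.0)))


# -- raster cubes ----------------------------------------------------------


@dataclass
class LayerFields:
    """Six aligned rasters describing one layer of a soil property cube."""

    conc: RasterField
    conc_std: RasterField
    bulk: RasterField
    bulk_std: RasterField
    cfrag: RasterField
    cfrag_std: RasterField

    def all_fields(self) -> list[RasterField]:
        return [self.conc, self.conc_std, self.bulk, self.bulk_std,
                self.cfrag, self.cfrag_std]

    @property
    def valid(self) -> np.ndarray:
        m = self.conc.valid_mask
        for f in self.all_fields()[1:]:
            m = m & f.valid_mask
        return m


@dataclass
class SoilCube:
    """Layered per-cell soil statistics for one element on one grid."""

    element: str
    layers: list[SoilLayerSpec]
    fields: list[LayerFields]

    def __post_init__(self):
        if len(self.layers) != len(self.fields):
            raise ValidationError("one LayerFields entry per layer required")
        require_alignment([f for lf in self.fields for f in lf.all_fields()])

    @property
    def grid(self) -> GeoGrid:
        return self.fields[0].conc.grid


@dataclass
class ComponentTable:
    """Soil components of each map unit: per-component fraction raster + cube.

    Fractions must sum to 1 (within 1e-6) on every cell where all component
    fractions are valid.
    """

    components: list[tuple[RasterField, SoilCube]]

    def __post_init__(self):
        fields = [f for f, _ in self.components]
        require_alignment(fields + [c.fields[0].conc for _, c in self.components])
        valid = np.ones(fields[0].grid.shape, dtype=bool)
        total = np.zeros(fields[0].grid.shape)
        for f, _ in self.components:
            valid &= f.valid_mask
            total += np.where(f.valid_mask, f.values, 0.0)
        bad = valid & (np.abs(total - 1.0) > _FRACTION_TOL)
        if bad.any():
            raise CompositionError(
                f"component fractions do not sum to 1 on {int(bad.sum())} cells"
            )

    @property
    def grid(self) -> GeoGrid:
        return self.components[0][0].grid

    @property
    def element(self) -> str:
        return self.components[0][1].element


@dataclass
class StockMap:
    """Per-cell areal stock mean and std (kg m-2) for one element and depth."""

    element: str
    depth_m: float
    mean: RasterField
    std: RasterField


def _cube_target_arrays(cube: SoilCube, depth_target: float, layer_mode: str):
    """(mean, var-or-std accumulator, valid) arrays for one depth target."""
    f = _layer_fractions(cube.layers, depth_target)
    shape = cube.grid.shape
    mean = np.zeros(shape)
    acc = np.zeros(shape)  # sum of squares (independent) or sum (correlated)
    valid = np.ones(shape, dtype=bool)
    for frac, layer, lf in zip(f, cube.layers, cube.fields):
        if frac <= 0:
            continue
        lv = lf.valid
        valid &= lv
        cn = np.where(lv, lf.conc.values, 0.0)
        cns = np.where(lv, lf.conc_std.values, 0.0)
        bd = np.where(lv, lf.bulk.values, 1.0)
        bds = np.where(lv, lf.bulk_std.values, 0.0)
        cf = np.where(lv, lf.cfrag.values, 0.0)
        cfs = np.where(lv, lf.cfrag_std.values, 0.0)
        m = layer_stock(cn, bd, cf, layer.thickness)
        s = layer_stock_std(cn, cns, bd, bds, cf, cfs, layer.thickness)
        mean += frac * m
        acc += (frac * s) ** 2 if layer_mode == "independent" else frac * s
    if layer_mode == "independent":
        std = np.sqrt(acc)
    elif layer_mode == "correlated":
        std = acc
    else:
        raise ValidationError(f"unknown layer_mode {layer_mode!r}")
    return mean, std, valid


def cube_to_stockmaps(
    cube: SoilCube | ComponentTable,
    depth_targets: Sequence[float],
    layer_mode: str = "independent",
    variance_mode: str = "mean_of_variances",
) -> list[StockMap]:
    """Vectorized per-cell stocks for each depth target.

    Results equal the scalar operations applied cell-wise.  Nodata is
    absorbing per depth target: a cell is nodata for a target iff any layer
    that target needs has a nodata input (deeper layers do not matter).
    """
    single = isinstance(cube, SoilCube)
    grid = cube.grid
    out = []
    for depth in depth_targets:
        if single:
            mean, std, valid = _cube_target_arrays(cube, depth, layer_mode)
        else:
            mean = np.zeros(grid.shape)
            var = np.zeros(grid.shape)
            valid = np.ones(grid.shape, dtype=bool)
            comp_means = []
            for frac_field, comp_cube in cube.components:
                m, s, v = _cube_target_arrays(comp_cube, depth, layer_mode)
                fv = frac_field.valid_mask
                valid &= v & fv
                fr = np.where(fv, frac_field.values, 0.0)
                mean += fr * m
                var += fr * s**2
                comp_means.append((fr, m))
            if variance_mode == "mixture":
                var += sum(fr * m**2 for fr, m in comp_means) - mean**2
                var = np.maximum(var, 0.0)
            elif variance_mode != "mean_of_variances":
                raise ValidationError(f"unknown variance_mode {variance_mode!r}")
            std = np.sqrt(var)
        mvals = np.where(valid, mean, grid.nodata)
        svals = np.where(valid, std, grid.nodata)
        element = cube.element
        out.append(StockMap(
            element=element, depth_m=float(depth),
            mean=RasterField(grid, mvals, "kg m-2", f"{element}_stock_{depth}m"),
            std=RasterField(grid, svals, "kg m-2", f"{element}_stock_std_{depth}m"),
        ))
    return out
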