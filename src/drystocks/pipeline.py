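"""Configuration-driven orchestration: simulate -> zonate -> stocks -> summarize.

A run is fully described by a :class:`RunConfig` (YAML-loadable); every
source of randomness flows from its single master seed, so a rerun with the
same config reproduces all CSV/JSON outputs bit-exactly.  Each run writes a
manifest listing every output with a content hash, plus the resolved
configuration, the layer-error combination mode and the Earth radius used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accounting import (DEFAULT_REFERENCE_POOLS, compare_pool,
                         direct_content_stock, stoichiometric_ratio, zonal_stock)
from .errors import PipelineStageError, ValidationError
from .grid import AUTHALIC_RADIUS_KM, GeoGrid, cell_areas
from .raster_io import read_cube, read_raster, write_cube, write_raster
from .stocks import cube_to_stockmaps
from .synthetic import (ELEMENTS, GeneratorConfig, generate_aridity,
                        generate_land, generate_p_maps, generate_soil_cube,
                        true_stocks)
from .worked import worked_examples_report
from .zonation import (AridityScheme, classify_aridity, mask_to_code_raster,
                       stratum_areas)

log = logging.getLogger("drystocks")

RATIO_STRATA = ("hyperarid", "arid", "semiarid", "dry_subhumid", "dry", "humid", "global")


@dataclass
class RunConfig:
    """Resolved configuration of one accounting run."""

    cell_size: float = 2.0
    seed: int = 0
    elements: tuple = ELEMENTS
    depth_targets: tuple = (0.3, 1.0, 2.0)
    p_depth: float = 0.5
    ratio_depth: float = 0.5
    layer_mode: str = "independent"
    variance_mode: str = "mean_of_variances"
    aridity_bounds: tuple = (0.03, 0.20, 0.50, 0.65)
    radius_km: float = AUTHALIC_RADIUS_KM
    reference_pools: dict = field(default_factory=lambda: dict(DEFAULT_REFERENCE_POOLS))
    n_components: int = 1
    nodata_fraction: float = 0.02
    input_dir: str | None = None   # read simulated rasters instead of generating
    outdir: str = "drystocks_out"
    write_rasters: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        depths = tuple(float(d) for d in self.depth_targets)
        if not depths or any(d <= 0 for d in depths) or list(depths) != sorted(depths):
            raise ValidationError("depth targets must be positive and sorted")
        self.depth_targets = depths
        if not self.elements:
            raise ValidationError("at least one element is required")
        self.elements = tuple(self.elements)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["reference_pools"] = dict(self.reference_pools)
        return d

    @property
    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            grid=GeoGrid.global_grid(self.cell_size), seed=self.seed,
            n_components=self.n_components, nodata_fraction=self.nodata_fraction,
            radius_km=self.radius_km,
        )

    @property
    def scheme(self) -> AridityScheme:
        return AridityScheme(bounds=tuple(self.aridity_bounds))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def _write_json(obj, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


class _Stage:
    """Context wrapper that renames any stage failure with its stage."""

    def __init__(self, name: str, timings: dict):
        self.name, self.timings = name, timings

    def __enter__(self):
        self._t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.timings[self.name] = time.perf_counter() - self._t0
        if exc is not None and not isinstance(exc, PipelineStageError):
            raise PipelineStageError(self.name, str(exc)) from exc
        return False


def simulate_inputs(config: RunConfig, outdir: Path) -> dict:
    """Generate and write all synthetic inputs plus the truth table."""
    gc = config.generator_config
    rasters = outdir / "rasters"
    outputs = {}
    outputs["aridity"] = write_raster(generate_aridity(gc), rasters / "aridity.nc")
    outputs["land"] = write_raster(generate_land(gc), rasters / "land.nc")
    for element in config.elements:
        cube = generate_soil_cube(gc, element)
        if hasattr(cube, "components"):  # ComponentTable: write each component cube
            for c, (frac, comp) in enumerate(cube.components):
                outputs[f"{element}_comp{c}_fraction"] = write_raster(
                    frac, rasters / f"{element}_comp{c}_fraction.nc")
                outputs[f"{element}_comp{c}_manifest"] = write_cube(
                    dataclasses.replace(comp, element=f"{element}_comp{c}"),
                    rasters)
        else:
            outputs[f"{element}_manifest"] = write_cube(cube, rasters)
    for form, fld in generate_p_maps(gc).items():
        outputs[f"p_{form}"] = write_raster(fld, rasters / f"p_{form}.nc")
    truth = true_stocks(gc, config.depth_targets, config.p_depth, config.scheme)
    outputs["truth"] = _write_csv(truth, outdir / "truth.csv")
    return outputs


def _load_inputs(config: RunConfig):
    """Inputs either from a simulated-raster directory or generated in memory."""
    if config.input_dir is not None:
        d = Path(config.input_dir) / "rasters"
        ai = read_raster(d / "aridity.nc", "mm mm-1")
        land = read_raster(d / "land.nc", "flag")
        cubes = {e: read_cube(d / f"{e}_manifest.yaml") for e in config.elements}
        from .synthetic import P_FORMS
        p_maps = {f: read_raster(d / f"p_{f}.nc", "g m-2") for f in P_FORMS}
        p_maps["total_P"] = read_raster(d / "p_total_P.nc", "g m-2")
        return ai, land, cubes, p_maps
    gc = config.generator_config
    ai = generate_aridity(gc)
    land = generate_land(gc)
    cubes = {e: generate_soil_cube(gc, e) for e in config.elements}
    return ai, land, cubes, generate_p_maps(gc)


def run_pipeline(config: RunConfig) -> dict:
    """End-to-end run; returns the manifest (also written to the output dir)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log.info("resolved config: %s", json.dumps(config.resolved(), sort_keys=True))
    log.info("layer-error combination mode: %s; Earth radius: %s km",
             config.layer_mode, config.radius_km)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict = {}
    outputs: dict = {}

    with _Stage("inputs", timings):
        ai, land, cubes, p_maps = _load_inputs(config)
        if config.input_dir is None and config.write_rasters:
            outputs.update(simulate_inputs(config, outdir))

    with _Stage("zonation", timings):
        masks = classify_aridity(ai, config.scheme, land)
        areas = cell_areas(ai.grid, config.radius_km)
        outputs["stratum_areas"] = _write_csv(stratum_areas(masks, areas),
                                              outdir / "stratum_areas.csv")
        if config.write_rasters:
            outputs["stratum_codes"] = write_raster(
                mask_to_code_raster(masks), outdir / "rasters" / "stratum_codes.nc")

    with _Stage("stocks", timings):
        depths = tuple(sorted(set(config.depth_targets) | {config.ratio_depth}))
        stockmaps = {e: cube_to_stockmaps(cubes[e], depths, config.layer_mode,
                                          config.variance_mode)
                     for e in config.elements}

    with _Stage("summarize", timings):
        frames = [zonal_stock(sm, masks, areas)
                  for e in config.elements for sm in stockmaps[e]
                  if sm.depth_m in config.depth_targets]
        summary = pd.concat(frames, ignore_index=True)
        outputs["zonal_summary"] = _write_csv(summary, outdir / "zonal_summary.csv")

        p_frames = [direct_content_stock(fld, masks, areas, name, config.p_depth)
                    for name, fld in p_maps.items()]
        p_summary = pd.concat(p_frames, ignore_index=True)
        outputs["p_summary"] = _write_csv(p_summary, outdir / "p_summary.csv")

        outputs["ratios"] = _write_json(
            _ratio_report(config, masks, areas, stockmaps, p_summary),
            outdir / "ratios.json")
        outputs["pool_comparisons"] = _write_json(
            _pool_report(config, summary), outdir / "pool_comparisons.json")

    with _Stage("verify", timings):
        report = worked_examples_report(config.reference_pools)
        outputs["worked_examples"] = _write_csv(report, outdir / "worked_examples.csv")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": config.resolved(),
        "layer_mode": config.layer_mode,
        "radius_km": config.radius_km,
        "timings_s": timings,
        "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                    for k, p in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _ratio_report(config: RunConfig, masks, areas, stockmaps: dict,
                  p_summary: pd.DataFrame) -> dict:
    """Stratum C:N:P mass ratios (normalized to P = 1) at the ratio depth."""
    depth = config.ratio_depth
    c_maps = [sm for sm in stockmaps.get("organic_C", []) if sm.depth_m == depth]
    n_maps = [sm for sm in stockmaps.get("total_N", []) if sm.depth_m == depth]
    if not c_maps or not n_maps:
        return {}
    c_df = zonal_stock(c_maps[0], masks, areas).set_index("stratum")
    n_df = zonal_stock(n_maps[0], masks, areas).set_index("stratum")
    p_df = p_summary[p_summary.element == "total_P"].set_index("stratum")
    out: dict = {"depth_m": depth}
    for stratum in RATIO_STRATA:
        p_pg = float(p_df.loc[stratum, "stock_Pg"])
        if not p_pg > 0:
            continue
        r = stoichiometric_ratio(float(c_df.loc[stratum, "stock_Pg"]),
                                 float(n_df.loc[stratum, "stock_Pg"]), p_pg)
        out[stratum] = {"C": r.c_to_p, "N": r.n_to_p, "P": 1.0,
                        "formatted": r.formatted()}
    return out


def _pool_report(config: RunConfig, summary: pd.DataFrame) -> dict:
    """Dryland C stocks at the deepest target vs the reference pools."""
    depth = max(config.depth_targets)
    out = {}
    for element in ("organic_C", "inorganic_C"):
        row = summary[(summary.stratum == "dry") & (summary.element == element)
                      & (summary.depth_m == depth)]
        if row.empty:
            continue
        subject = float(row.stock_Pg.iloc[0])
        for pool, value in config.reference_pools.items():
            cmp = compare_pool(subject, value, pool)
            out[f"dry_{element}_{depth}m_vs_{pool}"] = {
                "subject_Pg": subject, "reference_Pg": value,
                "percent_signed": cmp.percent, "phrase": cmp.phrase(),
            }
    return out
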