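"""Synthetic global soil world with known analytic truth.

Generates WISE30sec-like inputs — an aridity-index field, layered soil
property cubes (concentration, bulk density, coarse fragments, each with a
per-cell std field), direct areal P-form maps, a land mask and optional
map-unit component tables — from a single master seed, so every downstream
accounting stage can be tested against a closed-form expectation without
any external download.

Statistical structure emulated (and its defaults):

* The aridity trend is a longitude-indexed quantile curve calibrated so the
  dryland subtypes occupy ~5.8 / 14.0 / 16.1 / 8.9 % of land and drylands
  ~45% in total, with multiplicative lognormal noise on top.
* Organic C and total N concentrations increase with AI (wetter = richer),
  inorganic (carbonate) C and total P decrease with AI, all through
  saturating exponential curves; organic pools decay with depth, carbonate
  accumulates slightly.
* Between-cell dispersion is mean-preserving lognormal for concentrations
  and bulk density (positive support) and logit-normal for the
  coarse-fragment fraction (support (0, 100)%).
* Within-cell uncertainty fields are proportional to the realized value
  (std = relative-std x value), the simplest faithful emulation of a
  database that publishes per-unit standard deviations.
* Inorganic C is supplied directly as an equivalent-C concentration in
  g kg-1 (the CaCO3 % to carbonate-C conversion, factor 0.12, is a
  generator-side concern; the stock engine is element-agnostic).

Every product is a pure function of (config, seed): each product draws from
its own label-derived substream, so adding products never perturbs existing
ones.

``true_stocks`` returns the analytic expectation of the accounting
pipeline's per-stratum totals under the generator's mean fields.  Lognormal
dispersions are mean-preserving, so their expectation is the mean field
itself; the logit-normal coarse-fragment expectation has no closed form and
is evaluated by deterministic Gauss-Hermite quadrature.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import AUTHALIC_RADIUS_KM, GeoGrid, RasterField, cell_areas
from .stocks import ComponentTable, LayerFields, SoilCube, layers_from_boundaries
from .zonation import DRY_SUBTYPES, AridityScheme, classify_aridity

ELEMENTS = ("organic_C", "inorganic_C", "total_N")
P_FORMS = ("labile_inorganic", "organic", "occluded", "secondary_mineral", "apatite")

#: WISE30sec-convention layer boundaries: seven layers to 2 m depth.
DEFAULT_LAYER_BOUNDARIES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.5, 2.0)

#: AI quantile nodes (cumulative land fraction -> AI) calibrated to the
#: observed dryland subtype shares 5.8/14.0/16.1/8.9 % of land.
DEFAULT_AI_NODES = ((0.0, 0.0), (0.058, 0.03), (0.198, 0.20),
                    (0.359, 0.50), (0.448, 0.65), (1.0, 3.0))


@dataclass(frozen=True)
class ElementModel:
    """Mean-vs-AI curve and dispersion parameters for one element.

    The concentration mean is a saturating function of AI,
    ``lo + (hi - lo) * (1 - exp(-AI/tau))`` when increasing with AI
    (organic C, N) and its mirror when decreasing (carbonate C), times a
    depth factor ``exp(-depth_rate * z_mid)`` (negative rate = accumulation
    at depth).  ``cv`` is the between-cell lognormal sigma; ``rel_std`` the
    within-cell uncertainty as a fraction of the value.
    """

    lo: float       # g kg-1 at the dry end of the curve
    hi: float       # g kg-1 at the wet end
    tau: float      # AI scale of the saturating curve
    increasing: bool
    depth_rate: float
    cv: float = 0.25
    rel_std: float = 0.35

    def mean_conc(self, ai: np.ndarray, z_mid: float) -> np.ndarray:
        s = 1.0 - np.exp(-np.asarray(ai) / self.tau)
        base = self.lo + (self.hi - self.lo) * s if self.increasing \
            else self.hi - (self.hi - self.lo) * s
        return base * np.exp(-self.depth_rate * z_mid)


DEFAULT_ELEMENT_MODELS = {
    "organic_C": ElementModel(lo=4.0, hi=30.0, tau=0.6, increasing=True, depth_rate=1.2),
    "total_N": ElementModel(lo=0.5, hi=2.5, tau=0.35, increasing=True, depth_rate=1.2,
                            cv=0.20, rel_std=0.30),
    "inorganic_C": ElementModel(lo=0.3, hi=10.0, tau=0.4, increasing=False,
                                depth_rate=-0.25, cv=0.30, rel_std=0.40),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the synthetic world depends on; defaults are the study conditions."""

    grid: GeoGrid = field(default_factory=lambda: GeoGrid.global_grid(2.0))
    seed: int = 0
    land_fraction: float = 0.30
    ai_nodes: tuple = DEFAULT_AI_NODES
    ai_noise_sigma: float = 0.15
    ai_max: float = 3.0
    nodata_fraction: float = 0.02
    layer_boundaries: tuple = DEFAULT_LAYER_BOUNDARIES
    n_components: int = 1
    component_cv: float = 0.10
    elements: dict = field(default_factory=lambda: dict(DEFAULT_ELEMENT_MODELS))
    # shared physical fields
    bulk_hi: float = 1.58        # g cm-3 at the dry end
    bulk_amp: float = 0.25       # drop toward the wet end
    bulk_tau: float = 0.5
    bulk_depth_slope: float = 0.05  # g cm-3 per metre
    bulk_cv: float = 0.05
    bulk_rel_std: float = 0.10
    cfrag_hi: float = 25.0       # % at the dry end
    cfrag_lo: float = 10.0       # % at the wet end
    cfrag_tau: float = 0.5
    cfrag_logit_sigma: float = 0.30
    cfrag_rel_std: float = 0.20
    # phosphorus (areal content to 0.5 m)
    p_total_hi: float = 450.0    # g m-2 at the dry end
    p_total_lo: float = 230.0    # g m-2 at the wet end
    p_tau: float = 0.5
    p_cv: float = 0.15
    radius_km: float = AUTHALIC_RADIUS_KM

    def __post_init__(self):
        if not (0 <= self.nodata_fraction < 1):
            raise ValidationError("nodata_fraction must lie in [0, 1)")
        b = np.asarray(self.layer_boundaries)
        if b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ValidationError("layer boundaries must increase strictly from 0")
        for p in (self.ai_noise_sigma, self.bulk_cv, self.cfrag_logit_sigma, self.p_cv,
                  self.component_cv):
            if p < 0:
                raise ValidationError("dispersion parameters must be >= 0")
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")


def _rng(config: GeneratorConfig, label: str) -> np.random.Generator:
    """Independent, label-stable substream of the master seed."""
    h = int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([config.seed, h]))


def _lognormal_factor(rng, sigma: float, shape) -> np.ndarray:
    """Mean-preserving multiplicative lognormal noise (E[factor] = 1)."""
    if sigma == 0:
        return np.ones(shape)
    return np.exp(sigma * rng.standard_normal(shape) - 0.5 * sigma**2)


def _nodata_mask(config: GeneratorConfig, label: str) -> np.ndarray:
    if config.nodata_fraction == 0:
        return np.zeros(config.grid.shape, dtype=bool)
    return _rng(config, label).random(config.grid.shape) < config.nodata_fraction


# -- generators ------------------------------------------------------------


def generate_land(config: GeneratorConfig) -> RasterField:
    """0/1 land-mask raster; land cells drawn i.i.d. at ``land_fraction``."""
    vals = (_rng(config, "land").random(config.grid.shape)
            < config.land_fraction).astype(float)
    return RasterField(config.grid, vals, units="flag", name="land")


def _ai_trend(config: GeneratorConfig) -> np.ndarray:
    x = (np.arange(config.grid.n_cols) + 0.5) / config.grid.n_cols
    qx, qv = zip(*config.ai_nodes)
    trend_row = np.interp(x, qx, qv)
    return np.broadcast_to(trend_row, config.grid.shape).copy()


def generate_aridity(config: GeneratorConfig) -> RasterField:
    """Aridity-index raster (mm mm-1), deterministic under the master seed."""
    trend = _ai_trend(config)
    noise = _lognormal_factor(_rng(config, "ai/noise"), config.ai_noise_sigma,
                              config.grid.shape)
    ai = np.clip(trend * noise, 0.0, config.ai_max)
    ai[_nodata_mask(config, "ai/nodata")] = config.grid.nodata
    return RasterField(config.grid, ai, units="mm mm-1", name="aridity_index")


def _mean_bulk(config: GeneratorConfig, ai: np.ndarray, z_mid: float) -> np.ndarray:
    s = 1.0 - np.exp(-np.asarray(ai) / config.bulk_tau)
    return config.bulk_hi - config.bulk_amp * s + config.bulk_depth_slope * z_mid


def _mean_cfrag(config: GeneratorConfig, ai: np.ndarray) -> np.ndarray:
    s = 1.0 - np.exp(-np.asarray(ai) / config.cfrag_tau)
    return config.cfrag_hi - (config.cfrag_hi - config.cfrag_lo) * s


def _valid_cells(config: GeneratorConfig, ai_values: np.ndarray,
                 element_label: str) -> np.ndarray:
    """Cells where an element cube has data: valid AI and not element-nodata."""
    return (ai_values != config.grid.nodata) & ~_nodata_mask(
        config, f"{element_label}/nodata")


def _realized_shared_fields(config: GeneratorConfig, ai: np.ndarray, layer_idx: int,
                            z_mid: float):
    """Bulk density and coarse fragments, shared by all element cubes."""
    shape = config.grid.shape
    m_bulk = _mean_bulk(config, ai, z_mid)
    bulk = m_bulk * _lognormal_factor(_rng(config, f"bulk/{layer_idx}"),
                                      config.bulk_cv, shape)
    p = _mean_cfrag(config, ai) / 100.0
    if config.cfrag_logit_sigma > 0:
        z = _rng(config, f"cfrag/{layer_idx}").standard_normal(shape)
        logit = np.log(p / (1.0 - p)) + config.cfrag_logit_sigma * z
        p = 1.0 / (1.0 + np.exp(-logit))
    return bulk, 100.0 * p


def generate_soil_cube(config: GeneratorConfig, element: str):
    """Layered property cube (or ComponentTable if n_components > 1) for one element."""
    if element not in config.elements:
        raise ValidationError(
            f"unknown element {element!r}; known: {sorted(config.elements)}")
    model = config.elements[element]
    grid = config.grid
    ai_field = generate_aridity(config)
    ai = np.where(ai_field.valid_mask, ai_field.values, 0.0)
    valid = _valid_cells(config, ai_field.values, element)
    layers = layers_from_boundaries(config.layer_boundaries)

    def build_fields(conc_label_suffix: str) -> list[LayerFields]:
        fields = []
        for i, layer in enumerate(layers):
            z_mid = 0.5 * (layer.top + layer.bottom)
            m_conc = model.mean_conc(ai, z_mid)
            conc = m_conc * _lognormal_factor(
                _rng(config, f"{element}/conc/{i}"), model.cv, grid.shape)
            if conc_label_suffix:
                conc = conc * _lognormal_factor(
                    _rng(config, f"{element}/{conc_label_suffix}/{i}"),
                    config.component_cv, grid.shape)
            bulk, cfrag = _realized_shared_fields(config, ai, i, z_mid)

            def fld(vals, units, name):
                return RasterField(grid, np.where(valid, vals, grid.nodata), units, name)

            fields.append(LayerFields(
                conc=fld(conc, "g kg-1", f"{element}_conc_{i}"),
                conc_std=fld(model.rel_std * conc, "g kg-1", f"{element}_conc_std_{i}"),
                bulk=fld(bulk, "g cm-3", f"bulk_{i}"),
                bulk_std=fld(config.bulk_rel_std * bulk, "g cm-3", f"bulk_std_{i}"),
                cfrag=fld(cfrag, "%", f"cfrag_{i}"),
                cfrag_std=fld(config.cfrag_rel_std * cfrag, "%", f"cfrag_std_{i}"),
            ))
        return fields

    if config.n_components == 1:
        return SoilCube(element=element, layers=layers, fields=build_fields(""))

    k = config.n_components
    fracs = _rng(config, f"{element}/fractions").dirichlet(np.ones(k),
                                                           size=grid.shape)
    components = []
    for c in range(k):
        fvals = np.where(valid, fracs[..., c], grid.nodata)
        frac_field = RasterField(grid, fvals, units="fraction",
                                 name=f"{element}_component_{c}_fraction")
        cube = SoilCube(element=element, layers=layers,
                        fields=build_fields(f"comp{c}"))
        components.append((frac_field, cube))
    return ComponentTable(components=components)


def generate_p_maps(config: GeneratorConfig) -> dict[str, RasterField]:
    """Six areal P-content rasters (g m-2 to 0.5 m): five forms plus their total.

    The total is the cell-wise sum of the five forms by construction.  The
    total-P mean decreases with AI (dryland soils are P-richer); labile
    inorganic and apatite shares shrink toward the wet end while organic,
    occluded and secondary-mineral shares grow.
    """
    grid = config.grid
    ai_field = generate_aridity(config)
    ai = np.where(ai_field.valid_mask, ai_field.values, 0.0)
    valid = _valid_cells(config, ai_field.values, "p")
    total_mean, shares = _p_means(config, ai)
    out: dict[str, RasterField] = {}
    total = np.zeros(grid.shape)
    for form in P_FORMS:
        vals = shares[form] * total_mean * _lognormal_factor(
            _rng(config, f"p/{form}"), config.p_cv, grid.shape)
        total += vals
        out[form] = RasterField(grid, np.where(valid, vals, grid.nodata),
                                units="g m-2", name=f"p_{form}")
    out["total_P"] = RasterField(grid, np.where(valid, total, grid.nodata),
                                 units="g m-2", name="p_total")
    return out


def _p_means(config: GeneratorConfig, ai: np.ndarray):
    wet = 1.0 - np.exp(-np.asarray(ai) / config.p_tau)
    total_mean = config.p_total_hi - (config.p_total_hi - config.p_total_lo) * wet
    raw = {
        "labile_inorganic": 0.06 + 0.06 * (1.0 - wet),
        "apatite": 0.22 + 0.20 * (1.0 - wet),
        "organic": 0.14 + 0.14 * wet,
        "occluded": 0.18 + 0.10 * wet,
        "secondary_mineral": 0.12 + 0.08 * wet,
    }
    norm = sum(raw.values())
    return total_mean, {k: v / norm for k, v in raw.items()}


# -- analytic truth --------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(41)


def _expected_fine_earth(config: GeneratorConfig, ai: np.ndarray) -> np.ndarray:
    """E[1 - CFRAG/100] under the logit-normal dispersion (Gauss-Hermite)."""
    p = _mean_cfrag(config, ai) / 100.0
    if config.cfrag_logit_sigma == 0:
        return 1.0 - p
    logit = np.log(p / (1.0 - p))
    acc = np.zeros_like(p)
    s = config.cfrag_logit_sigma
    for x, w in zip(_GH_NODES, _GH_WEIGHTS):
        acc += w / (1.0 + np.exp(-(logit + np.sqrt(2.0) * s * x)))
    return 1.0 - acc / np.sqrt(np.pi)


def true_stocks(config: GeneratorConfig,
                depth_targets=(0.3, 1.0, 2.0),
                p_depth: float = 0.5,
                scheme: AridityScheme | None = None) -> pd.DataFrame:
    """Analytic expectation of per-stratum totals under the generator's means.

    Returns a tidy frame (stratum, element, depth_m, stock_Pg) covering the
    three soil-cube elements at the depth targets plus total P (and its five
    forms) at ``p_depth``.  Nodata cells are excluded exactly as the
    accounting pipeline excludes them; the dry row is the sum of the four
    subtype rows and global is dry + humid by construction.
    """
    grid = config.grid
    ai_field = generate_aridity(config)
    land = generate_land(config)
    masks = classify_aridity(ai_field, scheme or AridityScheme(), land)
    ai = np.where(ai_field.valid_mask, ai_field.values, 0.0)
    a_m2 = cell_areas(grid, config.radius_km).areas_m2
    layers = layers_from_boundaries(config.layer_boundaries)
    e_fine = {}
    rows = []

    def stratum_sums(content: np.ndarray, valid: np.ndarray, element: str,
                     depth: float, mass_per_pg: float):
        sub = {s: float(np.sum(content[masks[s] & valid] * a_m2[masks[s] & valid]))
               / mass_per_pg for s in DRY_SUBTYPES}
        humid = float(np.sum(content[masks["humid"] & valid]
                             * a_m2[masks["humid"] & valid])) / mass_per_pg
        dry = sum(sub.values())
        for s in DRY_SUBTYPES:
            rows.append((s, element, depth, sub[s]))
        rows.append(("dry", element, depth, dry))
        rows.append(("humid", element, depth, humid))
        rows.append(("global", element, depth, dry + humid))

    for element, model in config.elements.items():
        valid = _valid_cells(config, ai_field.values, element)
        e_layer = []
        for layer in layers:
            z_mid = 0.5 * (layer.top + layer.bottom)
            key = round(z_mid, 6)
            if key not in e_fine:
                e_fine[key] = _expected_fine_earth(config, ai)
            e_layer.append(layer.thickness * model.mean_conc(ai, z_mid)
                           * _mean_bulk(config, ai, z_mid) * e_fine[key])
        for depth in depth_targets:
            f = [np.clip((depth - l.top) / l.thickness, 0.0, 1.0) for l in layers]
            content = sum(fi * ei for fi, ei in zip(f, e_layer))
            stratum_sums(content, valid, element, float(depth), 1e12)

    total_mean, shares = _p_means(config, ai)
    p_valid = _valid_cells(config, ai_field.values, "p")
    for form in P_FORMS:
        stratum_sums(shares[form] * total_mean, p_valid, f"p_{form}", p_depth, 1e15)
    stratum_sums(total_mean, p_valid, "total_P", p_depth, 1e15)

    return pd.DataFrame(rows, columns=["stratum", "element", "depth_m", "stock_Pg"])
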