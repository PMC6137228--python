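"""Zonal aggregation of stock maps and derived reporting.

Per-stratum totals follow "content times area": the stock of a stratum is
the sum over its cells of areal content (kg m-2) times spherical cell area,
expressed in Pg (1 Pg = 1e15 g = 1e12 kg).  Standard deviations aggregate
under the assumption that estimation errors are spatially uncorrelated,

    std(stratum) = sqrt( sum_cells (area * stock_std)^2 ),

which makes the stratum std invariant under any partition-then-recombine of
its cells.  Because errors largely cancel in the sum, these aggregate stds
are small; with spatially correlated errors they would be much larger, and
a correlated aggregation hook is deliberately left out of default scope.

Shares and pool comparisons are rounded half-up to integers for report
phrasing; raw values are always kept alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .grid import CellAreaField, RasterField
from .stocks import StockMap
from .zonation import DRY_SUBTYPES, StratumMask

KG_PER_PG = 1e12
G_PER_PG = 1e15

#: Reference C pools (Pg) used in Discussion-style comparisons; overridable.
DEFAULT_REFERENCE_POOLS = {"vegetation": 520.0, "atmosphere": 829.0, "permafrost": 1035.0}

SUMMARY_COLUMNS = ["stratum", "element", "depth_m", "stock_Pg", "std_Pg",
                   "mean_content_kg_m2", "q1", "median", "q3",
                   "area_Mkm2", "nodata_area_Mkm2", "empty"]


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (report convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _check_aligned(*objs):
    ref = objs[0].grid
    for o in objs[1:]:
        if not ref.aligned_with(o.grid):
            raise AlignmentError("inputs are not on the same grid")


def _stratum_rows(content, std, valid, masks: StratumMask, areas: CellAreaField,
                  element: str, depth_m: float, mass_per_pg: float) -> pd.DataFrame:
    """Aggregate one content field over all report strata (incl. dry, global)."""
    a_m2 = areas.areas_m2
    a_mkm2 = areas.areas / 1e6
    rows = []
    report_masks = {s: masks[s] for s in DRY_SUBTYPES + ("dry", "humid")}
    report_masks["global"] = masks.classified
    for stratum, smask in report_masks.items():
        sel = smask & valid
        empty = not sel.any()
        total = float(np.sum(content[sel] * a_m2[sel])) / mass_per_pg
        if std is None:
            std_pg = np.nan
        else:
            std_pg = float(np.sqrt(np.sum((a_m2[sel] * std[sel]) ** 2))) / mass_per_pg
        area = float(a_mkm2[sel].sum())
        nodata_area = float(a_mkm2[smask & ~valid].sum())
        if empty:
            q1 = med = q3 = mean_content = np.nan
        else:
            mean_content = total * mass_per_pg / (area * 1e12)
            q1, med, q3 = np.percentile(content[sel], [25, 50, 75])
        rows.append((stratum, element, depth_m, total, std_pg, mean_content,
                     q1, med, q3, area, nodata_area, empty))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def zonal_stock(stockmap: StockMap, masks: StratumMask, areas: CellAreaField) -> pd.DataFrame:
    """Per-stratum total stock and std (Pg) of one stock map.

    Every row (including dry and global) is aggregated directly from its own
    mask; nodata cells are excluded and their area reported separately.
    Empty strata yield zero totals flagged in the ``empty`` column.
    """
    _check_aligned(stockmap.mean, stockmap.std, areas)
    if not stockmap.mean.grid.aligned_with(masks.grid):
        raise AlignmentError("stock map and stratum masks are not aligned")
    valid = stockmap.mean.valid_mask & stockmap.std.valid_mask
    return _stratum_rows(stockmap.mean.values, stockmap.std.values, valid, masks,
                         areas, stockmap.element, stockmap.depth_m, KG_PER_PG)


def direct_content_stock(content: RasterField, masks: StratumMask, areas: CellAreaField,
                         element: str, depth_m: float) -> pd.DataFrame:
    """Per-stratum totals of a direct areal-content map (g m-2), e.g. the P forms.

    Same aggregation as :func:`zonal_stock` but without the profile step and
    with no std column (these maps carry no uncertainty layer).
    """
    _check_aligned(content, areas)
    if not content.grid.aligned_with(masks.grid):
        raise AlignmentError("content map and stratum masks are not aligned")
    return _stratum_rows(content.values, None, content.valid_mask, masks,
                         areas, element, depth_m, G_PER_PG)


def share_percent(part: float, whole: float) -> float:
    """100 * part / whole; summaries print it rounded, full precision is kept."""
    if not (whole > 0):
        raise ValidationError(f"whole must be positive, got {whole}")
    return 100.0 * part / whole


@dataclass
class PoolComparison:
    """Signed percent difference of a stock against a reference pool."""

    subject_pg: float
    reference_pg: float
    reference_name: str = ""
    percent: float = field(init=False)

    def __post_init__(self):
        if not (self.reference_pg > 0):
            raise ValidationError(f"reference pool must be positive, got {self.reference_pg}")
        self.percent = 100.0 * (self.subject_pg - self.reference_pg) / self.reference_pg

    @property
    def direction(self) -> str:
        if self.percent > 0:
            return "greater"
        return "smaller" if self.percent < 0 else "equal"

    @property
    def magnitude_percent(self) -> float:
        return abs(self.percent)

    def phrase(self) -> str:
        if self.direction == "equal":
            return "equal to"
        return f"{round_half_up(self.magnitude_percent)}% {self.direction} than"


def compare_pool(subject: float, reference: float, name: str = "") -> PoolComparison:
    return PoolComparison(subject, reference, name)


@dataclass
class StoichiometricRatio:
    """Element mass ratio normalized to P = 1, formatted ``C:N:P``."""

    c_to_p: float
    n_to_p: float

    def formatted(self) -> str:
        return f"{self.c_to_p:.0f}:{self.n_to_p:.1f}:1"


def stoichiometric_ratio(c_pg: float, n_pg: float, p_pg: float) -> StoichiometricRatio:
    if not (p_pg > 0):
        raise ValidationError(f"P stock must be positive, got {p_pg}")
    return StoichiometricRatio(c_pg / p_pg, n_pg / p_pg)


def zonal_class_composition(classes: RasterField, masks: StratumMask,
                            areas: CellAreaField) -> pd.DataFrame:
    """Area share (%) of each integer class code within each stratum.

    Shares sum to 100% of the classified (valid-class) area per stratum.
    """
    _check_aligned(classes, areas)
    if not classes.grid.aligned_with(masks.grid):
        raise AlignmentError("class map and stratum masks are not aligned")
    valid = classes.valid_mask
    a = areas.areas
    rows = []
    report_masks = {s: masks[s] for s in DRY_SUBTYPES + ("dry", "humid")}
    for stratum, smask in report_masks.items():
        sel = smask & valid
        total = float(a[sel].sum())
        if total == 0:
            continue
        codes = np.unique(classes.values[sel]).astype(int)
        for code in codes:
            share = 100.0 * float(a[sel & (classes.values == code)].sum()) / total
            rows.append((stratum, code, share))
    return pd.DataFrame(rows, columns=["stratum", "class", "area_pct"])
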