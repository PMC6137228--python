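"""Aridity-index zonation.

The aridity index (AI) is the ratio of mean annual precipitation to
potential evapotranspiration (mm mm-1).  Land is stratified into hyperarid
(AI < 0.03), arid (0.03 <= AI < 0.20), semiarid (0.20 <= AI < 0.50),
dry subhumid (0.50 <= AI < 0.65) and humid (AI >= 0.65); "dry" is the union
of the first four.  Interval semantics are half-open exactly as written, so
AI = 0.03 is arid and AI = 0.65 is humid.  Thresholds are data, not code:
alternative atlas boundaries can be swapped in through the scheme object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import CellAreaField, GeoGrid, RasterField, require_alignment

DRY_SUBTYPES = ("hyperarid", "arid", "semiarid", "dry_subhumid")
STRATA = DRY_SUBTYPES + ("dry", "humid")
#: byte codes used in the exported classification raster
STRATUM_CODES = {"none": 0, "hyperarid": 1, "arid": 2, "semiarid": 3,
                 "dry_subhumid": 4, "humid": 5}


@dataclass(frozen=True)
class AridityScheme:
    """Ordered AI class boundaries partitioning [0, inf)."""

    bounds: tuple[float, ...] = (0.03, 0.20, 0.50, 0.65)
    names: tuple[str, ...] = DRY_SUBTYPES + ("humid",)

    def __post_init__(self):
        b = np.asarray(self.bounds)
        if len(self.bounds) + 1 != len(self.names):
            raise ValidationError("need one more class name than boundary")
        if np.any(np.diff(b) <= 0) or b[0] <= 0:
            raise ValidationError("boundaries must be strictly increasing and positive")

    def classify_values(self, ai: np.ndarray) -> np.ndarray:
        """Class index 0..len(bounds) with half-open [lo, hi) intervals."""
        return np.digitize(ai, self.bounds, right=False)


@dataclass
class StratumMask:
    """Boolean per-stratum masks derived from an AI field and a land mask.

    The four dryland subtype masks are pairwise disjoint and their union is
    the ``dry`` mask; ``dry`` and ``humid`` together cover exactly the
    classified land cells.  Cells that are non-land or have nodata AI belong
    to no stratum; land cells with nodata AI are tracked as ``unclassified``.
    """

    grid: GeoGrid
    masks: dict = field(default_factory=dict)
    land: np.ndarray | None = None
    unclassified: np.ndarray | None = None

    @property
    def classified(self) -> np.ndarray:
        return self.masks["dry"] | self.masks["humid"]

    def __getitem__(self, stratum: str) -> np.ndarray:
        return self.masks[stratum]


def classify_aridity(
    ai: RasterField, scheme: AridityScheme | None = None, land: RasterField | None = None
) -> StratumMask:
    """Stratify an AI raster into the dryland subtypes plus humid.

    ``land`` is a 0/1 raster; omitted, every cell counts as land.  Negative
    valid AI values are rejected with the offending cell count.
    """
    scheme = scheme or AridityScheme()
    fields = [ai] + ([land] if land is not None else [])
    require_alignment(fields)
    ai_valid = ai.valid_mask
    if land is not None:
        land_mask = land.valid_mask & (land.values > 0)
    else:
        land_mask = np.ones(ai.grid.shape, dtype=bool)
    n_neg = int(np.sum(ai_valid & (ai.values < 0)))
    if n_neg:
        raise ValidationError(f"{n_neg} cells have negative aridity index")

    usable = ai_valid & land_mask
    cls = scheme.classify_values(ai.values)
    masks = {}
    for i, name in enumerate(scheme.names):
        masks[name] = usable & (cls == i)
    masks["dry"] = usable & (cls < len(scheme.bounds))
    return StratumMask(
        grid=ai.grid, masks=masks, land=land_mask,
        unclassified=land_mask & ~ai_valid,
    )


def stratum_areas(mask: StratumMask, areas: CellAreaField) -> pd.DataFrame:
    """Area (Mkm^2) and share of classified land per stratum.

    The dry row is the sum of the four subtype rows (exact), land is
    dry + humid (exact); land cells with nodata AI appear as an
    ``unclassified`` row outside the percentage base.
    """
    if not mask.grid.aligned_with(areas.grid):
        from .errors import AlignmentError

        raise AlignmentError("mask and area grids are not aligned")
    a = areas.areas / 1e6  # km^2 -> Mkm^2
    subtype_areas = {s: float(a[mask[s]].sum()) for s in DRY_SUBTYPES}
    dry = sum(subtype_areas.values())
    humid = float(a[mask["humid"]].sum())
    land = dry + humid
    rows = []
    for s in DRY_SUBTYPES:
        rows.append((s, subtype_areas[s], 100.0 * subtype_areas[s] / land if land else np.nan))
    rows.append(("dry", dry, 100.0 * dry / land if land else np.nan))
    rows.append(("humid", humid, 100.0 * humid / land if land else np.nan))
    rows.append(("land", land, 100.0 if land else np.nan))
    uncl = float(a[mask.unclassified].sum()) if mask.unclassified is not None else 0.0
    rows.append(("unclassified", uncl, np.nan))
    return pd.DataFrame(rows, columns=["stratum", "area_Mkm2", "pct_of_land"])


def mask_to_code_raster(mask: StratumMask) -> RasterField:
    """Byte-coded classification raster: 0 none, 1..4 dryland subtypes, 5 humid."""
    codes = np.zeros(mask.grid.shape)
    for s in DRY_SUBTYPES + ("humid",):
        codes[mask[s]] = STRATUM_CODES[s]
    return RasterField(mask.grid, codes, units="class", name="stratum_code")
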