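"""Worked-arithmetic verification against the published dryland inventory.

The published global inventory (organic C, inorganic C and total N stocks
per aridity stratum at three depths, plus area shares and reference-pool
comparisons) contains arithmetic that this package's accounting operations
must reproduce from the printed constants alone: subtype stocks summing to
the dry total, dry + humid summing to the global total, the dryland share
of each global pool, and the percent comparisons of dryland C against the
vegetation, atmosphere and permafrost pools.

Printed values are rounded, so sums of printed addends may be off by up to
half a printed unit per addend; each sum check uses exactly that tolerance.
Share and comparison checks round half-up to the integer precision the
inventory prints (the dryland inorganic-C share is printed as "about 80%",
i.e. to the nearest ten).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .accounting import (DEFAULT_REFERENCE_POOLS, compare_pool, round_half_up,
                         share_percent)

#: Published land-area shares of the dryland subtypes (% of global land).
SUBTYPE_AREA_SHARES = {"hyperarid": 5.8, "arid": 14.0, "semiarid": 16.1,
                       "dry_subhumid": 8.9}
#: ... and the printed total dryland share they round to.
PRINTED_DRY_AREA_SHARE = 45

_DRY_SUBTYPES = ("hyperarid", "arid", "semiarid", "dry_subhumid")


def load_reference_stocks() -> pd.DataFrame:
    """The published stratum x element x depth stock table (Pg, as printed)."""
    with resources.files("drystocks.data").joinpath("table1_stocks.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class WorkedTarget:
    """One recomputed arithmetic claim with its pass/fail verdict."""

    target_id: str
    description: str
    computed: float
    expected: float
    rule: str          # 'abs_tol', 'round_int' or 'round_ten'
    tol: float = 0.0

    @property
    def passed(self) -> bool:
        if self.rule == "abs_tol":
            return abs(self.computed - self.expected) <= self.tol + 1e-12
        if self.rule == "round_int":
            return round_half_up(self.computed) == round_half_up(self.expected)
        if self.rule == "round_ten":
            return round_half_up(self.computed / 10.0) * 10 == self.expected
        raise ValueError(f"unknown rule {self.rule!r}")


def _stock(table: pd.DataFrame, stratum: str, element: str, depth: float) -> float:
    sel = table[(table.stratum == stratum) & (table.element == element)
                & (table.depth_m == depth)]
    return float(sel.stock_Pg.iloc[0])


def _ulp(table: pd.DataFrame, stratum: str, element: str) -> float:
    sel = table[(table.stratum == stratum) & (table.element == element)]
    return 10.0 ** -int(sel.decimals.iloc[0])


def reproduce_worked_examples(pools: dict | None = None) -> list[WorkedTarget]:
    """Recompute every worked-arithmetic target from the printed constants."""
    t = load_reference_stocks()
    pools = pools or DEFAULT_REFERENCE_POOLS
    targets: list[WorkedTarget] = []

    # internal additivity of the stock table
    for element in ("organic_C", "inorganic_C", "total_N"):
        for depth in (0.3, 1.0, 2.0):
            sub_sum = sum(_stock(t, s, element, depth) for s in _DRY_SUBTYPES)
            tol = sum(0.5 * _ulp(t, s, element) for s in _DRY_SUBTYPES)
            targets.append(WorkedTarget(
                f"sum_subtypes_{element}_{depth}m",
                f"four subtype {element} stocks to {depth} m sum to the printed dry total",
                sub_sum, _stock(t, "dry", element, depth), "abs_tol", tol))
            dh = _stock(t, "dry", element, depth) + _stock(t, "humid", element, depth)
            tol = 0.5 * (_ulp(t, "dry", element) + _ulp(t, "humid", element))
            targets.append(WorkedTarget(
                f"dry_plus_humid_{element}_{depth}m",
                f"dry + humid {element} stocks to {depth} m give the printed global total",
                dh, _stock(t, "global", element, depth), "abs_tol", tol))

    # dryland shares of the global pools
    targets.append(WorkedTarget(
        "share_dry_organic_C", "dryland organic C to 2 m as % of the global pool",
        share_percent(_stock(t, "dry", "organic_C", 2.0),
                      _stock(t, "global", "organic_C", 2.0)), 32, "round_int"))
    targets.append(WorkedTarget(
        "share_dry_total_N", "dryland total N to 2 m as % of the global pool",
        share_percent(_stock(t, "dry", "total_N", 2.0),
                      _stock(t, "global", "total_N", 2.0)), 40, "round_int"))
    targets.append(WorkedTarget(
        "share_dry_inorganic_C",
        "dryland inorganic C to 2 m as % of the global pool (printed 'about 80%')",
        share_percent(_stock(t, "dry", "inorganic_C", 2.0),
                      _stock(t, "global", "inorganic_C", 2.0)), 80, "round_ten"))

    # reference-pool comparisons
    soc = _stock(t, "dry", "organic_C", 2.0)
    sic = _stock(t, "dry", "inorganic_C", 2.0)
    for subject, label, pool, printed in (
        (soc, "organic_C", "vegetation", 24),
        (soc, "organic_C", "atmosphere", -22),
        (soc, "organic_C", "permafrost", -38),
        (sic, "inorganic_C", "permafrost", 20),
        (sic, "inorganic_C", "vegetation", 138),
        (sic, "inorganic_C", "atmosphere", 49),
    ):
        cmp = compare_pool(subject, pools[pool], pool)
        targets.append(WorkedTarget(
            f"compare_dry_{label}_vs_{pool}",
            f"dryland {label} to 2 m vs the {pool} pool ({pools[pool]:g} Pg), signed %",
            cmp.percent, printed, "round_int"))

    # dryland area share
    targets.append(WorkedTarget(
        "dryland_area_share",
        "subtype land-area shares sum to the printed dryland share of land",
        sum(SUBTYPE_AREA_SHARES.values()), PRINTED_DRY_AREA_SHARE, "round_int"))

    return targets


def worked_examples_report(pools: dict | None = None) -> pd.DataFrame:
    """Per-target pass/fail frame of :func:`reproduce_worked_examples`."""
    targets = reproduce_worked_examples(pools)
    return pd.DataFrame([
        {"target_id": w.target_id, "description": w.description,
         "computed": w.computed, "expected": w.expected, "rule": w.rule,
         "tol": w.tol, "passed": w.passed}
        for w in targets
    ])
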