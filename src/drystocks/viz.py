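"""Small plotting helpers for zonal summaries."""

from __future__ import annotations

import pandas as pd


def stratum_content_boxes(summary: pd.DataFrame, element: str, depth_m: float,
                          ax=None):
    """Quartile boxes of areal content per stratum for one element and depth.

    Draws the q1/median/q3 boxes from a zonal summary frame (whiskers are not
    reconstructible from the summary statistics and are omitted).
    """
    import matplotlib.pyplot as plt

    sel = summary[(summary.element == element) & (summary.depth_m == depth_m)]
    sel = sel[sel.stratum != "global"]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = range(len(sel))
    ax.bar(x, sel.q3 - sel.q1, bottom=sel.q1, width=0.6, fill=False, edgecolor="k")
    ax.plot(x, sel["median"], "k_", markersize=18)
    ax.set_xticks(list(x), sel.stratum, rotation=30, ha="right")
    ax.set_ylabel(f"{element} content to {depth_m} m (kg m$^{{-2}}$)")
    return ax
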