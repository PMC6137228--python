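"""Shared fixtures and the Monte-Carlo oracle for uncertainty propagation.

The MC oracle was written before the propagation engine and stays
independent of it: it estimates the stock standard deviation empirically
from independent normal draws on concentration, bulk density and coarse
fragments, truncated only to each variable's physical domain.
"""

import numpy as np
import pytest

from drystocks import GeneratorConfig, GeoGrid


def mc_layer_stock_std(cn, cn_std, bulk, bulk_std, cfrag, cfrag_std, hot,
                       n=100_000, seed=0):
    """Empirical std of HOT*CN*BULK*(1-CFRAG/100) under independent normals."""
    rng = np.random.default_rng(seed)
    c = np.clip(rng.normal(cn, cn_std, n), 0.0, None)
    b = np.clip(rng.normal(bulk, bulk_std, n), 1e-12, None)
    f = np.clip(rng.normal(cfrag, cfrag_std, n), 0.0, 100.0)
    return float(np.std(hot * c * b * (1.0 - f / 100.0), ddof=1))


def sort_based_quartiles(values):
    """Independent quartile oracle: sort + linear interpolation at (n-1)q."""
    x = np.sort(np.asarray(values, dtype=float))
    out = []
    for q in (0.25, 0.50, 0.75):
        pos = (len(x) - 1) * q
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        out.append(x[lo] + (pos - lo) * (x[hi] - x[lo]))
    return tuple(out)


@pytest.fixture
def tiny_grid():
    return GeoGrid(n_rows=4, n_cols=8, lat_origin=45.0, lon_origin=0.0,
                   cell_size=1.0)


@pytest.fixture
def default_config():
    """The default synthetic world (2 degree global grid) on a fixed seed."""
    return GeneratorConfig(seed=11)


@pytest.fixture
def quiet_config():
    """A dispersion-free world: every field equals its AI-driven mean."""
    from drystocks.synthetic import DEFAULT_ELEMENT_MODELS
    from dataclasses import replace

    elements = {k: replace(v, cv=0.0) for k, v in DEFAULT_ELEMENT_MODELS.items()}
    return GeneratorConfig(seed=11, ai_noise_sigma=0.0, nodata_fraction=0.0,
                           bulk_cv=0.0, cfrag_logit_sigma=0.0, p_cv=0.0,
                           elements=elements)
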