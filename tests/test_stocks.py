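"""Layer stocks, Taylor propagation, depth aggregation and compositing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import mc_layer_stock_std
from drystocks import (CellProfile, GeneratorConfig, GeoGrid, RasterField,
                       SoilLayerSpec, composite_cell, cube_to_stockmaps,
                       generate_soil_cube, layer_stock, layer_stock_std,
                       layers_from_boundaries, profile_stock)
from drystocks.errors import CompositionError, DepthError, ValidationError
from drystocks.stocks import LayerFields, SoilCube


class TestLayerStock:
    def test_hand_example(self):
        assert layer_stock(10, 1.4, 0, 0.2) == pytest.approx(2.8)

    def test_full_gravel_gives_zero(self):
        assert layer_stock(42.0, 1.7, 100, 0.5) == 0.0

    def test_zero_concentration_gives_zero(self):
        assert layer_stock(0.0, 1.4, 20, 0.2) == 0.0

    @pytest.mark.parametrize("kw", [dict(cn=-1), dict(bulk=-0.1), dict(cfrag=101),
                                    dict(cfrag=-1), dict(hot=0)])
    def test_domain_violations_rejected(self, kw):
        args = dict(cn=10, bulk=1.4, cfrag=0, hot=0.2)
        args.update(kw)
        with pytest.raises(ValidationError):
            layer_stock(**args)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    def test_linearity_in_concentration_and_thickness(self, k_cn, k_hot):
        base = layer_stock(12.0, 1.5, 30.0, 0.2)
        assert layer_stock(12.0 * k_cn, 1.5, 30.0, 0.2) == \
            pytest.approx(k_cn * base, rel=1e-12)
        assert layer_stock(12.0, 1.5, 30.0, 0.2 * k_hot) == \
            pytest.approx(k_hot * base, rel=1e-12)


class TestLayerStockStd:
    def test_hand_example(self):
        # 0.2 * sqrt(1.2544 + 0.64 + 0.49)
        assert layer_stock_std(10, 1, 1.4, 0.1, 20, 5, 0.2) == \
            pytest.approx(0.30883, abs=5e-6)

    def test_all_stds_zero_gives_zero(self):
        assert layer_stock_std(10, 0, 1.4, 0, 20, 0, 0.2) == 0.0

    def test_single_uncertain_input_reduces_to_closed_form(self):
        # only CN uncertain and no gravel: std = HOT * CN_std * BULK exactly
        assert layer_stock_std(10, 1.5, 1.4, 0, 0, 0, 0.2) == \
            pytest.approx(0.2 * 1.5 * 1.4, rel=1e-14)

    def test_negative_std_rejected(self):
        with pytest.raises(ValidationError):
            layer_stock_std(10, -1, 1.4, 0.1, 20, 5, 0.2)

    def test_homogeneous_under_joint_cn_scaling(self):
        s1 = layer_stock_std(10, 1, 1.4, 0.1, 20, 5, 0.2)
        s3 = layer_stock_std(30, 3, 1.4, 0.1, 20, 5, 0.2)
        assert s3 == pytest.approx(3 * s1, rel=1e-12)

    def test_agrees_with_monte_carlo_oracle(self):
        for seed, (cn, bulk, cf, hot) in enumerate(
                [(10, 1.4, 20, 0.2), (35, 1.1, 5, 0.5), (2, 1.7, 55, 0.3)]):
            taylor = layer_stock_std(cn, 0.1 * cn, bulk, 0.05 * bulk,
                                     cf, 0.15 * cf, hot)
            mc = mc_layer_stock_std(cn, 0.1 * cn, bulk, 0.05 * bulk,
                                    cf, 0.15 * cf, hot, seed=seed)
            assert taylor == pytest.approx(mc, rel=0.05)


@pytest.fixture
def flat_profile():
    """Two layers 0-0.2 and 0.2-0.4 m with identical per-metre density."""
    layers = layers_from_boundaries([0.0, 0.2, 0.4])
    return CellProfile(layers, cn=[10, 10], cn_std=[1, 1], bulk=[1.4, 1.4],
                       bulk_std=[0.1, 0.1], cfrag=[20, 20], cfrag_std=[5, 5])


class TestProfileStock:
    def test_pro_rata_truncation(self, flat_profile):
        full, _ = profile_stock(flat_profile, 0.4)
        part, _ = profile_stock(flat_profile, 0.3)
        assert part == pytest.approx(0.75 * full, rel=1e-12)

    def test_boundary_target_uses_complete_layers_only(self, flat_profile):
        m, s = profile_stock(flat_profile, 0.2)
        assert m == pytest.approx(layer_stock(10, 1.4, 20, 0.2), rel=1e-12)
        assert s == pytest.approx(layer_stock_std(10, 1, 1.4, 0.1, 20, 5, 0.2),
                                  rel=1e-12)

    def test_single_layer_matches_scalar_ops(self):
        p = CellProfile(layers_from_boundaries([0.0, 0.2]), cn=[10], cn_std=[1],
                        bulk=[1.4], bulk_std=[0.1], cfrag=[20], cfrag_std=[5])
        m, s = profile_stock(p, 0.2)
        assert m == pytest.approx(layer_stock(10, 1.4, 20, 0.2), rel=1e-14)
        assert s == pytest.approx(layer_stock_std(10, 1, 1.4, 0.1, 20, 5, 0.2),
                                  rel=1e-14)

    def test_straddling_layer_std_scaled_pro_rata(self, flat_profile):
        _, s_full = profile_stock(flat_profile, 0.4)
        _, s_part = profile_stock(flat_profile, 0.3)
        per_layer = layer_stock_std(10, 1, 1.4, 0.1, 20, 5, 0.2)
        assert s_part == pytest.approx(
            np.sqrt(per_layer**2 + (0.5 * per_layer) ** 2), rel=1e-12)
        assert s_full == pytest.approx(np.sqrt(2) * per_layer, rel=1e-12)

    def test_correlated_mode_adds_stds(self, flat_profile):
        _, s = profile_stock(flat_profile, 0.4, layer_mode="correlated")
        per_layer = layer_stock_std(10, 1, 1.4, 0.1, 20, 5, 0.2)
        assert s == pytest.approx(2 * per_layer, rel=1e-12)

    def test_target_below_profile_rejected(self, flat_profile):
        with pytest.raises(DepthError):
            profile_stock(flat_profile, 0.5)


class TestCompositeCell:
    def _profile(self, cn):
        return CellProfile(layers_from_boundaries([0.0, 1.0]), cn=[cn],
                           cn_std=[0.0], bulk=[1.0], bulk_std=[0.0],
                           cfrag=[0.0], cfrag_std=[0.0])

    def test_single_component_is_identity(self, flat_profile):
        assert composite_cell([(1.0, flat_profile)], 0.4) == \
            profile_stock(flat_profile, 0.4)

    def test_identical_components_are_symmetric(self, flat_profile):
        one = profile_stock(flat_profile, 0.4)
        two = composite_cell([(0.5, flat_profile), (0.5, flat_profile)], 0.4)
        assert two[0] == pytest.approx(one[0], rel=1e-12)
        assert two[1] == pytest.approx(one[1], rel=1e-12)

    def test_weighted_mean_of_stocks(self):
        m, s = composite_cell([(0.25, self._profile(2.0)),
                               (0.75, self._profile(4.0))], 1.0)
        assert m == pytest.approx(3.5, rel=1e-12)
        assert s == 0.0

    def test_mixture_variance_adds_between_component_spread(self):
        comps = [(0.5, self._profile(2.0)), (0.5, self._profile(4.0))]
        _, s_meas = composite_cell(comps, 1.0)
        _, s_mix = composite_cell(comps, 1.0, variance_mode="mixture")
        assert s_meas == 0.0
        assert s_mix == pytest.approx(1.0, rel=1e-12)  # spread of {2, 4} at 0.5/0.5

    def test_bad_fraction_sum_rejected(self, flat_profile):
        with pytest.raises(CompositionError):
            composite_cell([(0.6, flat_profile), (0.5, flat_profile)], 0.4)


def _one_cell_cube(grid, cn, cn_std, bulk, bulk_std, cfrag, cfrag_std,
                   boundaries=(0.0, 0.2, 0.4)):
    layers = layers_from_boundaries(boundaries)
    fields = []
    for i in range(len(layers)):
        def fld(v, u):
            return RasterField(grid, np.full(grid.shape, v[i]), u)
        fields.append(LayerFields(
            conc=fld(cn, "g kg-1"), conc_std=fld(cn_std, "g kg-1"),
            bulk=fld(bulk, "g cm-3"), bulk_std=fld(bulk_std, "g cm-3"),
            cfrag=fld(cfrag, "%"), cfrag_std=fld(cfrag_std, "%")))
    return SoilCube(element="organic_C", layers=layers, fields=fields)


class TestCubeToStockmaps:
    grid = GeoGrid(n_rows=1, n_cols=1, lat_origin=1.0, lon_origin=0.0,
                   cell_size=1.0)

    def test_one_cell_grid_reproduces_scalar_result(self):
        cube = _one_cell_cube(self.grid, [10, 10], [1, 1], [1.4, 1.4],
                              [0.1, 0.1], [20, 20], [5, 5])
        sm = cube_to_stockmaps(cube, [0.3])[0]
        profile = CellProfile(cube.layers, [10, 10], [1, 1], [1.4, 1.4],
                              [0.1, 0.1], [20, 20], [5, 5])
        m, s = profile_stock(profile, 0.3)
        assert sm.mean.values[0, 0] == pytest.approx(m, rel=1e-12)
        assert sm.std.values[0, 0] == pytest.approx(s, rel=1e-12)

    def test_nodata_scoped_to_depth_target(self):
        config = GeneratorConfig(grid=GeoGrid.global_grid(30.0), seed=2,
                                 nodata_fraction=0.0)
        cube = generate_soil_cube(config, "organic_C")
        # knock out bulk density in the third layer (0.4-0.6 m) of one cell
        cube.fields[2].bulk.values[2, 3] = config.grid.nodata
        deep, shallow = cube_to_stockmaps(cube, [2.0, 0.3])
        assert deep.mean.values[2, 3] == config.grid.nodata
        assert shallow.mean.values[2, 3] != config.grid.nodata

    def test_depth_monotonicity_on_generated_cube(self):
        config = GeneratorConfig(grid=GeoGrid.global_grid(15.0), seed=9)
        cube = generate_soil_cube(config, "organic_C")
        maps = cube_to_stockmaps(cube, [0.3, 1.0, 2.0])
        valid = maps[2].mean.valid_mask
        assert np.all(maps[0].mean.values[valid] <= maps[1].mean.values[valid])
        assert np.all(maps[1].mean.values[valid] <= maps[2].mean.values[valid])

    def test_scalar_vector_equivalence_on_random_cells(self):
        config = GeneratorConfig(grid=GeoGrid.global_grid(30.0), seed=4,
                                 nodata_fraction=0.0)
        cube = generate_soil_cube(config, "total_N")
        sm = cube_to_stockmaps(cube, [1.0])[0]
        rng = np.random.default_rng(0)
        for _ in range(10):
            i = rng.integers(cube.grid.n_rows)
            j = rng.integers(cube.grid.n_cols)
            profile = CellProfile(
                cube.layers,
                [lf.conc.values[i, j] for lf in cube.fields],
                [lf.conc_std.values[i, j] for lf in cube.fields],
                [lf.bulk.values[i, j] for lf in cube.fields],
                [lf.bulk_std.values[i, j] for lf in cube.fields],
                [lf.cfrag.values[i, j] for lf in cube.fields],
                [lf.cfrag_std.values[i, j] for lf in cube.fields])
            m, s = profile_stock(profile, 1.0)
            assert sm.mean.values[i, j] == pytest.approx(m, rel=1e-12)
            assert sm.std.values[i, j] == pytest.approx(s, rel=1e-12)
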