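"""Grid model: construction contracts, neighborhood location, scene indexing."""

import numpy as np
import pytest

from envtrack import (CRS, GridAxis, build_grid_variable, locate_neighborhood,
                      scenes_required)
from envtrack.errors import OutOfDomainError, ValidationError


def _lonlat_var(nx=11, ny=11, times=None, tile_shape=None, var_id="v"):
    axes = [("y", np.arange(ny, dtype=float)), ("x", np.arange(nx, dtype=float))]
    shape = [ny, nx]
    if times is not None:
        axes.insert(0, ("t", np.asarray(times, dtype=float)))
        shape.insert(0, len(times))
    rng = np.random.default_rng(0)
    return build_grid_variable(axes, rng.normal(size=shape),
                               tile_shape=tile_shape, var_id=var_id)


class TestBuildGridVariable:
    def test_node_lookup_identity(self):
        values = np.arange(121.0).reshape(11, 11)
        var = build_grid_variable(
            [("y", np.arange(11.0)), ("x", np.arange(11.0))], values)
        assert var.n_nodes == 121
        assert var.node_value(y=0, x=0) == values[0, 0]
        assert var.node_value(y=3, x=7) == values[3, 7]

    def test_axis_count_limits(self):
        coords = np.arange(3.0)
        axes4 = [("t", coords), ("z", coords), ("y", coords), ("x", coords)]
        var = build_grid_variable(axes4, np.zeros((3, 3, 3, 3)))
        assert var.axis_names == ["t", "z", "y", "x"]
        with pytest.raises(ValidationError):
            # a fifth axis is impossible by construction: duplicate name
            build_grid_variable(axes4 + [("x", coords)], np.zeros((3,) * 5))

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(ValidationError):
            GridAxis("x", [0.0, 2.0, 1.0])
        with pytest.raises(ValidationError):
            GridAxis("x", [0.0, 1.0, 1.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            build_grid_variable([("y", np.arange(5.0)), ("x", np.arange(4.0))],
                                np.zeros((4, 5)))

    def test_spacing_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            GridAxis("x", [0.0, 1.0, 2.5], spacing=1.0)

    def test_categorical_codes_preserved(self):
        codes = {11, 14, 20}
        vals = np.array([[11.0, 14.0], [20.0, 11.0]])
        var = build_grid_variable([("y", [0.0, 1.0]), ("x", [0.0, 1.0])],
                                  vals, kind="categorical", codes=codes)
        assert var.codes == frozenset(codes)
        assert var.node_value(y=1, x=0) == 20


class TestLocateNeighborhood:
    def test_point_on_node_at_scene_time(self):
        var = _lonlat_var(times=[0.0, 21600.0])
        nb = locate_neighborhood(var, 3.0, 4.0, 0.0)
        assert nb.frac == (0.0, 0.0)
        assert nb.t_before == nb.t_after == 0.0
        np.testing.assert_array_equal(nb.values_before, nb.values_after)
        assert nb.values_before[nb.core_row, nb.core_col] == var.node_value(t=0, y=4, x=3)

    def test_cell_center_midway_between_scenes(self):
        var = _lonlat_var(times=[0.0, 21600.0])
        nb = locate_neighborhood(var, 3.5, 4.5, 10800.0)
        assert nb.frac == (0.5, 0.5)
        assert (nb.t_before, nb.t_after) == (0.0, 21600.0)
        assert nb.n_nodes == 4

    def test_fractional_index_closed_form(self):
        # fx = (lon - lon0) / spacing on a regular 1-degree grid
        var = _lonlat_var()
        nb = locate_neighborhood(var, 0.25, 0.0)
        assert nb.frac[0] == pytest.approx(0.25, abs=1e-12)
        assert list(nb.ix) == [0, 1]

    def test_no_spatial_extrapolation(self):
        var = _lonlat_var()
        with pytest.raises(OutOfDomainError):
            locate_neighborhood(var, -0.5, 5.0)
        with pytest.raises(OutOfDomainError):
            locate_neighborhood(var, 5.0, 10.5)

    def test_time_edge_clamps_one_interval_then_errors(self):
        var = _lonlat_var(times=[0.0, 21600.0])
        with pytest.warns(UserWarning):
            nb = locate_neighborhood(var, 5.0, 5.0, 21600.0 + 20000.0)
        assert nb.t_before == nb.t_after == 21600.0
        with pytest.raises(OutOfDomainError):
            locate_neighborhood(var, 5.0, 5.0, 2 * 21600.0 + 1.0)

    def test_antimeridian_wrap_on_global_grid(self):
        # global 10-degree grid: -180, -170, ..., 170
        lons = np.arange(-180.0, 180.0, 10.0)
        lats = np.arange(-40.0, 50.0, 10.0)
        vals = np.arange(lats.size * lons.size, dtype=float).reshape(lats.size, lons.size)
        var = build_grid_variable([("y", lats), ("x", lons)], vals)
        assert var.x_is_circular
        nb = locate_neighborhood(var, 175.0, 5.0)  # between lon 170 and -180
        assert set(nb.ix) == {lons.size - 1, 0}
        assert nb.frac[0] == pytest.approx(0.5)

    def test_wider_ring_expands_neighborhood(self):
        var = _lonlat_var()
        nb = locate_neighborhood(var, 5.5, 5.5, ring=2)
        assert nb.values_before.shape == (4, 4)
        assert nb.core_row == nb.core_col == 1


def _brute_force_scene_keys(var, points):
    """Oracle: per-point neighbor tiles enumerated by hand."""
    keys = set()
    for x, y, t in points:
        nb = locate_neighborhood(var, x, y, t)
        for t_idx in set(nb.t_indices):
            for iy in nb.iy:
                for ix in nb.ix:
                    keys.add((var.id, t_idx,
                              (int(iy) // var.tile_shape[0],
                               int(ix) // var.tile_shape[1])))
    return keys


class TestScenesRequired:
    def test_points_in_one_tile_two_timestamps(self):
        var = _lonlat_var(times=[0.0, 21600.0], tile_shape=(11, 11))
        rng = np.random.default_rng(5)
        pts = [(rng.uniform(1, 9), rng.uniform(1, 9), rng.uniform(1, 21599))
               for _ in range(10)]
        keys = scenes_required(pts, var)
        assert len(keys) == 2
        assert keys == sorted(_brute_force_scene_keys(var, pts),
                              key=lambda k: (k[0], k[1], k[2]))

    def test_tile_boundary_straddle(self):
        var = _lonlat_var(nx=12, ny=12, times=[0.0, 21600.0], tile_shape=(12, 6))
        # x in (5, 6) straddles the tile boundary between columns 5 and 6
        keys = scenes_required([(5.5, 3.0, 10800.0)], var)
        assert len(keys) == 4  # 2 tiles x 2 timestamps

    def test_degenerate_bracket_single_scene(self):
        var = _lonlat_var(times=[0.0, 21600.0], tile_shape=(11, 11))
        keys = scenes_required([(3.0, 4.0, 0.0)], var)
        assert len(keys) == 1

    def test_order_invariance_and_oracle_agreement(self):
        var = _lonlat_var(nx=20, ny=20, times=[0.0, 21600.0, 43200.0],
                          tile_shape=(7, 5))
        rng = np.random.default_rng(9)
        pts = [(rng.uniform(0, 19), rng.uniform(0, 19), rng.uniform(0, 43200))
               for _ in range(40)]
        keys = scenes_required(pts, var)
        rng.shuffle(pts)
        assert scenes_required(pts, var) == keys
        assert set(keys) == _brute_force_scene_keys(var, pts)
        assert keys == sorted(keys, key=lambda k: (k[0], k[1], k[2]))

    def test_empty_point_list_rejected(self):
        var = _lonlat_var()
        with pytest.raises(ValidationError):
            scenes_required([], var)


def test_scene_payload_matches_tile_blocks():
    var = _lonlat_var(nx=10, ny=9, times=[0.0, 21600.0], tile_shape=(4, 6))
    assert var.n_tiles == (3, 2)
    p = var.scene_payload(1, (2, 1))  # edge tile, smaller than tile_shape
    np.testing.assert_array_equal(p, var.values[1, 8:9, 6:10])
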