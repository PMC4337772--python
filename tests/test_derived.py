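"""Wind decomposition, terrain operators, and uplift proxies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envtrack import (TerrainCell, orographic_uplift, rugosity, slope_aspect,
                      thermal_uplift, wind_speed_direction, wind_support)
from envtrack.derived import GRAVITY, direction_to_from, terrain_at_node
from envtrack.errors import UndefinedBearingError, ValidationError
from envtrack.synthetic import FieldSpec, make_field

finite = st.floats(-50, 50, allow_nan=False)


class TestWindSpeedDirection:
    def test_345_triangle(self):
        speed, _ = wind_speed_direction(3.0, 4.0)
        assert speed == 5.0

    def test_axis_cases(self):
        assert wind_speed_direction(5.0, 0.0)[1] == 90.0   # blowing toward east
        assert wind_speed_direction(0.0, 5.0)[1] == 0.0    # toward north
        assert wind_speed_direction(-5.0, 0.0)[1] == 270.0
        assert wind_speed_direction(0.0, -5.0)[1] == 180.0

    def test_atan2_example(self):
        _, direction = wind_speed_direction(3.0, 4.0)
        assert direction == pytest.approx(math.degrees(math.atan2(3, 4)), rel=1e-12)
        assert direction == pytest.approx(36.8699, abs=1e-4)

    def test_calm_air_flagged(self):
        speed, direction = wind_speed_direction(0.0, 0.0)
        assert speed == 0.0 and np.isnan(direction)

    def test_to_from_conversion(self):
        assert direction_to_from(90.0) == 270.0
        assert direction_to_from(direction_to_from(123.4)) == pytest.approx(123.4)


class TestWindSupport:
    def test_aligned_and_opposed_flow(self):
        assert wind_support(5.0, 0.0, 90.0) == pytest.approx((5.0, 0.0))
        tail, cross = wind_support(5.0, 0.0, 270.0)
        assert tail == pytest.approx(-5.0)  # head wind
        assert cross == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_example(self):
        tail, cross = wind_support(3.0, 4.0, 90.0)
        assert tail == pytest.approx(3.0)
        assert cross == pytest.approx(-4.0)
        assert tail ** 2 + cross ** 2 == pytest.approx(5.0 ** 2)

    def test_cross_sign_flag(self):
        _, cross = wind_support(3.0, 4.0, 90.0, cross_from_right=True)
        assert cross == pytest.approx(4.0)

    def test_undefined_heading_raises(self):
        with pytest.raises(UndefinedBearingError):
            wind_support(1.0, 1.0, float("nan"))

    @given(finite, finite, st.floats(0, 360))
    @settings(max_examples=100, derandomize=True)
    def test_energy_identity(self, u, v, heading):
        tail, cross = wind_support(u, v, heading)
        assert tail ** 2 + cross ** 2 == pytest.approx(u ** 2 + v ** 2, abs=1e-9)

    @given(finite, finite, st.floats(0, 360), st.floats(-180, 180))
    @settings(max_examples=100, derandomize=True)
    def test_rotation_equivariance(self, u, v, heading, rot):
        """Rotating wind vector and heading together leaves support unchanged."""
        tail0, cross0 = wind_support(u, v, heading)
        r = math.radians(rot)
        # rotate the wind vector by +rot in azimuth sense (north toward east)
        u2 = u * math.cos(r) + v * math.sin(r)
        v2 = -u * math.sin(r) + v * math.cos(r)
        tail1, cross1 = wind_support(u2, v2, (heading + rot) % 360.0)
        assert tail1 == pytest.approx(tail0, abs=1e-8)
        assert cross1 == pytest.approx(cross0, abs=1e-8)


class TestSlopeAspect:
    def test_flat_window(self):
        cell = slope_aspect(np.full((3, 3), 7.0), 30.0, 30.0)
        assert cell.slope == 0.0 and np.isnan(cell.aspect)

    def test_plane_rising_east(self):
        # z = 0.1 x, x eastward, 30 m cells; downslope faces west
        x = np.array([[-30.0, 0.0, 30.0]] * 3) * 0.1
        cell = slope_aspect(x, 30.0, 30.0)
        assert math.degrees(cell.slope) == pytest.approx(math.degrees(math.atan(0.1)))
        assert math.degrees(cell.slope) == pytest.approx(5.71, abs=0.01)
        assert cell.aspect == pytest.approx(270.0)

    def test_plane_rising_north(self):
        # rows run north->south, so z decreases down the rows
        y = np.array([[30.0] * 3, [0.0] * 3, [-30.0] * 3]) * 0.1
        cell = slope_aspect(y, 30.0, 30.0)
        assert cell.aspect == pytest.approx(180.0)

    def test_recovers_random_planes_exactly(self):
        rng = np.random.default_rng(31)
        xs = np.array([[-1, 0, 1]] * 3, dtype=float)
        ys = np.array([[1] * 3, [0] * 3, [-1] * 3], dtype=float)
        for _ in range(100):
            gx, gy = rng.uniform(-0.5, 0.5, 2)
            dx, dy = rng.uniform(5, 100, 2)
            z = gx * xs * dx + gy * ys * dy
            cell = slope_aspect(z, dx, dy)
            assert math.tan(cell.slope) == pytest.approx(math.hypot(gx, gy), rel=1e-12)
            if gx or gy:
                expected = math.degrees(math.atan2(-gx, -gy)) % 360.0
                assert cell.aspect == pytest.approx(expected, abs=1e-9)

    def test_missing_cell_flags_missing(self):
        w = np.full((3, 3), 1.0)
        w[1, 1] = np.nan
        cell = slope_aspect(w, 30.0, 30.0)
        assert np.isnan(cell.slope)


class TestRugosity:
    def test_constant_window_zero(self):
        assert rugosity(np.full((3, 3), 42.0)) == 0.0

    def test_single_spike_population_sd(self):
        w = np.zeros((3, 3))
        w[1, 1] = 10.0
        expected = math.sqrt((8 * (10 / 9) ** 2 + (10 - 10 / 9) ** 2) / 9)
        assert rugosity(w) == pytest.approx(expected, rel=1e-12)
        assert rugosity(w) == pytest.approx(3.143, abs=1e-3)

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=(3, 3))
        assert rugosity(-2.5 * w) == pytest.approx(2.5 * rugosity(w), rel=1e-12)

    def test_too_few_finite_cells(self):
        w = np.full((3, 3), np.nan)
        w[0, :3] = 1.0
        with pytest.raises(ValidationError):
            rugosity(w)
        assert np.isnan(rugosity(np.full((3, 3), np.nan)))


class TestOrographicUplift:
    def test_wind_directly_upslope(self):
        # 10 deg slope facing west (aspect 270) -> upslope azimuth 90 (east)
        cell = TerrainCell(slope=math.radians(10.0), aspect=270.0)
        w = orographic_uplift(10.0, 0.0, cell)  # wind toward east
        assert w == pytest.approx(10.0 * math.tan(math.radians(10.0)), rel=1e-12)
        assert w == pytest.approx(1.763, abs=1e-3)

    def test_along_slope_wind_gives_zero(self):
        cell = TerrainCell(slope=math.radians(10.0), aspect=270.0)
        assert orographic_uplift(0.0, 10.0, cell) == pytest.approx(0.0, abs=1e-12)

    def test_zero_wind_and_flat_cell(self):
        cell = TerrainCell(slope=math.radians(30.0), aspect=180.0)
        assert orographic_uplift(0.0, 0.0, cell) == 0.0
        assert orographic_uplift(10.0, 3.0, TerrainCell(0.0, float("nan"))) == 0.0

    def test_sign_flips_under_wind_reversal(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            cell = TerrainCell(slope=rng.uniform(0.01, 1.0),
                               aspect=rng.uniform(0, 360))
            u, v = rng.uniform(-20, 20, 2)
            assert orographic_uplift(-u, -v, cell) == pytest.approx(
                -orographic_uplift(u, v, cell), abs=1e-9)

    def test_clamp_option(self):
        cell = TerrainCell(slope=math.radians(10.0), aspect=270.0)
        assert orographic_uplift(-10.0, 0.0, cell, clamp_zero=True) == 0.0


class TestThermalUplift:
    def test_no_heating_no_uplift(self):
        assert thermal_uplift(0.0, 1000.0, 288.0) == 0.0
        assert thermal_uplift(-50.0, 1000.0, 288.0) == 0.0

    def test_closed_form_plug_in(self):
        w = thermal_uplift(300.0, 1000.0, 288.0, rho=1.225, c_p=1005.0)
        expected = ((GRAVITY * 1000.0 / 288.0) * 300.0 / (1.225 * 1005.0)) ** (1 / 3)
        assert w == pytest.approx(expected, rel=1e-12)
        assert w == pytest.approx(2.03, abs=0.03)

    def test_cube_root_scaling(self):
        w1 = thermal_uplift(200.0, 1500.0, 290.0)
        w2 = thermal_uplift(400.0, 1500.0, 290.0)
        assert w2 / w1 == pytest.approx(2 ** (1 / 3), rel=1e-12)

    def test_celsius_auto_conversion(self):
        assert thermal_uplift(300.0, 1000.0, 15.0) == \
            pytest.approx(thermal_uplift(300.0, 1000.0, 288.15), rel=1e-12)

    def test_nonphysical_inputs_rejected(self):
        with pytest.raises(ValidationError):
            thermal_uplift(300.0, -5.0, 288.0)
        with pytest.raises(ValidationError):
            thermal_uplift(300.0, 1000.0, 288.0, rho=-1.0)


def test_terrain_at_node_on_synthetic_plane():
    """DEM plane rising east: every interior node slopes down to the west."""
    var, _ = make_field(FieldSpec(
        form="dem_plane", params={"z0": 100.0, "gx": 50.0, "gy": 0.0},
        x=(0.0, 0.1, 20), y=(0.0, 0.1, 20), var_id="syn.dem"))
    cell = terrain_at_node(var, 10, 10)
    assert cell.aspect == pytest.approx(270.0, abs=1e-6)
    assert cell.slope > 0
    assert cell.rugosity > 0
    # edges are flagged missing
    assert np.isnan(terrain_at_node(var, 0, 5).slope)
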