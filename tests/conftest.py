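"""Shared fixtures: synthetic fields and tracks with known closed forms."""

import numpy as np
import pytest

from envtrack import FieldSpec, InterpMethod, TrackSpec, make_field, make_track

SCENE_TIMES = [0.0, 21600.0, 43200.0, 64800.0]  # four 6-hour scenes

BILIN = InterpMethod(spatial="bilinear", temporal="inverse_distance_weighted")
NN = InterpMethod(spatial="nearest_neighbour", temporal="nearest_neighbour")
IDW = InterpMethod(spatial="inverse_distance_weighted",
                   temporal="inverse_distance_weighted")

ALL_METHODS = [
    InterpMethod(spatial=s, temporal=t)
    for s in ("nearest_neighbour", "bilinear", "inverse_distance_weighted")
    for t in ("nearest_neighbour", "inverse_distance_weighted")
]


@pytest.fixture(scope="session")
def affine_field():
    """f(lon, lat, t) = 2 + 0.5 lon + 0.25 lat + 1 * t_hours on a 1-degree,
    6-hour grid (the principal interpolation oracle)."""
    var, f = make_field(FieldSpec(
        form="affine", params={"a": 2.0, "b": 0.5, "c": 0.25, "d": 1.0},
        x=(0.0, 1.0, 11), y=(0.0, 1.0, 11), times=SCENE_TIMES,
        var_id="syn.affine"))
    return var, f


@pytest.fixture(scope="session")
def random_field():
    """A seeded random continuous field (no closed form; used for bounds)."""
    rng = np.random.default_rng(42)
    var, _ = make_field(FieldSpec(
        form="uniform", params={"value": 0.0},
        x=(0.0, 1.0, 16), y=(0.0, 1.0, 16), times=SCENE_TIMES,
        var_id="syn.random"))
    var.values[:] = rng.normal(size=var.values.shape)
    return var


@pytest.fixture(scope="session")
def categorical_field():
    var, oracle = make_field(FieldSpec(
        form="categorical_mosaic", params={"codes": [11, 14, 20], "block_size": 3},
        x=(0.0, 1.0, 12), y=(0.0, 1.0, 12), times=SCENE_TIMES,
        var_id="syn.landuse", seed=7))
    return var, oracle


@pytest.fixture()
def short_track():
    return make_track(TrackSpec(
        waypoints=[(1.0, 1.0), (6.0, 4.0)], speed_mps=15.0,
        start_time=3600.0, individual="a1"))
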