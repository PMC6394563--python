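import numpy as np
import pytest

from pcamars import GridSpec, RasterLayer, SceneConfig, StationSample, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic city shared by read-only tests."""
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture
def small_spec():
    return GridSpec(n_rows=4, n_cols=5, cell_size=100.0, origin_x=0.0, origin_y=400.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stations(xs, ys, values, prefix="s"):
    return [
        StationSample(f"{prefix}{i}", float(x), float(y), float(v))
        for i, (x, y, v) in enumerate(zip(xs, ys, values))
    ]


def raster(spec, values, name="r"):
    return RasterLayer(spec, name, np.asarray(values, dtype=float))
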