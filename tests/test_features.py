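"""Covariate engineering: IDW, focal statistics, KDE, Moran's I, radius
selection, normalization and the 14-layer stack."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point

from pcamars import (
    DegenerateInputError,
    FEATURE_NAMES,
    GridSpec,
    RasterLayer,
    StationSample,
    VectorLayer,
    bivariate_morans_i,
    build_feature_stack,
    focal_mean,
    idw_surface,
    kde_surface,
    min_max_normalize,
    select_idw_power,
    select_radius,
)
from pcamars.features import idw_predict, inverse_distance_weights

from conftest import make_stations, raster


def brute_force_moran(z, c, w):
    """Independent double-sum implementation of the cross Moran statistic."""
    z = np.asarray(z, float) - np.mean(z)
    c = np.asarray(c, float) - np.mean(c)
    n = len(z)
    num = sum(w[i, j] * z[i] * c[j] for i in range(n) for j in range(n))
    return (n / w.sum()) * num / math.sqrt((z**2).sum() * (c**2).sum())


class TestIdw:
    def test_equidistant_symmetry(self):
        spec = GridSpec(n_rows=1, n_cols=1, cell_size=100.0, origin_y=100.0)
        for power in (0.5, 1.0, 2.0, 3.5):
            samples = make_stations([50.0, 50.0], [250.0, -150.0], [10.0, 20.0])
            out = idw_surface(samples, spec, power)
            assert out.values[0, 0] == pytest.approx(15.0)

    def test_exact_at_sample(self):
        spec = GridSpec(n_rows=2, n_cols=2, cell_size=100.0, origin_y=200.0)
        samples = make_stations([50.0, 150.0], [150.0, 50.0], [42.0, 7.0])
        out = idw_surface(samples, spec, 2.0)
        assert out.values[0, 0] == 42.0

    def test_hand_arithmetic_power_one(self):
        # cell center (1, 1); samples at distances 1 and 3 valued 10 and 20:
        # (10/1 + 20/3) / (1 + 1/3) = 12.5
        spec = GridSpec(n_rows=1, n_cols=1, cell_size=2.0, origin_y=2.0)
        samples = [
            StationSample("a", 1.0, 2.0, 10.0),
            StationSample("b", 1.0, -2.0, 20.0),
        ]
        out = idw_surface(samples, spec, 1.0)
        assert out.values[0, 0] == pytest.approx(12.5)

    def test_bounded_by_sample_range(self, rng):
        spec = GridSpec(n_rows=6, n_cols=6, cell_size=50.0, origin_y=300.0)
        samples = make_stations(
            rng.uniform(0, 300, 8), rng.uniform(1, 300, 8), rng.normal(50, 10, 8)
        )
        out = idw_surface(samples, spec, 2.0)
        vals = [s.value for s in samples]
        assert out.values.min() >= min(vals) - 1e-9
        assert out.values.max() <= max(vals) + 1e-9


class TestSelectIdwPower:
    def test_matches_loocv_enumeration_oracle(self, rng):
        # independent enumeration of LOOCV RMSE per candidate power
        xs = rng.uniform(0, 100, 12)
        ys = rng.uniform(0, 100, 12)
        samples = make_stations(xs, ys, xs)  # v = x (linear field)
        candidates = [1.0, 2.0, 3.0]

        def loocv_rmse(p):
            sq = 0.0
            for i, s in enumerate(samples):
                rest = samples[:i] + samples[i + 1 :]
                sq += (idw_predict(rest, s.x, s.y, p) - s.value) ** 2
            return math.sqrt(sq / len(samples))

        oracle = min(candidates, key=loocv_rmse)
        assert select_idw_power(samples, candidates) == oracle

    def test_tie_breaks_to_smallest(self):
        samples = make_stations([0.0, 10.0, 5.0], [0.0, 0.0, 8.0], [3.0, 3.0, 3.0])
        assert select_idw_power(samples, [3.0, 1.0, 2.0]) == 1.0

    def test_single_candidate(self):
        samples = make_stations([0.0, 10.0, 5.0], [0.0, 0.0, 8.0], [1.0, 2.0, 3.0])
        assert select_idw_power(samples, [2.0]) == 2.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            select_idw_power(make_stations([0.0], [0.0], [1.0]), [1.0])


class TestFocalMean:
    def test_constant_preserved(self, small_spec):
        layer = raster(small_spec, np.full((4, 5), 5.0))
        out = focal_mean(layer, 250.0)
        np.testing.assert_allclose(out.values, 5.0)

    def test_center_nine_cells_hand(self):
        spec = GridSpec(n_rows=3, n_cols=3, cell_size=100.0, origin_y=300.0)
        vals = np.zeros((3, 3))
        vals[1, 1] = 9.0
        out = focal_mean(raster(spec, vals), 150.0)
        assert out.values[1, 1] == pytest.approx(1.0)

    def test_radius_below_diagonal_is_identity(self, rng):
        spec = GridSpec(n_rows=5, n_cols=5, cell_size=100.0, origin_y=500.0)
        layer = raster(spec, rng.normal(size=(5, 5)))
        out = focal_mean(layer, 100.0)  # < cell diagonal: singleton neighbourhood
        np.testing.assert_allclose(out.values, layer.values, atol=1e-9)

    def test_radius_smaller_than_cell_rejected(self, small_spec):
        with pytest.raises(ValueError):
            focal_mean(raster(small_spec, np.zeros((4, 5))), 50.0)

    @given(c=st.floats(-100, 100))
    @settings(max_examples=20, deadline=None)
    def test_commutes_with_adding_constant(self, c):
        rng = np.random.default_rng(0)
        spec = GridSpec(n_rows=6, n_cols=6, cell_size=100.0, origin_y=600.0)
        vals = rng.normal(size=(6, 6))
        a = focal_mean(raster(spec, vals + c), 250.0).values
        b = focal_mean(raster(spec, vals), 250.0).values + c
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_nodata_excluded(self):
        spec = GridSpec(n_rows=3, n_cols=3, cell_size=100.0, origin_y=300.0)
        vals = np.full((3, 3), 2.0)
        vals[0, 0] = np.nan
        out = focal_mean(raster(spec, vals), 450.0)
        assert np.isnan(out.values[0, 0])  # nodata propagates
        assert out.values[1, 1] == pytest.approx(2.0)


class TestKde:
    def test_empty_layer_all_zero(self, small_spec):
        out = kde_surface(VectorLayer("points", []), small_spec, 200.0)
        assert (out.values == 0).all()

    def test_mass_conservation_interior_point(self):
        spec = GridSpec(n_rows=40, n_cols=40, cell_size=500.0, origin_y=20000.0)
        layer = VectorLayer("points", [Point(10000.0, 10000.0)], [3.0])
        out = kde_surface(layer, spec, 8 * 500.0)
        mass = out.values.sum() * 500.0**2
        assert mass == pytest.approx(3.0, rel=0.02)

    def test_compact_support(self):
        spec = GridSpec(n_rows=10, n_cols=10, cell_size=100.0, origin_y=1000.0)
        layer = VectorLayer("points", [Point(150.0, 850.0)])
        out = kde_surface(layer, spec, 200.0)
        # cell centered at (950, 50): distance ~1131 m >> 200 m
        assert out.values[9, 9] == 0.0
        assert (out.values >= 0).all()

    def test_line_density_total_mass_is_length(self):
        from shapely.geometry import LineString

        spec = GridSpec(n_rows=40, n_cols=40, cell_size=100.0, origin_y=4000.0)
        line = LineString([(1500.0, 2000.0), (2500.0, 2000.0)])  # 1000 m
        out = kde_surface(VectorLayer("polylines", [line]), spec, 500.0)
        mass = out.values.sum() * 100.0**2
        assert mass == pytest.approx(1000.0, rel=0.02)


class TestMoran:
    def test_path_graph_hand_example(self):
        w = np.array(
            [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]], dtype=float
        )
        val = bivariate_morans_i([1, 2, 3, 4], [1, 2, 3, 4], w)
        assert val == pytest.approx(1.0 / 3.0)

    def test_constant_variable_rejected(self):
        w = 1.0 - np.eye(4)
        with pytest.raises(DegenerateInputError):
            bivariate_morans_i([1, 1, 1, 1], [1, 2, 3, 4], w)

    def test_relabeling_invariance(self, rng):
        n = 7
        z = rng.normal(size=n)
        c = rng.normal(size=n)
        w = rng.uniform(0, 1, (n, n))
        np.fill_diagonal(w, 0.0)
        perm = rng.permutation(n)
        a = bivariate_morans_i(z, c, w)
        b = bivariate_morans_i(z[perm], c[perm], w[np.ix_(perm, perm)])
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("n", [4, 7, 10])
    def test_matches_brute_force_double_sum(self, n, rng):
        z = rng.normal(size=n)
        w = rng.uniform(0, 1, (n, n))
        np.fill_diagonal(w, 0.0)
        # univariate case: cov == dep
        assert bivariate_morans_i(z, z, w) == pytest.approx(brute_force_moran(z, z, w))
        c = rng.normal(size=n)
        assert bivariate_morans_i(z, c, w) == pytest.approx(brute_force_moran(z, c, w))


class TestSelectRadius:
    def _smoothed_scene(self, seed, planted_cells=3):
        rng = np.random.default_rng(seed)
        spec = GridSpec(n_rows=20, n_cols=20, cell_size=500.0, origin_y=10000.0)
        raw = RasterLayer(spec, "raw", rng.standard_normal(spec.shape))
        smoothed = focal_mean(raw, planted_cells * 500.0)
        xs = rng.uniform(0, 10000, 60)
        ys = rng.uniform(0.01, 10000, 60)
        dep = []
        for i, (x, y) in enumerate(zip(xs, ys)):
            r, c = spec.cell_of(x, y)
            dep.append(StationSample(f"s{i}", x, y, float(smoothed.values[r, c])))
        return raw, dep

    def test_single_candidate(self):
        raw, dep = self._smoothed_scene(0)
        res = select_radius(dep, lambda r: focal_mean(raw, r), [1000.0])
        assert res.selected_radius == 1000.0

    def test_recovers_planted_radius(self):
        sel = []
        for seed in range(20):
            raw, dep = self._smoothed_scene(seed)
            res = select_radius(
                dep, lambda r: focal_mean(raw, r), [500.0 * k for k in range(1, 7)]
            )
            sel.append(res.selected_radius / 500.0)
        assert abs(np.median(sel) - 3) <= 1

    def test_sign_flip_same_selection(self):
        raw, dep = self._smoothed_scene(3)
        radii = [500.0 * k for k in range(1, 7)]
        pos = select_radius(dep, lambda r: focal_mean(raw, r), radii)
        neg_raw = RasterLayer(raw.spec, "neg", -raw.values)
        neg = select_radius(dep, lambda r: focal_mean(neg_raw, r), radii)
        assert pos.selected_radius == neg.selected_radius
        np.testing.assert_allclose(pos.moran_values, [-v for v in neg.moran_values])

    def test_moran_values_recorded_per_candidate(self):
        raw, dep = self._smoothed_scene(1)
        radii = [500.0, 1000.0, 1500.0]
        res = select_radius(dep, lambda r: focal_mean(raw, r), radii)
        assert len(res.moran_values) == len(radii)
        best = int(np.argmax(np.abs(res.moran_values)))
        assert res.selected_radius == radii[best]


class TestNormalization:
    def test_definition(self):
        spec = GridSpec(n_rows=1, n_cols=3, cell_size=1.0, origin_y=1.0)
        out, (lo, hi) = min_max_normalize(raster(spec, [[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])
        assert (lo, hi) == (2.0, 6.0)

    def test_identity_when_already_unit(self):
        spec = GridSpec(n_rows=1, n_cols=3, cell_size=1.0, origin_y=1.0)
        out, _ = min_max_normalize(raster(spec, [[0.0, 0.25, 1.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 0.25, 1.0]])

    def test_constant_layer_rejected(self, small_spec):
        with pytest.raises(DegenerateInputError):
            min_max_normalize(raster(small_spec, np.full((4, 5), 3.0)))

    def test_denormalization_recovers(self, small_spec, rng):
        layer = raster(small_spec, rng.normal(10, 3, size=(4, 5)))
        out, (lo, hi) = min_max_normalize(layer)
        np.testing.assert_allclose(out.values * (hi - lo) + lo, layer.values, atol=1e-10)


class TestFeatureStack:
    def test_stack_shape_and_range(self, default_scene):
        stack = build_feature_stack(default_scene.inputs)
        assert len(stack.layers) == 14
        assert tuple(l.name for l in stack.layers) == FEATURE_NAMES
        for layer in stack.layers:
            vals = layer.values[~np.isnan(layer.values)]
            assert vals.min() >= -1e-12 and vals.max() <= 1 + 1e-12

    def test_deterministic(self, default_scene):
        a = build_feature_stack(default_scene.inputs)
        b = build_feature_stack(default_scene.inputs)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.values, lb.values)
        assert a.provenance["radii"] == b.provenance["radii"]

    def test_provenance_records_radii_and_powers(self, default_scene):
        stack = build_feature_stack(default_scene.inputs)
        assert set(stack.provenance["radii"]) == {
            "gas", "petrol", "green", "sport", "population", "roads", "avg_elevation",
        }
        assert set(stack.provenance["idw_power"]) == {
            "wind_speed", "temperature", "pressure", "relative_humidity",
        }
        assert len(stack.normalization_bounds) == 14


def test_idw_point_prediction_exact_at_sample():
    samples = make_stations([0.0, 10.0], [0.0, 0.0], [5.0, 9.0])
    assert idw_predict(samples, 10.0, 0.0, 2.0) == 9.0


def test_inverse_distance_weight_matrix_properties():
    w = inverse_distance_weights([0.0, 1.0, 3.0], [0.0, 0.0, 0.0])
    assert np.diag(w).sum() == 0
    assert (w >= 0).all()
    assert w[0, 1] == pytest.approx(1.0)
    assert w[0, 2] == pytest.approx(1.0 / 3.0)
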