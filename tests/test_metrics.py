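"""Vector error statistics: examples, oracles and geometric invariances."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation
from scipy import stats as sps

from costim.exceptions import DegenerateDataError, UndefinedDirectionError
from costim.metrics import (
    angular_deviation_to_mean,
    angular_sd,
    circular_angular_deviation,
    combined_r2,
    direction_error,
    force_prediction_error,
    magnitude_error,
    normalized_error,
    predicted_vector,
    sagittal_angle,
)

finite = st.floats(-10, 10, allow_nan=False)
vec3 = st.tuples(finite, finite, finite).map(np.array)
nonzero_vec3 = vec3.filter(lambda v: np.linalg.norm(v) > 1e-3)
rot = st.tuples(st.floats(-180, 180), st.floats(-90, 90), st.floats(-180, 180)).map(
    lambda e: Rotation.from_euler("zyx", e, degrees=True))


class TestPredictedVector:
    @pytest.mark.parametrize("a,b,expected", [
        ((1, 0, 0), (0, 1, 0), (1, 1, 0)),
        ((0.2, -0.7, 1.1), (0, 0, 0), (0.2, -0.7, 1.1)),
        ((0.3, -0.4, 0.1), (-0.3, 0.4, -0.1), (0, 0, 0)),
    ])
    def test_componentwise_sum(self, a, b, expected):
        np.testing.assert_allclose(predicted_vector(a, b), expected, atol=1e-15)


class TestErrorMeasures:
    def test_identical_vectors_have_zero_error(self):
        v = (0.3, -0.2, 0.9)
        assert force_prediction_error(v, v) == 0.0
        assert magnitude_error(v, v) == 0.0
        assert direction_error(v, v) == pytest.approx(0.0, abs=1e-5)

    def test_three_four_five_triangle(self):
        assert force_prediction_error((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)

    def test_magnitude_error_examples(self):
        # same magnitude, different direction
        assert magnitude_error((1, 0, 0), (0, 1, 0)) == pytest.approx(0.0)
        assert magnitude_error((1, 0, 0), (0, 0, 1.3)) == pytest.approx(0.3)

    @pytest.mark.parametrize("a,b,angle", [
        ((1, 0, 0), (2, 0, 0), 0.0),
        ((1, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (-1, 0, 0), 180.0),
    ])
    def test_direction_error_examples(self, a, b, angle):
        assert direction_error(a, b) == pytest.approx(angle, abs=1e-9)

    def test_near_parallel_clipped_not_nan(self):
        v = np.array([1.0, 1e-8, 0.0])
        w = np.array([1.0, 0.0, 1e-8])
        out = direction_error(v, w)
        assert np.isfinite(out) and out < 1e-3

    def test_zero_vector_direction_is_an_error(self):
        with pytest.raises(UndefinedDirectionError):
            direction_error((0, 0, 0), (1, 0, 0))

    def test_normalized_error_consistent_with_reported_fraction(self):
        # 0.10 N error on a 0.667 N prediction is a 15% normalized error
        assert normalized_error(0.10, (0.667, 0, 0)) == pytest.approx(0.15, abs=1e-3)
        assert normalized_error(0.0, (1, 1, 1)) == 0.0

    def test_normalized_error_scale_invariant(self):
        a = normalized_error(0.2, (0.5, 0.5, 0))
        b = normalized_error(0.4, (1.0, 1.0, 0))
        assert a == pytest.approx(b, rel=1e-12)

    def test_normalized_error_zero_prediction_raises(self):
        with pytest.raises(UndefinedDirectionError):
            normalized_error(0.1, (0, 0, 0))

    @settings(max_examples=200, deadline=None)
    @given(nonzero_vec3, nonzero_vec3)
    def test_magnitude_error_bounded_by_euclidean_error(self, p, o):
        assert magnitude_error(p, o) <= force_prediction_error(p, o) + 1e-12

    @settings(max_examples=100, deadline=None)
    @given(nonzero_vec3, nonzero_vec3, rot)
    def test_errors_invariant_under_common_rotation(self, p, o, r):
        rp, ro = r.apply(p), r.apply(o)
        assert force_prediction_error(rp, ro) == pytest.approx(
            force_prediction_error(p, o), abs=1e-9)
        assert magnitude_error(rp, ro) == pytest.approx(
            magnitude_error(p, o), abs=1e-9)
        # arccos loses ~sqrt(eps) precision for near-parallel vectors
        assert direction_error(rp, ro) == pytest.approx(
            direction_error(p, o), abs=1e-5)

    @settings(max_examples=100, deadline=None)
    @given(nonzero_vec3, nonzero_vec3)
    def test_direction_error_range(self, p, o):
        assert 0.0 <= direction_error(p, o) <= 180.0


class TestSagittalAngle:
    def test_axis_convention_anchors(self):
        assert sagittal_angle((0.5, 1, 0)) == pytest.approx(0.0)    # pure rostral
        assert sagittal_angle((0, 0, -1)) == pytest.approx(-90.0)   # pure ventral
        assert sagittal_angle((0, -1, 0)) == pytest.approx(180.0)   # pure caudal

    def test_mediolateral_component_ignored(self):
        assert sagittal_angle((5.0, 0.3, 0.7)) == sagittal_angle((0.0, 0.3, 0.7))

    def test_zero_sagittal_projection_raises(self):
        with pytest.raises(UndefinedDirectionError):
            sagittal_angle((1, 0, 0))


class TestAngularDeviation:
    def test_identical_vectors_deviate_zero(self):
        devs = angular_deviation_to_mean([[1, 2, 0]] * 5)
        np.testing.assert_allclose(devs, 0.0, atol=1e-5)

    def test_symmetric_pair_bisected_by_mean(self):
        a = np.array([np.cos(np.radians(10)), np.sin(np.radians(10)), 0])
        b = np.array([np.cos(np.radians(-10)), np.sin(np.radians(-10)), 0])
        np.testing.assert_allclose(angular_deviation_to_mean([a, b]),
                                   [10.0, 10.0], atol=1e-9)

    def test_zero_mean_vector_raises(self):
        with pytest.raises(UndefinedDirectionError):
            angular_deviation_to_mean([[1, 0, 0], [-1, 0, 0]])


class TestCircularDeviation:
    def test_equal_angles_give_zero(self):
        assert circular_angular_deviation([42.0] * 7) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_four_points_closed_form(self):
        # R = 0 so s = sqrt(2) rad = 81.0285 degrees
        out = circular_angular_deviation([0, 90, 180, 270])
        assert out == pytest.approx(np.degrees(np.sqrt(2)), abs=1e-9)

    def test_matches_direct_resultant_formula(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            angles = rng.uniform(-180, 180, size=rng.integers(2, 30))
            # brute-force: accumulate the resultant term by term
            c = sum(np.cos(np.radians(a)) for a in angles) / len(angles)
            s = sum(np.sin(np.radians(a)) for a in angles) / len(angles)
            expected = np.degrees(np.sqrt(2 * (1 - np.hypot(s, c))))
            assert circular_angular_deviation(angles) == pytest.approx(
                expected, abs=1e-10)

    def test_angular_sd_matches_scipy_circstd(self):
        rng = np.random.default_rng(9)
        angles = rng.normal(30, 15, size=50)
        expected = np.degrees(sps.circstd(np.radians(angles)))
        assert angular_sd(angles) == pytest.approx(expected, rel=1e-9)

    def test_empty_input_raises(self):
        with pytest.raises(DegenerateDataError):
            circular_angular_deviation([])


class TestCombinedR2:
    def test_perfect_prediction_is_one(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(size=(10, 3))
        assert combined_r2(obs, obs) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        rng = np.random.default_rng(2)
        obs = rng.normal(size=(15, 3))
        pred = np.tile(obs.mean(axis=0), (15, 1))
        assert combined_r2(pred, obs) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        pred = rng.normal(size=(20, 3))
        obs = rng.normal(size=(20, 3))
        ss_res = ss_tot = 0.0
        for axis in range(3):
            mean_axis = sum(obs[i, axis] for i in range(20)) / 20
            for i in range(20):
                ss_res += (obs[i, axis] - pred[i, axis]) ** 2
                ss_tot += (obs[i, axis] - mean_axis) ** 2
        assert combined_r2(pred, obs) == pytest.approx(1 - ss_res / ss_tot,
                                                       abs=1e-12)

    def test_reorder_invariance(self):
        rng = np.random.default_rng(5)
        pred = rng.normal(size=(12, 3))
        obs = rng.normal(size=(12, 3))
        perm = rng.permutation(12)
        assert combined_r2(pred[perm], obs[perm]) == pytest.approx(
            combined_r2(pred, obs), rel=1e-12)

    def test_noise_degrades_r2_in_expectation(self):
        rng = np.random.default_rng(6)
        pred = rng.normal(scale=1.0, size=(40, 3))
        means = []
        for sd in (0.05, 0.3, 1.0):
            vals = [combined_r2(pred, pred + rng.normal(scale=sd, size=pred.shape))
                    for _ in range(50)]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_constant_observations_raise(self):
        with pytest.raises(DegenerateDataError):
            combined_r2(np.zeros((5, 3)), np.ones((5, 3)))
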