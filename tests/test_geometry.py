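"""Transform model, landmark fitting and ΔD/ΔT/Δθ metric behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellalign.geometry import (
    AlignmentMetrics,
    DegenerateConfigurationError,
    LandmarkPairs,
    NotASimilarityError,
    RigidTransform,
    evaluate_alignment,
    fit_similarity,
    matrix_from_params,
    params_from_matrix,
    pixels_to_microns,
)

finite_angle = st.floats(-math.pi + 1e-6, math.pi)
finite_len = st.floats(-500, 500)


class TestMatrixParams:
    @pytest.mark.parametrize(
        "params,point,expected",
        [
            ((0.0, 1.0, 0.0, 0.0), (3.0, -2.0), (3.0, -2.0)),
            ((math.pi / 2, 1.0, 0.0, 0.0), (1.0, 0.0), (0.0, 1.0)),
            ((math.pi, 2.0, 1.0, 1.0), (1.0, 0.0), (-1.0, 1.0)),
        ],
    )
    def test_known_mappings(self, params, point, expected):
        M = matrix_from_params(*params)
        out = M @ np.array([point[0], point[1], 1.0])
        assert np.allclose(out[:2], expected, atol=1e-12)

    def test_identity_matrix(self):
        assert np.allclose(matrix_from_params(0, 1, 0, 0), np.eye(3))

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            matrix_from_params(0.1, 0.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            RigidTransform(theta=0.1, scale=-2.0)

    def test_params_identity(self):
        assert params_from_matrix(np.eye(3)) == (0.0, 1.0, 0.0, 0.0)

    def test_round_trip_example(self):
        got = params_from_matrix(matrix_from_params(0.3, 1.0, 10.0, -5.0))
        assert np.allclose(got, (0.3, 1.0, 10.0, -5.0), atol=1e-12)

    def test_reflection_rejected(self):
        M = np.eye(3)
        M[1, 1] = -1.0
        with pytest.raises(NotASimilarityError):
            params_from_matrix(M)

    def test_anisotropic_rejected(self):
        M = np.diag([2.0, 1.0, 1.0])
        with pytest.raises(NotASimilarityError):
            params_from_matrix(M)

    @settings(max_examples=50, deadline=None)
    @given(theta=finite_angle, scale=st.floats(0.1, 10), dx=finite_len, dy=finite_len)
    def test_round_trip_property(self, theta, scale, dx, dy):
        M = matrix_from_params(theta, scale, dx, dy)
        M2 = matrix_from_params(*params_from_matrix(M))
        assert np.allclose(M, M2, atol=1e-9)


class TestPixelsToMicrons:
    @pytest.mark.parametrize(
        "pixel_size,expected",
        [(0.325, (32.5, 65.0)), (0.212, (21.2, 42.4)), (1.0, (100.0, 200.0))],
    )
    def test_scaling(self, pixel_size, expected):
        out = pixels_to_microns(np.array([[100.0, 200.0]]), pixel_size)
        assert np.allclose(out, [expected])

    def test_nonpositive_pixel_size(self):
        with pytest.raises(ValueError):
            pixels_to_microns(np.zeros((1, 2)), 0.0)


def _random_landmarks(rng, n=8, scale=200.0):
    return rng.uniform(0, scale, (n, 2))


class TestFitSimilarity:
    def test_identity_when_target_equals_source(self, rng):
        pts = _random_landmarks(rng)
        fit = fit_similarity(LandmarkPairs(source=pts, target=pts))
        assert abs(fit.transform.theta) < 1e-12
        assert abs(fit.transform.scale - 1) < 1e-12
        assert fit.rms_residual < 1e-12

    def test_recovers_generating_transform(self, rng):
        truth = RigidTransform(theta=0.1, scale=1.0, dx=30.0, dy=-12.0)
        src = _random_landmarks(rng)
        fit = fit_similarity(LandmarkPairs(source=src, target=truth.apply(src)))
        assert abs(fit.transform.theta - truth.theta) < 1e-9
        assert abs(fit.transform.dx - truth.dx) < 1e-9
        assert abs(fit.transform.dy - truth.dy) < 1e-9

    def test_two_pairs_exact(self):
        # 2 non-coincident pairs determine the 4-DOF similarity exactly
        truth = RigidTransform(theta=-0.4, scale=1.7, dx=5.0, dy=8.0)
        src = np.array([[0.0, 0.0], [10.0, 4.0]])
        fit = fit_similarity(LandmarkPairs(source=src, target=truth.apply(src)))
        assert fit.rms_residual < 1e-9
        assert abs(fit.transform.scale - 1.7) < 1e-9

    def test_fix_scale_clamps(self, rng):
        src = _random_landmarks(rng)
        tgt = 2.0 * src  # pure scaling
        fit = fit_similarity(LandmarkPairs(source=src, target=tgt), fix_scale=True)
        assert fit.transform.scale == 1.0

    def test_coincident_sources_degenerate(self):
        src = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-12]])
        with pytest.raises((DegenerateConfigurationError, ValueError)):
            fit_similarity(LandmarkPairs(source=src, target=src + 5))

    def test_pair_order_invariance(self, rng):
        truth = RigidTransform(theta=0.2, dx=3.0, dy=4.0)
        src = _random_landmarks(rng)
        tgt = truth.apply(src) + rng.normal(0, 0.5, src.shape)
        a = fit_similarity(LandmarkPairs(source=src, target=tgt))
        perm = rng.permutation(len(src))
        b = fit_similarity(LandmarkPairs(source=src[perm], target=tgt[perm]))
        assert np.allclose(a.transform.matrix, b.transform.matrix, atol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(
        theta=finite_angle,
        scale=st.floats(0.2, 5),
        dx=finite_len,
        dy=finite_len,
        n=st.integers(2, 12),
        seed=st.integers(0, 10_000),
    )
    def test_noiseless_recovery_property(self, theta, scale, dx, dy, n, seed):
        rng = np.random.default_rng(seed)
        src = rng.uniform(0, 100, (n, 2))
        if np.ptp(src, axis=0).max() < 1e-3:
            return  # nearly coincident draw: not a valid configuration
        truth = RigidTransform(theta=theta, scale=scale, dx=dx, dy=dy)
        fit = fit_similarity(LandmarkPairs(source=src, target=truth.apply(src)))
        assert np.allclose(fit.transform.matrix, truth.matrix, rtol=1e-6, atol=1e-6)


class TestEvaluateAlignment:
    def _exact_setup(self, rng):
        truth = RigidTransform(theta=0.15, dx=20.0, dy=-10.0)
        src = _random_landmarks(rng)
        return truth, LandmarkPairs(source=src, target=truth.apply(src))

    def test_zero_when_exact(self, rng):
        truth, lm = self._exact_setup(rng)
        m = evaluate_alignment(truth, truth, lm)
        assert m.delta_D < 1e-9 and m.delta_T < 1e-9 and m.delta_theta < 1e-9

    def test_pure_shift_gives_pythagorean_dD(self, rng):
        truth, lm = self._exact_setup(rng)
        shifted = RigidTransform(
            theta=truth.theta, dx=truth.dx + 3.0, dy=truth.dy + 4.0
        )
        m = evaluate_alignment(shifted, truth, lm)
        assert abs(m.delta_D - 5.0) < 1e-9
        expected_dT = abs(
            math.hypot(truth.dx + 3, truth.dy + 4) - math.hypot(truth.dx, truth.dy)
        )
        assert abs(m.delta_T - expected_dT) < 1e-9
        assert m.delta_theta < 1e-9

    def test_rotation_about_centroid_gives_dtheta(self, rng):
        truth, lm = self._exact_setup(rng)
        c = lm.target.mean(axis=0)
        extra = math.radians(2.0)
        rot_about_c = RigidTransform(
            theta=extra,
            dx=float(c[0] - math.cos(extra) * c[0] + math.sin(extra) * c[1]),
            dy=float(c[1] - math.sin(extra) * c[0] - math.cos(extra) * c[1]),
        )
        estimated = rot_about_c.compose(truth)
        m = evaluate_alignment(estimated, truth, lm)
        assert abs(m.delta_theta - 2.0) < 1e-9

    def test_dD_invariant_to_landmark_order(self, rng):
        truth, lm = self._exact_setup(rng)
        est = RigidTransform(theta=truth.theta + 0.01, dx=truth.dx + 2, dy=truth.dy)
        m1 = evaluate_alignment(est, truth, lm)
        perm = rng.permutation(len(lm))
        lm2 = LandmarkPairs(source=lm.source[perm], target=lm.target[perm])
        m2 = evaluate_alignment(est, truth, lm2)
        assert abs(m1.delta_D - m2.delta_D) < 1e-12

    def test_dtheta_wraps_to_half_circle(self):
        # 359 deg of raw difference reports as 1 deg
        a = RigidTransform(theta=math.radians(179.5))
        b = RigidTransform(theta=math.radians(-179.5))
        lm = LandmarkPairs(source=np.array([[0, 0], [1, 1.0]]), target=np.array([[0, 0], [1, 1.0]]))
        m = evaluate_alignment(a, b, lm)
        assert abs(m.delta_theta - 1.0) < 1e-9
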