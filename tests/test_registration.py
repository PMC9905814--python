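"""Rigid registration: closed-form cases, the independent quaternion
(Horn absolute-orientation) oracle, and transform-algebra properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynifs.registration import (
    LandmarkCorrespondence,
    RigidTransform,
    apply_transform,
    compose,
    estimate_rigid_transform,
    invert,
    residual_rms,
    rotation_angle_deg,
)

from .conftest import axis_angle, random_rotation

TETRA = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                  [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])


def horn_quaternion(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent oracle: Horn's closed-form absolute orientation via the
    largest eigenvector of the 4x4 quaternion matrix."""
    mu_p = p.mean(axis=0)
    mu_q = q.mean(axis=0)
    m = (p - mu_p).T @ (q - mu_q)
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    w, v = np.linalg.eigh(n)
    qw, qx, qy, qz = v[:, -1]
    r = np.array([
        [1 - 2 * (qy**2 + qz**2), 2 * (qx * qy - qw * qz), 2 * (qx * qz + qw * qy)],
        [2 * (qx * qy + qw * qz), 1 - 2 * (qx**2 + qz**2), 2 * (qy * qz - qw * qx)],
        [2 * (qx * qz - qw * qy), 2 * (qy * qz + qw * qx), 1 - 2 * (qx**2 + qy**2)],
    ])
    return r, -r @ mu_p + mu_q


class TestEstimate:
    def test_identity_case(self):
        tf = estimate_rigid_transform(LandmarkCorrespondence(TETRA, TETRA))
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-12)

    def test_pure_translation(self):
        tf = estimate_rigid_transform(
            LandmarkCorrespondence(TETRA, TETRA + [1.0, 2.0, 3.0]))
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation, [1.0, 2.0, 3.0], atol=1e-12)

    def test_matches_quaternion_oracle_on_random_instances(self, rng):
        """SVD solution vs Horn's quaternion method, 1000 random instances."""
        for _ in range(1000):
            n = rng.integers(3, 10)
            p = rng.normal(size=(n, 3)) * 100
            while np.linalg.svd(p - p.mean(0), compute_uv=False)[1] < 1e-3:
                p = rng.normal(size=(n, 3)) * 100
            r0 = random_rotation(rng)
            t0 = rng.normal(size=3) * 50
            noise = rng.normal(size=(n, 3)) * rng.choice([0.0, 0.5])
            q = p @ r0.T + t0 + noise
            tf = estimate_rigid_transform(LandmarkCorrespondence(p, q))
            r_h, t_h = horn_quaternion(p, q)
            assert rotation_angle_deg(tf.rotation, r_h) < 1e-8
            assert np.linalg.norm(tf.translation - t_h) < 1e-8

    def test_noiseless_exact_recovery(self, rng):
        for _ in range(50):
            p = rng.normal(size=(6, 3)) * 100
            r0 = random_rotation(rng)
            t0 = rng.normal(size=3) * 200
            tf = estimate_rigid_transform(LandmarkCorrespondence(p, p @ r0.T + t0))
            corr = LandmarkCorrespondence(p, p @ r0.T + t0)
            assert residual_rms(tf, corr) < 1e-9

    def test_least_squares_optimality_under_perturbation(self, rng):
        p = rng.normal(size=(8, 3)) * 50
        q = p @ random_rotation(rng).T + rng.normal(size=3) * 10 \
            + rng.normal(size=(8, 3)) * 1.0
        corr = LandmarkCorrespondence(p, q)
        tf = estimate_rigid_transform(corr)
        base = residual_rms(tf, corr)
        for _ in range(50):
            dr = axis_angle(rng.normal(size=3), rng.uniform(1e-4, 1e-2))
            dt = rng.normal(size=3) * 1e-2
            pert = RigidTransform(dr @ tf.rotation, tf.translation + dt)
            assert residual_rms(pert, corr) >= base - 1e-12

    def test_reflection_guard_on_degenerate_data(self, rng):
        """Planar + noisy configurations must still give det(R) = +1."""
        for _ in range(200):
            p = rng.normal(size=(4, 3)) * 10
            p[:, 2] = 0.0  # coplanar source
            q = -p + rng.normal(size=(4, 3)) * 5  # adversarial target
            try:
                tf = estimate_rigid_transform(LandmarkCorrespondence(p, q))
            except ValueError:
                continue
            assert np.linalg.det(tf.rotation) > 0

    def test_errors(self):
        with pytest.raises(ValueError):
            LandmarkCorrespondence(TETRA[:2], TETRA[:2])
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            estimate_rigid_transform(LandmarkCorrespondence(line, line))
        bad = TETRA.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            LandmarkCorrespondence(bad, TETRA)


class TestApplyComposeInvert:
    def test_identity(self):
        np.testing.assert_array_equal(
            apply_transform(RigidTransform.identity(), TETRA), TETRA)

    def test_quarter_turn_closed_form(self):
        r = axis_angle([0, 0, 1], np.pi / 2)
        b = apply_transform(RigidTransform(r, np.zeros(3)), np.array([1.0, 0, 0]))
        np.testing.assert_allclose(b, [0.0, 1.0, 0.0], atol=1e-15)

    def test_apply_then_inverse_roundtrip(self, rng):
        tf = RigidTransform(random_rotation(rng), rng.normal(size=3) * 100)
        pts = rng.normal(size=(20, 3)) * 100
        back = apply_transform(invert(tf), apply_transform(tf, pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_distance_preservation(self, rng):
        tf = RigidTransform(random_rotation(rng), rng.normal(size=3))
        pts = rng.normal(size=(10, 3)) * 100
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        out = apply_transform(tf, pts)
        d1 = np.linalg.norm(out[:, None] - out[None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_two_half_turns_compose(self):
        r45 = RigidTransform(axis_angle([0, 0, 1], np.pi / 4), np.zeros(3))
        r90 = compose(r45, r45)
        np.testing.assert_allclose(r90.rotation, axis_angle([0, 0, 1], np.pi / 2),
                                   atol=1e-12)

    def test_compose_with_inverse_is_identity(self, rng):
        tf = RigidTransform(random_rotation(rng), rng.normal(size=3) * 10)
        ident = compose(tf, invert(tf))
        np.testing.assert_allclose(ident.rotation, np.eye(3), atol=1e-12)
        assert np.linalg.norm(ident.translation) < 1e-9

    def test_invert_identity(self):
        ident = invert(RigidTransform.identity())
        np.testing.assert_array_equal(ident.rotation, np.eye(3))


class TestRotationAngle:
    def test_same_rotation_zero(self, rng):
        r = random_rotation(rng)
        assert rotation_angle_deg(r, r) < 1e-10

    def test_quarter_turn(self, rng):
        r1 = random_rotation(rng)
        r2 = r1 @ axis_angle([0, 0, 1], np.pi / 2)
        assert abs(rotation_angle_deg(r1, r2) - 90.0) < 1e-9

    @given(theta=st.floats(0.001, 179.999))
    @settings(max_examples=50, deadline=None)
    def test_axis_angle_construction_oracle(self, theta):
        r = axis_angle([1.0, 2.0, -0.5], np.deg2rad(theta))
        assert abs(rotation_angle_deg(np.eye(3), r) - theta) < 1e-9

    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            rotation_angle_deg(np.diag([1.0, 1.0, -1.0]), np.eye(3))
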