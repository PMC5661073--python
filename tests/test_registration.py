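"""Spatial normalization: recovery of known poses, inversion, mask warping."""

from dataclasses import replace

import numpy as np
import pytest

from rsnrspect import (
    Grid,
    MaskVolume,
    RegistrationConfig,
    apply_transform,
    dice,
    estimate_normalization,
    inverse_consistency_residual,
    invert_transform,
    make_lv_phantom,
)
from rsnrspect.phantom import PhantomSpec, Pose
from rsnrspect.registration import identity_transform, translation_transform, SpatialTransform

GRID = Grid((48, 48, 48), (4.0, 4.0, 4.0))


def posed_pair(dr=(0.0, 0.0, 0.0), dt=(0.0, 0.0, 0.0), seed=5):
    """A canonical phantom and the same phantom under an extra rigid pose.

    The short axes are unequal so that rotation about the long axis is
    identifiable (a perfect ellipsoid of revolution leaves that spin as a
    gauge freedom of the registration), and counting noise is disabled so
    the recovered transform is compared against an exact ground truth.
    """
    base = PhantomSpec(
        grid=GRID, seed=seed, epi_axes=(36.0, 29.0, 47.0), endo_axes=(25.0, 19.0, 36.0),
        noise="none",
    )
    canon = make_lv_phantom(base, stress_pose=base.pose)
    pose2 = Pose(
        tuple(np.asarray(base.pose.rotation_deg) + dr),
        tuple(np.asarray(base.pose.translation_mm) + dt),
    )
    moved = make_lv_phantom(replace(base, pose=pose2, seed=seed + 1), stress_pose=pose2)
    return canon, moved, base.pose, pose2


def true_map(grid: Grid, pose_fixed: Pose, pose_moving: Pose):
    """World map sending fixed-space points to the matching moving-space
    points for two poses of the same phantom."""
    from rsnrspect.phantom import _rotation_matrix

    c = grid.center()
    Rf = _rotation_matrix(pose_fixed.rotation_deg)
    Rm = _rotation_matrix(pose_moving.rotation_deg)
    tf = np.asarray(pose_fixed.translation_mm)
    tm = np.asarray(pose_moving.translation_mm)
    L = Rm @ Rf.T

    def f(x):
        return L @ (np.asarray(x) - c - tf) + c + tm

    return L, f


def rotation_angle_deg(L_est, L_true):
    R = L_est @ np.linalg.inv(L_true)
    # nearest rotation via polar decomposition, then the rotation angle
    u, _, vt = np.linalg.svd(R)
    Q = u @ vt
    return np.degrees(np.arccos(np.clip((np.trace(Q) - 1) / 2, -1, 1)))


class TestEstimation:
    def test_self_registration_is_near_identity(self):
        canon, _, _, _ = posed_pair()
        t = estimate_normalization(canon.rest, canon.rest)
        A = t.affine_matrix()
        center = np.asarray(GRID.center())
        assert np.linalg.norm(t.transform_point(center) - center) < 1.0  # mm
        assert rotation_angle_deg(A[:3, :3], np.eye(3)) < 1.0

    def test_known_translation_recovered_within_1mm(self):
        dt = (8.0, -4.0, 4.0)
        canon, moved, pf, pm = posed_pair(dt=dt)
        t = estimate_normalization(moving=moved.rest, fixed=canon.rest)
        _, f_true = true_map(GRID, pf, pm)
        x0 = GRID.center() + np.asarray(pf.translation_mm)
        err = np.linalg.norm(t.transform_point(x0) - f_true(x0))
        assert err < 1.0

    def test_known_rotation_recovered_within_2deg(self):
        canon, moved, pf, pm = posed_pair(dr=(0.0, 0.0, 10.0))
        t = estimate_normalization(moving=moved.rest, fixed=canon.rest)
        L_true, _ = true_map(GRID, pf, pm)
        assert rotation_angle_deg(t.affine_matrix()[:3, :3], L_true) < 2.0

    def test_similarity_never_degrades(self):
        canon, moved, _, _ = posed_pair(dt=(6.0, 2.0, -4.0))
        t = estimate_normalization(moving=moved.rest, fixed=canon.rest)
        # sitk minimizes (NCC is negated): final must not exceed initial
        assert t.similarity_final <= t.similarity_initial

    def test_constant_volume_rejected(self):
        from rsnrspect import Volume3D

        flat = Volume3D(np.full(GRID.dims, 3.0), GRID)
        canon, _, _, _ = posed_pair()
        with pytest.raises(ValueError, match="constant"):
            estimate_normalization(flat, canon.rest)


class TestInversion:
    def test_identity_inverts_to_identity(self):
        t = identity_transform(GRID, GRID)
        inv = invert_transform(t)
        p = (10.0, 20.0, 30.0)
        np.testing.assert_allclose(inv.transform_point(p), p, atol=1e-12)

    def test_pure_translation_inverts_exactly(self):
        t = translation_transform((5.0, 0.0, 0.0), GRID, GRID)
        inv = invert_transform(t)
        np.testing.assert_allclose(
            inv.affine_matrix()[:3, 3], -t.affine_matrix()[:3, 3], atol=1e-12
        )

    def test_deformable_inverse_residual_below_half_voxel(self):
        canon, moved, _, _ = posed_pair(dr=(0.0, 0.0, 6.0), dt=(5.0, -3.0, 2.0))
        cfg = RegistrationConfig(deformable=True, deformable_iterations=5)
        t = estimate_normalization(moving=moved.rest, fixed=canon.rest, config=cfg)
        t_inv = invert_transform(t)
        resid = inverse_consistency_residual(t, t_inv, canon.truth_mask_rest)
        assert resid < 0.5 * 4.0  # half a voxel in mm

    def test_singular_affine_rejected(self):
        import SimpleITK as sitk

        bad = sitk.AffineTransform(3)
        bad.SetMatrix((1.0, 0, 0, 0, 1.0, 0, 0, 0, 0.0))
        with pytest.raises(ValueError, match="singular"):
            invert_transform(SpatialTransform(bad, GRID, GRID))


class TestApplication:
    def test_identity_transform_returns_input(self, noisefree_phantom):
        t = identity_transform(GRID, GRID)
        out = apply_transform(noisefree_phantom.rest, t, GRID)
        np.testing.assert_allclose(out.values, noisefree_phantom.rest.values, atol=1e-9)

    def test_integer_voxel_mask_shift_preserves_count(self, noisefree_phantom):
        mask = noisefree_phantom.truth_mask_rest
        t = translation_transform((8.0, 0.0, 0.0), GRID, GRID)  # 2 voxels along x
        out = apply_transform(mask, t, GRID)
        assert out.n_voxels == mask.n_voxels  # LV is interior; nothing clipped
        shifted = np.zeros_like(mask.values)
        shifted[2:] = mask.values[:-2]
        np.testing.assert_array_equal(out.values, shifted)

    def test_unknown_method_rejected(self, noisefree_phantom):
        t = identity_transform(GRID, GRID)
        with pytest.raises(ValueError, match="method"):
            apply_transform(noisefree_phantom.rest, t, GRID, method="spline")

    def test_mask_roundtrip_dice(self):
        canon, moved, _, _ = posed_pair(dr=(0.0, 0.0, 8.0), dt=(6.0, -2.0, 4.0))
        t = estimate_normalization(moving=moved.rest, fixed=canon.rest)
        warped = apply_transform(moved.truth_mask_rest, t, canon.rest.grid)
        back = apply_transform(warped, invert_transform(t), moved.rest.grid)
        assert dice(back, moved.truth_mask_rest) >= 0.95

    def test_transform_serialization_roundtrip(self, tmp_path):
        canon, moved, _, _ = posed_pair(dt=(4.0, 0.0, -4.0))
        t = estimate_normalization(moving=moved.rest, fixed=canon.rest)
        t.save(tmp_path / "norm")
        back = SpatialTransform.load(tmp_path / "norm")
        p = (30.0, 40.0, 50.0)
        np.testing.assert_allclose(back.transform_point(p), t.transform_point(p), atol=1e-9)
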