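import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stentoct import synthetic as syn
from stentoct.pose import (
    PoseError,
    estimate_pose,
    fit_stent_axis,
    measure_insertion_distance,
    measure_pitch,
    measure_yaw,
    stent_midpoint_um,
    yaw_pair_consistent,
    yaw_pair_inscribed_angle,
)
from stentoct.segmentation import StentMask
from stentoct.volume import Landmarks


def mask_from_points(points, shape):
    m = np.zeros(shape, dtype=bool)
    for p in points:
        m[tuple(p)] = True
    return StentMask(mask=m, roi=tuple((0, s) for s in shape), threshold_used=1.0)


def solid_cylinder_mask(direction, length_um=300.0, radius_um=25.0, pitch_um=5.0, shape=(100, 100, 100)):
    """Rasterize a solid cylinder along `direction` on an isotropic grid."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    center = (np.array(shape) - 1) * pitch_um / 2
    idx = np.indices(shape).reshape(3, -1).T * pitch_um
    rel = idx - center
    t = rel @ direction
    r = np.linalg.norm(rel - np.outer(t, direction), axis=1)
    sel = (np.abs(t) <= length_um / 2) & (r <= radius_um)
    m = np.zeros(shape, dtype=bool)
    m.reshape(-1)[sel] = True
    return StentMask(mask=m, roi=tuple((0, s) for s in shape), threshold_used=1.0)


def bruteforce_best_line(points):
    """Direction minimizing summed squared orthogonal distance, by
    coarse-to-fine grid search over the unit hemisphere."""
    c = points.mean(axis=0)
    rel = points - c
    total = (rel**2).sum()

    def ssd(u):
        return total - ((rel @ u) ** 2).sum()

    best, best_u = np.inf, None
    for step, center in [(np.radians(5), None), (np.radians(0.25), "refine")]:
        if center is None:
            thetas = np.arange(0, np.pi / 2 + step, step)
            phis = np.arange(0, 2 * np.pi, step)
        else:
            t0 = np.arccos(np.clip(best_u[1], -1, 1))
            p0 = np.arctan2(best_u[0], best_u[2])
            thetas = t0 + np.linspace(-np.radians(6), np.radians(6), 49)
            phis = p0 + np.linspace(-np.radians(6), np.radians(6), 49)
        for th in thetas:
            for ph in phis:
                u = np.array([np.sin(th) * np.sin(ph), np.cos(th), np.sin(th) * np.cos(ph)])
                v = ssd(u)
                if v < best:
                    best, best_u = v, u
    return best_u


def angle_between_deg(a, b):
    return np.degrees(np.arccos(np.clip(abs(np.dot(a, b)), 0, 1)))


class TestAxisFit:
    def test_cylinder_along_depth_axis(self):
        mask = solid_cylinder_mask([0, 1, 0], shape=(40, 80, 40), pitch_um=5.0)
        _, axis, aniso = fit_stent_axis(mask, (5.0, 5.0, 5.0))
        np.testing.assert_allclose(axis, [0, 1, 0], atol=1e-6)
        assert aniso > 1.2

    def test_oblique_cylinder_matches_bruteforce_line_oracle(self):
        theta, phi = np.radians(30), np.radians(20)
        truth = np.array([np.sin(theta) * np.sin(phi), np.cos(theta), np.sin(theta) * np.cos(phi)])
        mask = solid_cylinder_mask(truth, shape=(90, 90, 90), pitch_um=5.0)
        pitches = (5.0, 5.0, 5.0)
        _, axis, _ = fit_stent_axis(mask, pitches)
        assert angle_between_deg(axis, truth) <= 1.0
        pts = np.argwhere(mask.mask) * 5.0
        oracle = bruteforce_best_line(pts)
        assert angle_between_deg(axis, oracle) <= 1.0

    def test_spherical_blob_is_degenerate(self, rng):
        idx = np.indices((30, 30, 30)).reshape(3, -1).T
        r = np.linalg.norm(idx - 15, axis=1)
        m = np.zeros((30, 30, 30), dtype=bool)
        m.reshape(-1)[r <= 10] = True
        mask = StentMask(mask=m, roi=((0, 30),) * 3, threshold_used=1.0)
        with pytest.raises(PoseError, match="degenerate"):
            fit_stent_axis(mask, (5.0, 5.0, 5.0))

    def test_empty_mask(self):
        with pytest.raises(PoseError, match="empty"):
            fit_stent_axis(mask_from_points([], (5, 5, 5)), (5.0, 5.0, 5.0))

    def test_axis_stable_under_one_voxel_dilation(self, small_segmentation):
        from scipy import ndimage

        volume, truth, _, mask = small_segmentation
        pose = estimate_pose(mask, volume.pitches_um, truth.landmarks)
        dilated = StentMask(
            mask=_clip_to_roi(ndimage.binary_dilation(mask.mask), mask.roi),
            roi=mask.roi,
            threshold_used=mask.threshold_used,
        )
        pose2 = estimate_pose(dilated, volume.pitches_um, truth.landmarks)
        assert abs(pose.pitch_deg - pose2.pitch_deg) <= 2.0
        assert abs(pose.yaw_deg - pose2.yaw_deg) <= 2.0


def _clip_to_roi(mask, roi):
    out = np.zeros_like(mask)
    (y0, y1), (z0, z1), (x0, x1) = roi
    out[y0:y1, z0:z1, x0:x1] = mask[y0:y1, z0:z1, x0:x1]
    return out


class TestAngles:
    def test_pitch_zero_when_axis_is_ideal_insertion(self):
        alpha = np.radians(60.0)
        axis = np.array([0.0, np.sin(alpha), -np.cos(alpha)])
        assert measure_pitch(axis, 60.0) == pytest.approx(0.0, abs=1e-9)

    def test_pitch_ninety_when_axis_lies_along_tm_line(self):
        alpha = np.radians(60.0)
        axis = np.array([0.0, np.cos(alpha), np.sin(alpha)])
        assert measure_pitch(axis, 60.0) == pytest.approx(90.0, abs=1e-9)

    def test_yaw_reference_cases(self):
        assert measure_yaw(np.array([0.0, 0.3, 0.95])) == pytest.approx(0.0)
        assert measure_yaw(np.array([1.0, 0.0, 0.0])) == pytest.approx(90.0)
        axis = np.array([np.sin(np.radians(30)), 0.0, np.cos(np.radians(30))])
        assert measure_yaw(axis) == pytest.approx(30.0)

    def test_zero_projection_raises(self):
        with pytest.raises(PoseError):
            measure_yaw(np.array([0.0, 1.0, 0.0]))
        with pytest.raises(PoseError):
            measure_pitch(np.array([1.0, 0.0, 0.0]), 60.0)

    @settings(max_examples=50, deadline=None)
    @given(
        y=st.floats(-1, 1),
        z=st.floats(-1, 1),
        x=st.floats(-1, 1),
        alpha=st.floats(0, 179.0),
    )
    def test_angles_folded_and_sign_invariant(self, y, z, x, alpha):
        axis = np.array([y, z, x])
        n = np.linalg.norm(axis)
        if n < 1e-3 or abs(y) + abs(x) < 1e-3 or abs(z) + abs(x) < 1e-3:
            return
        axis = axis / n
        yaw = measure_yaw(axis)
        pitch = measure_pitch(axis, alpha)
        assert 0.0 <= yaw <= 90.0 and 0.0 <= pitch <= 90.0
        assert measure_yaw(-axis) == pytest.approx(yaw, abs=1e-9)
        assert measure_pitch(-axis, alpha) == pytest.approx(pitch, abs=1e-9)


class TestInsertionDistance:
    def test_coincident_points_give_zero(self):
        mask = solid_cylinder_mask([0, 1, 0], shape=(40, 60, 40), pitch_um=5.0)
        pitches = (5.0, 5.0, 5.0)
        c, a, _ = fit_stent_axis(mask, pitches)
        mid = stent_midpoint_um(mask, pitches, c, a)
        assert measure_insertion_distance(c, a, mid, mask=mask, pitches_um=pitches) == pytest.approx(0.0, abs=1e-9)

    def test_missing_landmark_raises(self):
        mask = solid_cylinder_mask([0, 1, 0], shape=(40, 60, 40), pitch_um=5.0)
        c, a, _ = fit_stent_axis(mask, (5.0, 5.0, 5.0))
        with pytest.raises(PoseError, match="landmark"):
            measure_insertion_distance(c, a, None)

    def test_phantom_insertion_distance_recovered(self, small_segmentation):
        volume, truth, _, mask = small_segmentation
        pose = estimate_pose(mask, volume.pitches_um, truth.landmarks)
        assert pose.insertion_distance_mm == pytest.approx(
            truth.pose["insertion_distance_mm"], abs=0.02
        )


class TestYawPair:
    def test_ideal_radial_pair(self):
        assert yaw_pair_inscribed_angle(0.0, 0.0) == 0.0

    def test_equal_split_strategy(self):
        assert yaw_pair_consistent(20.0, 20.0, 40.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(PoseError):
            yaw_pair_inscribed_angle(-1.0, 10.0)
        with pytest.raises(PoseError):
            yaw_pair_inscribed_angle(10.0, 95.0)

    @pytest.mark.parametrize("theta,split", [(35.0, 0.5), (35.0, 0.3), (50.0, 0.5)])
    def test_chord_geometry_oracle_sums_to_theta(self, theta, split):
        """Vector construction on the iris circle reproduces yaw1+yaw2=theta."""
        out = syn.make_yaw_pair_phantoms(theta_deg=theta, split=split, generate_phantoms=False)
        y1, y2 = out["geometric_yaws_deg"]
        assert y1 + y2 == pytest.approx(theta, abs=1e-9)
        assert out["central_angle_deg"] == pytest.approx(2 * theta, abs=1e-9)


class TestFullPoseRecovery:
    def test_round_trip_on_compact_phantom(self, small_segmentation):
        volume, truth, _, mask = small_segmentation
        pose = estimate_pose(mask, volume.pitches_um, truth.landmarks)
        assert pose.pitch_deg == pytest.approx(truth.pose["pitch_deg"], abs=2.0)
        assert pose.yaw_deg == pytest.approx(truth.pose["yaw_deg"], abs=2.0)
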