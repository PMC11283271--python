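"""Stent axis fitting and placement parameters.

Three quantities describe the implant placement:

* **insertion distance** — Euclidean distance (mm) from the stent's
  mid-segment to the annotated insertion point on Schwalbe's line;
* **pitch** — front-view (z, x) angle between the stent axis and the
  ideal insertion direction, i.e. the normal of the trabecular-meshwork
  line (whose inclination to the depth axis is supplied as a landmark);
* **yaw** — top-view (y, x) angle between the stent axis and the fast
  (radial) x axis, the ideal radial insertion.

Both angles are measured on 2D orthographic projections of the fitted
3D axis and folded to [0, 90] degrees; flipping the axis sign changes
neither.  The axis itself is the first principal direction of the
physically scaled mask voxel cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import StentMask
from .volume import Landmarks

__all__ = [
    "StentPose",
    "PoseError",
    "fit_stent_axis",
    "measure_pitch",
    "measure_yaw",
    "measure_insertion_distance",
    "yaw_pair_inscribed_angle",
    "yaw_pair_consistent",
    "estimate_pose",
]

MIN_ANISOTROPY = 1.2


class PoseError(ValueError):
    """Raised for degenerate masks or invalid pose inputs."""


@dataclass
class StentPose:
    """Fitted axis and the three placement parameters."""

    centroid_um: np.ndarray
    axis_unit: np.ndarray
    pitch_deg: float
    yaw_deg: float
    insertion_distance_mm: float
    anisotropy_ratio: float
    shadow_excluded_mask: bool = False

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.axis_unit) - 1.0) > 1e-9:
            raise PoseError("axis_unit must be unit length")
        if not (0.0 <= self.pitch_deg <= 90.0 and 0.0 <= self.yaw_deg <= 90.0):
            raise PoseError("angles must lie in [0, 90] degrees")
        if self.insertion_distance_mm < 0:
            raise PoseError("insertion distance must be >= 0")

    def as_record(self) -> dict:
        return {
            "insertion_distance_mm": round(float(self.insertion_distance_mm), 4),
            "pitch_deg": round(float(self.pitch_deg), 2),
            "yaw_deg": round(float(self.yaw_deg), 2),
            "anisotropy_ratio": round(float(self.anisotropy_ratio), 3),
            "shadow_excluded_mask": self.shadow_excluded_mask,
        }


def _mask_points_um(mask: StentMask, pitches_um: tuple[float, float, float]) -> np.ndarray:
    pts = np.argwhere(mask.mask).astype(float)
    if pts.size == 0:
        raise PoseError("empty mask")
    return pts * np.asarray(pitches_um, dtype=float)


def _orient_headward(axis: np.ndarray) -> np.ndarray:
    """Fix the sign convention: depth (z) component >= 0, tie-broken +x, +y."""
    for comp in (1, 2, 0):
        if abs(axis[comp]) > 1e-12:
            if axis[comp] < 0:
                axis = -axis
            break
    return axis / np.linalg.norm(axis)


def _refine_plane_normal(
    pts: np.ndarray, centroid: np.ndarray, normal: np.ndarray, n_iter: int = 6
) -> np.ndarray:
    """Robust plane normal: iteratively drop off-plane points and refit.

    The flange face is a thin sheet; voxels from the flange rim sit tens
    of micrometers off the face plane and tilt a plain least-squares
    normal by several degrees.  A median/MAD trim (floor 4 um, roughly
    the sheet's own rasterization thickness) removes them.
    """
    for _ in range(n_iter):
        d = (pts - centroid) @ normal
        med = np.median(d)
        sigma = 1.4826 * np.median(np.abs(d - med))
        keep = np.abs(d - med) <= max(3.0 * sigma, 4.0)
        if keep.sum() < 30:
            break
        centroid = pts[keep].mean(axis=0)
        _, _, vt = np.linalg.svd(pts[keep] - centroid, full_matrices=False)
        new = vt[2]
        if new @ normal < 0:
            new = -new
        normal = new
    return normal


def _component_points(
    mask: StentMask,
    pitches_um: tuple[float, float, float],
    link_radius_vox: tuple[int, int, int],
    min_points: int,
) -> list[np.ndarray]:
    """Split the mask into linked components (micrometer point clouds)."""
    from scipy import ndimage

    m = mask.mask
    ry, rz, rx = link_radius_vox
    linked = ndimage.binary_dilation(
        m, structure=np.ones((2 * ry + 1, 2 * rz + 1, 2 * rx + 1), dtype=bool)
    )
    labels, n_comp = ndimage.label(linked, structure=np.ones((3, 3, 3), dtype=bool))
    scale = np.asarray(pitches_um, dtype=float)
    out = []
    for i in range(1, n_comp + 1):
        pts = np.argwhere(m & (labels == i)).astype(float) * scale
        if len(pts) >= min_points:
            out.append(pts)
    return out


def fit_stent_axis(
    mask: StentMask,
    pitches_um: tuple[float, float, float],
    link_radius_vox: tuple[int, int, int] = (1, 4, 1),
    min_component_points: int = 30,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit the implant axis from the segmented voxel cloud.

    Voxel indices are scaled to micrometers (pitches in (y, z, x) index
    order) so anisotropic sampling does not bias directions.  Only the
    illuminated surface of the implant is segmented, so the cloud
    decomposes into surface sheets: the flange face — a plate
    perpendicular to the axis — and the half-tube strip along the
    thorax/head.  Each linked component is classified by its principal
    extents (rod: s1/s2 large; plate: s2/s3 large) and contributes an
    axis candidate — the first principal direction for a rod, the
    robust plane normal for a plate — and the highest-anisotropy
    candidate wins.  (A plate's normal is unbiased where a plain
    whole-cloud principal direction is tilted several degrees by the
    offset between sheets.)

    The sign is chosen head-ward: depth (z) component >= 0.  Returns
    (centroid_um of the whole cloud, axis_unit, anisotropy_ratio of the
    winning feature); a cloud with no feature more anisotropic than 1.2
    has no meaningful axis and raises.
    """
    pts_all = _mask_points_um(mask, pitches_um)
    centroid = pts_all.mean(axis=0)
    components = _component_points(mask, pitches_um, link_radius_vox, min_component_points)
    if not components:
        components = [pts_all]
    best_axis = None
    best_quality = 0.0
    for pts in components:
        c = pts.mean(axis=0)
        _, svals, vt = np.linalg.svd(pts - c, full_matrices=False)
        s = svals / np.sqrt(len(pts))
        rod = s[0] / max(s[1], 1e-12)
        plate = s[1] / max(s[2], 1e-12)
        if plate > rod:
            quality, axis = plate, _refine_plane_normal(pts, c, vt[2])
        else:
            quality, axis = rod, vt[0]
        if quality > best_quality:
            best_quality, best_axis = quality, axis
    if best_axis is None or best_quality < MIN_ANISOTROPY:
        raise PoseError(
            f"degenerate shape: anisotropy ratio {best_quality:.3f} < {MIN_ANISOTROPY}"
        )
    return centroid, _orient_headward(best_axis), float(best_quality)


def _folded_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between 2D directions, folded to [0, 90] degrees."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise PoseError("zero-length projection: angle undefined")
    c = abs(float(np.dot(u, v))) / (nu * nv)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def measure_pitch(axis_unit: np.ndarray, tm_plane_angle_deg: float) -> float:
    """Front-view angle between the stent axis and the ideal insertion.

    The TM line in the front (z, x) view is inclined at
    ``tm_plane_angle_deg`` to the depth axis; the ideal insertion is
    perpendicular to that line.  The axis is projected into the front
    view and the unsigned angle to the TM-line normal reported.
    """
    if not (0.0 <= tm_plane_angle_deg < 180.0):
        raise PoseError("tm_plane_angle_deg must lie in [0, 180)")
    a = np.radians(tm_plane_angle_deg)
    # TM line direction (z, x) = (cos a, sin a); its in-plane normal,
    # oriented into the tissue (positive depth):
    normal = np.array([np.sin(a), -np.cos(a)])
    proj = np.array([axis_unit[1], axis_unit[2]])  # (z, x)
    return _folded_angle_deg(proj, normal)


def measure_yaw(axis_unit: np.ndarray) -> float:
    """Top-view angle between the stent axis and the radial (x) axis.

    The fast-scan axis is aligned with the iris radius during
    acquisition, so yaw is read directly against the horizontal axis of
    the top (y, x) view.
    """
    proj = np.array([axis_unit[0], axis_unit[2]])  # (y, x)
    return _folded_angle_deg(proj, np.array([0.0, 1.0]))


def stent_midpoint_um(
    mask: StentMask,
    pitches_um: tuple[float, float, float],
    centroid_um: np.ndarray,
    axis_unit: np.ndarray,
) -> np.ndarray:
    """Axis-parameterized midpoint of the masked extent.

    The centroid projected onto the axis, re-centered between the
    extreme axial projections of the mask — the "middle segment" point
    used for the insertion-distance measurement.
    """
    pts = _mask_points_um(mask, pitches_um)
    t = (pts - centroid_um) @ axis_unit
    return centroid_um + axis_unit * (t.min() + t.max()) / 2.0


def measure_insertion_distance(
    centroid_um: np.ndarray,
    axis_unit: np.ndarray,
    schwalbe_point_um,
    mask: StentMask | None = None,
    pitches_um: tuple[float, float, float] | None = None,
) -> float:
    """Distance (mm) from the stent mid-segment to the Schwalbe's-line point.

    When the mask and pitches are supplied the mid-segment is the
    midpoint of the masked extent along the axis; otherwise the centroid
    stands in (identical for a symmetric voxel cloud).
    """
    if schwalbe_point_um is None:
        raise PoseError("missing Schwalbe's-line landmark")
    if mask is not None and pitches_um is not None:
        mid = stent_midpoint_um(mask, pitches_um, centroid_um, axis_unit)
    else:
        mid = np.asarray(centroid_um, dtype=float)
    return float(np.linalg.norm(mid - np.asarray(schwalbe_point_um, dtype=float)) / 1000.0)


def yaw_pair_inscribed_angle(yaw1_deg: float, yaw2_deg: float) -> float:
    """Inscribed angle formed by two stents sharing the corneal incision.

    Both stents are implanted through one corneal incision (the
    fulcrum); by the inscribed-angle relation the sum of their yaws
    equals the angle the two stents subtend at the fulcrum.
    """
    for y in (yaw1_deg, yaw2_deg):
        if not (0.0 <= y <= 90.0):
            raise PoseError(f"yaw {y} out of range [0, 90]")
    return float(yaw1_deg + yaw2_deg)


def yaw_pair_consistent(
    yaw1_deg: float, yaw2_deg: float, theta_deg: float, tol_deg: float = 2.0
) -> bool:
    """Check a measured yaw pair against a known fulcrum angle."""
    return abs(yaw_pair_inscribed_angle(yaw1_deg, yaw2_deg) - theta_deg) <= tol_deg


def estimate_pose(
    mask: StentMask,
    pitches_um: tuple[float, float, float],
    landmarks: Landmarks,
) -> StentPose:
    """Full pose measurement: axis fit, pitch, yaw and insertion distance."""
    centroid, axis, anisotropy = fit_stent_axis(mask, pitches_um)
    pitch = measure_pitch(axis, landmarks.tm_plane_angle_deg)
    yaw = measure_yaw(axis)
    dist = measure_insertion_distance(
        centroid, axis, landmarks.schwalbe_point_um, mask=mask, pitches_um=pitches_um
    )
    return StentPose(
        centroid_um=centroid,
        axis_unit=axis,
        pitch_deg=pitch,
        yaw_deg=yaw,
        insertion_distance_mm=dist,
        anisotropy_ratio=anisotropy,
        shadow_excluded_mask=mask.shadow_excluded,
    )
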