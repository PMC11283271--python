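"""Binary stent segmentation from OAC volumes.

The mask is the combination of a manually selected cuboid ROI with a
binarization of the OAC map (Otsu within the ROI by default), followed
by morphological cleanup.  Only the illuminated (anterior) surface of
the implant is bright — the metal blocks the beam — so the raw mask may
also pick up saturated shadow voxels; an optional shadow-exclusion
switch drops voxels more than ``shadow_keep_depth`` axial samples below
the first hit of each A-line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .attenuation import AttenuationVolume
from .volume import StructuralVolume, VolumeError

__all__ = [
    "StentMask",
    "SegmentationError",
    "binarize_in_roi",
    "refine_mask",
    "exclude_shadow",
    "split_foreground_background",
    "dice_coefficient",
]


class SegmentationError(ValueError):
    """Raised for degenerate or empty segmentation inputs/results."""


Cuboid = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass
class StentMask:
    """Boolean voxel mask of the implant, gated to its ROI."""

    mask: np.ndarray
    roi: Cuboid
    threshold_used: float
    threshold_method: str = "otsu"
    shadow_excluded: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise SegmentationError("mask must be 3D (y,z,x)")
        outside = self.mask.copy()
        (y0, y1), (z0, z1), (x0, x1) = self.roi
        outside[y0:y1, z0:z1, x0:x1] = False
        if outside.any():
            raise SegmentationError("mask voxels found outside the ROI")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def _roi_slices(roi: Cuboid) -> tuple[slice, slice, slice]:
    return tuple(slice(lo, hi) for lo, hi in roi)  # type: ignore[return-value]


def binarize_in_roi(
    oac: AttenuationVolume,
    roi: Cuboid,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> StentMask:
    """Threshold the OAC inside the ROI to produce the raw stent mask.

    ``method='otsu'`` computes Otsu's threshold from the OAC values
    inside the ROI; ``method='fixed'`` uses ``fixed_threshold`` (mm^-1).
    Voxels are selected where OAC >= threshold AND inside the ROI.
    """
    for (lo, hi), n in zip(roi, oac.shape):
        if not (0 <= lo < hi <= n):
            raise SegmentationError(f"ROI {roi} invalid for shape {oac.shape}")
    sub = oac.oac[_roi_slices(roi)]
    if sub.size == 0:
        raise SegmentationError("empty ROI")
    if method == "otsu":
        if np.ptp(sub) == 0:
            raise SegmentationError("constant OAC inside ROI: no separable classes")
        threshold = float(threshold_otsu(sub))
    elif method == "fixed":
        if fixed_threshold is None:
            raise SegmentationError("method='fixed' requires fixed_threshold")
        threshold = float(fixed_threshold)
    else:
        raise SegmentationError(f"unknown threshold method {method!r}")
    mask = np.zeros(oac.shape, dtype=bool)
    mask[_roi_slices(roi)] = sub >= threshold
    return StentMask(mask=mask, roi=roi, threshold_used=threshold, threshold_method=method)


def exclude_shadow(mask: StentMask, keep_depth: int = 8) -> StentMask:
    """Drop mask voxels deep under the first hit of each A-line.

    For each (y, x) column, keeps voxels within ``keep_depth`` axial
    samples of the shallowest true voxel; deeper hits are treated as
    saturated shadow, not implant surface.
    """
    m = mask.mask
    any_hit = m.any(axis=1)
    first = np.where(any_hit, m.argmax(axis=1), m.shape[1])
    z = np.arange(m.shape[1])[None, :, None]
    keep = z <= (first[:, None, :] + keep_depth)
    out = m & keep
    return StentMask(
        mask=out,
        roi=mask.roi,
        threshold_used=mask.threshold_used,
        threshold_method=mask.threshold_method,
        shadow_excluded=True,
        meta={**mask.meta, "shadow_keep_depth": keep_depth},
    )


def refine_mask(
    mask: StentMask,
    min_component_voxels: int = 50,
    closing_radius_vox: tuple[int, int, int] = (1, 1, 1),
    link_radius_vox: tuple[int, int, int] = (1, 4, 1),
) -> StentMask:
    """Morphological closing, then drop small spurious components.

    Connectivity is 26-neighbor, augmented by a linking tolerance: the
    illuminated surface of an oblique implant is a thin sheet whose
    depth jumps several axial samples between neighboring A-lines
    (axial sampling is much finer than lateral), so components are
    identified on a mask dilated by ``link_radius_vox`` — roughly one
    lateral pitch in every physical direction by default.  All linked
    components holding >= ``min_component_voxels`` original voxels are
    kept: the illuminated flange face and the thorax/head strip are
    separated by a genuine depth discontinuity and must both survive,
    while isolated speckle hits (a few voxels) are removed.  Raises if
    nothing survives.
    """
    m = mask.mask
    if not m.any():
        raise SegmentationError("empty mask")
    if any(r > 0 for r in closing_radius_vox):
        ry, rz, rx = closing_radius_vox
        structure = np.ones((2 * ry + 1, 2 * rz + 1, 2 * rx + 1), dtype=bool)
        m = ndimage.binary_closing(m, structure=structure)
        # Closing must not leak outside the ROI gate.
        gated = np.zeros_like(m)
        gated[_roi_slices(mask.roi)] = m[_roi_slices(mask.roi)]
        m = gated
        m |= mask.mask  # closing is additive cleanup, never removal
    link = m
    if any(r > 0 for r in link_radius_vox):
        ry, rz, rx = link_radius_vox
        structure = np.ones((2 * ry + 1, 2 * rz + 1, 2 * rx + 1), dtype=bool)
        link = ndimage.binary_dilation(m, structure=structure)
    labels, n_comp = ndimage.label(link, structure=np.ones((3, 3, 3), dtype=bool))
    if n_comp == 0:
        raise SegmentationError("empty mask after closing")
    counts = ndimage.sum_labels(m.astype(np.int64), labels, index=np.arange(1, n_comp + 1))
    keep_labels = np.flatnonzero(counts >= min_component_voxels) + 1
    if keep_labels.size == 0:
        raise SegmentationError(
            f"largest component has {int(counts.max())} voxels "
            f"(< min_component_voxels={min_component_voxels})"
        )
    out = m & np.isin(labels, keep_labels)
    return StentMask(
        mask=out,
        roi=mask.roi,
        threshold_used=mask.threshold_used,
        threshold_method=mask.threshold_method,
        shadow_excluded=mask.shadow_excluded,
        meta={**mask.meta, "n_components_before": int(n_comp)},
    )


def split_foreground_background(
    volume: StructuralVolume, mask: StentMask
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the intensity volume into stent and tissue channels.

    The two channels are complementary: stent carries intensity where
    the mask is true (zero elsewhere), tissue the reverse, and their sum
    reproduces the original volume — the basis of the two-color display.
    """
    if mask.mask.shape != volume.shape:
        raise SegmentationError(
            f"mask shape {mask.mask.shape} != volume shape {volume.shape}"
        )
    stent = np.where(mask.mask, volume.intensity, 0.0)
    tissue = np.where(mask.mask, 0.0, volume.intensity)
    return stent, tissue


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap between two boolean masks (1 = identical)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
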