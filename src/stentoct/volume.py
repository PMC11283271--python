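"""Shared volume / time-series data model and file IO.

Axis conventions used throughout the package:

* Structural volumes are indexed ``(y, z, x)`` — slow (B-scan) axis,
  depth (A-scan sample) axis, fast (A-scan) axis.  The fast axis is
  assumed to be aligned with the iris radius, so "radial" always means
  the x direction.
* BM-scan series are indexed ``(t, z, x)``.
* Physical coordinates are micrometers; voxel indices are 0-based and
  cuboid regions are half-open ``[lo, hi)`` per axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile

__all__ = [
    "StructuralVolume",
    "BMScanSeries",
    "Landmarks",
    "ProjectionImage",
    "read_volume",
    "write_volume",
    "read_bmscan",
    "write_bmscan",
    "average_repeats",
    "render_projection",
]

# Defaults taken from the high-definition anterior-segment protocol:
# a 3x1 mm^2 field sampled with 300 A-scans per B-scan at 100 B-scan
# positions (10 um pitch along both lateral axes).  The axial sample
# spacing is instrument-internal and therefore a configuration value.
DEFAULT_PITCH_X_UM = 10.0
DEFAULT_PITCH_Y_UM = 10.0
DEFAULT_PITCH_Z_UM = 3.0

# Phase-sensitive protocol constants: 1050 nm center wavelength,
# 3000 B-scans acquired over ~7 s at one position.
DEFAULT_LAMBDA0_NM = 1050.0
DEFAULT_N_TISSUE = 1.38
DEFAULT_DT_S = 7.0 / 3000.0


class VolumeError(ValueError):
    """Raised for malformed volumes, series or landmark records."""


@dataclass
class StructuralVolume:
    """3D OCT intensity cube with anisotropic physical voxel pitches.

    ``intensity`` is indexed ``(y, z, x)``; pitches are micrometers per
    voxel along each axis.
    """

    intensity: np.ndarray
    pitch_x_um: float = DEFAULT_PITCH_X_UM
    pitch_y_um: float = DEFAULT_PITCH_Y_UM
    pitch_z_um: float = DEFAULT_PITCH_Z_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 3:
            raise VolumeError(f"intensity must be 3D (y,z,x), got ndim={self.intensity.ndim}")
        if any(s < 2 for s in self.intensity.shape):
            raise VolumeError(f"need >= 2 samples per axis, got shape {self.intensity.shape}")
        if not np.all(np.isfinite(self.intensity)):
            raise VolumeError("intensity contains non-finite values")
        if np.any(self.intensity < 0):
            raise VolumeError("intensity must be non-negative")
        for name in ("pitch_x_um", "pitch_y_um", "pitch_z_um"):
            if not getattr(self, name) > 0:
                raise VolumeError(f"{name} must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape  # type: ignore[return-value]

    @property
    def pitches_um(self) -> tuple[float, float, float]:
        """Micrometer pitches in index order (y, z, x)."""
        return (self.pitch_y_um, self.pitch_z_um, self.pitch_x_um)

    def voxel_to_um(self, index_yzx: np.ndarray) -> np.ndarray:
        """Scale (y, z, x) voxel indices to physical micrometers."""
        return np.asarray(index_yzx, dtype=float) * np.array(self.pitches_um)


@dataclass
class BMScanSeries:
    """Complex-valued B-scan time stack indexed (t, z, x).

    Carries the optical constants needed for the Doppler phase-to-velocity
    conversion: center wavelength ``lambda0_nm``, tissue refractive index
    ``n_tissue`` and inter-frame interval ``dt_s``.
    """

    field: np.ndarray
    lambda0_nm: float = DEFAULT_LAMBDA0_NM
    n_tissue: float = DEFAULT_N_TISSUE
    dt_s: float = DEFAULT_DT_S
    pitch_x_um: float = DEFAULT_PITCH_X_UM
    pitch_z_um: float = DEFAULT_PITCH_Z_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field)
        if not np.iscomplexobj(self.field):
            self.field = self.field.astype(np.complex128)
        if self.field.ndim != 3:
            raise VolumeError(f"field must be 3D (t,z,x), got ndim={self.field.ndim}")
        if not np.all(np.isfinite(self.field)):
            raise VolumeError("field contains non-finite values")
        if not self.dt_s > 0:
            raise VolumeError("dt_s must be > 0")
        if not self.lambda0_nm > 0:
            raise VolumeError("lambda0_nm must be > 0")
        if not self.n_tissue >= 1:
            raise VolumeError("n_tissue must be >= 1")
        if not (self.pitch_x_um > 0 and self.pitch_z_um > 0):
            raise VolumeError("pitches must be > 0")

    @property
    def n_frames(self) -> int:
        return self.field.shape[0]


@dataclass
class Landmarks:
    """Manual annotations driving segmentation and pose measurement.

    ``roi`` is an axis-aligned cuboid in voxel indices, half-open per
    axis: ``((y0, y1), (z0, z1), (x0, x1))``.  ``tm_plane_angle_deg`` is
    the front-view inclination of the trabecular-meshwork line relative
    to the depth (z) axis.  ``tm_center`` is the (z, x) voxel location of
    the TM used to center the motion-analysis ellipse.
    """

    roi: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    schwalbe_point_um: tuple[float, float, float] | None = None
    tm_plane_angle_deg: float = 60.0
    tm_center: tuple[int, int] | None = None
    location_label: str | None = None
    day_label: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.tm_plane_angle_deg < 180.0):
            raise VolumeError("tm_plane_angle_deg must lie in [0, 180)")
        if self.roi is not None:
            roi = tuple((int(lo), int(hi)) for lo, hi in self.roi)
            for lo, hi in roi:
                if hi <= lo or lo < 0:
                    raise VolumeError(f"degenerate ROI bounds {roi}")
            self.roi = roi  # type: ignore[assignment]

    def validate_roi(self, shape: tuple[int, int, int]) -> None:
        if self.roi is None:
            raise VolumeError("landmarks carry no ROI")
        for (lo, hi), n in zip(self.roi, shape):
            if hi > n:
                raise VolumeError(f"ROI {self.roi} exceeds volume shape {shape}")


@dataclass
class ProjectionImage:
    """Orthographic projection of a volume.

    ``view='front'`` projects along the slow-scan (y) axis giving a
    (z, x) image; ``view='top'`` projects along the depth (z) axis giving
    a (y, x) image.  When a stent mask was supplied, ``stent_pixels``
    carries a matching second channel so renderers can two-color the
    implant against the tissue background.
    """

    pixels: np.ndarray
    view: Literal["front", "top"]
    axis_mapping: tuple[str, str]
    stent_pixels: np.ndarray | None = None


def read_volume(
    path: str | Path,
    pitches_um: tuple[float, float, float] = (DEFAULT_PITCH_Y_UM, DEFAULT_PITCH_Z_UM, DEFAULT_PITCH_X_UM),
) -> StructuralVolume:
    """Read a multi-page TIFF into a StructuralVolume.

    Pages are stacked along the slow (y) axis; ``pitches_um`` is given in
    index order (y, z, x).  A JSON sidecar ``<path>.json`` written by
    :func:`write_volume`, when present, overrides the pitches.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) != 1:
            raise VolumeError(f"ragged page shapes in {path}: {sorted(shapes)}")
        data = tif.asarray()
    if data.ndim == 2:
        data = data[None]
    if not np.issubdtype(data.dtype, np.number):
        raise VolumeError(f"non-numeric TIFF data of dtype {data.dtype}")
    meta: dict = {"source": str(path)}
    py, pz, px = pitches_um
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        py = side.get("pitch_y_um", py)
        pz = side.get("pitch_z_um", pz)
        px = side.get("pitch_x_um", px)
        meta.update(side.get("meta", {}))
    return StructuralVolume(data.astype(np.float64), pitch_x_um=px, pitch_y_um=py, pitch_z_um=pz, meta=meta)


def write_volume(volume: StructuralVolume, path: str | Path) -> Path:
    """Write a volume as float32 multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.intensity.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "pitch_x_um": volume.pitch_x_um,
                "pitch_y_um": volume.pitch_y_um,
                "pitch_z_um": volume.pitch_z_um,
                "meta": _json_safe(volume.meta),
            },
            indent=2,
        )
    )
    return path


def read_bmscan(path_real: str | Path, path_imag: str | Path | None = None) -> BMScanSeries:
    """Read a BM-scan series stored as paired real/imaginary TIFF stacks.

    ``path_imag`` defaults to the real path with ``_real`` replaced by
    ``_imag``.  Optical constants come from the JSON sidecar of the real
    stack (falling back to package defaults).
    """
    path_real = Path(path_real)
    if path_imag is None:
        path_imag = Path(str(path_real).replace("_real", "_imag"))
    path_imag = Path(path_imag)
    for p in (path_real, path_imag):
        if not p.exists():
            raise FileNotFoundError(p)
    re = tifffile.imread(path_real)
    im = tifffile.imread(path_imag)
    if re.shape != im.shape:
        raise VolumeError(f"real/imag shape mismatch: {re.shape} vs {im.shape}")
    kwargs: dict = {}
    sidecar = path_real.with_suffix(path_real.suffix + ".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        for key in ("lambda0_nm", "n_tissue", "dt_s", "pitch_x_um", "pitch_z_um"):
            if key in side:
                kwargs[key] = side[key]
    return BMScanSeries(re.astype(np.float64) + 1j * im.astype(np.float64), **kwargs)


def write_bmscan(series: BMScanSeries, path_real: str | Path) -> tuple[Path, Path]:
    """Write a complex series as two float32 stacks plus a JSON sidecar."""
    path_real = Path(path_real)
    path_real.parent.mkdir(parents=True, exist_ok=True)
    path_imag = Path(str(path_real).replace("_real", "_imag"))
    if path_imag == path_real:
        path_imag = path_real.with_name(path_real.stem + "_imag" + path_real.suffix)
    tifffile.imwrite(path_real, series.field.real.astype(np.float32))
    tifffile.imwrite(path_imag, series.field.imag.astype(np.float32))
    sidecar = path_real.with_suffix(path_real.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "lambda0_nm": series.lambda0_nm,
                "n_tissue": series.n_tissue,
                "dt_s": series.dt_s,
                "pitch_x_um": series.pitch_x_um,
                "pitch_z_um": series.pitch_z_um,
            },
            indent=2,
        )
    )
    return path_real, path_imag


def average_repeats(volumes: Sequence[StructuralVolume], group_size: int = 5) -> StructuralVolume:
    """Average consecutive groups of repeated acquisitions.

    The acquisition protocol records several slightly off-plane
    repetitions at each B-scan position and averages them to suppress
    speckle (default 5 repeats).  Input volumes must agree in shape and
    pitches and their number must be divisible by ``group_size``.
    """
    if group_size < 1:
        raise VolumeError("group_size must be >= 1")
    if len(volumes) == 0:
        raise VolumeError("no volumes to average")
    ref = volumes[0]
    for v in volumes[1:]:
        if v.shape != ref.shape or v.pitches_um != ref.pitches_um:
            raise VolumeError("averaged volumes must share shape and pitches")
    if len(volumes) % group_size:
        raise VolumeError(f"{len(volumes)} volumes not divisible by group_size={group_size}")
    stack = np.stack([v.intensity for v in volumes])
    grouped = stack.reshape(len(volumes) // group_size, group_size, *ref.shape).mean(axis=1)
    # One averaged cube per consecutive group, concatenated along the slow
    # axis.  Passing whole-cube repeats (one group) returns the plain mean;
    # passing per-B-scan pages returns len(volumes)/group_size positions.
    averaged = np.concatenate(list(grouped), axis=0)
    meta = dict(ref.meta)
    meta["averaged_repeats"] = group_size
    return StructuralVolume(
        averaged,
        pitch_x_um=ref.pitch_x_um,
        pitch_y_um=ref.pitch_y_um,
        pitch_z_um=ref.pitch_z_um,
        meta=meta,
    )


def render_projection(
    volume: StructuralVolume,
    mask: np.ndarray | None = None,
    view: Literal["front", "top"] = "front",
    reducer: Literal["max", "mean"] = "max",
) -> ProjectionImage:
    """Orthographically project a volume for display.

    The front view reduces along the slow-scan (y) axis and shows the
    (z, x) plane where pitch is measured; the top view reduces along the
    depth (z) axis and shows the (y, x) plane where yaw is measured.
    When ``mask`` is given (boolean, same shape), the projection is split
    into a tissue channel (mask excluded) and a stent channel (mask
    only) so the two can be rendered in different colors.
    """
    if view == "front":
        axis, mapping = 0, ("z", "x")
    elif view == "top":
        axis, mapping = 1, ("y", "x")
    else:
        raise ValueError(f"unknown view {view!r}")
    if reducer == "max":
        reduce = np.max
    elif reducer == "mean":
        reduce = np.mean
    else:
        raise ValueError(f"unknown reducer {reducer!r}")
    data = volume.intensity
    if mask is None:
        return ProjectionImage(reduce(data, axis=axis), view, mapping)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape:
        raise VolumeError(f"mask shape {mask.shape} != volume shape {data.shape}")
    tissue = reduce(np.where(mask, 0.0, data), axis=axis)
    stent = reduce(np.where(mask, data, 0.0), axis=axis)
    return ProjectionImage(tissue, view, mapping, stent_pixels=stent)


def _json_safe(obj):
    """Best-effort conversion of metadata values for JSON export."""
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
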