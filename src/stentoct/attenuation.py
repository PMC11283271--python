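"""Depth-resolved optical attenuation coefficient (OAC) conversion.

The metallic implant body attenuates the probe light almost completely,
so on an OAC map its illuminated surface saturates while tissue sits at
a few mm^-1 — the contrast the segmentation stage exploits.  The
estimator is the standard depth-resolved form

    mu[z] = I[z] / (2 * delta * sum_{z' > z} I[z']),

with ``delta`` the axial sample spacing in mm.  No confocal or
sensitivity roll-off correction is applied.  Where the tail sum
vanishes (below the stent surface, or at the last sample) the estimate
is undefined and is assigned the saturation value ``cap_value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import StructuralVolume, VolumeError

__all__ = ["AttenuationVolume", "compute_oac", "estimate_noise_floor"]

DEFAULT_CAP_MM = 50.0


@dataclass
class AttenuationVolume:
    """Per-voxel attenuation coefficient in mm^-1, same grid as its source."""

    oac: np.ndarray
    cap_value: float
    pitch_x_um: float
    pitch_y_um: float
    pitch_z_um: float
    noise_floor: float = 0.0
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cap_value > 0:
            raise VolumeError("cap_value must be > 0")
        if not np.all(np.isfinite(self.oac)):
            raise VolumeError("OAC contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.oac.shape  # type: ignore[return-value]

    @property
    def pitches_um(self) -> tuple[float, float, float]:
        return (self.pitch_y_um, self.pitch_z_um, self.pitch_x_um)


def estimate_noise_floor(volume: StructuralVolume, deepest_fraction: float = 0.05) -> float:
    """Median intensity of the deepest fraction of axial samples.

    A robust, data-driven noise floor: the deepest samples of an
    anterior-segment scan are dominated by noise and residual shadow.
    """
    nz = volume.shape[1]
    n_tail = max(1, int(round(deepest_fraction * nz)))
    return float(np.median(volume.intensity[:, nz - n_tail :, :]))


def _tail_remainder(intensity: np.ndarray, window: int) -> np.ndarray:
    """Geometric completion of the truncated intensity tail per A-line.

    The exclusive tail sum is cut off at the record bottom, which biases
    the estimator high near the bottom (the denominator misses the
    unrecorded decay).  Where the deepest ``window`` samples are all
    positive and decaying, their mean log-slope gives the terminal decay
    ratio r and the missing remainder is the geometric series
    I[-1] * r / (1 - r).  A-lines whose deep samples touch zero (shadow
    columns, post-subtraction noise) get no completion, so the
    saturation behavior the segmentation relies on is unchanged.
    """
    deep = intensity[:, -window:, :]
    valid = np.all(deep > 0, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(valid, np.diff(np.log(np.clip(deep, 1e-300, None)), axis=1).mean(axis=1), 0.0)
    r = np.exp(np.clip(slope, -np.inf, -1e-12))
    last = intensity[:, -1, :]
    remainder = np.where(valid & (slope < 0), last * r / (1.0 - r), 0.0)
    return remainder


def compute_oac(
    volume: StructuralVolume,
    noise_floor: float | None = None,
    cap_value: float = DEFAULT_CAP_MM,
    tail_completion: bool = True,
    tail_window: int = 16,
) -> AttenuationVolume:
    """Convert an intensity volume to a depth-resolved OAC map.

    Per A-line the noise floor is subtracted (clipped at zero), the
    cumulative intensity tail below each sample is formed (geometric
    completion of the truncated bottom when ``tail_completion``), and
    the depth-resolved estimator applied.  Samples with a vanishing
    tail receive ``cap_value``; the last axial sample is always
    ``cap_value`` by convention; everything else is clipped into
    ``[0, cap_value]``.

    ``noise_floor=None`` estimates the floor as the median of the
    deepest 5% of samples.
    """
    if not cap_value > 0:
        raise VolumeError("cap_value must be > 0")
    if noise_floor is None:
        noise_floor = estimate_noise_floor(volume)
    if noise_floor < 0:
        raise VolumeError("noise_floor must be >= 0")
    delta_mm = volume.pitch_z_um / 1000.0
    intensity = np.clip(volume.intensity - noise_floor, 0.0, None)
    # Exclusive tail sum below each sample along z (axis 1).
    csum = np.cumsum(intensity[:, ::-1, :], axis=1)[:, ::-1, :]
    tail = csum - intensity
    if tail_completion and volume.shape[1] > tail_window:
        tail = tail + _tail_remainder(intensity, tail_window)[:, None, :]
    # An A-line whose tail vanishes everywhere carries no attenuation
    # information at all; flag the map as (partially) degenerate.
    degenerate = bool(np.any(np.all(tail <= 0, axis=1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        oac = intensity / (2.0 * delta_mm * tail)
    oac = np.where(tail > 0, oac, cap_value)
    oac = np.clip(np.nan_to_num(oac, nan=cap_value, posinf=cap_value), 0.0, cap_value)
    oac[:, -1, :] = cap_value  # no recorded tail below the last sample
    return AttenuationVolume(
        oac=oac,
        cap_value=cap_value,
        pitch_x_um=volume.pitch_x_um,
        pitch_y_um=volume.pitch_y_um,
        pitch_z_um=volume.pitch_z_um,
        noise_floor=float(noise_floor),
        degenerate=degenerate,
        meta={"estimator": "depth-resolved", "cap_mm": cap_value},
    )
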