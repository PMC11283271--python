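"""Synthetic phantoms and BM-scan series with known ground truth.

Structural phantoms emulate the imaging physics that the pipeline
exploits: depth-exponential tissue backscatter with unit-mean
exponential (fully developed) speckle, a strongly reflecting stent
surface, and a dark shadow tail beneath the metal along each A-line.
The implant is a simple rigid parametric solid — flange disk, thorax
cylinder, head disk on one axis — whose scale defaults approximate the
device (length ~360 um, flange diameter ~230 um) without claiming
manufacturer dimensions.

BM-scan series invert the Doppler relation: a prescribed pulsatile TM
displacement d(t) is written into the inter-frame phase of a fixed
speckle frame as phi(t) = 4 pi n d(t) / lambda0 inside the TM ellipse,
with optional rigid bulk drift, random-walk bulk phase and additive
complex noise at a stated per-pixel SNR.

Every generator returns a :class:`SyntheticTruth` holding the exact
ground truth; identical seeds and parameters reproduce identical
outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from . import motion as _motion
from .volume import BMScanSeries, Landmarks, StructuralVolume

__all__ = [
    "SyntheticTruth",
    "SyntheticError",
    "make_stent_phantom",
    "make_pulse_waveform",
    "make_bmscan_series",
    "make_yaw_pair_phantoms",
    "make_cdisp_experiment",
    "truth_cdisp",
]


class SyntheticError(ValueError):
    """Raised for infeasible generator requests."""


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every generated dataset."""

    seed: int
    params: dict
    pose: dict | None = None
    motion: dict | None = None
    landmarks: Landmarks | None = None
    surface_mask: np.ndarray | None = None
    solid_mask: np.ndarray | None = None
    extras: dict = dc_field(default_factory=dict)


def _pose_axis(pitch_deg: float, yaw_deg: float, tm_plane_angle_deg: float) -> np.ndarray:
    """Unit axis in (y, z, x) realizing the requested pitch and yaw.

    The front-view direction is the TM-line normal rotated by the pitch
    (toward +x); the slow-axis component is then set so the top-view
    angle to the x axis equals the yaw.  Pitch depends only on the
    (z, x) components, so adding the y component leaves it unchanged.
    """
    a = np.radians(tm_plane_angle_deg)
    p = np.radians(pitch_deg)
    nz, nx = np.sin(a), -np.cos(a)  # ideal insertion, front view (z, x)
    dz = nz * np.cos(p) - nx * np.sin(p)
    dx = nz * np.sin(p) + nx * np.cos(p)
    if abs(dx) < 1e-12 and yaw_deg > 0:
        raise SyntheticError(
            "requested pitch makes the axis purely axial in the front view; "
            "yaw cannot be realized"
        )
    dy = abs(dx) * np.tan(np.radians(yaw_deg))
    axis = np.array([dy, dz, dx], dtype=float)
    axis /= np.linalg.norm(axis)
    if axis[1] < 0:
        axis = -axis
    return axis


def make_stent_phantom(
    dims: tuple[int, int, int] = (100, 400, 300),
    pitches_um: tuple[float, float, float] = (10.0, 3.0, 10.0),
    pitch_deg: float = 65.0,
    yaw_deg: float = 30.0,
    tm_plane_angle_deg: float = 60.0,
    insertion_distance_mm: float = 0.30,
    tissue_mu_mm: float = 2.0,
    surface_intensity: float = 20000.0,
    i0: float = 1000.0,
    noise_level: float = 1.0,
    noise_floor: float = 5.0,
    stent_length_um: float = 360.0,
    flange_diameter_um: float = 230.0,
    thorax_diameter_um: float = 80.0,
    head_diameter_um: float = 150.0,
    flange_thickness_um: float = 40.0,
    head_length_um: float = 90.0,
    surface_thickness_vox: int = 2,
    roi_margin_vox: int = 8,
    center_um: tuple[float, float, float] | None = None,
    include_stent: bool = True,
    seed: int = 0,
) -> tuple[StructuralVolume, SyntheticTruth]:
    """Structural phantom: speckled decaying tissue with an embedded stent.

    ``pitches_um`` is (y, z, x).  The stent solid is rotated to the
    requested pitch/yaw (relative to a TM plane inclined at
    ``tm_plane_angle_deg`` in the front view) and centered at
    ``center_um`` (grid center by default).  Only its illuminated
    surface is rendered bright; every voxel beneath it along the A-line
    is set to the noise floor — the shadow tail.  The Schwalbe's-line
    landmark is placed ``insertion_distance_mm`` from the surface
    mid-segment along the axis, so the true insertion distance is exact.
    """
    ny, nz, nx = dims
    if min(dims) < 2:
        raise SyntheticError(f"non-positive or degenerate dims {dims}")
    py, pz, px = pitches_um
    pitch_vec = np.array([py, pz, px])
    rng = np.random.default_rng(seed)
    if not include_stent:
        # Background-only limit: pure depth decay with speckle.
        z_um = np.arange(nz) * pz
        decay = i0 * np.exp(-2.0 * tissue_mu_mm * (z_um / 1000.0))
        if noise_level > 0:
            speckle = (1.0 - noise_level) + noise_level * rng.exponential(1.0, size=dims)
        else:
            speckle = np.ones(dims)
        volume = StructuralVolume(
            decay[None, :, None] * speckle,
            pitch_x_um=px,
            pitch_y_um=py,
            pitch_z_um=pz,
            meta={"synthetic": True, "seed": seed, "include_stent": False},
        )
        truth = SyntheticTruth(
            seed=seed,
            params={"dims": dims, "include_stent": False, "tissue_mu_mm": tissue_mu_mm,
                    "i0": i0, "noise_level": noise_level},
            extras={"decay_profile": decay},
        )
        return volume, truth
    axis = _pose_axis(pitch_deg, yaw_deg, tm_plane_angle_deg)
    if center_um is None:
        center = (np.array(dims) - 1) * pitch_vec / 2.0
    else:
        center = np.asarray(center_um, dtype=float)

    # Solid occupancy, computed on the stent's bounding subgrid only.
    half_len = stent_length_um / 2.0
    max_rad = max(flange_diameter_um, thorax_diameter_um, head_diameter_um) / 2.0
    # Per-axis reach of the tilted solid: axial half-length projected onto
    # the axis plus the radial envelope on the perpendicular complement.
    reach = half_len * np.abs(axis) + max_rad * np.sqrt(np.clip(1.0 - axis**2, 0.0, 1.0))
    lo_idx = np.maximum(np.floor((center - reach) / pitch_vec).astype(int) - 1, 0)
    hi_idx = np.minimum(np.ceil((center + reach) / pitch_vec).astype(int) + 2, dims)
    if np.any(center - reach < -0.5 * pitch_vec) or np.any(
        center + reach > (np.array(dims) - 0.5) * pitch_vec
    ):
        raise SyntheticError("stent solid does not fit inside the grid")
    iy, iz, ix = [np.arange(lo, hi) for lo, hi in zip(lo_idx, hi_idx)]
    grid = np.stack(np.meshgrid(iy, iz, ix, indexing="ij"), axis=-1) * pitch_vec
    rel = grid - center
    t = rel @ axis
    radial = rel - t[..., None] * axis
    r = np.linalg.norm(radial, axis=-1)
    flange = (t >= -half_len) & (t <= -half_len + flange_thickness_um) & (r <= flange_diameter_um / 2)
    head = (t <= half_len) & (t >= half_len - head_length_um) & (r <= head_diameter_um / 2)
    thorax = (np.abs(t) <= half_len) & (r <= thorax_diameter_um / 2)
    occupancy_sub = flange | head | thorax
    if not occupancy_sub.any():
        raise SyntheticError("stent solid rasterized to zero voxels; check pitches")

    solid = np.zeros(dims, dtype=bool)
    solid[lo_idx[0] : hi_idx[0], lo_idx[1] : hi_idx[1], lo_idx[2] : hi_idx[2]] = occupancy_sub

    # Background: depth-exponential mean with multiplicative speckle.
    z_um = np.arange(nz) * pz
    decay = i0 * np.exp(-2.0 * tissue_mu_mm * (z_um / 1000.0))
    if noise_level > 0:
        speckle = (1.0 - noise_level) + noise_level * rng.exponential(1.0, size=dims)
    else:
        speckle = np.ones(dims)
    intensity = decay[None, :, None] * speckle

    # Illuminated surface + shadow per A-line.
    hit_col = solid.any(axis=1)
    z_first = np.where(hit_col, solid.argmax(axis=1), nz)
    zgrid = np.arange(nz)[None, :, None]
    zf = z_first[:, None, :]
    surface = hit_col[:, None, :] & (zgrid >= zf) & (zgrid < zf + surface_thickness_vox)
    shadow = hit_col[:, None, :] & (zgrid >= zf + surface_thickness_vox)
    intensity = np.where(surface, surface_intensity * speckle, intensity)
    intensity = np.where(shadow, noise_floor * speckle, intensity)

    # Truth pose measured on the surface cloud (what segmentation sees).
    pts = np.argwhere(surface) * pitch_vec
    centroid = pts.mean(axis=0)
    t_surf = (pts - centroid) @ axis
    mid = centroid + axis * (t_surf.min() + t_surf.max()) / 2.0
    schwalbe = mid - axis * insertion_distance_mm * 1000.0

    bbox = np.argwhere(surface)
    lo = np.maximum(bbox.min(axis=0) - roi_margin_vox, 0)
    hi = np.minimum(bbox.max(axis=0) + 1 + roi_margin_vox, dims)
    roi = tuple((int(a), int(b)) for a, b in zip(lo, hi))

    landmarks = Landmarks(
        roi=roi,  # type: ignore[arg-type]
        schwalbe_point_um=tuple(schwalbe),
        tm_plane_angle_deg=tm_plane_angle_deg,
    )
    params = {
        "dims": dims,
        "pitches_um": pitches_um,
        "pitch_deg": pitch_deg,
        "yaw_deg": yaw_deg,
        "tm_plane_angle_deg": tm_plane_angle_deg,
        "insertion_distance_mm": insertion_distance_mm,
        "tissue_mu_mm": tissue_mu_mm,
        "surface_intensity": surface_intensity,
        "i0": i0,
        "noise_level": noise_level,
        "noise_floor": noise_floor,
        "stent_length_um": stent_length_um,
        "flange_diameter_um": flange_diameter_um,
        "thorax_diameter_um": thorax_diameter_um,
        "head_diameter_um": head_diameter_um,
        "flange_thickness_um": flange_thickness_um,
        "head_length_um": head_length_um,
        "surface_thickness_vox": surface_thickness_vox,
    }
    truth = SyntheticTruth(
        seed=seed,
        params=params,
        pose={
            "axis_unit": axis,
            "centroid_um": centroid,
            "midpoint_um": mid,
            "pitch_deg": pitch_deg,
            "yaw_deg": yaw_deg,
            "insertion_distance_mm": insertion_distance_mm,
        },
        landmarks=landmarks,
        surface_mask=surface,
        solid_mask=solid,
    )
    volume = StructuralVolume(
        intensity,
        pitch_x_um=px,
        pitch_y_um=py,
        pitch_z_um=pz,
        meta={"synthetic": True, "seed": seed},
    )
    return volume, truth


def make_pulse_waveform(
    duration_s: float = 7.0,
    dt_s: float = 7.0 / 3000.0,
    heart_rate_hz: float = 1.1,
    harmonic_amplitudes: tuple[float, ...] = (1.0,),
    phase_jitter_rad: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic cardiac pulse: fundamental plus harmonics, unit peak-to-peak.

    ``harmonic_amplitudes[k]`` weights the (k+1)-th multiple of the
    heart rate.  ``phase_jitter_rad`` randomizes harmonic phases
    (reproducibly by seed) for less idealized variants.
    """
    if duration_s <= 0 or heart_rate_hz <= 0:
        raise SyntheticError("duration and heart rate must be > 0")
    if duration_s < 1.0 / heart_rate_hz:
        raise SyntheticError("duration shorter than one cardiac period")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s / dt_s))) * dt_s
    pulse = np.zeros_like(t)
    for k, amp in enumerate(harmonic_amplitudes, start=1):
        phase = rng.uniform(-phase_jitter_rad, phase_jitter_rad) if phase_jitter_rad else 0.0
        pulse += amp * np.sin(2.0 * np.pi * k * heart_rate_hz * t + phase)
    ptp = np.ptp(pulse)
    if ptp > 0:
        pulse /= ptp
    return pulse


def make_bmscan_series(
    n_frames: int = 3000,
    shape_zx: tuple[int, int] = (40, 300),
    pitch_x_um: float = 10.0,
    pitch_z_um: float = 3.0,
    lambda0_nm: float = 1050.0,
    n_tissue: float = 1.38,
    dt_s: float = 7.0 / 3000.0,
    tm_center: tuple[int, int] | None = None,
    amplitude_um: float = 1.0,
    pulse: np.ndarray | None = None,
    heart_rate_hz: float = 1.1,
    semi_axes_um: tuple[float, float] = (25.0, 7.5),
    bulk_shift_amplitude_px: tuple[float, float] = (0.5, 1.5),
    bulk_shift_freq_hz: float = 0.23,
    bulk_phase_step_rad: float = 0.05,
    phase_snr_db: float | None = 20.0,
    allow_aliasing: bool = False,
    dtype=np.complex64,
    seed: int = 0,
) -> tuple[BMScanSeries, SyntheticTruth]:
    """BM-scan series encoding a prescribed pulsatile TM displacement.

    A single circular-complex-normal speckle frame is drawn once; per
    frame the TM-ellipse pixels are rotated by the cumulative Doppler
    phase 4 pi n d(t) / lambda0 with d(t) = amplitude * pulse(t), then a
    sinusoidal rigid drift (Fourier-shifted), a random-walk global
    phase, and additive complex noise at ``phase_snr_db`` (per-pixel
    complex-signal SNR; ``None`` disables noise) are applied.
    """
    if n_frames < 2:
        raise SyntheticError("need >= 2 frames")
    if amplitude_um < 0:
        raise SyntheticError("amplitude must be >= 0")
    nz, nx = shape_zx
    if tm_center is None:
        tm_center = (nz // 2, nx // 2)
    ellipse = _motion.ellipse_pixel_mask(
        shape_zx, tm_center, semi_axes_um, (pitch_x_um, pitch_z_um)
    )
    rng = np.random.default_rng(seed)
    if pulse is None:
        if amplitude_um == 0:
            pulse = np.zeros(n_frames)  # static scene needs no cardiac drive
        else:
            pulse = make_pulse_waveform(n_frames * dt_s, dt_s, heart_rate_hz, seed=seed)
    pulse = np.asarray(pulse, dtype=float)[:n_frames]
    if pulse.size < n_frames:
        raise SyntheticError("pulse waveform shorter than the series")
    displacement = amplitude_um * pulse
    lambda0_um = lambda0_nm * 1e-3
    phase = 4.0 * np.pi * n_tissue * displacement / lambda0_um
    dphi_max = float(np.max(np.abs(np.diff(phase)))) if n_frames > 1 else 0.0
    if dphi_max > np.pi and not allow_aliasing:
        raise SyntheticError(
            f"peak per-frame phase step {dphi_max:.3f} rad exceeds pi "
            "(velocity beyond the aliasing bound); pass allow_aliasing=True "
            "to generate wrapped data deliberately"
        )

    base = (rng.standard_normal(shape_zx) + 1j * rng.standard_normal(shape_zx)) / np.sqrt(2.0)
    az, ax = bulk_shift_amplitude_px
    tgrid = np.arange(n_frames) * dt_s
    # Drift starts at zero: the TM is centered in the ellipse at t = 0,
    # as an operator would align it at acquisition start.
    shift_trace = np.stack(
        [
            az * np.sin(2.0 * np.pi * bulk_shift_freq_hz * tgrid),
            ax * np.sin(2.0 * np.pi * 1.37 * bulk_shift_freq_hz * tgrid),
        ],
        axis=1,
    )
    if az == 0 and ax == 0:
        shift_trace[:] = 0.0
    bulk_phase = (
        np.cumsum(rng.normal(0.0, bulk_phase_step_rad, size=n_frames))
        if bulk_phase_step_rad > 0
        else np.zeros(n_frames)
    )
    bulk_phase[0] = 0.0

    sigma = 0.0
    if phase_snr_db is not None:
        sigma = float(np.sqrt(10.0 ** (-phase_snr_db / 10.0) / 2.0))

    frames = np.empty((n_frames,) + shape_zx, dtype=dtype)
    tm_rot = np.exp(1j * phase)
    for k in range(n_frames):
        frame = base.copy()
        frame[ellipse] *= tm_rot[k]
        if np.any(shift_trace[k] != 0):
            frame = np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(frame), shift_trace[k]))
        if bulk_phase[k] != 0:
            frame = frame * np.exp(1j * bulk_phase[k])
        if sigma > 0:
            frame = frame + sigma * (
                rng.standard_normal(shape_zx) + 1j * rng.standard_normal(shape_zx)
            )
        frames[k] = frame

    series = BMScanSeries(
        frames,
        lambda0_nm=lambda0_nm,
        n_tissue=n_tissue,
        dt_s=dt_s,
        pitch_x_um=pitch_x_um,
        pitch_z_um=pitch_z_um,
        meta={"synthetic": True, "seed": seed},
    )
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_frames": n_frames,
            "shape_zx": shape_zx,
            "amplitude_um": amplitude_um,
            "heart_rate_hz": heart_rate_hz,
            "phase_snr_db": phase_snr_db,
            "bulk_shift_amplitude_px": bulk_shift_amplitude_px,
            "bulk_phase_step_rad": bulk_phase_step_rad,
            "semi_axes_um": semi_axes_um,
            "tm_center": tm_center,
            "dt_s": dt_s,
            "lambda0_nm": lambda0_nm,
            "n_tissue": n_tissue,
        },
        motion={
            "displacement_um": displacement,
            "velocity_um_s": np.diff(displacement) / dt_s,
            "phase_rad": phase,
            "bulk_shift_px": shift_trace,
            "bulk_phase_rad": bulk_phase,
            "amplitude_um": amplitude_um,
            "pulse": pulse,
            "tm_center": tm_center,
        },
        landmarks=Landmarks(tm_center=tm_center),
    )
    return series, truth


def truth_cdisp(truth: SyntheticTruth, detrend: bool = True) -> float:
    """CDisp of the ideal noiseless waveform under the pipeline convention.

    The prescribed velocity is integrated with the same detrending and
    trapezoidal rule the pipeline uses, so recovery tests compare like
    with like: with mean-velocity removal, even a perfect measurement of
    a record holding a non-integer number of cardiac cycles differs from
    the raw displacement range.
    """
    if truth.motion is None:
        raise SyntheticError("truth record carries no motion ground truth")
    v = truth.motion["velocity_um_s"]
    d = _motion.integrate_displacement(v, truth.params["dt_s"], detrend=detrend)
    return _motion.compute_cdisp(d)


def make_yaw_pair_phantoms(
    theta_deg: float = 35.0,
    split: float = 0.5,
    iris_radius_um: float = 6000.0,
    generate_phantoms: bool = True,
    seed: int = 0,
    **phantom_kwargs,
) -> dict:
    """Two stent phantoms placed through one corneal incision fulcrum.

    The incision fulcrum F and both implantation sites P1, P2 lie on the
    iris circle; the stents point along the chords F->Pi while the ideal
    radial insertion points along the local radius Pi->O.  The central
    angle P1-O-P2 is 2*theta, so by the inscribed-angle relation the two
    yaw deviations sum to theta.  ``split`` apportions theta between the
    stents (0.5 = the symmetric, equal-yaw strategy).

    The per-stent yaw ground truths are computed vectorially from the
    chord construction (exact chord/inscribed-angle geometry), then fed
    to :func:`make_stent_phantom`.  Returns the phantoms, their truths,
    and the geometric expectation.
    """
    if not (0.0 < theta_deg < 90.0):
        raise SyntheticError("theta must lie in (0, 90) degrees")
    if not (0.0 <= split <= 1.0):
        raise SyntheticError("split must lie in [0, 1]")
    yaw1 = split * theta_deg
    yaw2 = (1.0 - split) * theta_deg
    # Exact vector oracle on the iris circle: chord vs radius angles.
    c1 = np.radians(180.0 - 2.0 * yaw1)
    c2 = np.radians(180.0 - 2.0 * yaw2)
    fulcrum = iris_radius_um * np.array([1.0, 0.0])
    p1 = iris_radius_um * np.array([np.cos(c1), np.sin(c1)])
    p2 = iris_radius_um * np.array([np.cos(c2), -np.sin(c2)])
    geo_yaws = []
    for p in (p1, p2):
        chord = fulcrum - p
        radial = -p
        cosang = abs(chord @ radial) / (np.linalg.norm(chord) * np.linalg.norm(radial))
        geo_yaws.append(float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
    central = float(
        np.degrees(np.arccos(np.clip((p1 @ p2) / iris_radius_um**2, -1, 1)))
    )
    phantoms = None
    if generate_phantoms:
        vol1, truth1 = make_stent_phantom(yaw_deg=geo_yaws[0], seed=seed, **phantom_kwargs)
        vol2, truth2 = make_stent_phantom(yaw_deg=geo_yaws[1], seed=seed + 1, **phantom_kwargs)
        phantoms = ((vol1, truth1), (vol2, truth2))
    return {
        "theta_deg": theta_deg,
        "geometric_yaws_deg": tuple(geo_yaws),
        "central_angle_deg": central,
        "phantoms": phantoms,
    }


def make_cdisp_experiment(
    effect: float = 1.3,
    n_days: int = 3,
    n_reps: int = 3,
    n_sites: int = 3,
    base_cdisp_um: float = 1.0,
    sigma_rel: float = 0.25,
    eye: str = "OD",
    seed: int = 0,
) -> list:
    """Synthetic CDisp experiment: 'between' sites at ``effect`` x 'remote'.

    Per (day, site, replicate) one measurement is drawn from a lognormal
    law with the group's mean and relative spread ``sigma_rel`` —
    positive by construction, mimicking the multiplicative variability
    of repeated motion measurements.  Defaults follow the acquisition
    design: 3 days x 3 sites x 3 replicates per location group.
    """
    from .motion import CDispRecord

    rng = np.random.default_rng(seed)
    sigma = float(sigma_rel)
    records = []
    for loc, mean in (("between", effect * base_cdisp_um), ("remote", base_cdisp_um)):
        for day in range(1, n_days + 1):
            for site in range(n_sites):
                for rep in range(1, n_reps + 1):
                    draw = mean * np.exp(sigma * rng.standard_normal() - sigma**2 / 2.0)
                    records.append(
                        CDispRecord(
                            cdisp_um=float(draw),
                            eye=eye,
                            location_label=loc,
                            day_label=f"day{day}",
                            replicate_index=rep,
                        )
                    )
    return records
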