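# Methods

This note documents the models, conventions and numerical choices in
`stentoct`, and what the synthetic-data tests do and do not establish
about real scans.

## Conventions

Structural volumes are indexed `(y, z, x)`: slow scan, depth, fast
scan. The fast axis is assumed aligned with the iris radius, so the
radial direction is `x` throughout; all angle definitions build on
this. Physical coordinates are micrometers, voxel indices 0-based,
cuboid ROIs half-open. BM-scan series are indexed `(t, z, x)`.
Protocol defaults: 300 A-scans per B-scan at 10 µm pitch, 100 B-scan
positions at 10 µm pitch, axial sample spacing 3 µm (a configuration
value — finer than the ~5 µm axial resolution of a 1050 nm / 100 nm
swept source; it is never hard-coded), λ0 = 1050 nm, tissue index
n = 1.38, and 3000 frames over ~7 s for BM-scans (ΔT ≈ 2.33 ms).

## Structural arm

**Attenuation conversion.** The depth-resolved estimator
µ[z] = I[z] / (2δ·Σ_{z′>z} I[z′]) is applied per A-line after
subtracting a noise floor (default: median of the deepest 5% of
samples — valid only when the record decays into noise by the bottom;
the floor is configurable for shallow records). No confocal or
roll-off correction is applied. Two boundary conventions:

* *Saturation*: where the tail sum vanishes (below the metal implant,
  whose shadow is clipped to zero by the floor subtraction), µ is
  assigned the cap (default 50 mm⁻¹). This saturation is the contrast
  the segmentation exploits; the deepest sample is always capped.
* *Geometric tail completion* (default on): the truncated record
  biases µ high near the bottom (the denominator misses the
  unrecorded decay — at 600 samples of µ = 2 mm⁻¹ tissue the bias
  reaches 3.4% at half depth, in closed form). Where the deepest 16
  samples are positive and decaying, their mean log-slope gives the
  terminal ratio r and the missing geometric remainder
  I[-1]·r/(1−r) is added to every tail. A-lines whose deep samples
  touch zero (shadow, clipped noise) are left uncompleted, so the
  saturation behavior is untouched.

**Segmentation.** Otsu's threshold computed on OAC values inside a
manually supplied cuboid ROI (a fixed threshold is available); voxels
with OAC ≥ threshold inside the ROI form the raw mask. Cleanup:
morphological closing (default radius 1 voxel per axis), then removal
of components below 50 voxels. Component identity uses 26-connectivity
on a mask dilated by (1, 4, 1) voxels — about one lateral pitch in
every physical direction — because the illuminated surface of an
oblique implant is a thin sheet whose depth jumps several (fine) axial
samples between neighboring A-lines. All sufficiently large linked
components are kept: the implant's flange face and its thorax/head
strip are separated by a genuine depth discontinuity (the flange
shadows the gap between them) and both carry pose information. An
optional shadow-exclusion switch drops voxels more than 8 axial
samples below the first hit of each A-line.

**Axis fit and pose.** Only the anterior surface of the metal is
visible, so the segmented cloud is a union of surface sheets, not a
solid. Each linked component is classified by its principal extents
(per-point SVD scales): *rod-like* if s1/s2 dominates, *plate-like* if
s2/s3 dominates. A rod contributes its first principal direction; a
plate — the flange face, a plane perpendicular to the device axis —
contributes its plane normal, refined by a median/MAD trim (floor
4 µm) that discards flange-rim voxels lying off the face plane. The
most anisotropic candidate wins. A plain whole-cloud principal
direction is *not* used: the cylinder-top strip is offset ~40 µm from
the true axis while the flange face is centered on it, and any
moment-based line fit mixing the two clusters inherits a tilt of
several degrees (≈7° at the default geometry, versus ≤0.2° for the
shape-aware fit on noiseless surfaces). Clouds with no feature more
anisotropic than 1.2 raise a degenerate-shape error.

Pitch is the front-view (z, x) angle between the projected axis and
the normal of the TM line (user-supplied inclination; the TM is never
auto-segmented), yaw the top-view (y, x) angle to the radial axis;
both folded to [0°, 90°], invariant to the axis sign. Insertion
distance is the Euclidean distance (mm) from the axis-parameterized
midpoint of the masked extent to the annotated Schwalbe's-line point.
For two stents implanted through one corneal incision, the sum of
their yaws equals the inscribed angle at the incision fulcrum; the
generator reproduces this with an exact chord construction on the iris
circle and the measurement respects it to within ~1°.

## Phase-sensitive arm

Processing order: subpixel rigid registration → bulk-phase
compensation → inter-frame phase difference → Doppler conversion →
6 Hz low-pass → TM-ellipse reduction → trapezoidal integration →
CDisp.

* **Registration** correlates the *complex* field of each frame with
  frame 0 (upsampled cross-correlation, default factor 100). The
  complex cross-power spectrum of shifted speckle carries an exact
  linear phase, whereas the magnitude image of fully developed speckle
  decorrelates under subpixel shifts; magnitude-based registration
  fails at the ~1 px level on speckle. Corrections are applied by
  Fourier shifting.
* **Bulk-phase compensation** estimates each adjacent-frame global
  phase jump as the argument of the reference-pixel sum of
  f[t+1]·conj(f[t]) and rotates the accumulated offset out. The
  default reference is every pixel brighter than the median temporal
  mean, excluding a 3× dilation of the TM ellipse.
* **Doppler conversion**: v = λ0/(4πn·ΔT)·Δφ in µm/s, applied to
  wrapped Δφ without temporal unwrapping; the aliasing bound
  λ0/(4n·ΔT) ≈ 82 µm/s is recorded in the output metadata, and the
  generator refuses supra-Nyquist motion unless explicitly asked.
* **Filtering** multiplies the spectrum by the Butterworth magnitude
  1/√(1+(f/6 Hz)^40) — a zero-phase frequency-domain magnitude filter
  (what the processing chain specifies), not an IIR recursion.
* **Ellipse reduction**: default is the Kasai estimator — the argument
  of the summed inter-frame complex products over the 50 × 15 µm²
  ellipse. Amplitude weighting is essential: near-null speckle pixels
  have essentially random phase, and an arithmetic mean of per-pixel
  phase shifts lets their wrap counts random-walk into the
  displacement (observed: up to 18% CDisp error at 0.5 µm amplitude
  and 20 dB SNR, versus ≤0.6% with Kasai). The literal arithmetic
  mean (`roi_average='mean'`, and `extract_tm_waveform`) is retained:
  it is exactly linear and commutes with the low-pass to 1e-10, which
  the Kasai path, being nonlinear, only approximates.
* **Integration and CDisp**: the record-mean velocity is removed by
  default (suppressing residual drift ramps), then cumulative
  trapezoidal integration from 0; CDisp is the range of the full
  record, not a per-cycle statistic. Recovery tests compare against
  the noiseless truth waveform pushed through the *same* integration
  convention: with a non-integer number of cardiac cycles in a 7 s
  record, mean-velocity removal changes the range of even a perfect
  measurement, so comparing to the raw prescribed range would conflate
  convention with error. The raw range is emitted alongside.

## Statistics

CDisp records carry eye / location / day / replicate labels. Binning
is per day (inter-day reproducibility; one cell per eye–location–day)
or pooled by location (one cell per eye–location; stent-adjacent
above/below sites pool per stent, remote sites pool per eye).
Pairwise two-sided independent-samples t-tests run between cells
differing in exactly one key; Welch's unequal-variance form is the
default with a pooled-variance switch, no multiplicity adjustment by
default (Holm available). Stars: p < 0.05 / 0.01 / 0.001 / 0.0001.
Quartiles use linear interpolation; a single-value cell has undefined
SD and is flagged.

## Synthetic data: what it emulates, and what it does not

Structural phantoms: unit-mean exponential (fully developed) speckle
multiplying a depth-exponential mean (default tissue µ = 2 mm⁻¹,
surface reflectivity 20× the entry intensity, floor 5 counts on
i0 = 1000); the implant is a rigid flange-disk + thorax-cylinder +
head-disk solid (length 360 µm, flange ⌀230 µm, thorax ⌀80 µm, head
⌀150 µm — scale parameters approximating the device, configurable and
not claimed as manufacturer dimensions). Only the illuminated surface
(2 voxels thick) is bright; everything beneath along each A-line sits
at the noise floor. Not modeled: the lateral/axial PSF (no blur —
surfaces are voxel-sharp), specular obliquity, refraction, multiple
scattering, motion between repeats. Consequently the passing recovery
tests show the *algorithms* are correct and well-conditioned at
protocol noise levels, not that real tissue boundaries or real device
reflectivity behave this simply.

BM-scan series: one circular-complex-normal speckle frame, TM-ellipse
pixels rotated by the cumulative Doppler phase 4πn·d(t)/λ0 with
d(t) = amplitude × unit-peak-to-peak cardiac pulse (default 1.1 Hz
fundamental); sinusoidal rigid drift (≤ ~1.5 px, starting at zero —
the operator centers the TM at acquisition start), random-walk global
phase (0.05 rad/frame steps), additive complex noise at a per-pixel
complex-signal SNR in dB (default 20 dB; noise power =
signal × 10^(−SNR/10)). Speckle never decorrelates with TM motion
(pure phase rotation), which flatters registration slightly; bulk
drift is rigid. Identical seed and parameters reproduce outputs bit
for bit.

The built-in CDisp experiment fixture draws lognormal measurements
(relative spread 25%, a realistic repeat-measurement variability) for
a "between" group at 1.3× the "remote" mean, 3 days × 3 sites × 3
replicates per group.

## Problem sizes used in the test suite

End-to-end structural recovery runs on 64 × 400 × 200 voxel phantoms
(full depth — the noise-floor estimator needs the record to decay into
noise — with a reduced lateral field); the pose grid covers pitch
{45, 55, 65, 75}° × yaw {0, 15, 30, 45}° × 3 seeds. Motion recovery
runs the full protocol length (3000 frames, 300 A-scans, depth 40
samples) at amplitudes {0.5, 1.0, 2.0} µm × 10 seeds, plus a static
scene. Statistics calibration uses 10,000 null simulations and 200
effect-fixture seeds.

## Known limitations

* The TM plane inclination, ROI, Schwalbe's-line point and TM ellipse
  center are manual annotations; nothing is auto-detected.
* The noise-floor estimate assumes the deepest 5% of samples are
  noise-dominated; shallow records need an explicit floor.
* CDisp is a range statistic on the full record and is sensitive to
  any unremoved low-frequency artifact; only mean-velocity detrending
  is applied.
* Angles are measured on 2D projections of the fitted 3D axis,
  matching the measurement procedure the pipeline mirrors; a full 3D
  angular decomposition would differ for strongly oblique axes.
* The t-test machinery treats replicates as independent samples when
  pooled; replicate averaging before testing is available but neither
  mode is asserted as the "correct" unit of analysis.
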