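# stentoct

Quantitative anterior-segment OCT analysis of trabecular micro-stents
(iStent-type implants) for glaucoma surgery, in two arms:

1. **Structural arm** — from a 3D OCT intensity volume, segment the
   implant and measure its placement: *insertion distance* (mm from the
   stent mid-segment to the annotated point on Schwalbe's line),
   *pitch* (front-view angle between the stent axis and the ideal
   insertion, i.e. the normal of the trabecular-meshwork plane) and
   *yaw* (top-view angle between the stent axis and the radial
   direction of the iris).
2. **Phase-sensitive arm** — from a repeated-B-scan (BM-scan) complex
   time series, quantify pulse-driven trabecular-meshwork (TM) motion:
   inter-frame phase shifts are converted to axial velocity, filtered,
   averaged over a TM ellipse, integrated to displacement, and reduced
   to the **cumulative displacement** statistic *CDisp* = max − min of
   the displacement record. Grouping and pairwise t-test machinery
   summarizes CDisp by day and by location.

Who it is for: researchers processing anterior-segment OCT of
micro-invasive glaucoma surgery (MIGS) implants who need reproducible
placement metrics and TM-motion readouts without vendor software.

## Core quantities

* Depth-resolved optical attenuation coefficient (makes the metallic
  implant saturate against tissue):

  `mu[z] = I[z] / (2 * delta * sum_{z' > z} I[z'])`, with `delta` the axial
  sample spacing in mm. Vanishing tails (under the implant's shadow)
  are assigned a saturation cap — the contrast the segmentation uses.

* Doppler phase-to-velocity conversion:

  `v = lambda0 / (4 * pi * n * dT) * dphi`  (lambda0 = 1050 nm, n = 1.38,
  dT = inter-frame interval, ~7 s / 3000 frames), low-passed with a
  20th-order 6 Hz frequency-domain Butterworth magnitude filter and
  averaged over a 50 × 15 µm² ellipse centered on the TM.

* `CDisp = max(d) − min(d)` of the time-integrated TM velocity.

A synthetic-data module generates structural phantoms (speckled
exponential-decay tissue, bright stent surface, dark shadow tail) and
BM-scan series (prescribed pulsatile TM displacement written into the
inter-frame phase, plus bulk drift, bulk phase and noise) with exact
ground truth, so the whole pipeline is testable without clinical scans.

## Worked example

```python
from stentoct import (make_stent_phantom, compute_oac, binarize_in_roi,
                      refine_mask, estimate_pose, make_bmscan_series,
                      extract_tm_motion)
from stentoct.synthetic import truth_cdisp

# structural arm: phantom placed at pitch 65 deg, yaw 30 deg, 0.30 mm insertion
vol, truth = make_stent_phantom(pitch_deg=65, yaw_deg=30, seed=0)
oac = compute_oac(vol)
mask = refine_mask(binarize_in_roi(oac, truth.landmarks.roi))
pose = estimate_pose(mask, vol.pitches_um, truth.landmarks)
print("pose:", pose.as_record())

# phase-sensitive arm: 3000-frame BM-scan, 1.0 um pulsatile TM amplitude
series, mtruth = make_bmscan_series(n_frames=3000, shape_zx=(40, 300),
                                    amplitude_um=1.0, seed=1)
waves = extract_tm_motion(series, mtruth.motion["tm_center"])
print("CDisp um:", round(waves.cdisp_um, 3), "truth:", round(truth_cdisp(mtruth), 3))
```

prints

```
pose: {'insertion_distance_mm': 0.2968, 'pitch_deg': 63.99, 'yaw_deg': 30.04,
       'anisotropy_ratio': 8.788, 'shadow_excluded_mask': False}
CDisp um: 1.398 truth: 1.4
```

The phantom was generated at (0.30 mm, 65°, 30°): the pipeline recovers
the insertion distance within 3 µm, both angles within ~1°, and the
motion arm recovers the prescribed CDisp within 0.2%. (`truth` here is
the noiseless waveform pushed through the same integration convention;
see `docs/methods.md`.)

A command-line interface wraps the same pipelines
(`stentoct simulate | segment | pose | motion | stats | fixtures`), with a
validated YAML configuration; every run writes its fully resolved
config next to its outputs.

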