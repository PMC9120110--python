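# rsompy

Analysis toolkit for raster-scan optoacoustic mesoscopy (RSOM) of human
skin. RSOM raster-scans a focused, ultra-broadband (10–120 MHz) ultrasound
detector over the skin while short laser pulses excite optical absorbers —
melanin in the epidermis, hemoglobin in dermal microvessels — and records a
time-resolved pressure signal (an *A-line*) at every scan position. From
such scans the package reconstructs dual-band 3D images, segments the skin
layers and the vasculature, and quantifies six vascular biomarkers that
discriminate malignant melanoma from benign nevi.

The chain covers:

* **Breathing-motion estimation, correction, and quality control.** The skin
  surface dominates each A-line; vertical displacement at scan position *i*
  is the lag of the cross-correlation maximum between the reference A-line
  and A-line *i*, converted via `dz = c·dt·lag` with sub-sample parabolic
  refinement. Scans are graded Q1 (max |dz| ≤ 70 µm, usable), Q2 (≤ 300 µm,
  correctable) or Q3 (rejected).
* **Dual-band delay-and-sum reconstruction.** Zero-phase Butterworth
  band-split into 10–40 MHz (large structures) and 40–120 MHz (fine
  structures), then sensitivity-weighted beamforming onto a 12×12×3 µm
  default voxel grid: each voxel sums A-line samples at the one-way delay
  ‖voxel − position‖/c, weighted by a depth-dependent Gaussian aperture.
  The two bands composite into red (low) / green (high) channels.
* **Segmentation.** Surface flattening; epidermis/dermis interface traced
  per B-scan by a globally optimal column-monotone dynamic-programming path
  on a depth-gradient cost; pigmented-lesion boundary traced by the same DP
  machinery in polar coordinates on the epidermal projection; the
  surrounding-tissue-vessel (STV) band is the 500 µm Euclidean extension of
  the lesion outward; vessels segmented by hysteresis thresholding and
  topology-preserving thinning into a skeleton with branch points.
* **Biomarkers.** Total blood volume TBV = N/V (nonzero-voxel fraction),
  vessel density (skeleton pixel fraction), average vessel length
  (Σ AL / branch points), tortuosity via the distance metric DM = AL/SL per
  segment (reported as the index mean(DM − 1)), box-counting fractal number
  FN = slope of log N(r) vs log(1/r), and lacunarity
  L = mean(I²)/mean(I)² − 1.
* **Cohort statistics.** Two-tailed Mann–Whitney U tests (exact null for
  small untied samples), per-marker ROC/AUC, and a multivariate logistic
  combination scored by in-sample predicted probabilities.
* **Synthetic data.** Ground-truth phantoms (random-walk vessel trees with
  controllable density/curvature/branching, layered melanin skin with a
  pigmented-lesion disk, non-crossing sinusoidal tubes with analytic
  tortuosity) and a band-limited single-scattering forward model with
  breathing motion and noise, so every stage is testable without patient
  data.

## Worked example

```python
import numpy as np
from rsompy.datatypes import MotionParams, PhantomTruth, ScanConfig
from rsompy.motion import classify_quality, correct_motion, estimate_displacement
from rsompy.phantom import generate_vessel_phantom
from rsompy.pipeline import quantify_vessels
from rsompy.reconstruction import bandpass_split, beamform
from rsompy.simulate import simulate_scan

# motion estimation needs a strong common echo: an absorbing sheet at 400 um
surface = np.zeros((32, 32, 200), dtype=np.float32)
surface[:, :, 80] = 1.0
sheet = PhantomTruth(absorption=surface, voxel_size_um=(20, 20, 5),
                     vessel_mask=surface > 0,
                     melanin_mask=np.zeros_like(surface, dtype=bool),
                     vessel_segments=[])
slow_cfg = ScanConfig(n_fast=31, n_slow=31, step_fast_um=20, step_slow_um=20,
                      n_samples=1024, rep_rate_hz=64)
scan = simulate_scan(sheet, slow_cfg,
                     motion=MotionParams(amplitude_um=150, period_s=4), seed=0)
trace = estimate_displacement(scan)
print(f"motion: max |dz| = {trace.max_abs_um:.1f} um -> "
      f"grade {classify_quality(trace).grade}")
corrected = correct_motion(scan, trace)
print(f"after correction: max |dz| = "
      f"{estimate_displacement(corrected).max_abs_um:.2f} um")

# vessel biomarkers from a simulated dermal scan
phantom = generate_vessel_phantom(
    grid_shape=(64, 64, 64), voxel_size_um=(12, 12, 6),
    target_tbv=0.035, curvature=0.3, depth_range_um=(120, 350),
    radius_um=40, seed=0)
config = ScanConfig(n_fast=39, n_slow=39, step_fast_um=20, step_slow_um=20,
                    n_samples=640, rep_rate_hz=1400)
scan = simulate_scan(phantom, config, seed=0)
low, high = bandpass_split(scan)
volume = beamform(high, voxel_size_um=(12, 12, 6), z_range_um=(0, 384),
                  band_mhz=(40, 120), weight_compensation=True)
markers, _ = quantify_vessels(volume, depth_range_um=(100, 350),
                              threshold="otsu")
print(f"TBV: measured {markers.tbv:.3f} "
      f"(phantom truth {phantom.vessel_mask.mean():.3f})")
```

Output:

```
motion: max |dz| = 151.8 um -> grade Q2
after correction: max |dz| = 0.08 um
TBV: measured 0.040 (phantom truth 0.036)
```

The injected 150 µm breathing sinusoid is estimated within ~1% and removed
to below a tenth of a micron (one time sample corresponds to 1.5 µm of
depth at 1 GS/s and c = 1500 m/s). The measured volume fraction of the
reconstructed, segmented vasculature lands within ~10% of the rasterized
phantom truth.

## Command line

`rsompy` exposes the chain as subcommands:

```bash
rsompy --seed 1 simulate --preset melanoma-edge --out scan.h5
rsompy qc scan.h5
rsompy motion-correct scan.h5 --out corrected.h5
rsompy reconstruct corrected.h5 --voxel-um 12,12,3 --out-prefix recon
rsompy segment recon_band_40-120.tiff --out-prefix seg
rsompy biomarkers recon_band_40-120.tiff --lesion-id M01 --group melanoma --out cohort.csv
rsompy cohort-stats cohort.csv --out report.json
rsompy unmix wl*.tiff --spectra spectra.csv --out-prefix unmixed
```

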