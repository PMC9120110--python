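# Methods

This note documents the models and numerical choices behind `rsompy`: what
each stage assumes, which parameters matter, what the synthetic data do and
do not emulate, and where the design was genuinely open.

## Acquisition model and forward simulation

A raster scan records one A-line per laser shot on an `n_fast × n_slow`
grid (defaults 201×101 at 20 µm pitch, i.e. 4×2 mm) digitized at 1 GS/s.
Time maps to depth through the one-way relation `z = c·t` with a default
speed of sound of 1500 m/s (soft tissue; the hardware value is not
critical because all depths scale together). One sample therefore
corresponds to 1.5 µm of depth.

The simulator (`rsompy.simulate`) is a single-scattering, fluence-flat
model. Every absorbing voxel emits an N-shaped bipolar pulse — the
derivative of a Gaussian with spectral peak at 60 MHz, whose magnitude
spectrum spans roughly the 10–120 MHz detection band — delayed by the
one-way travel time to the scan position, weighted by the detector's
lateral sensitivity and attenuated as 1/distance. Breathing is a rigid
vertical translation of the whole object, evaluated at each A-line's
acquisition time from the shot index and repetition rate:
`dz(t) = A·sin(2πt/T + φ) + drift·t`. White Gaussian noise is added last.

Not modeled: acoustic heterogeneity and attenuation, wavelength-dependent
fluence, shear waves, transducer impulse-response ripple, lateral motion.
Consequently, tests passing on simulated scans demonstrate the *analysis*
chain (geometry, delays, band logic, segmentation, statistics) — not
robustness to the full physics of patient data.

### Detector sensitivity field

The focused detector is modeled as a Gaussian aperture cone:
`σ(z) = waist + spread·|z − z_focus|`, with weight `exp(−r²/2σ(z)²)` and a
hard support cutoff at 2.5σ. Defaults: waist 10 µm, spread 0.5, focus at
the surface. These were chosen so the simulated system's lateral
point-spread function is ≈25 µm FWHM at ~200 µm depth, the regime of real
RSOM detectors with NA ≈ 0.5; no published parameterization of the
weighting field was available, so this is a configuration default, not a
literature value.

## Motion estimation, correction, grading

The skin surface is detected per A-line as the first sample whose
envelope (magnitude of the analytic signal) exceeds a fraction (default
0.5) of the line's maximum; all-zero lines get a missing sentinel.
Displacement per position is the lag of the cross-correlation maximum
between the reference A-line (first in acquisition order) and each other
line, computed on envelopes within a ±100-sample window around the
reference surface. The correlation is evaluated in full mode and masked
to ±`n_samples/4` lags: restricting the *signal window* instead (valid
mode) silently clips large negative lags when the window touches sample 0,
which corrupted 350 µm displacements. The peak is refined by a 3-point
parabolic fit; ties resolve to the smallest |lag|. Missing lines get
displacement linearly interpolated in acquisition order and are flagged.

Correction shifts each A-line by the negated displacement with linear
interpolation (sub-sample). Residual displacement on shift-only inputs is
below one sample equivalent (1.5 µm).

Grading uses the maximum absolute displacement: Q1 ≤ 70 µm (breath-hold
regime, usable as-is), Q2 ≤ 300 µm (correctable), Q3 beyond (free
breathing on the torso reaches ~350 µm, past what correction can fix).
Boundaries are inclusive. The Q2 threshold is a repository choice anchored
loosely by the observed 350 µm failure regime.

Limitation: the estimator assumes a common dominant echo (the surface or
the melanin layer). On scenes without one — e.g. a vessels-only phantom —
cross-correlation between unrelated A-lines is meaningless and the
estimate is garbage; quality control on real data relies on the skin
surface always being present.

## Reconstruction

Band-splitting uses a 4th-order zero-phase Butterworth band-pass
(`sosfiltfilt`) per A-line; bands above Nyquist are rejected. Beamforming
is direct delay-and-sum with linear sub-sample interpolation, the
sensitivity weight as apodization, and optional weight-sum compensation
(equalizes the depth-dependent aperture; used by the quantification
pipeline). The envelope (analytic signal along depth) is taken after
summation; `envelope=False` exposes the signed sum, which is linear in the
input and is used by the linearity tests. Voxels with empty sensitivity
support stay zero and are counted in `meta["uncovered_voxels"]`.

Dual-band composites normalize each band to its 99.9th percentile and clip
to [0, 1] (low → red, high → green). MIPs are per-pixel maxima along depth
(coronal) or the slow axis (cross-sectional), restricted to a half-open
depth window.

A practical observation that shaped the quantification defaults: in the
full 10–120 MHz band, wavelengths up to 150 µm dominate the image of a
40–80 µm vessel, smearing it into a broad bipolar lobe; the 40–120 MHz
band resolves vessel boundaries at the cost of weaker interiors. The
volumetric pipeline therefore quantifies the high band and fills
interiors morphologically (below).

Spectral unmixing solves per-voxel non-negative least squares
`S·f = m` over wavelengths (rows of `S`), rejecting rank-deficient spectra,
and reports the total residual norm.

## Segmentation

*Flattening.* The per-column surface depth (first voxel above half the
column maximum) is shifted to depth 0 with linear interpolation; shifts are
stored for inversion.

*DP boundary tracer.* One row per column, vertical jump ≤ 2 px between
columns, minimizing summed node costs; implemented as dynamic programming
with first-occurrence argmin so ties resolve to the topmost path. It is
exhaustively checked against a Dijkstra oracle on random instances.

*EP/DR interface.* Per B-scan, the cost is the signed depth-gradient
(steepest intensity drop), with depths above a 30 µm margin excluded; the
traced depths are median-filtered across the grid. If the mean intensity
above the boundary does not exceed the mean below by ≥1.2×, the volume has
no epidermal contrast and the caller is pointed to the fixed-thickness
override.

*Lesion boundary.* Otsu threshold on the EP coronal projection; rejected
as "no lesion contrast" if the between-class variance explains <20% of the
total. The largest connected component is kept and hole-filled; the
boundary is refined as the DP path over radial gradient magnitude in polar
coordinates around the component centroid (360 angular columns).

*STV band.* Euclidean distance transform of the lesion complement;
`band_px = ceil(band_um / pixel_um)` (500 µm default); clipping at the
image border raises a warning. A standoff of 3 z-voxels below the traced
EP bottom keeps melanin out of the dermal projection.

*Vessels.* Optional Gaussian background subtraction, hysteresis threshold
(percentile mode 97/90 within the ROI for clinical-style data; Otsu mode
with low = high/2 for clean reconstructions; plain global Otsu,
`"otsu-global"`, for volumetric fractions where hysteresis growth would
bias the foreground fraction), removal of components under 5 px,
morphological closing, topology-preserving thinning, spur pruning under
3 px. Branch points are skeleton pixels with ≥3 neighbors, with adjacent
junction pixels merged to their centroid. Segments are skeleton paths
between nodes; arc length is the cumulative Euclidean step length (per-axis
voxel sizes respected in 3D) of a moving-average-smoothed copy of the path
(window 5, endpoints pinned) — raw integer-grid paths overestimate arc
length by 5–15% through quantization zig-zag. Closed loops (zero chord)
split at the point farthest from the start.

## Biomarkers

* TBV = nonzero voxels / ROI voxels. The pipeline measures it on the
  high-band reconstruction with a plain global Otsu cut followed by
  anisotropic closing (3×3×5 voxels ≈ half a PSF) and hole filling, which
  bridges the PSF and restores hollow tube interiors. On phantom ladders
  the measured/true ratio averages ≈1.0 with per-phantom scatter of
  roughly ±25%, dominated by the threshold's placement on weakly bimodal
  histograms at low vessel density.
* Vessel density = skeleton pixels / ROI pixels (mask-pixel mode
  available). Skeleton counting matches the ~0.01–0.02 scale of reported
  clinical values; mask counting runs ~10× higher.
* Average vessel length = total skeleton arc length / branch-point count,
  with divisor 1 when no branch point exists.
* Tortuosity: DM = AL/SL per segment; the primary output is the index
  mean(DM − 1), because reported group means (0.27/0.47) lie below the
  DM lower bound of 1; the raw mean DM is also stored. The pipeline
  excludes segments with chord < 5 px: a 2–3 px junction fragment has
  DM ≈ 2.4 from grid quantization alone and a single one can shift the
  mean by >0.1. Unweighted mean by default; AL-weighted available.
* Fractal number: box counts at dyadic sizes 2, 4, 8, … up to a quarter of
  the short image side (r = 1 saturates at the pixel count, very coarse
  boxes at O(1) counts; both bias the slope), least-squares slope of
  log N(r) against log(1/r), grid anchored at the image origin. A
  depth-5 Sierpinski carpet evaluates to within 0.04 of log 8/log 3.
* Lacunarity: mean(I²)/mean(I)² − 1 on the same image used for box
  counting; equals 1/p − 1 exactly for binary fill fraction p. A
  gliding-box variant is provided.

## Cohort statistics

Mann–Whitney U uses the exact permutation null when the pooled sample is
≤16 without ties, otherwise the normal approximation with tie and
continuity corrections (the behavior of the commercial package commonly
used for such analyses). ROC curves traverse tied scores jointly; the
trapezoidal AUC equals U/(n₁n₀) exactly, which is asserted to 1e-12.
Logistic regression is IRLS with intercept, convergence at max step <1e-8
or 100 iterations; perfect separation (diverging norm or singular system)
triggers a 1e-4 ridge refit and a flag. The combined-marker AUC uses
in-sample predicted probabilities (no cross-validation), matching the
published procedure; markers are standardized before the fit. Single-marker
AUCs use a fixed a-priori orientation — higher values indicate melanoma
for every biomarker except average vessel length, where shorter vessels
do — rather than the AUC ≥ 0.5 convention.

Per-lesion source data for the published cohort are not redistributable;
`make_synthetic_cohort` draws normal deviates per group and affinely
rescales them so the group means and sample SDs (ddof = 1) match the
published summaries exactly. Means, SDs and the significance pattern of
the report are therefore faithful; inter-marker correlations — and hence
the exact AUC values — are synthetic.

## Phantoms and recovery experiments

Random-walk vessel trees grow segments of gamma-distributed length
(mean 300 µm) with per-step Gaussian direction perturbation (the
`curvature` parameter; 0 gives exactly straight segments), branching with
probability 0.6 into two daughters up to depth 3, terminated at the
bounding box (reflection would bend straight segments and corrupt the
ground-truth tortuosity). Rasterization stamps a ball along the polyline
in ~100 µm chunks so the realized volume fraction stops close to the
target. Ground truth comes from the continuous geometry: capsule volumes
(cylinder + end caps) for TBV, polyline arc/chord for tortuosity, the
branching count for average length; the fractal number and lacunarity,
which have no closed form for a random tree, are evaluated on an ideal
noiseless centerline projection at twice the voxel resolution.

The skin phantom adds a melanin slab (default contrast 3× the vessel
value) and a pigmented-lesion disk (3× the slab) above the vessels, and
rejects overlapping melanin/vessel depth ranges.

The sinusoidal phantom places parallel tubes in disjoint lateral stripes,
oscillating with controlled amplitude and wavelength. Because the tubes
never cross — even in coronal projection — the measured skeleton topology
matches the generated one, isolating tortuosity from the
segment-fragmentation effects that random tangles produce; the tortuosity
recovery experiment uses it for exactly that reason, with amplitudes
capped where the bend radius approaches the tube radius (self-overlap).

Recovery experiments (in the acceptance suite and `scripts/acceptance.py`)
run at 64³-voxel phantoms (12×12×6 µm voxels) scanned at 39×39 positions
with 640 samples — sizes chosen so a full ladder runs in ~35 s on one
CPU while keeping ≥3 vessels per phantom and the full depth range in
view. The density ladder (targets 0.01–0.09, radius 40 µm) checks monotone
ordering of measured TBV and a ladder-mean measured/true ratio within
±25%; the amplitude ladder (0–85 µm, 3 tubes) checks monotone ordering of
the measured tortuosity index and agreement with the analytic truth within
0.1 (observed ≤0.03).

## Known limitations

* TBV accuracy is threshold-limited: single-phantom errors up to ~±30%
  occur at low vessel density even noiselessly; only ladder averages are
  accurate to ±25%. Any global threshold on a PSF-blurred image trades
  interior loss against halo gain.
* Tortuosity is measured at the segment scale; when projected vessels
  cross, junction splitting shortens segments and biases DM toward 1.
  The 3D geometry mode (`geometry_from="3d"`) avoids projection crossings
  but inherits clutter loops from the volumetric mask.
* Motion estimation requires a dominant common echo (surface/melanin);
  it is undefined on scenes without one.
* The forward model omits fluence and acoustic attenuation, so absolute
  intensities carry no physical units; all quantification is relative.
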