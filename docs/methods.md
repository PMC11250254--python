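# Methods

This note documents the models, parameter choices and numerical decisions
behind `cardioulm`, and what the synthetic test bed does and does not
establish about real transthoracic data.

## Acquisition model and units

All lengths are micrometres internally, times seconds, frequencies hertz;
frequencies are accepted in MHz at API boundaries where the field
convention expects it. The coordinate convention is: depth `z ≥ 0`
downward from the array centre, lateral `x` signed, polar angle measured
from the depth axis — so `x = r sin θ`, `z = r cos θ`.

The probe model is a single effective row of 80 elements at 270 µm pitch
(the physical probe's three-row layout and elevation focusing are not
modelled). The diverging-wave virtual source for steering angle α sits at
distance `D = 21.6 mm` behind the array along the steered direction; the
transmit path to a point is `|p − vs| − D`, making the wavefront's time
zero the moment it passes the array centre. Sound speed defaults to
1540 m/s (standard soft tissue; it reproduces the 320/452 µm
half-wavelengths at 2.4/1.7 MHz within 0.3%). The PRF (5,490 Hz) is treated
as a given system constant, never derived from depth: real systems add
overheads that a `c/(2·depth)` bound ignores.

## Synthetic acquisition generator

The generator produces the study conditions the pipeline assumes, with
ground truth retained at every step.

* **Vessel phantoms.** Parallel-pair (exact centreline separation — the
  resolution phantom), symmetric branching trees, and rings. Centrelines
  are polylines in µm; per-segment diameter and mean flow speed.
* **Bubble transits.** Poisson injections (segment choice proportional to
  length), per-bubble speed lognormal around the segment mean (log-sd 0.4
  by default), bubble intensity lognormal around 1 (log-sd 0.25). Bubble
  velocities in the ground-truth table are *forward finite differences* of
  the emitted positions times the frame rate, so position/velocity
  consistency is exact by construction. Default bubble rates keep the mean
  nearest-neighbour spacing above twice the lateral PSF FWHM — the
  slow-infusion regime in which one-bubble-per-patch localization is
  meaningful.
* **Cardiac motion.** Displacement = `a(phase) × [affine + smooth harmonic
  non-rigid]`. The temporal profile `a` is zero through diastole and a
  sharp-attack (√), smooth-release (cos²) bump through systole, so the
  first systolic frame carries the largest inter-frame change — which is
  what intensity-correlation gating detects; `a(0) = a(1) = 0` makes the
  field exactly periodic. `scaled_to_peak` rescales the whole field so its
  peak magnitude over a stated domain equals a requested amplitude
  (1.4–1.7 mm is the physiological in-plane range; tests use 1.5 mm).
* **Image rendering.** Bubbles are splatted with an anisotropic Gaussian
  PSF whose lateral FWHM interpolates linearly between the printed
  contrast-echo anchors (1,700 µm at 30 mm and 5,850 µm at 120 mm for
  2.4 MHz; 1,950/7,310 µm for 1.7 MHz) and whose axial FWHM defaults to
  one transmit wavelength. SNR is defined as mean clean-signal power over
  the signal support divided by the additive white-noise variance; the
  default is 30 dB, localization-precision experiments use 40 dB.
* **RF simulation (desk scale).** Narrowband Gaussian-windowed sinusoids;
  echo delay = (virtual-source path − standoff + element path)/c; channel
  sampling at 4× the transmit frequency. The two half-amplitude AM
  transmits are modelled as the same wavefront at half pressure, so linear
  scatterers cancel exactly while a power-law scatterer
  (`response ∝ amplitude^γ`, γ = 1.5 by default) survives. No attenuation,
  aberration or multiple scattering.

What the generator does **not** emulate: speckle statistics of real
tissue, chamber side-lobe artefacts, out-of-plane motion, nonlinear
propagation of the tissue path, and real bubble size distributions. Tests
passing on this bed therefore establish the *algorithmic* correctness of
each stage under its stated model, not clinical performance.

## Beamforming decisions

* Delay sampling is linear in time; scan conversion uses cubic splines
  (the step where spline interpolation is the named convention).
* The CV weight is implemented as `|mean(s)|² / var(s)` (variance pooled
  over all channels and angles), clipped to `w_max = 1`; zero variance
  (full coherence) maps to `w_max`. This normalization suppresses i.i.d.
  noise by ~`1/N` in amplitude while leaving coherent point targets at the
  DAS level — the behavior the side-lobe/noise-reduction role requires.
  Whether the variance should instead be computed per angle and averaged
  is unknown; pooled is the documented choice.
* Inter-angle bubble-motion correction estimates axial velocity from the
  lag-1 complex autocorrelation between repeats of each steering angle
  (ensemble rate = compounded frame rate; sign: a scatterer moving deeper
  lowers the sampled phase by `4πf d/c`). Each angle image is resampled
  along depth to the compounding-centre time with cubic interpolation
  (linear interpolation blurs the carrier enough to cancel the gain); no
  phase rotation is applied, consistent with Hilbert-domain processing.
  The estimator aliases at `c·f_rate/(4 f_tx)` ≈ 49 mm/s for the native
  sequence at 2.4 MHz; tests exercise speeds below that limit.
* Moving-average edges use truncated 2-frame windows so the frame count is
  preserved.

## Gating and motion correction

* Systole starts are prominence-filtered minima of the adjacent-frame
  correlation with a refractory window of 0.4 × the estimated period (the
  period is the median spacing of a first, unconstrained minima pass).
  Diastole is the contiguous block above the cycle's 75th correlation
  percentile immediately before the next systole start, clipped to
  0.2–0.4 s.
* The reference frame maximizes structural similarity (default SSIM
  constants) to the cycle-mean frame; ties break to the lowest index.
* Affine stage: 6 parameters about the image centre, Levenberg–Marquardt
  on the SSD residual vector (500-iteration cap, parameter tolerance
  1e-6).
* B-spline stage: cubic lattice (knot spacing 16 px ex vivo / 32 px in
  vivo) with one overhanging knot per side; the dense field is
  `B_z C B_x^T`, so the SSD gradient projects onto the lattice through the
  exact separable adjoint. Steepest descent with a backtracking line
  search (grow 1.6×, halve on failure), early stop after 20 consecutive
  relative cost changes below 1e-5. Images and their gradients are sampled
  with prefiltered cubic splines — with linear interpolation the cost
  surface has kinks at integer displacements and the line search stalls
  there.
* Thin-plate penalty: second-difference bending energy of the control
  lattice, weight 0.01 relative to the SSD of [0, 1]-scaled images. The
  weight restrains boundary control points (which the image term barely
  constrains) at a small bias cost; known-warp recovery stays within
  0.5 px RMS.
* All transforms map *reference* coordinates to *moving* coordinates (the
  resampling convention); localizations travel the other way through a
  fixed-point inverse (20 iterations — displacement fields here are far
  below the contraction limit).
* Known-warp recovery is tested in the representable direction (register
  the original onto the warped image): the inverse of a B-spline warp is
  generally *not* a member of the same B-spline family, so testing the
  other direction would measure family mismatch, not estimator error.

## Localization

* Noise floor: per-depth-row `median + 3 × 1.4826 × MAD` (bubbles occupy a
  small fraction of any row, so row statistics track the depth-dependent
  noise). Adaptive threshold: local mean over a square window of 1/8 the
  smaller image dimension, offset by the larger of 2 robust noise sigmas
  and 5% of the frame peak. The window must stay wider than the local PSF;
  analyses on small crops of a full-sector grid should pass the
  full-sector window size (99 px) explicitly.
* PSF-bank candidate selection (the bootstrap the estimation needs):
  patches of ≥ 9 px whose nearest neighbour is ≥ 3 patch diagonals away
  and whose aspect-normalized isoperimetric roundness is ≥ 0.6 (the
  normalization lets the strongly elongated deep-field PSFs qualify while
  rejecting ragged or multi-lobed shapes). Regions with too few candidates
  borrow the nearest populated region's PSF; an empty bank falls back to
  an analytic Gaussian with a warning.
* The weighted centroid of each NCC-cropped single-bubble image uses
  intensities *above the crop's own baseline*. Without that, the crop
  boundary pixels carry near-threshold weight that jumps in whole-pixel
  steps as a bubble moves sub-pixel distances — for the widest deep-field
  PSFs this quantization dominated the error budget (≈100 µm lateral
  scatter at 110 mm; ≈5 µm with the baseline removed). Reported bubble
  intensity remains the plain sum of crop pixel values.
* Coordinates snap to the 13.5 µm grid; the quantization alone contributes
  ≈3.9 µm mean absolute error per axis.

## Tracking

* Cost = intensity mismatch `|I_a − I_b| / max(I_a, I_b)` divided by the
  bivariate Gaussian innovation density of the constant-velocity Kalman
  model, floored at 1e-12 (the ratio is undefined at zero probability).
  Assignment is the exact global optimum over a square matrix augmented
  with dummy rows/columns; the dummy cost defaults to the cost of a pair
  at the 150 mm/s window edge with the frame's median intensity mismatch.
  The search window gates on raw displacement from the last measured
  position (innovation gating is the plausible alternative; raw
  displacement is the documented choice).
* Fuzzy initialization: new-track velocity = membership-weighted mean of
  the velocities implied by previous-frame localizations in the window,
  memberships Gaussian in distance (σ = half the window) and intensity
  mismatch (σ = 0.3).
* Process noise Q is the empirical covariance of frame-to-frame velocity
  increments from a nearest-neighbour warm-up pass over the first 20
  frames (position block scaled by dt²); with under 10 usable increments a
  documented default (σ_v = 5 mm/s) applies. Measurement noise R is the
  13.5 µm grid quantization variance.
* No gap linking: a missed frame terminates a track, matching
  consecutive-frame pairing.

## Rendering and quantification

* Density accumulates one count per super-covered cell per track (joints
  between consecutive steps are not double-counted within a track); the
  smoothing Gaussian (FWHM = λ/4, 160.4 µm at 2.4 MHz) integrates to one,
  so total mass is preserved. Speed/direction maps accumulate per-step
  values per cell and divide disk-smoothed numerator by disk-smoothed
  density (disk diameter = Gaussian FWHM); the ratio form keeps the kernel
  size from biasing speeds. Direction convention: 0° = +x, 90° = towards
  the probe; a vanishing averaged vector masks the pixel.
* FRC splits whole tracks (never frames within a track — a bubble's own
  localizations are correlated and would leak resolution across the
  split), renders both halves identically on the raw 13.5 µm grid
  (un-smoothed by default; the λ/4 Gaussian variant is available), and
  crosses the half-bit threshold
  `T(n) = (0.2071 + 1.9102/√n) / (1.2071 + 0.9102/√n)` computed from
  per-ring sample counts with one-frequency-sample rings. No crossing is
  flagged, with the grid Nyquist wavelength reported.
* Morphometry binarizes at any positive density, skeletonizes, and doubles
  the distance transform on centreline pixels; 50 µm bins, values above
  1,500 µm counted at the cap. Cross-sections average over a 0.5 mm
  perpendicular band, normalize to the maximum, and detect peaks above 0.3
  of it with ≥ 2-cell separation.

## Problem sizes in the test suite

The suite exercises every stage at desk scale as its own design choice:
beamforming grids of order 10⁴–10⁵ pixels with the full 80-channel,
6-angle, 3-pulse sequence; motion-correction stacks of 40–250 frames at
135 µm pixels; 100 point targets per depth for localization precision; and
hundreds of ground-truth tracks for the rendering/quantification phantoms.
The acceptance script uses 100 targets at each of three depths. End-to-end
pipeline smoke runs use ~1 s of data at 100 Hz in a 16 × 16 mm window.

## Known limitations

* 2D only: out-of-plane motion is uncorrectable by design of the imaging
  plane, and the simulator does not generate it.
* The tracker carries no appearance model beyond scalar intensity.
* NCC against a regional mean PSF cannot separate bubbles much closer than
  the PSF main lobe; multi-peak NCC handles moderate overlap only.
* The fuzzy-initialization and noise-estimation formulas follow the stated
  intent of the framework; their exact published forms live in
  supplementary material that is not part of this package's sources, so
  the implementations here are documented interpretations.
* The B-spline optimizer is a plain first-order method; capture range
  relies on the warm start along the frame sequence. Very fast motion
  between consecutive frames (≫ knot spacing) would need a
  multi-resolution extension.
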