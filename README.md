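# cardioulm

Ultrasound localization microscopy (ULM) of the myocardial microvasculature
through the chest wall, as a reusable Python pipeline. Transthoracic cardiac
imaging with a low-frequency phased array is limited to a lateral resolution
of a few millimetres; ULM breaks that limit by localizing individual
intravenous microbubbles over thousands of frames and accumulating their
tracks into super-resolved maps of vessel density, flow speed and flow
direction. Doing this in a beating heart requires every stage of the chain
to cooperate: contrast-specific beamforming of diverging waves, cardiac
gating, non-rigid tissue motion correction, sub-wavelength localization and
robust tracking.

The package implements that chain end to end, together with a fully
ground-truthed synthetic acquisition simulator so that every stage is
testable without clinical data. It is aimed at ultrasound researchers who
want to reproduce, probe or extend the processing itself.

## The method

**Acquisition model.** An 80-element, 270 µm pitch phased array (centre
frequency 2.84 MHz) transmits diverging waves from a virtual source 21.6 mm
behind the array centre (53° field of view), steering through six angles in
an ascending/descending triangle sequence (−15°, −3°, 9°, 15°, 3°, −9°)
with a three-pulse amplitude-modulation (AM) set — half, full, half — per
angle. At the 5,490 Hz PRF this compounds to 5,490 / 6 / 3 = 305 Hz.

**Contrast beamforming.** Per channel, the AM combination
`full − (half_a + half_b)` cancels linear tissue echoes and keeps the
nonlinear bubble response; a 3-frame moving-average subtraction removes
residual tissue. After a Hilbert transform, delay-and-sum (DAS) beamforming
reconstructs each angle on a polar grid (67.8 µm × 0.5°). B-mode uses plain
coherent compounding (linear, as the SVD clutter separation downstream
requires); the contrast image uses the coherence-to-variance (CV) weight
`w = |mean(s)|² / var(s)` over all channel×angle samples per pixel, after
shifting each angle image along depth by the bubble displacement estimated
from the per-angle Doppler ensemble. Envelopes are scan-converted to
Cartesian coordinates (67.8 × 135.0 µm) with spline interpolation.

**Cardiac gating and motion correction.** Systole starts are the minima of
the adjacent-frame image correlation; 0.2–0.4 s of quiescent diastole per
cycle is kept. Within a cycle, B-mode frames (tissue-only via a 5% SVD
reconstruction, log-compressed to 50 dB) are registered to a reference
frame by a two-stage transform — affine (Levenberg–Marquardt on SSD) then
B-spline free-form (steepest descent on SSD plus a thin-plate bending
penalty, 16/32 px knot spacing) — with a warm start from the neighbouring
frame. A rigid registration between per-cycle mean contrast images removes
inter-cycle drift.

**Localization and tracking.** Bubble candidates come from adaptive
thresholding plus a depth-dependent noise floor and 8-connectivity
labelling. The field of view is split into 5 × 5 regions and a point spread
function (PSF) is estimated per region by averaging ten isolated
single-bubble images. Each patch is matched against its regional PSF by
normalized cross-correlation; every connected NCC region above 0.5 yields
one bubble, localized by the intensity-weighted centroid on a 13.5 µm grid.
Tracking uses a feature-motion-model cost — intensity mismatch divided by
the Kalman innovation likelihood — solved as a global assignment with dummy
nodes, a 150 mm/s search window, fuzzy velocity initialization for new
bubbles, and a data-driven process-noise estimate. Tracks shorter than four
frames are dropped.

**Rendering and quantification.** Tracks are rasterized on the 13.5 µm grid
and smoothed with a Gaussian whose FWHM is a quarter wavelength; flow-speed
and direction maps divide disk-smoothed accumulated speed/velocity by the
disk-smoothed density. Resolution is estimated by Fourier ring correlation
between density maps of two random halves of the whole-track set, against
the half-bit information threshold. Vessel diameters are twice the distance
transform on the skeleton of the binarized density map (50 µm bins, capped
at 1,500 µm); speed statistics are the non-zero speed-map pixels (5 mm/s
bins) with a maximum-likelihood lognormal fit.

## Worked example

Resolve two parallel 300 µm-separated vessels — below the ~320 µm
half-wavelength of the 2.4 MHz transmit — from simulated bubble transits:

```python
import numpy as np
from cardioulm import AcquisitionGeometry
from cardioulm.simulate import make_vessel_phantom, simulate_transit
from cardioulm.tracking import finalize_tracks
from cardioulm.maps import render_density
from cardioulm.quantify import cross_section

geom = AcquisitionGeometry()
print("frame rate  :", geom.frame_rate_hz, "Hz")
print("angular FOV :", round(geom.angular_fov_deg, 1), "deg")

tree = make_vessel_phantom({"family": "parallel_pair", "separation_um": 300.0,
                            "center_um": (0.0, 40e3), "length_um": 6e3,
                            "mean_speed_mm_s": 20.0}, seed=0)
gt = simulate_transit(tree, duration_s=5.0, frame_rate_hz=geom.frame_rate_hz,
                      bubble_rate_per_s=50.0, seed=1)
hists = [[(int(r.frame), r.x_um, r.z_um, r.intensity) for r in sub.itertuples()]
         for _, sub in gt.records.groupby("id")]
tracks = finalize_tracks(hists, geom.frame_rate_hz, min_frames=4)
density, grid = render_density(tracks, fwhm_um=160.4)
profile = cross_section(density, grid, (0.0, 39e3), (0.0, 41e3), avg_width_um=500.0)
print("tracks      :", tracks.n_tracks)
print("separation  :", round(profile.peak_separations_um[0], 1), "um")
i0 = np.searchsorted(profile.s_um, profile.peak_positions_um[0])
i1 = np.searchsorted(profile.s_um, profile.peak_positions_um[1])
print("profile dip :", round(profile.profile[i0:i1].min(), 2))
```

Output:

```
frame rate  : 305.0 Hz
angular FOV : 53.1 deg
tracks      : 250
separation  : 297.3 um
profile dip : 0.19
```

The two centrelines are recovered 297.3 µm apart (truth: 300 µm, one
13.5 µm cell of error) and the normalized cross-profile dips to 0.19
between the peaks — the vessels are clearly resolved.

The full pipeline (simulate → gate → motion-correct → localize → track →
maps → statistics) runs from the command line:

```bash
cardioulm run --out runs/demo --seed 0          # bundled default simulation
cardioulm run --out runs/exvivo --no-gating     # ex vivo pathway
```

Each run writes the stacks (multi-frame TIFF + YAML sidecar), localization
and track CSVs, map TIFFs, a statistics CSV and a reproducibility manifest.

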