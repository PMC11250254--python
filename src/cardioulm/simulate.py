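"""Synthetic acquisition generator with ground truth.

Produces vessel trees, microbubble transits, periodic cardiac tissue motion,
contrast (CEUS) + B-mode image stacks with depth-dependent point spread
functions, and small-scale per-channel RF echo sets for diverging-wave AM
sequences.  Every output is deterministic for a fixed seed so each
downstream stage can be tested against known truth.

The generator emulates the slow-infusion contrast regime: bubble density is
kept low enough that the mean nearest-neighbour spacing exceeds twice the
lateral PSF width, the regime in which one-bubble-per-patch localization is
meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import AcquisitionGeometry, CartesianGrid
from .containers import ImageStack, RFFrameSet

__all__ = [
    "VesselSegment",
    "VesselTree",
    "GroundTruth",
    "MotionModel",
    "PSFModel",
    "Scatterer",
    "make_vessel_phantom",
    "simulate_transit",
    "sample_lognormal_speeds",
    "apply_tissue_motion",
    "make_tissue_template",
    "render_ceus_stack",
    "gaussian_pulse",
    "simulate_rf",
    "simulate_rf_frameset",
]


# ---------------------------------------------------------------------------
# Vessel phantoms
# ---------------------------------------------------------------------------

@dataclass
class VesselSegment:
    """A centreline polyline (N, 2) in µm (x, z) with a diameter and a mean
    flow speed."""

    polyline_um: np.ndarray
    diameter_um: float
    mean_speed_mm_s: float
    parent: int = -1

    def __post_init__(self):
        self.polyline_um = np.asarray(self.polyline_um, dtype=float)
        if self.polyline_um.ndim != 2 or self.polyline_um.shape[1] != 2:
            raise ValueError("polyline_um must be (N, 2)")
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")

    @property
    def arclength_um(self) -> np.ndarray:
        d = np.diff(self.polyline_um, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])

    @property
    def length_um(self) -> float:
        return float(self.arclength_um[-1])

    def point_at(self, s_um: float) -> np.ndarray:
        """Centreline point at arclength s (µm), clipped to the segment."""
        s_axis = self.arclength_um
        s = float(np.clip(s_um, 0.0, s_axis[-1]))
        x = np.interp(s, s_axis, self.polyline_um[:, 0])
        z = np.interp(s, s_axis, self.polyline_um[:, 1])
        return np.array([x, z])


@dataclass
class VesselTree:
    segments: list = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def min_centreline_distance(self) -> float:
        """Minimum pairwise distance between centreline vertex sets of
        distinct segments (µm)."""
        best = np.inf
        for i in range(self.n_segments):
            for j in range(i + 1, self.n_segments):
                a = self.segments[i].polyline_um
                b = self.segments[j].polyline_um
                d = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
                best = min(best, float(d.min()))
        return best


def _resample_polyline(points: np.ndarray, step_um: float) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    d = np.diff(points, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])
    n = max(int(math.ceil(s[-1] / step_um)) + 1, 2)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])])


def make_vessel_phantom(phantom_spec: dict, seed: int = 0) -> VesselTree:
    """Build a deterministic vessel-tree phantom.

    ``phantom_spec["family"]`` selects among:

    ``parallel_pair``
        two straight parallel vessels at an exact centreline separation —
        the resolution phantom;
    ``branching``
        a symmetric bifurcating tree;
    ``ring``
        a circular vessel.

    An optional ``sector`` entry ``{"depth_um": D, "half_angle_deg": A}``
    validates that every centreline vertex lies inside the imaging sector.
    """
    spec = dict(phantom_spec or {})
    family = spec.pop("family", None)
    sector = spec.pop("sector", None)
    tree = VesselTree()
    if family is None:
        return tree
    rng = np.random.default_rng(seed)

    if family == "parallel_pair":
        cx, cz = spec.get("center_um", (0.0, 60e3))
        sep = float(spec["separation_um"])
        length = float(spec.get("length_um", 10e3))
        theta = math.radians(spec.get("orientation_deg", 0.0))
        diam = float(spec.get("diameter_um", 200.0))
        speed = float(spec.get("mean_speed_mm_s", 20.0))
        u = np.array([math.cos(theta), math.sin(theta)])    # along-vessel
        nvec = np.array([-math.sin(theta), math.cos(theta)])  # normal
        for sgn in (-0.5, 0.5):
            c = np.array([cx, cz]) + sgn * sep * nvec
            line = np.stack([c - 0.5 * length * u, c + 0.5 * length * u])
            tree.segments.append(
                VesselSegment(_resample_polyline(line, 100.0), diam, speed)
            )
    elif family == "branching":
        cx, cz = spec.get("root_um", (0.0, 40e3))
        length = float(spec.get("trunk_length_um", 15e3))
        diam = float(spec.get("trunk_diameter_um", 600.0))
        speed = float(spec.get("mean_speed_mm_s", 30.0))
        levels = int(spec.get("levels", 3))
        branch_angle = math.radians(spec.get("branch_angle_deg", 30.0))
        shrink = float(spec.get("shrink", 0.7))

        def grow(p0, direction, length, diam, speed, level, parent):
            p1 = p0 + length * direction
            seg = VesselSegment(_resample_polyline(np.stack([p0, p1]), 100.0),
                                diam, speed, parent=parent)
            tree.segments.append(seg)
            idx = len(tree.segments) - 1
            if level + 1 < levels:
                a0 = math.atan2(direction[1], direction[0])
                for da in (-branch_angle, branch_angle):
                    d = np.array([math.cos(a0 + da), math.sin(a0 + da)])
                    grow(p1, d, length * shrink, diam * shrink, speed * shrink,
                         level + 1, idx)

        grow(np.array([cx, cz], dtype=float), np.array([0.0, 1.0]), length,
             diam, speed, 0, -1)
    elif family == "ring":
        cx, cz = spec.get("center_um", (0.0, 60e3))
        radius = float(spec.get("radius_um", 10e3))
        diam = float(spec.get("diameter_um", 300.0))
        speed = float(spec.get("mean_speed_mm_s", 20.0))
        ang = np.linspace(0.0, 2.0 * math.pi, max(int(2 * math.pi * radius / 200.0), 16))
        line = np.column_stack([cx + radius * np.cos(ang), cz + radius * np.sin(ang)])
        tree.segments.append(VesselSegment(line, diam, speed))
    else:
        raise ValueError(f"unknown phantom family: {family!r}")

    if sector is not None:
        depth = float(sector["depth_um"])
        half = math.radians(float(sector["half_angle_deg"]))
        for seg in tree.segments:
            x, z = seg.polyline_um[:, 0], seg.polyline_um[:, 1]
            r = np.hypot(x, z)
            th = np.arctan2(x, z)
            if np.any(r > depth) or np.any(np.abs(th) > half) or np.any(z < 0):
                raise ValueError("vessel phantom extends outside the imaging sector")
    return tree


# ---------------------------------------------------------------------------
# Bubble transit
# ---------------------------------------------------------------------------

def sample_lognormal_speeds(mu: float, sigma: float, n: int, rng: np.random.Generator
                            ) -> np.ndarray:
    """Lognormal speed samples (mm/s) with log-mean ``mu`` and log-sd
    ``sigma``; mean is exp(mu + sigma^2/2)."""
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


@dataclass
class GroundTruth:
    """Per-frame bubble records plus the generating objects.

    ``records`` columns: frame, id, x_um, z_um, vx_mm_s, vz_mm_s, intensity.
    Velocities are forward finite differences of the positions times the
    frame rate, so position/velocity consistency is exact by construction.
    """

    records: pd.DataFrame
    tree: VesselTree
    frame_rate_hz: float
    n_frames: int
    seed: int
    motion: Optional["MotionModel"] = None

    def frame_records(self, f: int) -> pd.DataFrame:
        return self.records[self.records["frame"] == f]

    def save_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def simulate_transit(
    tree: VesselTree,
    duration_s: float,
    frame_rate_hz: float,
    bubble_rate_per_s: float,
    speed_sigma: float = 0.4,
    intensity_sigma: float = 0.25,
    speed_law: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    seed: int = 0,
) -> GroundTruth:
    """Advect bubbles along vessel centrelines and emit per-frame records.

    Bubbles are injected as a Poisson process at ``bubble_rate_per_s``,
    assigned to segments with probability proportional to segment length,
    and advected at a per-bubble speed drawn from a lognormal law whose mean
    equals the segment's mean flow speed (log-sd ``speed_sigma``); pass
    ``speed_law(rng, n) -> mm/s`` to override.  Bubble intensity is lognormal
    around 1.  A bubble's record ends when it exits its segment.
    """
    if duration_s <= 0 or frame_rate_hz <= 0:
        raise ValueError("duration and frame rate must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate_hz))
    dt = 1.0 / frame_rate_hz
    rows = []
    if tree.n_segments and bubble_rate_per_s > 0:
        n_bubbles = rng.poisson(bubble_rate_per_s * duration_s)
        lengths = np.array([s.length_um for s in tree.segments])
        p = lengths / lengths.sum()
        seg_idx = rng.choice(tree.n_segments, size=n_bubbles, p=p)
        t_inject = rng.uniform(0.0, duration_s, size=n_bubbles)
        intensities = rng.lognormal(mean=0.0, sigma=intensity_sigma, size=n_bubbles)
        for b in range(n_bubbles):
            seg = tree.segments[seg_idx[b]]
            if speed_law is not None:
                speed = float(np.atleast_1d(speed_law(rng, 1))[0])
            else:
                # lognormal multiplier with unit mean around the segment speed
                mult = rng.lognormal(mean=-0.5 * speed_sigma**2, sigma=speed_sigma)
                speed = seg.mean_speed_mm_s * mult
            f0 = int(math.ceil(t_inject[b] * frame_rate_hz))
            positions = []
            f = f0
            while f < n_frames:
                s_um = (f * dt - t_inject[b]) * speed * 1e3  # mm/s -> µm/s
                if s_um > seg.length_um:
                    break
                positions.append((f, seg.point_at(s_um)))
                f += 1
            for k, (f, p_um) in enumerate(positions):
                if k + 1 < len(positions):
                    nxt = positions[k + 1][1]
                    v = (nxt - p_um) * frame_rate_hz * 1e-3  # µm/frame -> mm/s
                elif k > 0:
                    prev = positions[k - 1][1]
                    v = (p_um - prev) * frame_rate_hz * 1e-3
                else:
                    v = np.zeros(2)
                rows.append((f, b, p_um[0], p_um[1], v[0], v[1], intensities[b]))
    records = pd.DataFrame(
        rows, columns=["frame", "id", "x_um", "z_um", "vx_mm_s", "vz_mm_s", "intensity"]
    ).sort_values(["frame", "id"], ignore_index=True)
    return GroundTruth(records=records, tree=tree, frame_rate_hz=frame_rate_hz,
                       n_frames=n_frames, seed=seed)


# ---------------------------------------------------------------------------
# Cardiac tissue motion
# ---------------------------------------------------------------------------

@dataclass
class MotionModel:
    """Periodic in-plane cardiac deformation: affine + coarse non-rigid.

    The displacement field is ``a(phase) * [affine(p) + nonrigid(p)]`` where
    the temporal profile ``a`` is zero through diastole and a sharp-attack,
    smooth-release bump through systole, so the first systolic frame carries
    the largest inter-frame change (what intensity-correlation gating keys
    on).  ``a(0) == a(1) == 0`` makes the field exactly periodic.

    Amplitudes: ``translation_um`` (tx, tz), ``rotation_deg`` and ``scale``
    about ``center_um``, and ``nonrigid_amplitude_um`` on a smooth low-order
    harmonic field with spatial period ``nonrigid_period_um``.
    """

    period_s: float = 1.0
    systole_fraction: float = 0.35
    translation_um: tuple = (0.0, 0.0)
    rotation_deg: float = 0.0
    scale: float = 1.0
    center_um: tuple = (0.0, 60e3)
    nonrigid_amplitude_um: float = 0.0
    nonrigid_period_um: float = 20e3
    attack_fraction: float = 0.25
    field_scale: float = 1.0  # overall multiplier set by scaled_to_peak

    def phase(self, t_s) -> np.ndarray:
        return np.mod(np.asarray(t_s, dtype=float) / self.period_s, 1.0)

    def amplitude(self, t_s) -> np.ndarray:
        """Temporal profile in [0, 1]; 0 through diastole."""
        u = self.phase(t_s) / self.systole_fraction
        u = np.asarray(u)
        a = np.zeros_like(u)
        ua = self.attack_fraction
        rising = (u >= 0) & (u < ua)
        falling = (u >= ua) & (u < 1.0)
        with np.errstate(invalid="ignore"):
            a[rising] = np.sqrt(u[rising] / ua)
            a[falling] = np.cos(0.5 * np.pi * (u[falling] - ua) / (1.0 - ua)) ** 2
        return a

    def _spatial(self, x_um, z_um):
        x = np.asarray(x_um, dtype=float)
        z = np.asarray(z_um, dtype=float)
        cx, cz = self.center_um
        dx = np.zeros_like(x)
        dz = np.zeros_like(z)
        # affine part
        th = math.radians(self.rotation_deg)
        rel_x, rel_z = x - cx, z - cz
        ax = (math.cos(th) * self.scale - 1.0) * rel_x - math.sin(th) * self.scale * rel_z
        az = math.sin(th) * self.scale * rel_x + (math.cos(th) * self.scale - 1.0) * rel_z
        dx += ax + self.translation_um[0]
        dz += az + self.translation_um[1]
        # smooth non-rigid part (low-order harmonics; periodic, zero-mean)
        if self.nonrigid_amplitude_um:
            k = 2.0 * math.pi / self.nonrigid_period_um
            dx += self.nonrigid_amplitude_um * np.sin(k * rel_z) * np.cos(0.5 * k * rel_x)
            dz += self.nonrigid_amplitude_um * np.cos(0.7 * k * rel_x) * np.sin(0.6 * k * rel_z)
        return self.field_scale * dx, self.field_scale * dz

    def displacement(self, x_um, z_um, t_s):
        """(dx, dz) in µm at positions (x, z) and time t."""
        a = self.amplitude(t_s)
        dx, dz = self._spatial(x_um, z_um)
        return a * dx, a * dz

    def peak_displacement_um(self, x_um, z_um) -> float:
        dx, dz = self._spatial(x_um, z_um)
        return float(np.max(np.hypot(dx, dz)))

    def scaled_to_peak(self, peak_um: float, x_um, z_um) -> "MotionModel":
        """Return a copy rescaled so the peak displacement magnitude over the
        given sample points equals ``peak_um``."""
        cur = self.peak_displacement_um(x_um, z_um)
        if cur == 0:
            raise ValueError("motion model has zero displacement; cannot rescale")
        return MotionModel(
            period_s=self.period_s,
            systole_fraction=self.systole_fraction,
            translation_um=self.translation_um,
            rotation_deg=self.rotation_deg,
            scale=self.scale,
            center_um=self.center_um,
            nonrigid_amplitude_um=self.nonrigid_amplitude_um,
            nonrigid_period_um=self.nonrigid_period_um,
            attack_fraction=self.attack_fraction,
            field_scale=self.field_scale * peak_um / cur,
        )

    def systole_start_frames(self, n_frames: int, frame_rate_hz: float) -> np.ndarray:
        """Frame indices of each systole onset (phase crossing 0 upward)."""
        t = np.arange(n_frames) / frame_rate_hz
        ph = self.phase(t)
        starts = np.where(np.diff(ph) < 0)[0] + 1
        if ph[0] < 1.0 / (self.period_s * frame_rate_hz):
            starts = np.concatenate([[0], starts])
        return starts


def apply_tissue_motion(gt: GroundTruth, mm: MotionModel) -> GroundTruth:
    """Displace every bubble record by the tissue motion field at its frame
    time; the model is stored so renderers warp the tissue template with the
    identical field."""
    rec = gt.records.copy()
    if len(rec):
        t = rec["frame"].to_numpy() / gt.frame_rate_hz
        dx, dz = mm.displacement(rec["x_um"].to_numpy(), rec["z_um"].to_numpy(), t)
        rec["x_um"] = rec["x_um"] + dx
        rec["z_um"] = rec["z_um"] + dz
        # keep velocity = forward difference of the displaced positions
        rec = rec.sort_values(["id", "frame"], ignore_index=True)
        ids = rec["id"].to_numpy()
        same = ids[1:] == ids[:-1]  # row i and i+1 belong to one track
        fwd = np.where(same)[0]
        last_with_prev = np.where(~np.r_[same, False] & np.r_[False, same])[0]
        for col_v, col_p in (("vx_mm_s", "x_um"), ("vz_mm_s", "z_um")):
            p = rec[col_p].to_numpy()
            dv = (p[1:] - p[:-1]) * gt.frame_rate_hz * 1e-3
            v = np.zeros_like(p)
            v[fwd] = dv[fwd]
            v[last_with_prev] = dv[last_with_prev - 1]
            rec[col_v] = v
        rec = rec.sort_values(["frame", "id"], ignore_index=True)
    return GroundTruth(records=rec, tree=gt.tree, frame_rate_hz=gt.frame_rate_hz,
                       n_frames=gt.n_frames, seed=gt.seed, motion=mm)


# ---------------------------------------------------------------------------
# PSF model and image rendering
# ---------------------------------------------------------------------------

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

# Printed lateral PSF FWHM anchors of the contrast echocardiograph
# (depth mm -> FWHM µm) per transmit frequency.
_LATERAL_FWHM_ANCHORS = {
    2.4: ((30.0, 1700.0), (120.0, 5850.0)),
    1.7: ((30.0, 1950.0), (120.0, 7310.0)),
}


@dataclass
class PSFModel:
    """Depth-dependent anisotropic Gaussian PSF.

    Lateral FWHM interpolates linearly between two depth anchors (widening
    with depth, as diverging-wave transmission does); axial FWHM defaults to
    one transmit wavelength, constant with depth.
    """

    depth_anchors_mm: tuple = (30.0, 120.0)
    lateral_fwhm_anchors_um: tuple = (1700.0, 5850.0)
    axial_fwhm_um: float = 641.7
    noise_floor: float = 0.0

    @classmethod
    def for_frequency(cls, f_tx_mhz: float, sound_speed_m_s: float = 1540.0) -> "PSFModel":
        key = min(_LATERAL_FWHM_ANCHORS, key=lambda k: abs(k - f_tx_mhz))
        (d0, w0), (d1, w1) = _LATERAL_FWHM_ANCHORS[key]
        lam = sound_speed_m_s / f_tx_mhz
        return cls(depth_anchors_mm=(d0, d1), lateral_fwhm_anchors_um=(w0, w1),
                   axial_fwhm_um=lam)

    def lateral_fwhm_um(self, depth_um) -> np.ndarray:
        d_mm = np.asarray(depth_um, dtype=float) / 1e3
        (d0, d1) = self.depth_anchors_mm
        (w0, w1) = self.lateral_fwhm_anchors_um
        return w0 + (w1 - w0) * (d_mm - d0) / (d1 - d0)

    def sigmas_um(self, depth_um):
        """(sigma_z, sigma_x) in µm at a depth."""
        sx = self.lateral_fwhm_um(depth_um) * _FWHM_TO_SIGMA
        sz = self.axial_fwhm_um * _FWHM_TO_SIGMA
        return sz, sx

    def kernel(self, depth_um: float, dz_um: float, dx_um: float) -> np.ndarray:
        """Unit-peak PSF image sampled on a (z, x) pixel grid at a depth."""
        sz, sx = self.sigmas_um(depth_um)
        hz = max(int(math.ceil(4.0 * sz / dz_um)), 2)
        hx = max(int(math.ceil(4.0 * sx / dx_um)), 2)
        z = np.arange(-hz, hz + 1) * dz_um
        x = np.arange(-hx, hx + 1) * dx_um
        return np.exp(-0.5 * ((z[:, None] / sz) ** 2 + (x[None, :] / sx) ** 2))


def _splat(frame: np.ndarray, grid: CartesianGrid, x_um: float, z_um: float,
           amp: float, psf: PSFModel) -> None:
    sz, sx = psf.sigmas_um(z_um)
    zi = (z_um - grid.z_um[0]) / grid.dz_um
    xi = (x_um - grid.x_um[0]) / grid.dx_um
    hz = int(math.ceil(4.0 * sz / grid.dz_um))
    hx = int(math.ceil(4.0 * sx / grid.dx_um))
    z0, z1 = max(int(zi) - hz, 0), min(int(zi) + hz + 1, frame.shape[0])
    x0, x1 = max(int(xi) - hx, 0), min(int(xi) + hx + 1, frame.shape[1])
    if z0 >= z1 or x0 >= x1:
        return
    zz = (grid.z_um[z0:z1] - z_um) / sz
    xx = (grid.x_um[x0:x1] - x_um) / sx
    frame[z0:z1, x0:x1] += amp * np.exp(-0.5 * (zz[:, None] ** 2 + xx[None, :] ** 2))


def make_tissue_template(grid: CartesianGrid, seed: int = 0,
                         feature_scale_um: float = 2000.0) -> np.ndarray:
    """Smooth pseudo-speckle tissue image: band-limited random field with a
    broad intensity envelope, positive everywhere."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(grid.shape)
    sig_z = feature_scale_um / grid.dz_um / 4.0
    sig_x = feature_scale_um / grid.dx_um / 4.0
    f = gaussian_filter(raw, (sig_z, sig_x))
    f = (f - f.min()) / (f.max() - f.min() + 1e-30)
    zz = (grid.z_um - grid.z_um.mean()) / (np.ptp(grid.z_um) / 2 + 1e-30)
    xx = (grid.x_um - grid.x_um.mean()) / (np.ptp(grid.x_um) / 2 + 1e-30)
    envelope = np.exp(-0.5 * (zz[:, None] ** 2 + xx[None, :] ** 2) / 0.6**2)
    return (0.15 + f) * envelope


def _signal_power(clean: np.ndarray) -> float:
    support = clean > 1e-3 * clean.max() if clean.max() > 0 else np.zeros(clean.shape, bool)
    if not support.any():
        return 0.0
    return float(np.mean(clean[support] ** 2))


def render_ceus_stack(
    gt: GroundTruth,
    psf: PSFModel,
    grid: CartesianGrid,
    snr_db: float = 30.0,
    seed: int = 0,
    tissue_template: Optional[np.ndarray] = None,
    tissue_seed: int = 1,
) -> tuple[ImageStack, ImageStack]:
    """Render the ground truth to a CEUS stack plus a paired B-mode stack.

    Each bubble is splatted with the local depth-dependent PSF; white
    Gaussian noise is added so that mean signal power over the bubble
    support divided by the noise variance equals ``snr_db``.  The B-mode
    stack is the tissue template warped by the stored motion model (if any),
    with the same SNR definition applied to its own content.
    """
    from scipy.ndimage import map_coordinates

    rng = np.random.default_rng(seed)
    n = gt.n_frames
    ceus = np.zeros((n,) + grid.shape, dtype=np.float64)
    for f in range(n):
        rec = gt.frame_records(f)
        frame = ceus[f]
        for _, row in rec.iterrows():
            _splat(frame, grid, row["x_um"], row["z_um"], row["intensity"], psf)

    if tissue_template is None:
        tissue_template = make_tissue_template(grid, seed=tissue_seed)
    bmode = np.empty_like(ceus)
    zz, xx = np.meshgrid(grid.z_um, grid.x_um, indexing="ij")
    for f in range(n):
        if gt.motion is not None:
            t = f / gt.frame_rate_hz
            # backward warp: sample template at p - d(p) approximates forward
            # advection of the template by d for smooth fields
            dx, dz = gt.motion.displacement(xx, zz, t)
            zi = (zz - dz - grid.z_um[0]) / grid.dz_um
            xi = (xx - dx - grid.x_um[0]) / grid.dx_um
            bmode[f] = map_coordinates(tissue_template, [zi, xi], order=1, mode="nearest")
        else:
            bmode[f] = tissue_template

    p_sig = _signal_power(ceus)
    if p_sig > 0 and np.isfinite(snr_db):
        ceus += rng.normal(0.0, math.sqrt(p_sig / 10 ** (snr_db / 10)), ceus.shape)
    p_tis = _signal_power(bmode)
    if p_tis > 0 and np.isfinite(snr_db):
        bmode += rng.normal(0.0, math.sqrt(p_tis / 10 ** (snr_db / 10)), bmode.shape)

    ceus_stack = ImageStack(ceus.astype(np.float32), grid, gt.frame_rate_hz,
                            kind="ceus", coordinate_frame="cartesian")
    bmode_stack = ImageStack(bmode.astype(np.float32), grid, gt.frame_rate_hz,
                             kind="bmode", coordinate_frame="cartesian")
    return ceus_stack, bmode_stack


# ---------------------------------------------------------------------------
# RF channel simulation (desk scale)
# ---------------------------------------------------------------------------

@dataclass
class Scatterer:
    """Point scatterer at (x, z) µm; ``gamma`` is the amplitude-response
    exponent (1 = linear; >1 emulates a nonlinear bubble echo)."""

    x_um: float
    z_um: float
    amplitude: float = 1.0
    gamma: float = 1.0


def gaussian_pulse(t_s: np.ndarray, f_hz: float, n_cycles: float = 2.0) -> np.ndarray:
    """Gaussian-windowed sinusoid centred at t = 0."""
    sigma = n_cycles / (2.0 * f_hz) / 2.355
    return np.exp(-0.5 * (t_s / sigma) ** 2) * np.sin(2.0 * math.pi * f_hz * t_s)


_AM_TX_AMPLITUDE = {"half_a": 0.5, "full": 1.0, "half_b": 0.5}


def simulate_rf(
    scatterers: Sequence[Scatterer],
    geom: AcquisitionGeometry,
    angle_deg: float,
    am_pulse: str = "full",
    n_samples: Optional[int] = None,
) -> np.ndarray:
    """Per-channel RF traces for one diverging-wave transmit.

    The transmit wavefront emanates from the virtual source behind the array;
    the echo delay to a channel is ``(|vs - p| - |vs| + |p - e|) / c``.  The
    half-amplitude AM transmits excite interleaved element halves and are
    modelled as the same wavefront at half pressure, so a linear scatterer
    cancels exactly in ``full - (half_a + half_b)`` while a nonlinear
    (``gamma != 1``) scatterer leaves a residual.
    """
    if am_pulse not in _AM_TX_AMPLITUDE:
        raise ValueError(f"am_pulse must be one of {sorted(_AM_TX_AMPLITUDE)}")
    tx_amp = _AM_TX_AMPLITUDE[am_pulse]
    c_um_s = geom.sound_speed_m_s * 1e6
    fs = 4.0 * geom.f_tx_mhz * 1e6
    if n_samples is None:
        t_max = 2.2 * geom.imaging_depth_mm * 1e3 / c_um_s
        n_samples = int(math.ceil(t_max * fs))
    t = np.arange(n_samples) / fs
    vs = geom.virtual_source_um(angle_deg)
    d_vs = float(np.hypot(*vs))
    elems = geom.element_positions_um
    traces = np.zeros((geom.n_elements, n_samples))
    for sc in scatterers:
        p = np.array([sc.x_um, sc.z_um])
        d_tx = float(np.hypot(*(p - vs))) - d_vs
        response = sc.amplitude * tx_amp ** sc.gamma
        d_rx = np.hypot(p[0] - elems, p[1])
        delays = (d_tx + d_rx) / c_um_s
        for ch in range(geom.n_elements):
            traces[ch] += response * gaussian_pulse(t - delays[ch], geom.f_tx_mhz * 1e6)
    return traces


def simulate_rf_frameset(
    scatterers_per_frame: Sequence[Sequence[Scatterer]],
    geom: AcquisitionGeometry,
    n_samples: Optional[int] = None,
) -> RFFrameSet:
    """Full AM x angle RF set: samples[frame, channel, time, angle, pulse].

    Scatterer positions are held fixed within one compounded frame unless the
    caller passes per-frame scatterer lists that already encode inter-frame
    motion.  For moving targets across the angle sequence use
    ``simulate_rf_moving`` instead.
    """
    fs = 4.0 * geom.f_tx_mhz * 1e6
    frames = []
    for scats in scatterers_per_frame:
        per_angle = []
        for ang in geom.steering_angles_deg:
            pulses = [simulate_rf(scats, geom, ang, p, n_samples)
                      for p in ("half_a", "full", "half_b")]
            per_angle.append(np.stack(pulses, axis=-1))
        frames.append(np.stack(per_angle, axis=-2))  # (ch, t, angle, pulse)
    samples = np.stack(frames)
    return RFFrameSet(samples=samples, fs_hz=fs)


def simulate_rf_moving(
    scatterer: Scatterer,
    velocity_mm_s: tuple,
    geom: AcquisitionGeometry,
    n_frames: int,
    n_samples: Optional[int] = None,
) -> RFFrameSet:
    """RF set for a single scatterer moving at constant velocity, advancing
    between every transmit event (angle slots and frames)."""
    fs = 4.0 * geom.f_tx_mhz * 1e6
    vx, vz = velocity_mm_s
    dt_angle = geom.n_am_pulses / geom.prf_hz  # time per angle slot (s)
    frames = []
    for f in range(n_frames):
        per_angle = []
        for a, ang in enumerate(geom.steering_angles_deg):
            t = (f * geom.n_angles + a) * dt_angle
            sc = Scatterer(scatterer.x_um + vx * 1e3 * t,
                           scatterer.z_um + vz * 1e3 * t,
                           scatterer.amplitude, scatterer.gamma)
            pulses = [simulate_rf([sc], geom, ang, p, n_samples)
                      for p in ("half_a", "full", "half_b")]
            per_angle.append(np.stack(pulses, axis=-1))
        frames.append(np.stack(per_angle, axis=-2))
    return RFFrameSet(samples=np.stack(frames), fs_hz=fs)
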