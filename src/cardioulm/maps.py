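"""Super-resolution map rendering from microbubble tracks.

Trajectories are drawn on the 13.5 µm localization grid by linking paired
positions with straight lines (supercover rasterization, so a segment marks
every cell it passes through).  The density map accumulates trajectories and
is optionally smoothed with a 2D Gaussian whose FWHM is a quarter of the
transmit wavelength; flow-speed and flow-direction maps divide the
disk-smoothed accumulated speed/velocity by the disk-smoothed accumulated
density (the disk diameter equals the Gaussian FWHM), which keeps the
smoothing kernel from biasing the velocity estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import convolve, gaussian_filter

from .localize import SR_GRID_UM
from .tracking import TrackSet

__all__ = [
    "SRGrid",
    "SRMapBundle",
    "default_fwhm_um",
    "supercover_cells",
    "render_density",
    "render_speed",
    "render_direction",
    "render_maps",
    "compose_hsv",
    "animate",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def default_fwhm_um(f_tx_mhz: float, sound_speed_m_s: float = 1540.0) -> float:
    """Rendering Gaussian FWHM: a quarter of the transmit wavelength."""
    return sound_speed_m_s / f_tx_mhz / 4.0


@dataclass
class SRGrid:
    """Super-resolved rendering grid (13.5 µm pitch by default)."""

    x0_um: float
    z0_um: float
    nx: int
    nz: int
    pitch_um: float = SR_GRID_UM

    @classmethod
    def from_bounds(cls, x_min, x_max, z_min, z_max, pitch_um: float = SR_GRID_UM):
        nx = int(math.ceil((x_max - x_min) / pitch_um)) + 1
        nz = int(math.ceil((z_max - z_min) / pitch_um)) + 1
        return cls(x0_um=x_min, z0_um=z_min, nx=nx, nz=nz, pitch_um=pitch_um)

    @classmethod
    def for_tracks(cls, tracks: TrackSet, margin_um: float = 500.0,
                   pitch_um: float = SR_GRID_UM):
        d = tracks.data
        if not len(d):
            return cls(0.0, 0.0, 2, 2, pitch_um)
        return cls.from_bounds(d["x_um"].min() - margin_um, d["x_um"].max() + margin_um,
                               d["z_um"].min() - margin_um, d["z_um"].max() + margin_um,
                               pitch_um)

    @property
    def shape(self):
        return (self.nz, self.nx)

    def to_cells(self, x_um, z_um):
        return ((np.asarray(x_um) - self.x0_um) / self.pitch_um,
                (np.asarray(z_um) - self.z0_um) / self.pitch_um)


def supercover_cells(x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
    """All integer cells a 2D segment passes through (grid traversal).

    Coordinates are in cell units (cell (i, j) spans [i-0.5, i+0.5)).
    Returns an (n, 2) integer array of (x, y) cells, endpoint-inclusive.
    """
    cells = [(int(round(x0)), int(round(y0)))]
    cx, cy = cells[0]
    ex, ey = int(round(x1)), int(round(y1))
    dx, dy = x1 - x0, y1 - y0
    sx = 1 if dx > 0 else -1
    sy = 1 if dy > 0 else -1
    tx = ((cx + 0.5 * sx) - x0) / dx if dx != 0 else np.inf
    ty = ((cy + 0.5 * sy) - y0) / dy if dy != 0 else np.inf
    dtx = abs(1.0 / dx) if dx != 0 else np.inf
    dty = abs(1.0 / dy) if dy != 0 else np.inf
    guard = 0
    while (cx, cy) != (ex, ey) and guard < 100000:
        if tx <= ty:
            cx += sx
            tx += dtx
        else:
            cy += sy
            ty += dty
        cells.append((cx, cy))
        guard += 1
    return np.array(cells, dtype=int)


@dataclass
class SRMapBundle:
    """Density, speed and direction maps plus their rendering parameters."""

    grid: SRGrid
    density: np.ndarray
    speed: Optional[np.ndarray] = None
    direction_deg: Optional[np.ndarray] = None
    direction_valid: Optional[np.ndarray] = None
    fwhm_um: Optional[float] = None
    params: dict = field(default_factory=dict)


def _track_step_cells(tracks: TrackSet, grid: SRGrid):
    """Yield (cells, vx, vz, speed) per track step, cells clipped to grid."""
    for tid in tracks.track_ids():
        t = tracks.track(tid)
        xi, zi = grid.to_cells(t["x_um"].to_numpy(), t["z_um"].to_numpy())
        vx = t["vx_mm_s"].to_numpy()
        vz = t["vz_mm_s"].to_numpy()
        for k in range(len(t) - 1):
            cells = supercover_cells(xi[k], zi[k], xi[k + 1], zi[k + 1])
            keep = ((cells[:, 0] >= 0) & (cells[:, 0] < grid.nx)
                    & (cells[:, 1] >= 0) & (cells[:, 1] < grid.nz))
            yield cells[keep], vx[k], vz[k], math.hypot(vx[k], vz[k])


def render_density(tracks: TrackSet, grid: Optional[SRGrid] = None,
                   fwhm_um: Optional[float] = None,
                   gaussian: bool = True) -> tuple[np.ndarray, SRGrid]:
    """Accumulated-trajectory density map.

    Each track contributes one count to every cell its polyline passes
    through; the map is then convolved with the unit-mass 2D Gaussian of the
    stated FWHM (skippable for the raw single-pixel variant).
    """
    if grid is None:
        grid = SRGrid.for_tracks(tracks)
    acc = np.zeros(grid.shape)
    for tid in tracks.track_ids():
        t = tracks.track(tid)
        xi, zi = grid.to_cells(t["x_um"].to_numpy(), t["z_um"].to_numpy())
        seen = set()
        for k in range(max(len(t) - 1, 0)):
            for cx, cz in supercover_cells(xi[k], zi[k], xi[k + 1], zi[k + 1]):
                if 0 <= cx < grid.nx and 0 <= cz < grid.nz:
                    seen.add((cz, cx))
        if len(t) == 1:
            cz, cx = int(round(zi[0])), int(round(xi[0]))
            if 0 <= cx < grid.nx and 0 <= cz < grid.nz:
                seen.add((cz, cx))
        for cz, cx in seen:
            acc[cz, cx] += 1.0
    if gaussian and fwhm_um and acc.any():
        sigma = fwhm_um * _FWHM_TO_SIGMA / grid.pitch_um
        acc = gaussian_filter(acc, sigma)
    return acc, grid


def _disk_kernel(diameter_um: float, pitch_um: float) -> np.ndarray:
    r = max(diameter_um / 2.0 / pitch_um, 0.5)
    n = int(math.ceil(r))
    ax = np.arange(-n, n + 1)
    k = (ax[:, None] ** 2 + ax[None, :] ** 2) <= r ** 2
    return k.astype(float)


def _accumulate_speed(tracks: TrackSet, grid: SRGrid):
    num = np.zeros(grid.shape)       # accumulated speed
    den = np.zeros(grid.shape)       # accumulated trajectory density
    vx_acc = np.zeros(grid.shape)
    vz_acc = np.zeros(grid.shape)
    for cells, vx, vz, sp in _track_step_cells(tracks, grid):
        cz, cx = cells[:, 1], cells[:, 0]
        np.add.at(den, (cz, cx), 1.0)
        np.add.at(num, (cz, cx), sp)
        np.add.at(vx_acc, (cz, cx), vx)
        np.add.at(vz_acc, (cz, cx), vz)
    return num, den, vx_acc, vz_acc


def render_speed(tracks: TrackSet, grid: Optional[SRGrid] = None,
                 fwhm_um: float = 160.4) -> tuple[np.ndarray, SRGrid]:
    """Flow-speed map: disk-smoothed accumulated speed over disk-smoothed
    accumulated density, zero where no trajectory passes."""
    if grid is None:
        grid = SRGrid.for_tracks(tracks)
    num, den, _, _ = _accumulate_speed(tracks, grid)
    k = _disk_kernel(fwhm_um, grid.pitch_um)
    num_s = convolve(num, k, mode="constant")
    den_s = convolve(den, k, mode="constant")
    out = np.zeros(grid.shape)
    nz = den_s > 0
    out[nz] = num_s[nz] / den_s[nz]
    out[den == 0] = 0.0  # speed defined only on the trajectory support
    return out, grid


def render_direction(tracks: TrackSet, grid: Optional[SRGrid] = None,
                     fwhm_um: float = 160.4,
                     ) -> tuple[np.ndarray, np.ndarray, SRGrid]:
    """Flow-direction map from disk-smoothed accumulated velocities.

    Direction convention: 0° = +x (lateral right), 90° = -z (towards the
    probe), in [0, 360).  Pixels with a vanishing averaged vector (e.g.
    balanced opposite flows) are masked invalid.
    """
    if grid is None:
        grid = SRGrid.for_tracks(tracks)
    num, den, vx_acc, vz_acc = _accumulate_speed(tracks, grid)
    k = _disk_kernel(fwhm_um, grid.pitch_um)
    den_s = convolve(den, k, mode="constant")
    vx_s = convolve(vx_acc, k, mode="constant")
    vz_s = convolve(vz_acc, k, mode="constant")
    vx_m = np.zeros(grid.shape)
    vz_m = np.zeros(grid.shape)
    nz = den_s > 0
    vx_m[nz] = vx_s[nz] / den_s[nz]
    vz_m[nz] = vz_s[nz] / den_s[nz]
    mag = np.hypot(vx_m, vz_m)
    scale = mag.max() if mag.max() > 0 else 1.0
    valid = (den > 0) & (mag > 1e-6 * scale)
    direction = np.zeros(grid.shape)
    direction[valid] = np.degrees(np.arctan2(-vz_m[valid], vx_m[valid])) % 360.0
    return direction, valid, grid


def render_maps(tracks: TrackSet, grid: Optional[SRGrid] = None,
                fwhm_um: float = 160.4, gaussian: bool = True) -> SRMapBundle:
    """Render the full bundle (density, speed, direction) on one grid."""
    if grid is None:
        grid = SRGrid.for_tracks(tracks)
    density, _ = render_density(tracks, grid, fwhm_um=fwhm_um, gaussian=gaussian)
    speed, _ = render_speed(tracks, grid, fwhm_um=fwhm_um)
    direction, valid, _ = render_direction(tracks, grid, fwhm_um=fwhm_um)
    return SRMapBundle(grid=grid, density=density, speed=speed,
                       direction_deg=direction, direction_valid=valid,
                       fwhm_um=fwhm_um,
                       params={"fwhm_um": fwhm_um, "gaussian": gaussian,
                               "pitch_um": grid.pitch_um})


def compose_hsv(bundle: SRMapBundle, mode: str = "speed") -> np.ndarray:
    """HSV composite: hue encodes speed or direction, value encodes density,
    saturation is fixed.  Returns an (nz, nx, 3) float RGB image in [0, 1]."""
    from matplotlib.colors import hsv_to_rgb

    if mode not in ("speed", "direction"):
        raise ValueError("mode must be 'speed' or 'direction'")
    v = bundle.density / bundle.density.max() if bundle.density.max() > 0 \
        else np.zeros(bundle.grid.shape)
    if mode == "speed":
        src = bundle.speed
        h = (src / src.max() if src is not None and src.max() > 0
             else np.zeros(bundle.grid.shape)) * 0.66  # blue→red span
    else:
        if bundle.direction_deg is None:
            h = np.zeros(bundle.grid.shape)
        else:
            h = np.where(bundle.direction_valid, bundle.direction_deg, 0.0) / 360.0
    hsv = np.stack([h, np.ones_like(h), v], axis=-1)
    return hsv_to_rgb(hsv)


_WARM = np.array([1.0, 0.35, 0.1])
_COLD = np.array([0.15, 0.45, 1.0])


def animate(tracks: TrackSet, fps: float, out_path,
            grid: Optional[SRGrid] = None, duration_s: Optional[float] = None,
            track_frame_rate_hz: float = 305.0, marker_px: int = 1) -> int:
    """Render an animation of bubbles advected along their trajectories.

    Each localized bubble marker moves along its own track at the estimated
    speed; warm colour marks bubbles moving upwards (towards the probe,
    -z), cold colour downwards.  Returns the number of frames written
    (``duration * fps``).
    """
    import imageio.v2 as imageio

    if grid is None:
        grid = SRGrid.for_tracks(tracks)
    d = tracks.data
    if duration_s is None:
        span = (d["frame"].max() - d["frame"].min() + 1) if len(d) else 1
        duration_s = span / track_frame_rate_hz
    n_out = max(int(round(duration_s * fps)), 1)
    frames_rgb = []
    t0 = d["frame"].min() / track_frame_rate_hz if len(d) else 0.0
    for k in range(n_out):
        t = t0 + k / fps
        img = np.zeros(grid.shape + (3,))
        for tid in tracks.track_ids():
            tr = tracks.track(tid)
            tf = tr["frame"].to_numpy() / track_frame_rate_hz
            if t < tf[0] or t > tf[-1]:
                continue
            x = np.interp(t, tf, tr["x_um"].to_numpy())
            z = np.interp(t, tf, tr["z_um"].to_numpy())
            vz = np.interp(t, tf, tr["vz_mm_s"].to_numpy())
            xi, zi = grid.to_cells(x, z)
            cx, cz = int(round(float(xi))), int(round(float(zi)))
            colour = _WARM if vz < 0 else _COLD
            for dz in range(-marker_px, marker_px + 1):
                for dx in range(-marker_px, marker_px + 1):
                    if 0 <= cz + dz < grid.nz and 0 <= cx + dx < grid.nx:
                        img[cz + dz, cx + dx] = colour
        frames_rgb.append((img * 255).astype(np.uint8))
    imageio.mimsave(out_path, frames_rgb, duration=1000.0 / fps, loop=0)
    return n_out
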