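"""Contrast-specific beamforming for diverging-wave AM sequences.

The chain per steering angle is: AM combination of the half/full/half pulse
triplet (isolates nonlinear bubble echoes), temporal moving-average
subtraction across frames (suppresses residual tissue), Hilbert transform to
analytic signals, delay-and-sum onto a polar grid, inter-angle Doppler
correction of bubble motion, and either coherent (DAS) compounding for
B-mode — linear, as the downstream SVD clutter separation requires — or
coherence-to-variance (CV) weighting for the contrast image.  Envelope
images are finally scan-converted to Cartesian coordinates with spline
interpolation.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import hilbert

from .geometry import AcquisitionGeometry, PolarGrid, CartesianGrid, cartesian_to_polar
from .containers import ImageStack, RFFrameSet

__all__ = [
    "am_contrast",
    "moving_average_subtract",
    "das_beamform",
    "das_delayed_samples",
    "cv_compound",
    "estimate_axial_velocity",
    "interangle_motion_correct",
    "scan_convert",
    "scan_convert_inverse",
    "reconstruct",
]


def am_contrast(half_a: np.ndarray, full: np.ndarray, half_b: np.ndarray) -> np.ndarray:
    """AM contrast combination ``full - (half_a + half_b)``.

    Linear echoes cancel; any amplitude-nonlinear response survives.
    """
    half_a, full, half_b = (np.asarray(a) for a in (half_a, full, half_b))
    if not (half_a.shape == full.shape == half_b.shape):
        raise ValueError("AM pulse traces must share one shape")
    return full - (half_a + half_b)


def moving_average_subtract(stack: np.ndarray, window: int = 3) -> np.ndarray:
    """Subtract the centred ``window``-frame temporal mean from each frame.

    Static content vanishes; transits survive.  Edge frames use truncated
    windows so the frame count is preserved.  The frame axis is axis 0.
    """
    stack = np.asarray(stack)
    n = stack.shape[0]
    if n < window:
        raise ValueError(f"stack has {n} frames; window={window} requires at least {window}")
    half = window // 2
    out = np.empty_like(stack, dtype=np.result_type(stack.dtype, np.float64))
    for f in range(n):
        lo, hi = max(0, f - half), min(n, f + half + 1)
        out[f] = stack[f] - stack[lo:hi].mean(axis=0)
    return out


def _pixel_delays_s(geom: AcquisitionGeometry, angle_deg: float, grid: PolarGrid):
    """Two-way time of flight (n_r, n_theta, n_channels), diverging-wave
    transmit + element receive."""
    c = geom.sound_speed_m_s * 1e6  # µm/s
    th = np.deg2rad(grid.theta_deg)
    r = grid.r_um
    px = r[:, None] * np.sin(th)[None, :]
    pz = r[:, None] * np.cos(th)[None, :]
    vs = geom.virtual_source_um(angle_deg)
    d_vs = float(np.hypot(*vs))
    d_tx = np.hypot(px - vs[0], pz - vs[1]) - d_vs
    elems = geom.element_positions_um
    d_rx = np.hypot(px[..., None] - elems[None, None, :], pz[..., None])
    return (d_tx[..., None] + d_rx) / c


def das_delayed_samples(
    traces: np.ndarray,
    geom: AcquisitionGeometry,
    angle_deg: float,
    grid: PolarGrid,
    fs_hz: float,
    t0_s: float = 0.0,
) -> np.ndarray:
    """Delay-aligned analytic samples per pixel: (n_r, n_theta, n_channels).

    ``traces`` are complex analytic channel signals (n_channels, n_samples);
    sampling is linear in time; out-of-range delays contribute zero.
    """
    traces = np.asarray(traces)
    n_ch, n_t = traces.shape
    delays = _pixel_delays_s(geom, angle_deg, grid)
    idx = (delays - t0_s) * fs_hz
    i0 = np.floor(idx).astype(np.int64)
    frac = idx - i0
    valid = (i0 >= 0) & (i0 < n_t - 1)
    i0c = np.clip(i0, 0, n_t - 2)
    out = np.empty(delays.shape, dtype=complex)
    ch_idx = np.broadcast_to(np.arange(n_ch)[None, None, :], delays.shape)
    s0 = traces[ch_idx, i0c]
    s1 = traces[ch_idx, i0c + 1]
    out = s0 * (1.0 - frac) + s1 * frac
    out[~valid] = 0.0
    return out


def das_beamform(
    traces: np.ndarray,
    geom: AcquisitionGeometry,
    angle_deg: float,
    grid: PolarGrid,
    fs_hz: float,
    t0_s: float = 0.0,
) -> np.ndarray:
    """Delay-and-sum a single-angle analytic trace set onto the polar grid."""
    return das_delayed_samples(traces, geom, angle_deg, grid, fs_hz, t0_s).sum(axis=-1)


def cv_compound(delayed: np.ndarray, w_max: float = 1.0) -> np.ndarray:
    """Coherence-to-variance compounding of delayed samples.

    ``delayed`` carries the channel-and-angle sample axis last.  The pixel
    weight is the squared magnitude of the sample mean over the sample
    variance, clipped to ``w_max`` (zero variance — full coherence — maps to
    ``w_max``); the output is the weight times the coherent sum.
    """
    delayed = np.asarray(delayed)
    s_sum = delayed.sum(axis=-1)
    mean = delayed.mean(axis=-1)
    var = np.mean(np.abs(delayed - mean[..., None]) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.abs(mean) ** 2 / var
    w[~np.isfinite(w)] = w_max
    return np.minimum(w, w_max) * s_sum


def estimate_axial_velocity(
    per_angle_images: np.ndarray,
    frame_rate_hz: float,
    f_mhz: float,
    sound_speed_m_s: float = 1540.0,
    smooth_px: float = 1.0,
) -> np.ndarray:
    """Axial velocity map (mm/s, positive away from the probe) from the
    lag-1 complex autocorrelation between repeats of each steering angle.

    ``per_angle_images`` has shape (n_frames, n_angles, n_r, n_theta); each
    angle recurs once per compounded frame, so the Doppler ensemble rate is
    the frame rate.
    """
    img = np.asarray(per_angle_images)
    if img.ndim != 4 or img.shape[0] < 2:
        raise ValueError("need (n_frames>=2, n_angles, n_r, n_theta) per-angle images")
    r1 = np.sum(np.conj(img[:-1]) * img[1:], axis=(0, 1))
    if smooth_px:
        from scipy.ndimage import gaussian_filter
        r1 = gaussian_filter(r1.real, smooth_px) + 1j * gaussian_filter(r1.imag, smooth_px)
    phi = np.angle(r1)
    # pulse-echo: a scatterer moving deeper by d lowers the sampled phase by
    # 4*pi*f*d/c per frame interval, hence the minus sign
    d_um = -phi * (sound_speed_m_s * 1e6) / (4.0 * math.pi * f_mhz * 1e6)
    return d_um * frame_rate_hz * 1e-3  # µm/frame -> mm/s


def _shift_along_r(image: np.ndarray, shift_px: np.ndarray) -> np.ndarray:
    """Resample ``image`` at r + shift (per-pixel), cubic-spline interpolation
    (linear would blur the carrier of analytic signals)."""
    n_r, n_t = image.shape
    ri = np.arange(n_r)[:, None] + shift_px
    ti = np.broadcast_to(np.arange(n_t)[None, :], image.shape)
    coords = [ri, ti]
    if np.iscomplexobj(image):
        return (map_coordinates(image.real, coords, order=3, mode="constant")
                + 1j * map_coordinates(image.imag, coords, order=3, mode="constant"))
    return map_coordinates(image, coords, order=3, mode="constant")


def interangle_motion_correct(
    per_angle_images: np.ndarray,
    frame_rate_hz: float,
    geom: AcquisitionGeometry,
    grid: PolarGrid,
    velocity_mm_s: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Shift each angle image along depth to the compounding-centre time.

    A bubble moving axially decorrelates across the six angle transmits of a
    frame; with its velocity estimated from the per-angle Doppler ensemble,
    the image for angle slot ``a`` (acquired ``t_a - t_c`` before/after the
    frame centre) is resampled by the corresponding axial displacement.  No
    phase rotation is applied (analytic signals are shifted as-is).

    Returns (corrected per-angle images, velocity map in mm/s).
    """
    img = np.asarray(per_angle_images)
    if img.ndim != 4:
        raise ValueError("per_angle_images must be (n_frames, n_angles, n_r, n_theta)")
    n_frames, n_angles = img.shape[:2]
    if n_angles != geom.n_angles:
        raise ValueError("angle axis does not match the steering sequence (unpaired angles)")
    if velocity_mm_s is None:
        velocity_mm_s = estimate_axial_velocity(
            img, frame_rate_hz, geom.f_tx_mhz, geom.sound_speed_m_s)
    dt_angle = geom.n_am_pulses / geom.prf_hz
    t_c = (n_angles - 1) / 2.0 * dt_angle
    out = np.empty_like(img)
    for a in range(n_angles):
        # content seen at t_a sits at r(t_c) + v*(t_a - t_c); sample there
        shift_px = velocity_mm_s * 1e3 * (a * dt_angle - t_c) / grid.dr_um
        for f in range(n_frames):
            out[f, a] = _shift_along_r(img[f, a], shift_px)
    return out, velocity_mm_s


def scan_convert(
    polar_image: np.ndarray,
    polar: PolarGrid,
    cart: CartesianGrid,
    order: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Spline-interpolate an envelope image from (r, theta) to (z, x).

    Returns (image, validity mask); pixels outside the sector are zero.
    """
    zz, xx = np.meshgrid(cart.z_um, cart.x_um, indexing="ij")
    r, th = cartesian_to_polar(xx, zz)
    ri = (r - polar.r_um[0]) / polar.dr_um
    ti = (th - polar.theta_deg[0]) / polar.dtheta_deg
    mask = ((ri >= 0) & (ri <= polar.r_um.size - 1)
            & (ti >= 0) & (ti <= polar.theta_deg.size - 1))
    img = map_coordinates(np.asarray(polar_image, dtype=float), [ri, ti],
                          order=order, mode="nearest")
    img[~mask] = 0.0
    return img, mask


def scan_convert_inverse(
    cart_image: np.ndarray,
    cart: CartesianGrid,
    polar: PolarGrid,
    order: int = 3,
) -> np.ndarray:
    """Resample a Cartesian image back onto the polar grid (round trips)."""
    th = np.deg2rad(polar.theta_deg)
    px = polar.r_um[:, None] * np.sin(th)[None, :]
    pz = polar.r_um[:, None] * np.cos(th)[None, :]
    zi = (pz - cart.z_um[0]) / cart.dz_um
    xi = (px - cart.x_um[0]) / cart.dx_um
    return map_coordinates(np.asarray(cart_image, dtype=float), [zi, xi],
                           order=order, mode="nearest")


def reconstruct(
    rfset: RFFrameSet,
    geom: AcquisitionGeometry,
    polar: PolarGrid,
    cart: Optional[CartesianGrid] = None,
    motion_correct: bool = True,
    ma_window: int = 3,
    w_max: float = 1.0,
) -> tuple[ImageStack, ImageStack]:
    """Full reconstruction of an RF frame set into CEUS and B-mode stacks.

    B-mode: full-amplitude pulse, DAS with coherent angle compounding
    (linear).  CEUS: AM combination, moving-average tissue subtraction,
    DAS delays, inter-angle bubble-motion correction, CV compounding.
    Envelope images are scan-converted when a Cartesian grid is given,
    otherwise returned on the polar grid.
    """
    n_frames = rfset.n_frames
    n_angles = rfset.n_angles
    fr = geom.frame_rate_hz

    # AM contrast RF and tissue-suppression filtering, per channel and angle
    contrast_rf = am_contrast(rfset.samples[..., 0], rfset.samples[..., 1],
                              rfset.samples[..., 2])
    if n_frames >= ma_window:
        contrast_rf = moving_average_subtract(contrast_rf, ma_window)
    full_rf = rfset.samples[..., 1]

    contrast_an = hilbert(contrast_rf, axis=2)
    full_an = hilbert(full_rf, axis=2)

    shape = (polar.r_um.size, polar.theta_deg.size)
    bmode = np.zeros((n_frames,) + shape)
    ceus = np.zeros((n_frames,) + shape)
    # per-angle delayed channel tensors for the contrast path
    delayed = np.zeros((n_frames, n_angles) + shape + (geom.n_elements,), dtype=complex)
    per_angle_img = np.zeros((n_frames, n_angles) + shape, dtype=complex)
    for f in range(n_frames):
        b = np.zeros(shape, dtype=complex)
        for a, ang in enumerate(geom.steering_angles_deg):
            b += das_beamform(full_an[f, :, :, a], geom, ang, polar, rfset.fs_hz,
                              rfset.t0_s)
            d = das_delayed_samples(contrast_an[f, :, :, a], geom, ang, polar,
                                    rfset.fs_hz, rfset.t0_s)
            delayed[f, a] = d
            per_angle_img[f, a] = d.sum(axis=-1)
        bmode[f] = np.abs(b)

    if motion_correct and n_frames >= 2:
        _, v = interangle_motion_correct(per_angle_img, fr, geom, polar)
        dt_angle = geom.n_am_pulses / geom.prf_hz
        t_c = (n_angles - 1) / 2.0 * dt_angle
        for f in range(n_frames):
            for a in range(n_angles):
                shift_px = v * 1e3 * (a * dt_angle - t_c) / polar.dr_um
                for ch in range(geom.n_elements):
                    delayed[f, a, :, :, ch] = _shift_along_r(delayed[f, a, :, :, ch],
                                                             shift_px)
    for f in range(n_frames):
        stacked = np.moveaxis(delayed[f], 0, -2).reshape(shape + (-1,))
        ceus[f] = np.abs(cv_compound(stacked, w_max=w_max))

    if cart is not None:
        bm = np.stack([scan_convert(fr_, polar, cart)[0] for fr_ in bmode])
        ce = np.stack([scan_convert(fr_, polar, cart)[0] for fr_ in ceus])
        frame_tag = "cartesian"
        grid = cart
    else:
        bm, ce, frame_tag, grid = bmode, ceus, "polar", polar
    return (
        ImageStack(ce.astype(np.float32), grid, fr, kind="ceus", coordinate_frame=frame_tag),
        ImageStack(bm.astype(np.float32), grid, fr, kind="bmode", coordinate_frame=frame_tag),
    )
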