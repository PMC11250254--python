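"""Acquisition geometry, pulse-sequence arithmetic and imaging grids.

The acquisition model is a 2 MHz-class cardiac phased array transmitting
diverging waves from a virtual source behind the array, with a triangle
steering-angle sequence and a three-pulse amplitude-modulation (AM) set per
angle.  All lengths are stored in micrometres internally, times in seconds
and frequencies in hertz; converters live at the API boundary (frequencies
are accepted in MHz where noted, matching field conventions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "AcquisitionGeometry",
    "PolarGrid",
    "CartesianGrid",
    "compounded_frame_rate",
    "angular_fov",
    "wavelength",
    "half_wavelength",
    "build_grids",
    "polar_to_cartesian",
    "cartesian_to_polar",
]


def compounded_frame_rate(prf: float, n_angles: int, n_am_pulses: int) -> float:
    """Compounded frame rate in Hz: ``prf / (n_angles * n_am_pulses)``.

    One compounded frame consumes ``n_angles * n_am_pulses`` transmits, e.g.
    5490 Hz with 6 angles and 3 AM pulses gives 305 Hz.
    """
    if prf <= 0 or n_angles <= 0 or n_am_pulses <= 0:
        raise ValueError("prf, n_angles and n_am_pulses must all be positive")
    return prf / (n_angles * n_am_pulses)


def angular_fov(aperture_width: float, virtual_source_depth: float) -> float:
    """Angular field of view (degrees) of a diverging wave.

    The virtual source sits ``virtual_source_depth`` behind the array centre;
    the sector is bounded by rays from the source through the aperture edges:
    ``2 * atan((aperture_width / 2) / virtual_source_depth)``.  Both arguments
    must use the same length unit.
    """
    if aperture_width <= 0:
        raise ValueError("aperture_width must be positive")
    if virtual_source_depth <= 0:
        raise ValueError("virtual_source_depth must be positive")
    return math.degrees(2.0 * math.atan((aperture_width / 2.0) / virtual_source_depth))


def wavelength(sound_speed: float, f_mhz: float) -> float:
    """Wavelength in µm for a sound speed in m/s and frequency in MHz."""
    if sound_speed <= 0 or f_mhz <= 0:
        raise ValueError("sound_speed and frequency must be positive")
    return sound_speed / f_mhz


def half_wavelength(sound_speed: float, f_mhz: float) -> float:
    """Half wavelength in µm (e.g. 320.8 µm at 2.4 MHz in soft tissue)."""
    return wavelength(sound_speed, f_mhz) / 2.0


@dataclass
class AcquisitionGeometry:
    """Probe, virtual-source and pulse-sequence description.

    Defaults reproduce an 80-element, 270 µm pitch phased array driven with
    six diverging-wave steering angles in ascending-then-descending triangle
    order and a half/full/half AM pulse triplet at the maximum PRF for a
    120 mm imaging depth.
    """

    n_elements: int = 80
    pitch_um: float = 270.0
    virtual_source_depth_mm: float = 21.6
    sound_speed_m_s: float = 1540.0
    f_tx_mhz: float = 2.4
    f_center_mhz: float = 2.84
    prf_hz: float = 5490.0
    steering_angles_deg: tuple = (-15.0, -3.0, 9.0, 15.0, 3.0, -9.0)
    n_am_pulses: int = 3
    imaging_depth_mm: float = 120.0

    def __post_init__(self):
        if self.n_elements <= 0 or self.pitch_um <= 0:
            raise ValueError("n_elements and pitch_um must be positive")
        if self.virtual_source_depth_mm <= 0:
            raise ValueError("virtual_source_depth_mm must be positive")
        if len(self.steering_angles_deg) % 2 != 0:
            raise ValueError("steering_angles_deg must have even length (triangle sequence)")
        self.steering_angles_deg = tuple(float(a) for a in self.steering_angles_deg)

    # -- derived quantities -------------------------------------------------
    @property
    def aperture_width_um(self) -> float:
        return self.n_elements * self.pitch_um

    @property
    def element_positions_um(self) -> np.ndarray:
        """Lateral element centre offsets from the array centre (µm)."""
        n = self.n_elements
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch_um

    @property
    def n_angles(self) -> int:
        return len(self.steering_angles_deg)

    @property
    def frame_rate_hz(self) -> float:
        return compounded_frame_rate(self.prf_hz, self.n_angles, self.n_am_pulses)

    @property
    def angular_fov_deg(self) -> float:
        return angular_fov(self.aperture_width_um, self.virtual_source_depth_mm * 1e3)

    @property
    def wavelength_um(self) -> float:
        return wavelength(self.sound_speed_m_s, self.f_tx_mhz)

    def virtual_source_um(self, angle_deg: float) -> np.ndarray:
        """Virtual source position (x, z) in µm for one steering angle.

        The source lies behind the array (z < 0) on the line through the array
        centre at the steering angle, at the virtual-source standoff distance.
        """
        d = self.virtual_source_depth_mm * 1e3
        a = math.radians(angle_deg)
        return np.array([-d * math.sin(a), -d * math.cos(a)])

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["steering_angles_deg"] = list(self.steering_angles_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        d = dict(d)
        if "steering_angles_deg" in d:
            d["steering_angles_deg"] = tuple(d["steering_angles_deg"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"geometry": self.to_dict()}, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "AcquisitionGeometry":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d["geometry"])


def _axis(start: float, stop: float, step: float) -> np.ndarray:
    """Inclusive sample axis covering [start, stop] with the given spacing."""
    if step <= 0:
        raise ValueError("grid spacing must be positive")
    span = stop - start
    if step > span:
        raise ValueError("grid spacing larger than the axis extent")
    n = int(math.ceil(span / step)) + 1
    return start + step * np.arange(n)


@dataclass
class PolarGrid:
    """Beamforming grid: radius from the array centre × angle from broadside.

    Angle samples are centred on 0° (broadside) because the steering set is
    symmetric.  Default spacings: 67.8 µm radially and 0.5°.
    """

    dr_um: float = 67.8
    dtheta_deg: float = 0.5
    r_max_um: float = 120e3
    theta_span_deg: float = 53.13

    r_um: np.ndarray = field(init=False, repr=False)
    theta_deg: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.r_um = _axis(0.0, self.r_max_um, self.dr_um)
        half = self.theta_span_deg / 2.0
        self.theta_deg = _axis(-half, half, self.dtheta_deg)

    @property
    def shape(self):
        return (self.r_um.size, self.theta_deg.size)

    def to_dict(self) -> dict:
        return {
            "dr_um": self.dr_um,
            "dtheta_deg": self.dtheta_deg,
            "r_max_um": self.r_max_um,
            "theta_span_deg": self.theta_span_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolarGrid":
        return cls(**d)


@dataclass
class CartesianGrid:
    """Scan-converted grid: z ≥ 0 downward from the array centre, x signed.

    Default spacings follow the reconstruction convention: 67.8 µm along
    depth and 135.0 µm laterally.
    """

    dz_um: float = 67.8
    dx_um: float = 135.0
    z_min_um: float = 0.0
    z_max_um: float = 120e3
    x_min_um: float = -60e3
    x_max_um: float = 60e3

    z_um: np.ndarray = field(init=False, repr=False)
    x_um: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.z_um = _axis(self.z_min_um, self.z_max_um, self.dz_um)
        self.x_um = _axis(self.x_min_um, self.x_max_um, self.dx_um)

    @property
    def shape(self):
        return (self.z_um.size, self.x_um.size)

    def to_dict(self) -> dict:
        return {
            "dz_um": self.dz_um,
            "dx_um": self.dx_um,
            "z_min_um": self.z_min_um,
            "z_max_um": self.z_max_um,
            "x_min_um": self.x_min_um,
            "x_max_um": self.x_max_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CartesianGrid":
        return cls(**d)


def build_grids(
    geom: AcquisitionGeometry,
    dr_um: float = 67.8,
    dtheta_deg: float = 0.5,
    dz_um: float = 67.8,
    dx_um: float = 135.0,
) -> tuple[PolarGrid, CartesianGrid]:
    """Polar grid spanning depth × angular FOV, and a Cartesian grid bounding
    the sector."""
    depth = geom.imaging_depth_mm * 1e3
    fov = geom.angular_fov_deg
    polar = PolarGrid(dr_um=dr_um, dtheta_deg=dtheta_deg, r_max_um=depth, theta_span_deg=fov)
    half_rad = math.radians(fov / 2.0)
    x_half = depth * math.sin(half_rad)
    cart = CartesianGrid(
        dz_um=dz_um, dx_um=dx_um, z_min_um=0.0, z_max_um=depth,
        x_min_um=-x_half, x_max_um=x_half,
    )
    return polar, cart


def polar_to_cartesian(r_um, theta_deg):
    """(r, θ) → (x, z) with θ measured from the depth axis (broadside)."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    r = np.asarray(r_um, dtype=float)
    return r * np.sin(th), r * np.cos(th)


def cartesian_to_polar(x_um, z_um):
    """(x, z) → (r, θ degrees from broadside)."""
    x = np.asarray(x_um, dtype=float)
    z = np.asarray(z_um, dtype=float)
    return np.hypot(x, z), np.rad2deg(np.arctan2(x, z))
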