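"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .geometry import PolarGrid, CartesianGrid


@dataclass
class ImageStack:
    """Time-ordered stack of 2D frames on a tagged coordinate grid.

    ``frames`` has shape (n_frames, n_ax0, n_ax1): (r, theta) on a polar grid
    or (z, x) on a Cartesian grid.  ``frame_rate_hz`` fixes the timestamps
    unless explicit ``timestamps_s`` are given.
    """

    frames: np.ndarray
    grid: Union[PolarGrid, CartesianGrid]
    frame_rate_hz: float
    kind: str = "ceus"  # "ceus" | "bmode"
    coordinate_frame: str = "cartesian"  # "cartesian" | "polar"
    timestamps_s: Optional[np.ndarray] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, ny, nx) array")
        if self.coordinate_frame not in ("cartesian", "polar"):
            raise ValueError("coordinate_frame must be 'cartesian' or 'polar'")
        if self.timestamps_s is None:
            self.timestamps_s = np.arange(self.n_frames) / self.frame_rate_hz
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self):
        return self.frames.shape[1:]


# Semantic aliases used throughout the pipeline.
CEUSStack = ImageStack
BModeStack = ImageStack


@dataclass
class RFFrameSet:
    """Per-channel RF echoes: samples[channel, time, angle, pulse].

    The pulse axis holds the three AM transmits (half_a, full, half_b); the
    angle axis follows the steering sequence order.  ``fs_hz`` is the channel
    sampling rate (4x the transmit frequency by convention).
    """

    samples: np.ndarray  # (n_channels, n_samples, n_angles, n_pulses) per frame list
    fs_hz: float
    t0_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.samples.ndim == 4:
            self.samples = self.samples[None]  # promote single frame
        if self.samples.ndim != 5:
            raise ValueError(
                "samples must be (n_frames, n_channels, n_samples, n_angles, n_pulses)"
            )

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_angles(self) -> int:
        return self.samples.shape[3]

    @property
    def n_pulses(self) -> int:
        return self.samples.shape[4]

    @property
    def t_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples.shape[2]) / self.fs_hz
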