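"""Cardiac-cycle gating and tissue extraction.

Transthoracic acquisitions span several cardiac cycles; only diastole — the
quiescent phase — is usable for localization.  The cycle phase is read from
the adjacent-frame intensity correlation of the B-mode stack: the frame with
the lowest correlation in a cycle marks the start of systole, and the
high-correlation plateau before each systole start is taken as diastole
(clipped to 0.2–0.4 s of data per cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .containers import ImageStack

__all__ = ["CycleIndex", "frame_correlation", "gate_diastole", "tissue_from_svd",
           "select_reference"]


@dataclass
class CycleIndex:
    """Gating result: systole onsets, per-cycle diastole frame lists and the
    adjacent-frame correlation trace (trace[f] correlates frame f with
    frame f-1; trace[0] is 1 by convention)."""

    systole_start_frames: np.ndarray
    diastole_frames: list = field(default_factory=list)
    correlation_trace: np.ndarray = None

    @property
    def n_cycles(self) -> int:
        return len(self.diastole_frames)

    def all_diastole_frames(self) -> np.ndarray:
        if not self.diastole_frames:
            return np.array([], dtype=int)
        return np.concatenate([np.asarray(d, dtype=int) for d in self.diastole_frames])


def frame_correlation(frames: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of each frame with its predecessor."""
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    trace = np.ones(n)
    flat = frames.reshape(n, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(flat, axis=1)
    for f in range(1, n):
        denom = norms[f] * norms[f - 1]
        trace[f] = float(flat[f] @ flat[f - 1] / denom) if denom > 0 else 1.0
    return trace


class GatingError(RuntimeError):
    """No cardiac periodicity detected; carries the correlation trace."""

    def __init__(self, message: str, trace: np.ndarray):
        super().__init__(message)
        self.correlation_trace = trace


def gate_diastole(
    bmode: ImageStack,
    frame_rate_hz: float = None,
    diastole_min_s: float = 0.2,
    diastole_max_s: float = 0.4,
    refractory_fraction: float = 0.4,
    plateau_percentile: float = 75.0,
) -> CycleIndex:
    """Detect systole onsets and select diastolic frames.

    Systole starts are local minima of the adjacent-frame correlation with a
    refractory window of ``refractory_fraction`` x estimated period; the
    diastole of a cycle is the high-correlation plateau (above the cycle's
    ``plateau_percentile`` correlation) immediately preceding the next
    systole start, clipped to the [``diastole_min_s``, ``diastole_max_s``]
    duration bound.
    """
    fr = frame_rate_hz if frame_rate_hz is not None else bmode.frame_rate_hz
    frames = bmode.frames
    trace = frame_correlation(frames)
    dip = trace.max() - trace.min()
    if dip <= 1e-6:
        raise GatingError("no cardiac periodicity detected (flat correlation trace)", trace)
    # first pass: prominent minima; second pass: enforce refractory window
    inv = -trace
    minima, props = find_peaks(inv, prominence=0.3 * dip)
    if len(minima) < 2:
        raise GatingError("no cardiac periodicity detected (fewer than 2 cycles)", trace)
    period = float(np.median(np.diff(minima)))
    minima, _ = find_peaks(inv, prominence=0.3 * dip,
                           distance=max(int(refractory_fraction * period), 1))
    if len(minima) < 2:
        raise GatingError("no cardiac periodicity detected after refractory filtering", trace)

    n_min = max(int(round(diastole_min_s * fr)), 1)
    n_max = max(int(round(diastole_max_s * fr)), n_min)
    diastoles = []
    for k in range(1, len(minima)):
        c0, c1 = minima[k - 1], minima[k]
        cyc = trace[c0:c1]
        thr = np.percentile(cyc, plateau_percentile)
        # contiguous high-correlation block ending just before the systole start
        end = c1
        start = end
        while start - 1 > c0 and trace[start - 1] >= thr:
            start -= 1
        if end - start > n_max:
            start = end - n_max
        if end - start < n_min:
            start = max(c0 + 1, end - n_min)
        diastoles.append(list(range(start, end)))
    return CycleIndex(systole_start_frames=np.asarray(minima),
                      diastole_frames=diastoles, correlation_trace=trace)


def tissue_from_svd(frames: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Rank-truncated space-time SVD reconstruction keeping the largest
    singular values.

    The stack is reshaped to a (space x time) Casorati matrix; the top
    ``ceil(fraction * rank)`` singular components capture the slowly varying
    tissue while transiting bubbles fall in the discarded tail.
    """
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    casorati = frames.reshape(n, -1).T  # (space, time)
    u, s, vt = np.linalg.svd(casorati, full_matrices=False)
    rank = s.size
    k = min(max(int(np.ceil(fraction * rank)), 1), rank)
    rec = (u[:, :k] * s[:k]) @ vt[:k]
    return rec.T.reshape(frames.shape)


def select_reference(frames: np.ndarray) -> int:
    """Index of the frame most similar (structural similarity) to the mean
    frame of the cycle; ties break to the lowest index."""
    from skimage.metrics import structural_similarity

    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] == 1:
        return 0
    mean = frames.mean(axis=0)
    rng = float(max(frames.max() - frames.min(), 1e-12))
    scores = np.array([
        structural_similarity(f, mean, data_range=rng) for f in frames
    ])
    return int(np.argmax(scores))
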