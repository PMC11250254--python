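"""Feature-motion-model microbubble tracking.

Localizations are paired frame-to-frame by a globally optimal assignment
whose cost combines an appearance term with a motion model: the intensity
difference of a candidate pair, normalized by the stronger of the two,
divided by the probability of the pair under a linear constant-velocity
Kalman model (the bivariate Gaussian innovation density).  Candidate pairs
are gated by a maximum-speed search window (150 mm/s by default); dummy
rows/columns let bubbles appear and disappear when every real pairing costs
more than the dummy limit.  Two refinements remove manual tuning: a fuzzy
initialization gives a newly appeared bubble a velocity estimated from its
neighbourhood instead of assuming it static, and the process-noise
covariance is estimated from the data via a nearest-neighbour warm-up pass.
Tracks shorter than four frames are discarded as low-confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .localize import SR_GRID_UM

__all__ = [
    "KalmanTrackState",
    "TrackSet",
    "FeatureMotionModelTracker",
    "pair_frame",
    "fuzzy_init",
    "estimate_process_noise",
    "finalize_tracks",
    "track_localizations",
]

P_FLOOR = 1e-12  # probability floor in the cost ratio
_BIG = 1e18      # forbidden-assignment sentinel


def _transition(dt: float) -> np.ndarray:
    f = np.eye(4)
    f[0, 2] = f[1, 3] = dt
    return f


_H = np.zeros((2, 4))
_H[0, 0] = _H[1, 1] = 1.0


def default_measurement_noise() -> np.ndarray:
    """R from the 13.5 µm localization grid quantization (uniform variance)."""
    return np.eye(2) * (SR_GRID_UM ** 2 / 12.0)


@dataclass
class KalmanTrackState:
    """Constant-velocity state [x µm, z µm, vx µm/s, vz µm/s] with
    covariances; ``history`` collects (frame, x_um, z_um, intensity)."""

    state: np.ndarray
    cov: np.ndarray
    q: np.ndarray
    r: np.ndarray
    intensity: float
    track_id: int
    history: list = field(default_factory=list)

    def predict(self, dt: float):
        """Predicted measurement and innovation covariance after dt."""
        f = _transition(dt)
        x_pred = f @ self.state
        p_pred = f @ self.cov @ f.T + self.q
        s = _H @ p_pred @ _H.T + self.r
        return x_pred, p_pred, s

    def update(self, x_pred, p_pred, meas_um: np.ndarray):
        nu = meas_um - _H @ x_pred
        s = _H @ p_pred @ _H.T + self.r
        k = p_pred @ _H.T @ np.linalg.inv(s)
        self.state = x_pred + k @ nu
        self.cov = (np.eye(4) - k @ _H) @ p_pred


@dataclass
class TrackSet:
    """Finalized tracks: (track_id, frame, x_um, z_um, vx_mm_s, vz_mm_s,
    intensity), frames strictly increasing within a track."""

    data: pd.DataFrame

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique() if len(self.data) else 0

    def track_ids(self):
        return self.data["track_id"].unique()

    def track(self, tid) -> pd.DataFrame:
        return self.data[self.data["track_id"] == tid]

    def save_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "TrackSet":
        return cls(pd.read_csv(path))


def _innovation_density(nu: np.ndarray, s: np.ndarray) -> float:
    det = s[0, 0] * s[1, 1] - s[0, 1] * s[1, 0]
    if det <= 0:
        return 0.0
    inv = np.array([[s[1, 1], -s[0, 1]], [-s[1, 0], s[0, 0]]]) / det
    return math.exp(-0.5 * float(nu @ inv @ nu)) / (2.0 * math.pi * math.sqrt(det))


def pair_frame(
    predictions: list,
    last_positions: np.ndarray,
    last_intensities: np.ndarray,
    localizations: np.ndarray,
    intensities: np.ndarray,
    frame_rate_hz: float,
    max_speed_mm_s: float = 150.0,
    cost_limit: Optional[float] = None,
    nearest_neighbour: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal one-to-one pairing with dummy augmentation.

    ``predictions`` holds (pred_xz_um, innovation_cov) per active track;
    ``last_positions`` the tracks' last measured positions (the search
    window gates on raw displacement from these).  Returns
    (track_assignment, loc_assignment): for each track the paired
    localization index or -1; for each localization the paired track or -1.

    With ``nearest_neighbour`` the cost degenerates to the Euclidean
    distance — the ablation baseline without motion or feature terms.
    """
    n_t = len(predictions)
    n_l = len(localizations)
    if n_t == 0 or n_l == 0:
        return -np.ones(n_t, dtype=int), -np.ones(n_l, dtype=int)
    gate_um = max_speed_mm_s / frame_rate_hz * 1e3

    cost = np.full((n_t, n_l), _BIG)
    mismatches = []
    for i, (pred, s) in enumerate(predictions):
        d = np.hypot(localizations[:, 0] - last_positions[i, 0],
                     localizations[:, 1] - last_positions[i, 1])
        inside = d <= gate_um
        for j in np.nonzero(inside)[0]:
            if nearest_neighbour:
                cost[i, j] = d[j]
                continue
            mis = abs(intensities[j] - last_intensities[i]) / max(
                intensities[j], last_intensities[i], 1e-30)
            p = _innovation_density(localizations[j] - pred, s)
            cost[i, j] = mis / max(p, P_FLOOR)
            mismatches.append(mis)

    if cost_limit is None:
        if nearest_neighbour:
            cost_limit = gate_um
        else:
            med_mis = float(np.median(mismatches)) if mismatches else 0.1
            med_mis = max(med_mis, 1e-3)
            limits = []
            for pred, s in predictions:
                p_edge = _innovation_density(np.array([gate_um, 0.0]), s)
                limits.append(med_mis / max(p_edge, P_FLOOR))
            cost_limit = float(np.median(limits))

    n = n_t + n_l
    big = np.full((n, n), 0.0)
    big[:n_t, :n_l] = cost
    big[:n_t, n_l:] = _BIG
    big[n_t:, :n_l] = _BIG
    big[np.arange(n_t), n_l + np.arange(n_t)] = cost_limit
    big[n_t + np.arange(n_l), np.arange(n_l)] = cost_limit
    rows, cols = linear_sum_assignment(big)
    t_assign = -np.ones(n_t, dtype=int)
    l_assign = -np.ones(n_l, dtype=int)
    for r, c in zip(rows, cols):
        if r < n_t and c < n_l and cost[r, c] < _BIG:
            t_assign[r] = c
            l_assign[c] = r
    return t_assign, l_assign


def fuzzy_init(
    new_loc_um: np.ndarray,
    new_intensity: float,
    prev_locs_um: np.ndarray,
    prev_intensities: np.ndarray,
    frame_rate_hz: float,
    max_speed_mm_s: float = 150.0,
    intensity_sigma: float = 0.3,
) -> np.ndarray:
    """Initial velocity (µm/s) of a newly appeared bubble.

    Every previous-frame localization inside the search window implies a
    candidate velocity; the result is their membership-weighted average,
    memberships decaying with displacement (Gaussian, sigma = half the
    window) and intensity mismatch.  No in-window neighbour -> zero.
    """
    if len(prev_locs_um) == 0:
        return np.zeros(2)
    gate_um = max_speed_mm_s / frame_rate_hz * 1e3
    d = np.hypot(prev_locs_um[:, 0] - new_loc_um[0],
                 prev_locs_um[:, 1] - new_loc_um[1])
    inside = d <= gate_um
    if not inside.any():
        return np.zeros(2)
    dl = prev_locs_um[inside]
    di = prev_intensities[inside]
    vels = (new_loc_um[None, :] - dl) * frame_rate_hz  # µm/s
    mis = np.abs(di - new_intensity) / np.maximum.reduce(
        [di, np.full_like(di, new_intensity), np.full_like(di, 1e-30)])
    w = np.exp(-0.5 * (d[inside] / (gate_um / 2.0)) ** 2) \
        * np.exp(-0.5 * (mis / intensity_sigma) ** 2)
    w_sum = w.sum()
    if w_sum <= 0:
        return np.zeros(2)
    return (w[:, None] * vels).sum(axis=0) / w_sum


DEFAULT_SIGMA_V_MM_S = 5.0  # default per-frame velocity-increment scale


def estimate_process_noise(
    provisional_tracks: list,
    frame_rate_hz: float,
    min_steps: int = 10,
) -> np.ndarray:
    """Q (4x4) from the empirical covariance of frame-to-frame velocity
    increments of warm-up tracks.

    ``provisional_tracks`` is a list of (n_i, 2) position arrays (µm) at
    consecutive frames.  Velocities are finite differences x frame rate;
    their increments estimate the white-acceleration noise.  With fewer
    than ``min_steps`` usable increments a documented default is returned.
    """
    incs = []
    for pos in provisional_tracks:
        pos = np.asarray(pos, dtype=float)
        if pos.shape[0] < 3:
            continue
        v = np.diff(pos, axis=0) * frame_rate_hz
        incs.append(np.diff(v, axis=0))
    q = np.zeros((4, 4))
    if incs:
        inc = np.vstack(incs)
    else:
        inc = np.empty((0, 2))
    if inc.shape[0] >= min_steps:
        qv = np.cov(inc.T) if inc.shape[0] > 1 else np.eye(2) * (inc ** 2).mean()
        qv = np.atleast_2d(qv)
    else:
        qv = np.eye(2) * (DEFAULT_SIGMA_V_MM_S * 1e3) ** 2
    dt = 1.0 / frame_rate_hz
    q[2:, 2:] = qv
    q[:2, :2] = qv * dt ** 2  # position noise induced by the velocity noise
    return q


class FeatureMotionModelTracker:
    """Frame-sequential tracker over a localization table.

    Parameters
    ----------
    frame_rate_hz : compounded frame rate.
    max_speed_mm_s : search-window speed limit (150 mm/s default).
    min_frames : minimum track length kept (4).
    mode : "fmm" (feature + Kalman motion model) or "nn" (nearest-neighbour
        baseline for ablations).
    q, r : process/measurement noise; ``q=None`` triggers the automatic
        warm-up estimation.
    """

    def __init__(self, frame_rate_hz: float, max_speed_mm_s: float = 150.0,
                 min_frames: int = 4, mode: str = "fmm",
                 q: Optional[np.ndarray] = None, r: Optional[np.ndarray] = None,
                 cost_limit: Optional[float] = None, warmup_frames: int = 20):
        if mode not in ("fmm", "nn"):
            raise ValueError("mode must be 'fmm' or 'nn'")
        self.frame_rate_hz = frame_rate_hz
        self.max_speed_mm_s = max_speed_mm_s
        self.min_frames = min_frames
        self.mode = mode
        self.q = q
        self.r = r if r is not None else default_measurement_noise()
        self.cost_limit = cost_limit
        self.warmup_frames = warmup_frames

    # -- internal ----------------------------------------------------------
    def _warmup_q(self, frames: dict) -> np.ndarray:
        """Nearest-neighbour warm-up pass to seed the process noise."""
        keys = sorted(frames)[: self.warmup_frames]
        gate = self.max_speed_mm_s / self.frame_rate_hz * 1e3
        chains: list = []
        open_chains: dict = {}
        prev = None
        for f in keys:
            locs = frames[f][0]
            if prev is None or len(open_chains) == 0 or len(locs) == 0:
                new_open = {}
                for j in range(len(locs)):
                    new_open[j] = [locs[j]]
                if prev is not None:
                    chains.extend(open_chains.values())
                open_chains = new_open
                prev = locs
                continue
            preds = [(open_chains[i][-1], np.eye(2)) for i in open_chains]
            idx = list(open_chains)
            last_pos = np.array([open_chains[i][-1] for i in idx])
            t_assign, l_assign = pair_frame(
                preds, last_pos, np.ones(len(idx)), locs, np.ones(len(locs)),
                self.frame_rate_hz, self.max_speed_mm_s,
                nearest_neighbour=True)
            new_open = {}
            for k, i in enumerate(idx):
                j = t_assign[k]
                if j >= 0:
                    new_open[j] = open_chains[i] + [locs[j]]
                else:
                    chains.append(open_chains[i])
            for j in range(len(locs)):
                if j not in new_open:
                    new_open[j] = [locs[j]]
            open_chains = new_open
            prev = locs
        chains.extend(open_chains.values())
        return estimate_process_noise(chains, self.frame_rate_hz)

    # -- public ------------------------------------------------------------
    def track(self, localizations: pd.DataFrame) -> TrackSet:
        """Pair localizations across frames and return finalized tracks."""
        req = {"frame", "x_um", "z_um", "intensity"}
        if not req.issubset(localizations.columns):
            raise ValueError(f"localization table must have columns {sorted(req)}")
        frames: dict = {}
        for f, sub in localizations.groupby("frame"):
            frames[int(f)] = (sub[["x_um", "z_um"]].to_numpy(dtype=float),
                              sub["intensity"].to_numpy(dtype=float))
        if not frames:
            return finalize_tracks([], self.frame_rate_hz, self.min_frames)

        q = self.q
        if q is None and self.mode == "fmm":
            q = self._warmup_q(frames)
        elif q is None:
            q = estimate_process_noise([], self.frame_rate_hz)

        dt = 1.0 / self.frame_rate_hz
        active: list = []
        done: list = []
        next_id = 0
        prev_locs = np.empty((0, 2))
        prev_ints = np.empty(0)
        all_frames = sorted(frames)
        prev_frame = None
        for f in all_frames:
            locs, ints = frames[f]
            if prev_frame is not None and f != prev_frame + 1:
                done.extend(active)  # no gap linking: a missed frame ends tracks
                active = []
                prev_locs = np.empty((0, 2))
                prev_ints = np.empty(0)
            preds = []
            pred_states = []
            for tr in active:
                x_pred, p_pred, s = tr.predict(dt)
                preds.append((x_pred[:2], s))
                pred_states.append((x_pred, p_pred))
            last_pos = np.array([tr.history[-1][1:3] for tr in active]) \
                if active else np.empty((0, 2))
            last_int = np.array([tr.intensity for tr in active])
            t_assign, l_assign = pair_frame(
                preds, last_pos, last_int, locs, ints, self.frame_rate_hz,
                self.max_speed_mm_s, cost_limit=self.cost_limit,
                nearest_neighbour=(self.mode == "nn"))
            survivors = []
            for i, tr in enumerate(active):
                j = t_assign[i]
                if j >= 0:
                    tr.update(*pred_states[i], locs[j])
                    tr.intensity = float(ints[j])
                    tr.history.append((f, float(locs[j][0]), float(locs[j][1]),
                                       float(ints[j])))
                    survivors.append(tr)
                else:
                    done.append(tr)
            for j in range(len(locs)):
                if l_assign[j] < 0:
                    v0 = fuzzy_init(locs[j], float(ints[j]), prev_locs, prev_ints,
                                    self.frame_rate_hz, self.max_speed_mm_s) \
                        if self.mode == "fmm" else np.zeros(2)
                    state = np.array([locs[j][0], locs[j][1], v0[0], v0[1]])
                    cov = np.eye(4)
                    cov[:2, :2] = self.r * 4.0
                    gate_v = self.max_speed_mm_s * 1e3
                    cov[2:, 2:] = np.eye(2) * (gate_v / 2.0) ** 2
                    tr = KalmanTrackState(state=state, cov=cov, q=q, r=self.r,
                                          intensity=float(ints[j]),
                                          track_id=next_id,
                                          history=[(f, float(locs[j][0]),
                                                    float(locs[j][1]),
                                                    float(ints[j]))])
                    next_id += 1
                    survivors.append(tr)
            active = survivors
            prev_locs, prev_ints = locs, ints
            prev_frame = f
        done.extend(active)
        return finalize_tracks([tr.history for tr in done], self.frame_rate_hz,
                               self.min_frames)


def finalize_tracks(histories: list, frame_rate_hz: float,
                    min_frames: int = 4) -> TrackSet:
    """Drop tracks observed in fewer than ``min_frames`` frames and compute
    per-step velocities (forward displacement x frame rate, mm/s; the last
    sample repeats the previous step)."""
    rows = []
    tid = 0
    for hist in histories:
        if len(hist) < min_frames:
            continue
        hist = sorted(hist)
        arr = np.array([[h[1], h[2]] for h in hist])
        v = np.diff(arr, axis=0) * frame_rate_hz * 1e-3
        if len(v):
            v = np.vstack([v, v[-1]])
        else:
            v = np.zeros((1, 2))
        for k, (f, x, z, inten) in enumerate(hist):
            rows.append((tid, f, x, z, v[k, 0], v[k, 1], inten))
        tid += 1
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "z_um",
                                     "vx_mm_s", "vz_mm_s", "intensity"])
    return TrackSet(df)


def track_localizations(localizations: pd.DataFrame, frame_rate_hz: float,
                        **kwargs) -> TrackSet:
    """Convenience wrapper: build a tracker and run it."""
    return FeatureMotionModelTracker(frame_rate_hz, **kwargs).track(localizations)
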