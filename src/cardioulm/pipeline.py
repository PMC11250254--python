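"""End-to-end orchestration: simulate -> (beamform) -> gate/moco ->
localize -> track -> maps -> quantify, with explicit seeds and a run
manifest sufficient to reproduce a run."""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import AcquisitionGeometry, CartesianGrid
from .containers import ImageStack
from .simulate import (MotionModel, PSFModel, apply_tissue_motion,
                       make_vessel_phantom, render_ceus_stack, simulate_transit)
from .gating import GatingError, gate_diastole, select_reference, tissue_from_svd
from .registration import (intercycle_rigid, log_compress, register_stack,
                           warp_points, warp_stack)
from .localize import build_psf_bank, localize_stack
from .tracking import FeatureMotionModelTracker, TrackSet
from .maps import SRGrid, default_fwhm_um, render_maps
from .quantify import frc_resolution, speed_stats, vessel_diameters
from .io import save_stack, save_map_bundle

__all__ = ["PipelineConfig", "RunManifest", "default_config", "simulate_stage",
           "ulm_stage", "run"]

_SECTIONS = {"geometry", "simulation", "processing", "output"}
_SIM_KEYS = {"phantom", "duration_s", "bubble_rate_per_s", "snr_db", "motion",
             "seed", "region_um", "dz_um", "dx_um", "frame_rate_hz"}
_PROC_KEYS = {"no_gating", "bspline_spacing_px", "thin_plate_weight",
              "max_speed_mm_s", "min_track_frames", "ncc_threshold",
              "render_fwhm_um", "psf_regions"}


@dataclass
class PipelineConfig:
    geometry: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    processing: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _SECTIONS
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        if "geometry" not in d:
            raise ValueError("config must contain a geometry section")
        for key, allowed in (("simulation", _SIM_KEYS), ("processing", _PROC_KEYS)):
            bad = set(d.get(key, {})) - allowed
            if bad:
                raise ValueError(f"unknown keys in {key} section: {sorted(bad)}")
        return cls(**{k: d.get(k, {}) for k in _SECTIONS})

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {"geometry": self.geometry, "simulation": self.simulation,
                "processing": self.processing, "output": self.output}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        ).hexdigest()[:16]


def default_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale default: a branching phantom in a 20 x 30 mm window at the
    native compounded frame rate, two cardiac cycles of data."""
    return PipelineConfig.from_dict({
        "geometry": AcquisitionGeometry().to_dict(),
        "simulation": {
            "phantom": {"family": "branching", "root_um": [0.0, 32e3],
                        "trunk_length_um": 8e3, "trunk_diameter_um": 400.0,
                        "mean_speed_mm_s": 30.0, "levels": 2},
            "duration_s": 2.0,
            "bubble_rate_per_s": 30.0,
            "snr_db": 30.0,
            "motion": {"period_s": 1.0, "peak_um": 1500.0},
            "region_um": [-12e3, 12e3, 25e3, 55e3],
            "seed": seed,
        },
        "processing": {"no_gating": False},
        "output": {},
    })


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seeds: dict
    stages: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def save(self, path) -> None:
        payload = {"config_hash": self.config_hash, "version": self.version,
                   "seeds": self.seeds, "stages": self.stages,
                   "timings_s": self.timings_s}
        tmp = str(path) + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
        os.replace(tmp, path)  # atomic manifest write


def simulate_stage(config: PipelineConfig):
    """Phantom + transit + tissue motion + rendering; returns
    (ceus, bmode, ground_truth, grid)."""
    geom = AcquisitionGeometry.from_dict(config.geometry)
    sim = config.simulation
    seed = int(sim.get("seed", 0))
    x0, x1, z0, z1 = sim.get("region_um", [-12e3, 12e3, 25e3, 55e3])
    grid = CartesianGrid(dz_um=sim.get("dz_um", 67.8), dx_um=sim.get("dx_um", 135.0),
                         z_min_um=z0, z_max_um=z1, x_min_um=x0, x_max_um=x1)
    tree = make_vessel_phantom(sim.get("phantom", {}), seed=seed)
    fr = sim.get("frame_rate_hz", geom.frame_rate_hz)
    gt = simulate_transit(tree, sim.get("duration_s", 2.0), fr,
                          sim.get("bubble_rate_per_s", 30.0), seed=seed)
    motion_cfg = sim.get("motion")
    if motion_cfg:
        mm = MotionModel(period_s=motion_cfg.get("period_s", 1.0),
                         translation_um=(300.0, 600.0), rotation_deg=1.0,
                         scale=1.01, nonrigid_amplitude_um=200.0,
                         center_um=((x0 + x1) / 2, (z0 + z1) / 2))
        peak = motion_cfg.get("peak_um")
        if peak:
            zz, xx = np.meshgrid(grid.z_um[::8], grid.x_um[::8], indexing="ij")
            mm = mm.scaled_to_peak(peak, xx.ravel(), zz.ravel())
        gt = apply_tissue_motion(gt, mm)
    psf = PSFModel.for_frequency(geom.f_tx_mhz, geom.sound_speed_m_s)
    ceus, bmode = render_ceus_stack(gt, psf, grid, snr_db=sim.get("snr_db", 30.0),
                                    seed=seed + 1)
    return ceus, bmode, gt, grid


def ulm_stage(
    ceus: ImageStack,
    bmode: ImageStack,
    no_gating: bool = False,
    bspline_spacing_px: float = 32.0,
    thin_plate_weight: float = 0.01,
    max_speed_mm_s: float = 150.0,
    min_track_frames: int = 4,
    ncc_threshold: float = 0.5,
    motion_correct: bool = True,
) -> tuple[TrackSet, pd.DataFrame]:
    """Gating, two-level motion correction, localization and tracking.

    With ``no_gating`` (the ex vivo pathway) the whole stack is one cycle
    and the inter-cycle rigid stage is skipped.
    """
    fr = ceus.frame_rate_hz
    if no_gating:
        cycles = [list(range(ceus.n_frames))]
    else:
        idx = gate_diastole(bmode)
        cycles = [c for c in idx.diastole_frames if len(c) >= 2]
        if not cycles:
            raise GatingError("gating produced no usable diastole frames",
                              idx.correlation_trace)

    corrected_cycles = []
    cycle_means = []
    for frames_idx in cycles:
        b = bmode.frames[frames_idx].astype(float)
        c = ceus.frames[frames_idx].astype(float)
        if motion_correct and len(frames_idx) >= 2:
            tissue = tissue_from_svd(b, fraction=0.05)
            grey = np.stack([log_compress(f) for f in tissue])
            ref = select_reference(grey)
            transforms = register_stack(grey, ref, spacing=bspline_spacing_px,
                                        lam=thin_plate_weight)
            c = warp_stack(c, transforms)
        corrected_cycles.append((frames_idx, c))
        cycle_means.append(c.mean(axis=0))

    if not no_gating and len(cycle_means) >= 2 and motion_correct:
        rigids = intercycle_rigid(np.stack(cycle_means))
        corrected_cycles = [
            (fi, warp_stack(c, [rigids[k]] * c.shape[0]))
            for k, (fi, c) in enumerate(corrected_cycles)
        ]

    all_frames_idx = []
    all_frames = []
    for fi, c in corrected_cycles:
        all_frames_idx.extend(fi)
        all_frames.append(c)
    corr_stack = ImageStack(np.concatenate(all_frames).astype(np.float32),
                            ceus.grid, fr, kind="ceus",
                            coordinate_frame=ceus.coordinate_frame)
    locs = localize_stack(corr_stack, ncc_threshold=ncc_threshold)
    # restore original frame indices so time gaps between cycles break tracks
    locs["frame"] = locs["frame"].map(dict(enumerate(all_frames_idx)))
    tracker = FeatureMotionModelTracker(fr, max_speed_mm_s=max_speed_mm_s,
                                        min_frames=min_track_frames)
    tracks = tracker.track(locs)
    return tracks, locs


def run(config: PipelineConfig, out_dir, no_gating: Optional[bool] = None) -> RunManifest:
    """Execute every stage and write all artifacts under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    geom = AcquisitionGeometry.from_dict(config.geometry)
    proc = config.processing
    if no_gating is None:
        no_gating = bool(proc.get("no_gating", False))
    manifest = RunManifest(config_hash=config.hash(), version=__version__,
                           seeds={"simulation": int(config.simulation.get("seed", 0))})
    config.save(os.path.join(out_dir, "config.yaml"))

    t0 = time.time()
    ceus, bmode, gt, grid = simulate_stage(config)
    save_stack(ceus, os.path.join(out_dir, "ceus.tif"))
    save_stack(bmode, os.path.join(out_dir, "bmode.tif"))
    gt.save_csv(os.path.join(out_dir, "ground_truth.csv"))
    manifest.stages["simulate"] = ["ceus.tif", "bmode.tif", "ground_truth.csv"]
    manifest.timings_s["simulate"] = round(time.time() - t0, 3)

    t0 = time.time()
    tracks, locs = ulm_stage(
        ceus, bmode, no_gating=no_gating,
        bspline_spacing_px=proc.get("bspline_spacing_px", 32.0),
        thin_plate_weight=proc.get("thin_plate_weight", 0.01),
        max_speed_mm_s=proc.get("max_speed_mm_s", 150.0),
        min_track_frames=proc.get("min_track_frames", 4),
        ncc_threshold=proc.get("ncc_threshold", 0.5),
    )
    locs.to_csv(os.path.join(out_dir, "localizations.csv"), index=False)
    tracks.save_csv(os.path.join(out_dir, "tracks.csv"))
    manifest.stages["ulm"] = ["localizations.csv", "tracks.csv"]
    manifest.timings_s["ulm"] = round(time.time() - t0, 3)

    t0 = time.time()
    fwhm = proc.get("render_fwhm_um", default_fwhm_um(geom.f_tx_mhz,
                                                      geom.sound_speed_m_s))
    bundle = render_maps(tracks, fwhm_um=fwhm)
    save_map_bundle(bundle, os.path.join(out_dir, "maps"))
    manifest.stages["maps"] = ["maps/density.tif", "maps/speed.tif",
                               "maps/direction.tif"]
    manifest.timings_s["maps"] = round(time.time() - t0, 3)

    t0 = time.time()
    stats_rows = []
    vs = vessel_diameters(bundle.density, pitch_um=bundle.grid.pitch_um)
    if vs.diameters_um is not None and vs.diameters_um.size:
        for lo, p in zip(vs.diameter_bin_edges_um[:-1], vs.diameter_proportions):
            stats_rows.append(("diameter_um", lo, p))
    ss = speed_stats(bundle.speed)
    if ss.speed_proportions is not None and ss.speed_proportions.size:
        for lo, p in zip(ss.speed_bin_edges_mm_s[:-1], ss.speed_proportions):
            stats_rows.append(("speed_mm_s", lo, p))
        stats_rows.append(("lognormal_mu", 0.0, ss.lognormal_mu))
        stats_rows.append(("lognormal_sigma", 0.0, ss.lognormal_sigma))
    if tracks.n_tracks >= 2:
        frc = frc_resolution(tracks, seed=int(config.simulation.get("seed", 0)))
        stats_rows.append(("frc_resolution_um", 0.0, frc.resolution_um))
    pd.DataFrame(stats_rows, columns=["metric", "bin", "value"]).to_csv(
        os.path.join(out_dir, "stats.csv"), index=False)
    manifest.stages["quantify"] = ["stats.csv"]
    manifest.timings_s["quantify"] = round(time.time() - t0, 3)

    manifest.save(os.path.join(out_dir, "manifest.json"))
    return manifest
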