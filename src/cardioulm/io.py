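"""Standard-format I/O: multi-frame TIFF stacks with YAML sidecars, CSV
tables for localizations/tracks/statistics."""

from __future__ import annotations

import os

import numpy as np
import tifffile
import yaml

from .geometry import PolarGrid, CartesianGrid
from .containers import ImageStack
from .maps import SRGrid, SRMapBundle

__all__ = ["save_stack", "load_stack", "save_map_bundle", "load_map_bundle",
           "sidecar_path"]


def sidecar_path(path) -> str:
    return str(path) + ".yaml"


_GRID_CLASSES = {"PolarGrid": PolarGrid, "CartesianGrid": CartesianGrid}


def save_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-frame TIFF plus a metadata sidecar."""
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32),
                     photometric="minisblack")
    meta = {
        "kind": stack.kind,
        "coordinate_frame": stack.coordinate_frame,
        "frame_rate_hz": float(stack.frame_rate_hz),
        "grid_class": type(stack.grid).__name__,
        "grid": stack.grid.to_dict(),
    }
    with open(sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_stack(path) -> ImageStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    try:
        with open(sidecar_path(path)) as fh:
            meta = yaml.safe_load(fh)
        grid = _GRID_CLASSES[meta["grid_class"]].from_dict(meta["grid"])
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise ValueError(f"corrupted or missing sidecar for {path}: {exc}") from exc
    return ImageStack(frames, grid, meta["frame_rate_hz"], kind=meta["kind"],
                      coordinate_frame=meta["coordinate_frame"])


def save_map_bundle(bundle: SRMapBundle, directory) -> None:
    """Write density/speed/direction maps as 32-bit TIFFs + one sidecar."""
    os.makedirs(directory, exist_ok=True)
    tifffile.imwrite(os.path.join(directory, "density.tif"),
                     bundle.density.astype(np.float32), photometric="minisblack")
    if bundle.speed is not None:
        tifffile.imwrite(os.path.join(directory, "speed.tif"),
                         bundle.speed.astype(np.float32), photometric="minisblack")
    if bundle.direction_deg is not None:
        tifffile.imwrite(os.path.join(directory, "direction.tif"),
                         bundle.direction_deg.astype(np.float32), photometric="minisblack")
        tifffile.imwrite(os.path.join(directory, "direction_valid.tif"),
                         bundle.direction_valid.astype(np.uint8), photometric="minisblack")
    meta = {
        "grid": {"x0_um": float(bundle.grid.x0_um), "z0_um": float(bundle.grid.z0_um),
                 "nx": int(bundle.grid.nx), "nz": int(bundle.grid.nz),
                 "pitch_um": float(bundle.grid.pitch_um)},
        "fwhm_um": None if bundle.fwhm_um is None else float(bundle.fwhm_um),
        "params": {k: (float(v) if isinstance(v, (int, float)) else v)
                   for k, v in bundle.params.items()},
    }
    with open(os.path.join(directory, "maps.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_map_bundle(directory) -> SRMapBundle:
    with open(os.path.join(directory, "maps.yaml")) as fh:
        meta = yaml.safe_load(fh)
    grid = SRGrid(**meta["grid"])
    density = tifffile.imread(os.path.join(directory, "density.tif"))
    speed = direction = valid = None
    sp = os.path.join(directory, "speed.tif")
    if os.path.exists(sp):
        speed = tifffile.imread(sp)
    dp = os.path.join(directory, "direction.tif")
    if os.path.exists(dp):
        direction = tifffile.imread(dp)
        valid = tifffile.imread(os.path.join(directory, "direction_valid.tif")).astype(bool)
    return SRMapBundle(grid=grid, density=density, speed=speed,
                       direction_deg=direction, direction_valid=valid,
                       fwhm_um=meta.get("fwhm_um"), params=meta.get("params") or {})
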