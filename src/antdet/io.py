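"""Readers and writers for frames, masks, label maps, centers and configs.

Conventions shared by every module and the CLI:

* Frames are zero-padded PNGs (``frame_000000.png`` ...) in a directory,
  8-bit grayscale; intensities map to floats in [0, 1]. A video file
  readable by imageio is accepted as input too.
* Center CSVs have the header ``frame,x,y`` with 0-based coordinates,
  x = column, y = row, origin at the top-left.
* Label maps are single-channel PNGs with literal pixel values {0, 1, 2}
  for bit-exact round trips; ``viewable=True`` writes a scaled
  {0, 128, 255} variant instead. Foreground masks are {0, 255} PNGs.
* Every pipeline run writes a JSON manifest (config echo, seed, package
  version) into its output directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_frames", "read_frames",
    "write_centers_csv", "read_centers_csv",
    "write_labelmaps", "read_labelmaps",
    "write_masks", "read_masks",
    "load_config", "write_manifest",
]


def write_frames(directory, frames) -> list[Path]:
    """Quantize float frames in [0, 1] to 8-bit PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(np.asarray(frames)):
        img = np.clip(np.round(frame * 255.0), 0, 255).astype(np.uint8)
        path = directory / f"frame_{i:06d}.png"
        iio.imwrite(path, img)
        paths.append(path)
    return paths


def read_frames(path) -> np.ndarray:
    """Read a frame directory (sorted PNGs) or a video file.

    Returns (N, H, W) float in [0, 1]; color inputs are kept as
    (N, H, W, 3).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames found in {path}")
        frames = np.stack([iio.imread(f) for f in files])
    elif path.exists():
        frames = np.asarray(iio.imread(path))
        if frames.ndim == 2:
            frames = frames[None]
    else:
        raise FileNotFoundError(f"frame source does not exist: {path}")
    return frames.astype(np.float64) / 255.0


def write_centers_csv(path, centers_per_frame) -> Path:
    """Write per-frame (x, y) centers as ``frame,x,y`` rows.

    Deterministic byte output: fixed column order, ``%.4f`` coordinates.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for t, centers in enumerate(centers_per_frame):
        for x, y in np.asarray(centers, dtype=float).reshape(-1, 2):
            rows.append((t, x, y))
    df = pd.DataFrame(rows, columns=["frame", "x", "y"])
    df.to_csv(path, index=False, float_format="%.4f", lineterminator="\n")
    return path


def read_centers_csv(path, n_frames: int | None = None) -> list[np.ndarray]:
    """Read a centers CSV back into a per-frame list of (n, 2) arrays."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"centers CSV does not exist: {path}")
    try:
        df = pd.read_csv(path)
        frames = df["frame"].to_numpy(dtype=int)
        xy = df[["x", "y"]].to_numpy(dtype=float)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed centers CSV {path}: {exc}") from exc
    last = int(frames.max()) + 1 if len(frames) else 0
    n_frames = last if n_frames is None else n_frames
    out = [np.zeros((0, 2)) for _ in range(n_frames)]
    for t in range(n_frames):
        sel = frames == t
        if sel.any():
            out[t] = xy[sel]
    return out


def write_labelmaps(directory, labelmaps, viewable: bool = False) -> list[Path]:
    """Write dense class maps as single-channel PNGs.

    Literal {0, 1, 2} pixel values by default; ``viewable=True`` scales to
    {0, 128, 255} for inspection (not round-trippable).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, lm in enumerate(np.asarray(labelmaps)):
        img = np.asarray(lm, dtype=np.uint8)
        if viewable:
            img = (img.astype(np.int32) * 128).clip(0, 255).astype(np.uint8)
        path = directory / f"label_{i:06d}.png"
        iio.imwrite(path, img)
        paths.append(path)
    return paths


def read_labelmaps(directory) -> np.ndarray:
    directory = Path(directory)
    files = sorted(directory.glob("label_*.png"))
    if not files:
        raise FileNotFoundError(f"no label maps found in {directory}")
    maps = np.stack([iio.imread(f) for f in files])
    if maps.max() > 2:
        raise ValueError(
            f"label PNGs in {directory} contain values > 2; were they "
            "written with viewable=True?")
    return maps.astype(np.uint8)


def write_masks(directory, masks) -> list[Path]:
    """Write binary foreground masks as {0, 255} PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, mask in enumerate(np.asarray(masks, dtype=bool)):
        path = directory / f"mask_{i:06d}.png"
        iio.imwrite(path, (mask * np.uint8(255)))
        paths.append(path)
    return paths


def read_masks(directory) -> np.ndarray:
    directory = Path(directory)
    files = sorted(directory.glob("mask_*.png"))
    if not files:
        raise FileNotFoundError(f"no masks found in {directory}")
    return np.stack([iio.imread(f) for f in files]) > 127


def load_config(path) -> dict:
    """Load a YAML pipeline config into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file does not exist: {path}")
    with open(path) as fh:
        try:
            cfg = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_manifest(directory, config: dict, seed: int, extra: dict | None = None
                   ) -> Path:
    """Echo the effective config + seed + version for reproducibility."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seed": seed,
        "antdet_version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = directory / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
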