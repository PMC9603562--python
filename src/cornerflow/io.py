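"""Readers/writers for the plain-text and image formats the pipeline uses."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidInputError
from .tracking import TipTrajectory
from .younglaplace import DropProfile


def write_profile_csv(profile: DropProfile, path) -> None:
    """2-column CSV (x_m, z_m) with a one-line header."""
    pd.DataFrame({"x_m": profile.x, "z_m": profile.z}).to_csv(path, index=False)


def read_profile_csv(path, orientation: str = "pendant") -> DropProfile:
    df = pd.read_csv(path)
    if not {"x_m", "z_m"} <= set(df.columns):
        raise InvalidInputError("profile CSV must have columns x_m, z_m")
    return DropProfile(df["x_m"].to_numpy(), df["z_m"].to_numpy(),
                       orientation=orientation)


def write_json(record: dict, path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


def read_grayscale_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:  # collapse RGB(A)
        img = img[..., :3].mean(axis=-1)
    return np.asarray(img, dtype=float)


def write_grayscale_png(pixels: np.ndarray, path) -> None:
    arr = np.clip(pixels, 0.0, 1.0)
    iio.imwrite(path, (arr * 255).round().astype(np.uint8))


def read_stack(path) -> np.ndarray:
    """Multi-page TIFF, or a directory of images in lexicographic order."""
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir()
                       if f.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise InvalidInputError(f"no image frames in {p}")
        return np.stack([read_grayscale_image(f) for f in files])
    arr = np.asarray(tifffile.imread(p), dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack_tiff(stack: np.ndarray, path) -> None:
    arr = np.clip(stack, 0.0, 1.0)
    tifffile.imwrite(path, (arr * 255).round().astype(np.uint8))


def write_stack_pngs(stack: np.ndarray, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack):
        write_grayscale_png(frame, d / f"frame_{i:05d}.png")


def write_trajectory_csv(traj: TipTrajectory, path) -> None:
    pd.DataFrame({"t_h": traj.times_h,
                  "Hc_mm": traj.heights_m * 1e3}).to_csv(path, index=False)


def read_trajectory_csv(path, frame_interval_min: float = 2.0) -> TipTrajectory:
    df = pd.read_csv(path)
    if not {"t_h", "Hc_mm"} <= set(df.columns):
        raise InvalidInputError("trajectory CSV must have columns t_h, Hc_mm")
    return TipTrajectory(df["t_h"].to_numpy(), df["Hc_mm"].to_numpy() * 1e-3,
                         frame_interval_min=frame_interval_min)
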