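"""File formats and round-trips for the pipeline.

Images are 8-bit RGB PNG/TIFF; masks are single-channel 0/255 PNG; perfusion
frames are multi-page float32 TIFF with a ``calibration.csv`` sidecar; tables
are comma-separated UTF-8 with one leading ``#`` provenance line.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .perfusion import PerfusionMap

__all__ = [
    "FormatError",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_frames",
    "write_frames",
    "read_table",
    "write_table",
    "write_overlay",
    "save_synthetic_sample",
]

OVERLAY_RGB = (128, 0, 160)  # purple
OVERLAY_ALPHA = 0.5


class FormatError(ValueError):
    """A file exists but is not in the declared format."""


def read_image(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit image, got {arr.dtype}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected RGB image, got shape {arr.shape}")
    return arr


def write_image(path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise FormatError("images are written as 8-bit; cast explicitly first")
    iio.imwrite(path, image)


def read_mask(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    vals = np.unique(arr)
    if not np.isin(vals, (0, 255)).all():
        raise FormatError(
            f"{path}: mask must contain only 0/255, found values {vals[:8]}"
        )
    return arr == 255


def write_mask(path, mask: np.ndarray) -> None:
    mask = np.asarray(mask)
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.isin(vals, (0, 1)).all():
            raise FormatError("mask must be boolean or 0/1")
        mask = mask.astype(bool)
    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def write_frames(path, frames: list[PerfusionMap]) -> None:
    """Multi-page float32 TIFF plus ``calibration.csv`` next to it."""
    path = Path(path)
    stack = np.stack([f.values.astype(np.float32) for f in frames])
    tifffile.imwrite(path, stack, photometric="minisblack")
    calib = pd.DataFrame({"pixel_pitch_mm": [frames[0].pixel_pitch_mm]})
    calib.to_csv(path.with_name("calibration.csv"), index=False)


def read_frames(path, pixel_pitch_mm: float | None = None) -> list[PerfusionMap]:
    """Read a multi-page TIFF (or directory of TIFFs) into perfusion maps.

    Calibration is taken from ``calibration.csv`` beside the file unless
    given explicitly.
    """
    path = Path(path)
    if pixel_pitch_mm is None:
        calib_path = (path if path.is_dir() else path.parent) / "calibration.csv"
        if not calib_path.exists():
            raise FormatError(f"no calibration.csv next to {path}")
        pixel_pitch_mm = float(pd.read_csv(calib_path)["pixel_pitch_mm"].iloc[0])
    if path.is_dir():
        pages = [tifffile.imread(p) for p in sorted(path.glob("*.tif*"))]
        stack = np.stack(pages)
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
    if stack.dtype != np.float32:
        raise FormatError(f"{path}: perfusion frames must be float32")
    return [PerfusionMap(values=f, pixel_pitch_mm=pixel_pitch_mm) for f in stack]


def write_table(path, df: pd.DataFrame, provenance: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write("# " + json.dumps(provenance, sort_keys=True, default=str) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_overlay(path, image: np.ndarray, mask: np.ndarray) -> None:
    """Predicted vessels tinted purple at 50% alpha over the input image."""
    img = np.asarray(image, dtype=np.float64)
    m = np.asarray(mask).astype(bool)
    tint = np.asarray(OVERLAY_RGB, dtype=np.float64)
    out = img.copy()
    out[m] = (1 - OVERLAY_ALPHA) * img[m] + OVERLAY_ALPHA * tint
    write_image(path, np.clip(np.round(out), 0, 255).astype(np.uint8))


def save_synthetic_sample(out_dir, sample_id: str, sample) -> None:
    """Write image, mask, truth row and tree sidecar for one sample."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_image(out_dir / f"{sample_id}.png", sample.image)
    write_mask(out_dir / f"{sample_id}_mask.png", sample.truth_mask)
    row = {"sample_id": sample_id, **sample.truth_morphometrics.as_dict(),
           "seed": sample.seed}
    truth_path = out_dir / "truth.csv"
    df = pd.DataFrame([row])
    if truth_path.exists():
        old = read_table(truth_path)
        df = pd.concat([old, df], ignore_index=True)
    write_table(truth_path, df, provenance={"writer": "camquant.simulate"})
    tree_json = {
        "canvas_size": list(sample.tree.canvas_size),
        "segments": [
            {
                "points": seg.points.tolist(),
                "radii": seg.radii.tolist(),
                "parent": seg.parent,
                "parent_vertex": seg.parent_vertex,
                "deep": bool(seg.deep),
            }
            for seg in sample.tree.segments
        ],
    }
    (out_dir / f"{sample_id}_tree.json").write_text(json.dumps(tree_json))
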