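"""Laser-speckle-style perfusion analysis.

Works on sequences of 2-D perfusion maps in arbitrary perfusion units (PU)
with a pixel-to-mm calibration: selects the most stable run of consecutive
frames and averages it, applies a PU band-pass to define the perfused area,
and reports mean perfusion, perfused area and their product (mean blood
flow, PU*mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PerfusionMap",
    "PerfusionConfig",
    "PerfusionSummary",
    "stable_window",
    "apply_pu_filter",
    "summarize_perfusion",
    "speckle_flow_index",
]


@dataclass
class PerfusionMap:
    values: np.ndarray        # (H, W), PU, >= 0
    pixel_pitch_mm: float     # mm per pixel side

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("perfusion map must be 2-D")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be > 0")
        if (self.values < 0).any():
            raise ValueError("perfusion values must be >= 0")


@dataclass(frozen=True)
class PerfusionConfig:
    """Band-pass and frame-averaging settings.

    ``stability_tol`` (PU) bounds the frame-to-frame mean absolute
    difference allowed inside the averaged window; ``None`` accepts the best
    window unconditionally.
    """

    filter_lo: float = 800.0
    filter_hi: float = 3000.0
    k_frames: int = 10
    stability_tol: float | None = None

    def __post_init__(self):
        if not 0 <= self.filter_lo < self.filter_hi:
            raise ValueError("require 0 <= filter_lo < filter_hi")
        if self.k_frames < 1:
            raise ValueError("k_frames must be >= 1")


@dataclass(frozen=True)
class PerfusionSummary:
    mean_perfusion: float     # PU over perfused pixels
    perfused_area: float      # mm^2
    mean_blood_flow: float    # PU * mm^2


class UnstableRecordingError(RuntimeError):
    """No window of consecutive frames met the stability tolerance."""


def _as_stack(frames: Sequence[PerfusionMap]) -> tuple[np.ndarray, float]:
    if len(frames) == 0:
        raise ValueError("no frames given")
    pitch = frames[0].pixel_pitch_mm
    shape = frames[0].values.shape
    for f in frames[1:]:
        if f.values.shape != shape:
            raise ValueError("frames differ in shape")
        if f.pixel_pitch_mm != pitch:
            raise ValueError("frames differ in calibration")
    return np.stack([f.values.astype(np.float64) for f in frames]), pitch


def stable_window(
    frames: Sequence[PerfusionMap], config: PerfusionConfig | None = None
) -> tuple[int, PerfusionMap]:
    """Pick the stillest run of ``k_frames`` consecutive frames and average it.

    The instability of a window is the maximum over its adjacent frame pairs
    of the mean absolute per-pixel PU difference; the window minimizing this
    wins, earliest window on ties.  With ``k_frames == 1`` every window
    scores zero and the first frame is returned.
    """
    config = config or PerfusionConfig()
    stack, pitch = _as_stack(frames)
    T = stack.shape[0]
    k = config.k_frames
    if T < k:
        raise ValueError(f"need at least {k} frames, got {T}")
    if k == 1:
        scores = np.zeros(T)
    else:
        deltas = np.abs(np.diff(stack, axis=0)).mean(axis=(1, 2))  # (T-1,)
        scores = np.array(
            [deltas[s:s + k - 1].max() for s in range(T - k + 1)]
        )
    start = int(np.argmin(scores))  # argmin takes the earliest on ties
    if config.stability_tol is not None and scores[start] > config.stability_tol:
        raise UnstableRecordingError(
            f"best window instability {scores[start]:.2f} PU exceeds "
            f"tolerance {config.stability_tol:.2f} PU"
        )
    avg = stack[start:start + k].mean(axis=0)
    return start, PerfusionMap(values=avg, pixel_pitch_mm=pitch)


def apply_pu_filter(
    pmap: PerfusionMap, config: PerfusionConfig | None = None
) -> np.ndarray:
    """Boolean mask of perfused pixels: ``filter_lo <= PU <= filter_hi``.

    Both bounds are inclusive.
    """
    config = config or PerfusionConfig()
    v = pmap.values
    return (v >= config.filter_lo) & (v <= config.filter_hi)


def summarize_perfusion(
    pmap: PerfusionMap, config: PerfusionConfig | None = None
) -> PerfusionSummary:
    """Mean PU over perfused pixels, perfused area (mm^2) and their product."""
    config = config or PerfusionConfig()
    perfused = apply_pu_filter(pmap, config)
    n = int(perfused.sum())
    area = n * pmap.pixel_pitch_mm ** 2
    mean_pu = float(pmap.values[perfused].mean()) if n else 0.0
    return PerfusionSummary(
        mean_perfusion=mean_pu,
        perfused_area=float(area),
        mean_blood_flow=float(mean_pu * area),
    )


def speckle_flow_index(
    intensity: np.ndarray, window: int = 7, eps: float = 1e-12
) -> np.ndarray:
    """Relative flow map ``1/K^2`` from a raw speckle intensity image.

    ``K`` is the local speckle contrast (windowed SD over windowed mean).
    This is a model-based convenience for instruments that expose raw
    speckle frames; the main pipeline consumes instrument PU maps directly
    and never calls this.
    """
    from scipy import ndimage

    x = np.asarray(intensity, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("intensity must be 2-D")
    mean = ndimage.uniform_filter(x, size=window)
    sq = ndimage.uniform_filter(x * x, size=window)
    var = np.maximum(sq - mean * mean, 0.0)
    k2 = var / np.maximum(mean * mean, eps)
    return 1.0 / np.maximum(k2, eps)
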