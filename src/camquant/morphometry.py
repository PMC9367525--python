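"""Vascular morphometry from binary vessel masks.

Four readouts are computed from a segmentation mask: total vessel area,
total vessel length, mean vessel thickness and the number of branching
points.  Length and branching are measured on a one-pixel-wide skeleton;
thickness samples the Euclidean distance transform along that skeleton.

Conventions (fixed here, since no single standard exists):

* components smaller than ``min_component_px`` (default 10) are removed
  before any readout;
* length is geodesic over the 8-connected skeleton graph — orthogonal
  steps count 1 px, diagonal steps sqrt(2) px;
* a branching point is a cluster of skeleton pixels having >= 3 skeleton
  neighbours; nearby candidates are merged into a single point;
* thickness at a skeleton pixel is ``2 * EDT - 1`` (the EDT of a
  one-pixel line is 1, so a hairline reads thickness 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

__all__ = [
    "Morphometrics",
    "vessel_area",
    "skeletonize_mask",
    "vessel_length",
    "branch_points",
    "mean_thickness",
    "quantify",
    "EmptySkeletonError",
]

SQRT2 = float(np.sqrt(2.0))

#: default minimum connected-component size (px) kept before readouts
MIN_COMPONENT_PX = 10

#: dilation radius used to merge adjacent branch-point candidates
BRANCH_MERGE_RADIUS = 2


class EmptySkeletonError(ValueError):
    """Raised when a readout is undefined because the skeleton is empty."""


@dataclass(frozen=True)
class Morphometrics:
    """The four vessel readouts, all in pixel units."""

    total_vessel_area: float      # px^2
    total_vessel_length: float    # px
    mean_vessel_thickness: float  # px
    branching_points: int
    flags: tuple[str, ...] = field(default=(), compare=False)

    def as_dict(self) -> dict:
        return {
            "area_px2": self.total_vessel_area,
            "length_px": self.total_vessel_length,
            "thickness_px": self.mean_vessel_thickness,
            "branch_points": self.branching_points,
            "flags": ";".join(self.flags),
        }


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if mask.dtype == bool:
        return mask
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask must be binary (values 0/1 or bool)")
    return mask.astype(bool)


def _filter_components(mask: np.ndarray, min_component_px: int) -> np.ndarray:
    if min_component_px <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_component_px
    keep[0] = False
    return keep[labels]


def vessel_area(mask: np.ndarray, *, min_component_px: int = MIN_COMPONENT_PX) -> int:
    """Count vessel pixels after minimum-component filtering."""
    mask = _filter_components(_check_binary(mask), min_component_px)
    return int(mask.sum())


def skeletonize_mask(mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide, 8-connectivity-preserving skeleton of ``mask``."""
    mask = _check_binary(mask)
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    return skeletonize(mask)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")


def vessel_length(skeleton: np.ndarray) -> float:
    """Geodesic skeleton length: 1 per orthogonal step, sqrt(2) per diagonal."""
    skel = _check_binary(skeleton)
    if not skel.any():
        return 0.0
    s = skel.astype(np.uint8)
    ortho = np.count_nonzero(s[:, 1:] & s[:, :-1]) + np.count_nonzero(
        s[1:, :] & s[:-1, :]
    )
    diag = np.count_nonzero(s[1:, 1:] & s[:-1, :-1]) + np.count_nonzero(
        s[1:, :-1] & s[:-1, 1:]
    )
    return float(ortho + SQRT2 * diag)


def branch_points(
    skeleton: np.ndarray, *, merge_radius: int = BRANCH_MERGE_RADIUS
) -> int:
    """Count junction clusters: skeleton pixels with >= 3 skeleton neighbours.

    Candidate pixels within ``merge_radius`` of each other (after dilation)
    collapse into a single branching point, so a thick junction zone is not
    over-counted.
    """
    skel = _check_binary(skeleton)
    if not skel.any():
        return 0
    cand = skel & (_neighbor_counts(skel) >= 3)
    if not cand.any():
        return 0
    if merge_radius > 0:
        cand = ndimage.binary_dilation(
            cand, structure=ndimage.generate_binary_structure(2, 2),
            iterations=merge_radius,
        )
    _, n = ndimage.label(cand, structure=np.ones((3, 3)))
    return int(n)


def mean_thickness(mask: np.ndarray, skeleton: np.ndarray | None = None) -> float:
    """Mean ``2*EDT - 1`` over skeleton pixels.

    Raises :class:`EmptySkeletonError` when the skeleton is empty — the
    readout has no defined value there.
    """
    mask = _check_binary(mask)
    skel = skeletonize_mask(mask) if skeleton is None else _check_binary(skeleton)
    if not skel.any():
        raise EmptySkeletonError("mean thickness undefined for an empty skeleton")
    edt = ndimage.distance_transform_edt(mask)
    return float(np.mean(2.0 * edt[skel] - 1.0))


def _prune_spurs(skel: np.ndarray, edt: np.ndarray, factor: float = 2.0) -> np.ndarray:
    """Remove terminal twigs shorter than the local vessel radius.

    Skeletonization of wide vessels grows short spurs at end caps and
    junction zones; a terminal path shorter than ``factor`` times the EDT at
    its attachment point is an artefact of the cross-section, not a vessel.
    """
    skel = skel.copy()
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for _ in range(3):  # a few passes catch nested spurs
        counts = _neighbor_counts(skel)
        endpoints = np.argwhere(skel & (counts == 1))
        removed_any = False
        for r0, c0 in endpoints:
            if not skel[r0, c0]:
                continue
            path = [(r0, c0)]
            prev = None
            r, c = r0, c0
            while True:
                nbrs = [
                    (r + dr, c + dc)
                    for dr, dc in offsets
                    if 0 <= r + dr < skel.shape[0]
                    and 0 <= c + dc < skel.shape[1]
                    and skel[r + dr, c + dc]
                    and (r + dr, c + dc) != prev
                ]
                if len(nbrs) != 1:
                    break  # junction, dead end, or isolated pixel
                prev = (r, c)
                r, c = nbrs[0]
                if _neighbor_counts_at(skel, r, c) >= 3:
                    break
                path.append((r, c))
                if len(path) > 4 * edt[r0, c0] + 8:
                    break
            limit = factor * edt[r, c] + 1.0
            if len(path) <= limit and len(path) < skel.sum():
                for pr, pc in path:
                    skel[pr, pc] = False
                removed_any = True
        if not removed_any:
            break
    return skel


def _neighbor_counts_at(skel: np.ndarray, r: int, c: int) -> int:
    r0, r1 = max(r - 1, 0), min(r + 2, skel.shape[0])
    c0, c1 = max(c - 1, 0), min(c + 2, skel.shape[1])
    return int(skel[r0:r1, c0:c1].sum()) - int(skel[r, c])


def quantify(
    mask: np.ndarray,
    *,
    min_component_px: int = MIN_COMPONENT_PX,
    prune_spurs: bool = True,
) -> Morphometrics:
    """Compute all four readouts from one binary mask.

    Component filtering runs once and is shared by every readout.  An empty
    mask (or one emptied by filtering) yields zeros with an
    ``"empty_skeleton"`` flag rather than an error, so batch tables stay
    rectangular.
    """
    mask = _filter_components(_check_binary(mask), min_component_px)
    area = int(mask.sum())
    if area == 0:
        return Morphometrics(0, 0.0, 0.0, 0, flags=("empty_skeleton",))
    skel = skeletonize_mask(mask)
    edt = ndimage.distance_transform_edt(mask)
    if prune_spurs:
        skel = _prune_spurs(skel, edt)
    if not skel.any():
        return Morphometrics(area, 0.0, 0.0, 0, flags=("empty_skeleton",))
    length = vessel_length(skel)
    thickness = float(np.mean(2.0 * edt[skel] - 1.0))
    branches = branch_points(skel)
    return Morphometrics(area, length, thickness, branches)
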