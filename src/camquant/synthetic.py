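"""Synthetic CAM-style image generator with analytic ground truth.

Produces branching vessel trees (centerline polylines with per-vertex
radii), rasterized binary masks, rendered RGB images imitating an in ovo
chorioallantoic membrane (red vessels on a pink-yellow background, blurred
sub-membrane distractor vessels, optional tumor disc, illumination gradient
and sensor noise), and matching perfusion-map sequences.  Every generator
is a pure function of its parameters and a seed.

Geometry convention: rasters are row-major with origin top-left; points are
``(row, col)`` floats; a vertex of radius ``r`` paints every pixel whose
center lies within distance ``r`` of the (linearly interpolated) centerline,
so the nominal diameter of a vessel is ``2 * r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .morphometry import Morphometrics
from .perfusion import PerfusionMap

__all__ = [
    "Segment",
    "VesselTree",
    "TreeParams",
    "RenderStyle",
    "PerfusionParams",
    "SyntheticSample",
    "generate_vessel_tree",
    "rasterize_tree",
    "render_cam_image",
    "generate_perfusion_frames",
    "make_sample",
    "detection_tree",
    "segment_pixel_counts",
]

MIN_CANVAS = 64


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """One unbranched vessel run: an ordered polyline with per-vertex radii."""

    points: np.ndarray            # (N, 2) float64, (row, col)
    radii: np.ndarray             # (N,) float64, > 0
    parent: int | None = None     # index of parent segment in the tree
    parent_vertex: int | None = None  # vertex on the parent where this attaches
    deep: bool = False            # sub-membrane distractor, excluded from truth

    def arc_length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def chain_length(self) -> float:
        """Arc length in the 8-connected chain metric.

        A digitized straight run with displacement (a, b), a >= b, walks
        ``a - b`` orthogonal and ``b`` diagonal steps, measuring
        ``a + b*(sqrt(2) - 1)`` under the 1/sqrt(2) step convention used by
        skeleton-based length readouts.  Truth lengths are expressed in this
        metric so they share the measurement convention.
        """
        if len(self.points) < 2:
            return 0.0
        d = np.abs(np.diff(self.points, axis=0))
        hi = d.max(axis=1)
        lo = d.min(axis=1)
        return float((hi + (np.sqrt(2.0) - 1.0) * lo).sum())

    def mean_diameter(self) -> float:
        """Arc-length-weighted mean diameter (2r) along the polyline."""
        if len(self.points) < 2:
            return float(2.0 * self.radii.mean())
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        mid_d = self.radii[:-1] + self.radii[1:]  # = 2 * mean radius per edge
        total = steps.sum()
        if total == 0:
            return float(2.0 * self.radii.mean())
        return float((steps * mid_d).sum() / total)

    def mean_raster_thickness(self) -> float:
        """Expected ``2*EDT - 1`` thickness of this segment's raster.

        Pixel centers strictly outside the tube are background, so a tube of
        continuum diameter ``2r`` measures ``2r - 1`` under the skeleton-EDT
        convention (a hairline measures 1).
        """
        return max(self.mean_diameter() - 1.0, 1.0)


@dataclass
class VesselTree:
    canvas_size: tuple[int, int]
    segments: list[Segment] = field(default_factory=list)

    def superficial_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.segments) if not s.deep]

    def branch_vertices(self, superficial_only: bool = True) -> list[tuple[int, int]]:
        """Distinct (segment, vertex) junctions with >= 3 incident centerlines."""
        attach: dict[tuple[int, int], int] = {}
        for seg in self.segments:
            if seg.parent is None:
                continue
            if superficial_only and (seg.deep or self.segments[seg.parent].deep):
                continue
            key = (seg.parent, int(seg.parent_vertex))
            attach[key] = attach.get(key, 0) + 1
        out = []
        for (pidx, v), n_children in attach.items():
            parent = self.segments[pidx]
            # parent contributes 2 incident lines at an interior vertex, 1 at an end
            incident = n_children + (2 if 0 < v < len(parent.points) - 1 else 1)
            if parent.parent is not None and v == 0:
                incident += 1  # the parent's own upstream attachment
            if incident >= 3:
                out.append((pidx, v))
        return out

    def validate(self) -> None:
        H, W = self.canvas_size
        for i, seg in enumerate(self.segments):
            if (seg.radii <= 0).any():
                raise ValueError(f"segment {i}: radii must be positive")
            pts = seg.points
            if (pts[:, 0] < 0).any() or (pts[:, 0] > H - 1).any() \
                    or (pts[:, 1] < 0).any() or (pts[:, 1] > W - 1).any():
                raise ValueError(f"segment {i}: polyline leaves the canvas")
            if seg.parent is not None:
                pr = self.segments[seg.parent].radii[seg.parent_vertex]
                if seg.radii[0] > pr + 1e-9:
                    raise ValueError(
                        f"segment {i}: child radius exceeds parent at branch"
                    )


@dataclass(frozen=True)
class TreeParams:
    """Growth parameters for the random vessel tree."""

    n_roots: int = 3
    branch_probability: float = 0.08     # per growth step
    branch_angle_spread: float = 0.9     # radians
    diameter_range: tuple[float, float] = (3.0, 40.0)
    taper_factor: float = 0.8            # child radius = parent radius * taper
    deep_fraction: float = 0.15          # fraction of root trees flagged deep
    step_px: float = 4.0
    jitter: float = 0.18                 # direction noise (rad) per step
    elongation_taper: float = 0.9975     # slow radius decay per step
    min_branch_separation_px: float = 24.0
    max_segments: int = 48
    max_steps: int = 160
    avoid_overlap: bool = True
    overlap_margin: float = 3.0
    min_elongation: float = 3.0   # min segment arc length in units of its radius


@dataclass(frozen=True)
class RenderStyle:
    """Appearance model for :func:`render_cam_image`."""

    background_rgb: tuple[float, float, float] = (233.0, 205.0, 172.0)
    gradient_amplitude: float = 16.0
    vessel_rgb: tuple[float, float, float] = (146.0, 40.0, 52.0)
    depth_fade: float = 0.55          # deep vessels blend toward background
    blur_superficial: float = 0.8     # px
    blur_deep: float = 4.0            # px, must exceed blur_superficial
    noise_sd: float = 5.0
    tumor: tuple[tuple[float, float], float, tuple[float, float, float]] | None = None

    def validate(self) -> None:
        if self.blur_deep <= self.blur_superficial:
            raise ValueError("deep-distractor blur must exceed superficial blur")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


@dataclass(frozen=True)
class PerfusionParams:
    pu_vessel_range: tuple[float, float] = (1200.0, 2600.0)
    pu_background: float = 120.0
    n_frames: int = 20
    motion_frames: tuple[int, ...] = ()
    motion_amplitude: float = 800.0
    noise_sd: float = 15.0
    deep_pu_factor: float = 0.5       # sub-membrane vessels read weaker
    pixel_pitch_mm: float = 0.1


@dataclass
class SyntheticSample:
    image: np.ndarray            # (H, W, 3) uint8
    truth_mask: np.ndarray       # (H, W) bool, superficial vessels only
    truth_morphometrics: Morphometrics
    tree: VesselTree
    seed: int


# ---------------------------------------------------------------------------
# tree growth
# ---------------------------------------------------------------------------

def _check_canvas(canvas_size) -> tuple[int, int]:
    H, W = int(canvas_size[0]), int(canvas_size[1])
    if H < MIN_CANVAS or W < MIN_CANVAS:
        raise ValueError(
            f"canvas {H}x{W} is degenerate; each side must be >= {MIN_CANVAS} px"
        )
    return H, W


def generate_vessel_tree(
    canvas_size: tuple[int, int],
    params: TreeParams | None = None,
    seed: int = 0,
) -> VesselTree:
    """Grow a random branching vessel tree on the given canvas.

    Segments advance as jittered random walks; at each step a child may be
    spawned (probability ``branch_probability``) with radius scaled by
    ``taper_factor``.  With ``avoid_overlap`` enabled, a walk terminates
    before colliding with any non-parent segment, which keeps junction
    counts in the rasterized mask equal to the analytic branch count.
    """
    H, W = _check_canvas(canvas_size)
    p = params or TreeParams()
    d_lo, d_hi = p.diameter_range
    if not (1.0 <= d_lo < d_hi <= min(H, W) / 2):
        raise ValueError(
            f"diameter_range {p.diameter_range} must lie within "
            f"[1, {min(H, W) / 2}] for canvas {H}x{W}"
        )
    if not 0.0 <= p.branch_probability <= 1.0:
        raise ValueError("branch_probability must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    tree = VesselTree((H, W))
    r_lo, r_hi = d_lo / 2.0, d_hi / 2.0

    # occupancy record for collision checks: one row per accepted vertex
    occ_pts: list[np.ndarray] = []
    occ_rad: list[float] = []
    occ_seg: list[int] = []
    occ_vtx: list[int] = []

    def collides(pt, r, parent_idx, parent_vertex, own_pts, own_rad) -> bool:
        """True if a disk at ``pt`` would touch any non-adjacent vessel part.

        The parent is exempt only near the attach vertex, and the walk's own
        trail only over its last few steps, so loops back onto the parent or
        onto itself register as collisions.
        """
        if not p.avoid_overlap:
            return False
        if occ_pts:
            pts = np.asarray(occ_pts)
            d = np.linalg.norm(pts - pt, axis=1)
            lim = np.asarray(occ_rad) + r + p.overlap_margin
            hit = d < lim
            if parent_idx is not None and hit.any():
                segs = np.asarray(occ_seg)
                vtxs = np.asarray(occ_vtx)
                window = (np.asarray(occ_rad) + r + p.overlap_margin) / p.step_px + 2
                near_attach = (segs == parent_idx) & (
                    np.abs(vtxs - parent_vertex) <= window
                )
                hit &= ~near_attach
            if hit.any():
                return True
        # self-collision beyond the trailing contact window
        k_self = int(np.ceil((2 * r + p.overlap_margin) / p.step_px)) + 2
        if len(own_pts) > k_self:
            prior = np.asarray(own_pts[:-k_self])
            d = np.linalg.norm(prior - pt, axis=1)
            lim = np.asarray(own_rad[:-k_self]) + r + p.overlap_margin
            if (d < lim).any():
                return True
        return False

    # queue of pending walks:
    # (start, direction, radius, deep, parent, parent_vertex, min_arc)
    queue: list[tuple] = []
    margin = 4.0
    for k in range(p.n_roots):
        start = np.array(
            [rng.uniform(margin, H - 1 - margin), rng.uniform(margin, W - 1 - margin)]
        )
        theta = rng.uniform(0.0, 2.0 * np.pi)
        # log-uniform root diameter covers both ends of the configured range
        d0 = float(np.exp(rng.uniform(np.log(d_lo), np.log(d_hi))))
        deep = bool(rng.random() < p.deep_fraction)
        if k == 0:
            deep = False  # guarantee at least one superficial segment
        queue.append(
            (start, theta, d0 / 2.0, deep, None, None,
             p.min_elongation * d0 / 2.0)
        )

    min_sep_steps = max(1, int(round(p.min_branch_separation_px / p.step_px)))
    # junctions must sit at least 3 max-radii apart for their raster
    # neighbourhoods not to interact
    junction_sep = max(3.0 * r_hi, 24.0)
    junctions: list[np.ndarray] = []

    while queue and len(tree.segments) < p.max_segments:
        start, theta, r, deep, parent, pvertex, min_arc = queue.pop(0)
        seg_idx = len(tree.segments)
        pts = [start.copy()]
        rads = [r]
        child_specs = []  # (point, theta, radius, vertex) — enqueued on acceptance
        steps_since_branch = 0
        for _ in range(p.max_steps):
            # wide trunks run straighter than capillaries
            theta += rng.normal(0.0, p.jitter * np.sqrt(2.0 / max(r, 2.0)))
            r *= p.elongation_taper
            if r < r_lo:
                break
            nxt = pts[-1] + p.step_px * np.array([np.sin(theta), np.cos(theta)])
            # keep the full disk inside the canvas so end caps are not clipped
            b = r + 2.0
            if not (b <= nxt[0] <= H - 1 - b and b <= nxt[1] <= W - 1 - b):
                break
            if collides(nxt, r, parent, pvertex, pts, rads):
                break
            pts.append(nxt)
            rads.append(r)
            steps_since_branch += 1
            # spawn at most one child per branch vertex
            border_ok = (
                r + 8.0 * p.step_px
                < min(nxt[0], nxt[1], H - 1 - nxt[0], W - 1 - nxt[1])
            )
            junction_ok = not junctions or (
                np.linalg.norm(np.asarray(junctions) - nxt, axis=1).min()
                >= junction_sep
            )
            if (
                steps_since_branch >= min_sep_steps
                and border_ok
                and junction_ok
                and len(tree.segments) + len(queue) + len(child_specs) + 1
                < p.max_segments
                and rng.random() < p.branch_probability
            ):
                child_r = r * p.taper_factor
                sign = 1.0 if rng.random() < 0.5 else -1.0
                spread = p.branch_angle_spread * rng.uniform(0.6, 1.0)
                if child_r >= r_lo:
                    # the child must walk far enough to clear the parent
                    # lumen at its branch angle, or it is pure overlap
                    sep = (r + child_r + p.overlap_margin) / max(
                        np.sin(min(spread, np.pi / 2)), 0.2
                    )
                    child_min_arc = max(
                        p.min_elongation * child_r,
                        2.0 * r + 4.0 * p.step_px,
                        sep + r,
                    )
                    child_specs.append(
                        (pts[-1].copy(), theta + sign * spread, child_r,
                         len(pts) - 1, child_min_arc)
                    )
                    junctions.append(pts[-1].copy())
                    steps_since_branch = 0
        # discard walks too short to exist, and child walks that never make
        # it out of the parent lumen (they would be invisible in the raster)
        # a vessel must be elongated: blobs shorter than ~1.5x their own
        # diameter have no meaningful centerline
        arc = (len(pts) - 1) * p.step_px
        if len(pts) < 2 or arc < min_arc:
            continue
        seg = Segment(
            points=np.asarray(pts),
            radii=np.asarray(rads),
            parent=parent,
            parent_vertex=pvertex,
            deep=deep,
        )
        tree.segments.append(seg)
        for v, (pt, rr) in enumerate(zip(pts, rads)):
            occ_pts.append(pt)
            occ_rad.append(rr)
            occ_seg.append(seg_idx)
            occ_vtx.append(v)
        # children only exist once their parent segment is real
        for cpt, ctheta, cr, cvertex, cmin_arc in child_specs:
            queue.append((cpt, ctheta, cr, deep, seg_idx, cvertex, cmin_arc))

    # a parent whose walk ended just past its last branch leaves a stub
    # shorter than the junction radius: the raster shows a bend, not a Y.
    # Trim the stub so the analytic junction degree matches the geometry.
    last_attach: dict[int, int] = {}
    for seg in tree.segments:
        if seg.parent is not None:
            last_attach[seg.parent] = max(
                last_attach.get(seg.parent, 0), int(seg.parent_vertex)
            )
    for pidx, v in last_attach.items():
        parent = tree.segments[pidx]
        tail_px = (len(parent.points) - 1 - v) * p.step_px
        if 0 < tail_px < 2.0 * parent.radii[v] + 2.0:
            parent.points = parent.points[:v + 1]
            parent.radii = parent.radii[:v + 1]

    # every tree must expose at least one superficial segment; retry with
    # fresh superficial roots if all walks were discarded
    attempts = 0
    while not any(not s.deep for s in tree.segments) and attempts < 50:
        attempts += 1
        start = np.array(
            [rng.uniform(margin, H - 1 - margin), rng.uniform(margin, W - 1 - margin)]
        )
        theta = rng.uniform(0.0, 2.0 * np.pi)
        d0 = float(np.exp(rng.uniform(np.log(d_lo), np.log(d_hi))))
        queue.append(
            (start, theta, d0 / 2.0, False, None, None,
             p.min_elongation * d0 / 2.0)
        )
        start2, theta2, r2, deep2, par2, pv2, _ = queue.pop(0)
        seg_idx = len(tree.segments)
        pts = [start2.copy()]
        rads = [r2]
        for _ in range(p.max_steps):
            theta2 += rng.normal(0.0, p.jitter)
            r2 *= p.elongation_taper
            if r2 < r_lo:
                break
            nxt = pts[-1] + p.step_px * np.array([np.sin(theta2), np.cos(theta2)])
            b = r2 + 2.0
            if not (b <= nxt[0] <= H - 1 - b and b <= nxt[1] <= W - 1 - b):
                break
            if collides(nxt, r2, None, None, pts, rads):
                break
            pts.append(nxt)
            rads.append(r2)
        if len(pts) >= 2 and (len(pts) - 1) * p.step_px >= p.min_elongation * rads[0]:
            tree.segments.append(
                Segment(points=np.asarray(pts), radii=np.asarray(rads), deep=False)
            )
    if not any(not s.deep for s in tree.segments):
        raise RuntimeError(
            "could not place a superficial segment; relax the tree parameters"
        )

    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _paint_segment(mask: np.ndarray, seg: Segment) -> None:
    """Stamp one segment into a boolean raster (pixel-center-in-tube test)."""
    H, W = mask.shape
    pts, rads = seg.points, seg.radii
    for i in range(len(pts) - 1):
        p0, p1 = pts[i], pts[i + 1]
        r0, r1 = rads[i], rads[i + 1]
        rmax = max(r0, r1)
        lo_r = max(int(np.floor(min(p0[0], p1[0]) - rmax - 1)), 0)
        hi_r = min(int(np.ceil(max(p0[0], p1[0]) + rmax + 1)) + 1, H)
        lo_c = max(int(np.floor(min(p0[1], p1[1]) - rmax - 1)), 0)
        hi_c = min(int(np.ceil(max(p0[1], p1[1]) + rmax + 1)) + 1, W)
        if lo_r >= hi_r or lo_c >= hi_c:
            continue
        rr, cc = np.meshgrid(
            np.arange(lo_r, hi_r, dtype=np.float64),
            np.arange(lo_c, hi_c, dtype=np.float64),
            indexing="ij",
        )
        v = p1 - p0
        vv = float(v @ v)
        if vv == 0:
            t = np.zeros_like(rr)
        else:
            t = ((rr - p0[0]) * v[0] + (cc - p0[1]) * v[1]) / vv
            t = np.clip(t, 0.0, 1.0)
        dr = rr - (p0[0] + t * v[0])
        dc = cc - (p0[1] + t * v[1])
        rad_t = r0 + (r1 - r0) * t
        inside = dr * dr + dc * dc <= rad_t * rad_t
        mask[lo_r:hi_r, lo_c:hi_c] |= inside


def _rasterize(tree: VesselTree, indices) -> np.ndarray:
    mask = np.zeros(tree.canvas_size, dtype=bool)
    for i in indices:
        _paint_segment(mask, tree.segments[i])
    return mask


def rasterize_tree(
    tree: VesselTree, canvas_size: tuple[int, int] | None = None
) -> tuple[np.ndarray, Morphometrics]:
    """Rasterize superficial segments and derive analytic morphometrics.

    Returns ``(truth_mask, truth_morphometrics)`` where length is the sum of
    superficial polyline arc lengths in the 8-connected chain metric (the
    same convention skeleton readouts use), thickness the length-weighted
    mean raster thickness, the branch count the number of superficial
    junction vertices and the area the rasterized superficial pixel count.
    """
    if canvas_size is not None:
        canvas = _check_canvas(canvas_size)
        if canvas != tuple(tree.canvas_size):
            tree = replace_canvas(tree, canvas)
    tree.validate()
    sup = tree.superficial_indices()
    mask = _rasterize(tree, sup)
    length = sum(tree.segments[i].chain_length() for i in sup)
    if length > 0:
        thickness = (
            sum(
                tree.segments[i].arc_length() * tree.segments[i].mean_raster_thickness()
                for i in sup
            )
            / length
        )
    else:
        thickness = 0.0
    truth = Morphometrics(
        total_vessel_area=float(mask.sum()),
        total_vessel_length=float(length),
        mean_vessel_thickness=float(thickness),
        branching_points=len(tree.branch_vertices(superficial_only=True)),
    )
    return mask, truth


def replace_canvas(tree: VesselTree, canvas_size: tuple[int, int]) -> VesselTree:
    out = VesselTree(tuple(canvas_size), list(tree.segments))
    out.validate()
    return out


def segment_pixel_counts(
    tree: VesselTree, pred_mask: np.ndarray | None = None
) -> list[tuple[int, float, int, int]]:
    """Per-superficial-segment pixel bookkeeping for detection analysis.

    Returns ``(segment_index, mean_diameter, n_pixels, n_pixels_predicted)``
    rows; the last entry is 0 when ``pred_mask`` is None.
    """
    rows = []
    for i in tree.superficial_indices():
        m = np.zeros(tree.canvas_size, dtype=bool)
        _paint_segment(m, tree.segments[i])
        n = int(m.sum())
        hit = int((m & pred_mask).sum()) if pred_mask is not None else 0
        rows.append((i, tree.segments[i].mean_diameter(), n, hit))
    return rows


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_cam_image(
    tree: VesselTree, style: RenderStyle | None = None, seed: int = 0
) -> SyntheticSample:
    """Render a tree into an RGB image with CAM-like appearance.

    Deep-distractor segments are composited first, faded toward the
    background and blurred with ``blur_deep``; superficial vessels go on
    top with a light blur.  The truth mask covers superficial pixels only.
    """
    style = style or RenderStyle()
    style.validate()
    rng = np.random.default_rng(seed)
    H, W = tree.canvas_size
    truth_mask, truth = rasterize_tree(tree)

    bg = np.asarray(style.background_rgb, dtype=np.float64)
    img = np.broadcast_to(bg, (H, W, 3)).copy()

    if style.gradient_amplitude > 0:
        phi = rng.uniform(0.0, 2.0 * np.pi)
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        proj = (rr * np.sin(phi) + cc * np.cos(phi)) / np.hypot(H, W)
        grad = style.gradient_amplitude * 2.0 * (proj - proj.mean())
        img += grad[:, :, None]

    if style.tumor is not None:
        (tr, tc), trad, trgb = style.tumor
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        disc = ((rr - tr) ** 2 + (cc - tc) ** 2 <= trad ** 2).astype(np.float64)
        disc = ndimage.gaussian_filter(disc, 2.0)
        img = (1 - 0.9 * disc[:, :, None]) * img + 0.9 * disc[:, :, None] * np.asarray(
            trgb, dtype=np.float64
        )

    deep_idx = [i for i, s in enumerate(tree.segments) if s.deep]
    if deep_idx:
        alpha = _rasterize(tree, deep_idx).astype(np.float64)
        alpha = ndimage.gaussian_filter(alpha, style.blur_deep)
        np.clip(alpha, 0.0, 1.0, out=alpha)
        deep_rgb = style.depth_fade * bg + (1 - style.depth_fade) * np.asarray(
            style.vessel_rgb
        )
        img = (1 - alpha[:, :, None]) * img + alpha[:, :, None] * deep_rgb

    if truth_mask.any():
        alpha = ndimage.gaussian_filter(
            truth_mask.astype(np.float64), style.blur_superficial
        )
        np.clip(alpha, 0.0, 1.0, out=alpha)
        img = (1 - alpha[:, :, None]) * img + alpha[:, :, None] * np.asarray(
            style.vessel_rgb, dtype=np.float64
        )

    if style.noise_sd > 0:
        img += rng.normal(0.0, style.noise_sd, size=img.shape)

    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SyntheticSample(
        image=image, truth_mask=truth_mask, truth_morphometrics=truth,
        tree=tree, seed=seed,
    )


def make_sample(
    canvas_size: tuple[int, int] = (512, 512),
    tree_params: TreeParams | None = None,
    style: RenderStyle | None = None,
    perfusion_params: PerfusionParams | None = None,
    seed: int = 0,
) -> SyntheticSample:
    """One-stop sample: tree + render driven by a single master seed."""
    ss = np.random.SeedSequence(seed)
    tree_seed, render_seed = (int(s) for s in ss.generate_state(2))
    tree = generate_vessel_tree(canvas_size, tree_params, seed=tree_seed)
    sample = render_cam_image(tree, style, seed=render_seed)
    sample.seed = seed
    return sample


# ---------------------------------------------------------------------------
# perfusion frames
# ---------------------------------------------------------------------------

def generate_perfusion_frames(
    tree: VesselTree,
    params: PerfusionParams | None = None,
    seed: int = 0,
) -> list[PerfusionMap]:
    """Simulate an LSCI-style frame sequence over the tree's canvas.

    Each vessel segment carries a constant perfusion level drawn from
    ``pu_vessel_range`` (deep segments attenuated by ``deep_pu_factor``);
    frames add i.i.d. Gaussian pixel noise and the frames listed in
    ``motion_frames`` receive a global additive perturbation.
    """
    p = params or PerfusionParams()
    if p.n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    bad = [f for f in p.motion_frames if not 0 <= f < p.n_frames]
    if bad:
        raise ValueError(f"motion_frames {bad} outside [0, {p.n_frames})")
    rng = np.random.default_rng(seed)
    base = np.full(tree.canvas_size, p.pu_background, dtype=np.float64)
    lo, hi = p.pu_vessel_range
    for seg in tree.segments:
        pu = rng.uniform(lo, hi)
        if seg.deep:
            pu *= p.deep_pu_factor
        m = np.zeros(tree.canvas_size, dtype=bool)
        _paint_segment(m, seg)
        base[m] = pu

    frames = []
    motion = set(p.motion_frames)
    for t in range(p.n_frames):
        f = base.copy()
        if p.noise_sd > 0:
            f += rng.normal(0.0, p.noise_sd, size=f.shape)
        if t in motion:
            f += p.motion_amplitude
        np.clip(f, 0.0, None, out=f)
        frames.append(PerfusionMap(values=f.astype(np.float32),
                                   pixel_pitch_mm=p.pixel_pitch_mm))
    return frames


def perfusion_ground_truth(tree: VesselTree, params: PerfusionParams, seed: int):
    """Noise-free base perfusion map matching :func:`generate_perfusion_frames`.

    Uses the identical draw sequence, so the analytic summary of this map is
    the oracle for the noisy pipeline.
    """
    p = params
    rng = np.random.default_rng(seed)
    base = np.full(tree.canvas_size, p.pu_background, dtype=np.float64)
    lo, hi = p.pu_vessel_range
    for seg in tree.segments:
        pu = rng.uniform(lo, hi)
        if seg.deep:
            pu *= p.deep_pu_factor
        m = np.zeros(tree.canvas_size, dtype=bool)
        _paint_segment(m, seg)
        base[m] = pu
    return PerfusionMap(values=base.astype(np.float32),
                        pixel_pitch_mm=p.pixel_pitch_mm)


# ---------------------------------------------------------------------------
# constructed suites
# ---------------------------------------------------------------------------

def detection_tree(
    canvas_size: tuple[int, int] = (512, 512),
    diameters: tuple[float, ...] = (220.0, 65.0, 33.0, 17.0, 9.0, 5.0, 3.0),
    seed: int = 0,
) -> VesselTree:
    """Parallel straight segments of the requested diameters, widest first.

    Lays the vessels out left-to-right with gaps so none overlap; endpoints
    get sub-pixel jitter so rasterized widths are not lattice-aligned.  Used
    to probe which diameters a segmenter detects.
    """
    H, W = _check_canvas(canvas_size)
    rng = np.random.default_rng(seed)
    ds = sorted(diameters, reverse=True)
    gap = 14.0
    need = sum(ds) + gap * (len(ds) + 1)
    if need > W:
        raise ValueError(f"diameters need {need:.0f} px of width, canvas has {W}")
    tree = VesselTree((H, W))
    x = gap
    for d in ds:
        r = d / 2.0
        cx = x + r + rng.uniform(-0.45, 0.45)
        tilt = rng.uniform(-2.5, 2.5)
        top = np.array([max(r / 4, 4.0), cx - tilt / 2])
        bot = np.array([H - 1 - max(r / 4, 4.0), cx + tilt / 2])
        n_v = 8
        t = np.linspace(0.0, 1.0, n_v)[:, None]
        pts = top[None, :] * (1 - t) + bot[None, :] * t
        tree.segments.append(
            Segment(points=pts, radii=np.full(n_v, r), parent=None, deep=False)
        )
        x += d + gap
    tree.validate()
    return tree
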