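import numpy as np
import pytest
from scipy import ndimage

from camquant import morphometry as morph
from camquant import synthetic as syn

from conftest import straight_segment_tree


# ---------------------------------------------------------------------------
# vessel_area
# ---------------------------------------------------------------------------

def test_area_empty_mask():
    assert morph.vessel_area(np.zeros((32, 32), dtype=bool)) == 0


def test_area_filled_rectangle():
    mask = np.zeros((40, 40), dtype=bool)
    mask[10:15, 5:25] = True  # 5 x 20
    assert morph.vessel_area(mask) == 100


def test_area_min_component_filter():
    mask = np.zeros((64, 64), dtype=bool)
    mask[5:15, 5:15] = True          # 100 px component
    mask[40, 40:43] = True           # 3 px component, below the 10 px floor
    assert morph.vessel_area(mask, min_component_px=10) == 100


def test_area_rejects_nonbinary():
    with pytest.raises(ValueError):
        morph.vessel_area(np.full((8, 8), 3))


# ---------------------------------------------------------------------------
# skeletonize_mask
# ---------------------------------------------------------------------------

def test_skeleton_empty():
    skel = morph.skeletonize_mask(np.zeros((16, 16), dtype=bool))
    assert not skel.any()


def test_skeleton_horizontal_bar_single_path():
    mask = np.zeros((20, 60), dtype=bool)
    mask[8:13, 5:55] = True  # 5 x 50 bar
    skel = morph.skeletonize_mask(mask)
    assert skel.any()
    assert (skel & ~mask).sum() == 0  # skeleton subset of mask
    # single 8-connected path: one component, exactly two endpoints, no junctions
    _, n_comp = ndimage.label(skel, structure=np.ones((3, 3)))
    assert n_comp == 1
    counts = morph._neighbor_counts(skel)
    assert int(((counts == 1) & skel).sum()) == 2
    assert int(((counts >= 3) & skel).sum()) == 0
    # endpoints near the bar ends
    rows, cols = np.nonzero(skel)
    assert cols.min() <= 9 and cols.max() >= 50
    assert 46 <= morph.vessel_length(skel) <= 51


def test_skeleton_idempotent(small_tree):
    mask, _ = syn.rasterize_tree(small_tree)
    skel = morph.skeletonize_mask(mask)
    assert np.array_equal(morph.skeletonize_mask(skel), skel)


# ---------------------------------------------------------------------------
# vessel_length
# ---------------------------------------------------------------------------

def test_length_empty():
    assert morph.vessel_length(np.zeros((8, 8), dtype=bool)) == 0.0


def test_length_horizontal_run():
    skel = np.zeros((5, 110), dtype=bool)
    skel[2, 3:103] = True  # 100 pixels -> 99 unit steps
    assert morph.vessel_length(skel) == pytest.approx(99.0)


def test_length_diagonal_run():
    skel = np.zeros((60, 60), dtype=bool)
    idx = np.arange(50)
    skel[idx + 2, idx + 4] = True  # 50 pixels -> 49 diagonal steps
    assert morph.vessel_length(skel) == pytest.approx(49 * np.sqrt(2.0))


# ---------------------------------------------------------------------------
# branch_points
# ---------------------------------------------------------------------------

def _draw_arm(skel, start, step, n):
    r, c = start
    dr, dc = step
    for _ in range(n):
        r += dr
        c += dc
        skel[r, c] = True


def test_branch_points_straight_line():
    skel = np.zeros((9, 40), dtype=bool)
    skel[4, 5:35] = True
    assert morph.branch_points(skel) == 0


def test_branch_points_y_shape():
    # three 20 px arms meeting at one pixel; brute-force oracle: the center
    # is the only pixel with >= 3 neighbors
    skel = np.zeros((64, 64), dtype=bool)
    skel[32, 32] = True
    _draw_arm(skel, (32, 32), (-1, 0), 20)
    _draw_arm(skel, (32, 32), (1, -1), 20)
    _draw_arm(skel, (32, 32), (1, 1), 20)
    counts = morph._neighbor_counts(skel)
    assert int(((counts >= 3) & skel).sum()) == 1  # oracle
    assert morph.branch_points(skel) == 1


def test_branch_points_plus_shape():
    skel = np.zeros((64, 64), dtype=bool)
    skel[32, 32] = True
    for step in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        _draw_arm(skel, (32, 32), step, 15)
    assert morph.branch_points(skel) == 1


def test_branch_points_two_separated_ys():
    skel = np.zeros((64, 128), dtype=bool)
    for cc in (30, 96):
        skel[32, cc] = True
        _draw_arm(skel, (32, cc), (-1, 0), 12)
        _draw_arm(skel, (32, cc), (1, -1), 12)
        _draw_arm(skel, (32, cc), (1, 1), 12)
    assert morph.branch_points(skel) == 2


# ---------------------------------------------------------------------------
# mean_thickness
# ---------------------------------------------------------------------------

def test_thickness_one_px_line():
    mask = np.zeros((9, 40), dtype=bool)
    mask[4, 5:35] = True
    # EDT oracle: every line pixel has EDT exactly 1
    edt = ndimage.distance_transform_edt(mask)
    assert np.all(edt[mask] == 1.0)
    assert morph.mean_thickness(mask) == pytest.approx(1.0)


def test_thickness_rectangle():
    mask = np.zeros((30, 220), dtype=bool)
    mask[10:21, 10:210] = True  # 11 x 200
    val = morph.mean_thickness(mask)
    assert val == pytest.approx(11.0, rel=0.05)


def test_thickness_empty_mask_errors():
    with pytest.raises(morph.EmptySkeletonError):
        morph.mean_thickness(np.zeros((16, 16), dtype=bool))


# ---------------------------------------------------------------------------
# quantify
# ---------------------------------------------------------------------------

def test_quantify_single_straight_segment():
    # analytic oracle: tilted tube, length 100, radius 5
    p0 = np.array([40.3, 30.7])
    direction = np.array([0.6, 0.8])
    tree = straight_segment_tree(p0, p0 + 100 * direction, 5.0)
    mask, truth = syn.rasterize_tree(tree)
    m = morph.quantify(mask)
    assert m.total_vessel_area == pytest.approx(
        2 * 5 * 100 + np.pi * 25, rel=0.03
    )
    assert m.total_vessel_length == pytest.approx(truth.total_vessel_length, rel=0.05)
    assert m.mean_vessel_thickness == pytest.approx(
        truth.mean_vessel_thickness, rel=0.10
    )
    assert m.branching_points == 0


def test_quantify_empty_mask():
    m = morph.quantify(np.zeros((32, 32), dtype=bool))
    assert (m.total_vessel_area, m.total_vessel_length,
            m.mean_vessel_thickness, m.branching_points) == (0, 0.0, 0.0, 0)
    assert "empty_skeleton" in m.flags


def test_quantify_two_separated_y_trees():
    canvas = (200, 400)
    trees = []
    for cc in (100.4, 300.2):
        c = np.array([100.3, cc])
        arms = [np.array([-1.0, 0.0]), np.array([0.87, 0.5]),
                np.array([0.87, -0.5])]
        segs = [
            syn.Segment(points=np.stack([c, c + 55 * a]),
                        radii=np.array([4.0, 4.0]))
            for a in arms
        ]
        trees.extend(segs)
    tree = syn.VesselTree(canvas, trees)
    mask, _ = syn.rasterize_tree(tree)
    assert morph.quantify(mask).branching_points == 2


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

def test_translation_invariance(small_tree):
    mask, _ = syn.rasterize_tree(small_tree)
    pad = np.zeros((260, 260), dtype=bool)
    pad[10:202, 10:202] = mask
    shifted = np.roll(np.roll(pad, 17, axis=0), -9, axis=1)
    a = morph.quantify(pad)
    b = morph.quantify(shifted)
    assert a.total_vessel_area == b.total_vessel_area
    assert a.total_vessel_length == pytest.approx(b.total_vessel_length)
    assert a.mean_vessel_thickness == pytest.approx(b.mean_vessel_thickness)
    assert a.branching_points == b.branching_points


def test_rotation_90_invariance(small_tree):
    mask, _ = syn.rasterize_tree(small_tree)
    a = morph.quantify(mask)
    b = morph.quantify(np.rot90(mask))
    assert a.total_vessel_area == b.total_vessel_area
    assert a.branching_points == b.branching_points
    assert b.total_vessel_length == pytest.approx(a.total_vessel_length, rel=0.02)
    assert b.mean_vessel_thickness == pytest.approx(a.mean_vessel_thickness, rel=0.02)


def test_radius_scaling_monotonic():
    p0 = np.array([60.3, 20.7])
    p1 = np.array([100.9, 140.2])
    prev = 0.0
    for r in (3.0, 5.0, 8.0):
        tree = straight_segment_tree(p0, p1, r)
        mask, _ = syn.rasterize_tree(tree)
        m = morph.quantify(mask)
        assert m.mean_vessel_thickness > prev
        assert m.branching_points == 0
        prev = m.mean_vessel_thickness
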