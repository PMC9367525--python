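"""End-to-end benchmark runs shared by the test suite and the acceptance report.

The synthetic curriculum mixes capillary-scale and large-vessel trees so
the trained segmenter sees the full diameter spectrum; held-out seeds form
the validation suite.  All functions are deterministic in their seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import synthetic as syn
from . import segmentation as seg
from . import perfusion as perf
from . import morphometry as morph

__all__ = [
    "curriculum_sample",
    "build_suites",
    "run_segmentation_benchmark",
    "run_detection_benchmark",
    "run_perfusion_benchmark",
]

# (diameter range, n_roots, branch probability) presets; a per-sample draw
# picks one, so small vessels dominate but wide trunks appear regularly.
_PRESETS = [
    ((3.0, 12.0), 4, 0.10),
    ((3.0, 12.0), 4, 0.10),
    ((4.0, 30.0), 3, 0.09),
    ((4.0, 30.0), 3, 0.09),
    ((8.0, 60.0), 3, 0.08),
    ((20.0, 126.0), 2, 0.05),
]


def curriculum_sample(size: int, seed: int) -> syn.SyntheticSample:
    """One training/validation sample from the default curriculum."""
    rng = np.random.default_rng(seed)
    d_range, n_roots, bp = _PRESETS[int(rng.integers(len(_PRESETS)))]
    params = syn.TreeParams(
        n_roots=n_roots,
        branch_probability=bp,
        diameter_range=d_range,
        deep_fraction=0.15,
    )
    style = syn.RenderStyle()
    if rng.random() < 0.3:
        cx = rng.uniform(0.3 * size, 0.7 * size)
        cy = rng.uniform(0.3 * size, 0.7 * size)
        style = replace(
            style, tumor=((cx, cy), rng.uniform(0.06, 0.12) * size,
                          (214.0, 196.0, 198.0))
        )
    return syn.make_sample((size, size), params, style, seed=seed)


def build_suites(n_train: int = 40, n_val: int = 10, size: int = 256,
                 seed: int = 0):
    """Disjoint train/validation suites: seeds are offset by the master seed."""
    base = int(seed) * 1_000_003
    train = [curriculum_sample(size, base + k) for k in range(n_train)]
    val = [curriculum_sample(size, base + 10_000 + k) for k in range(n_val)]
    return train, val


def run_segmentation_benchmark(
    seed: int = 0,
    n_train: int = 40,
    n_val: int = 10,
    size: int = 256,
    config: seg.SegmentationConfig | None = None,
):
    """Train on the default curriculum; report pooled validation metrics.

    Returns ``(metrics, model_state, log)`` where metrics pools TP/FP/FN
    over all validation pixels.
    """
    config = config or seg.SegmentationConfig(seed=seed)
    train, val = build_suites(n_train, n_val, size, seed)
    state, log = seg.train_segmenter(train, val, config)
    pairs = []
    for s in val:
        score = seg.predict_scoremap(state, s.image, config)
        pairs.append((seg.binarize(score, config.threshold), s.truth_mask))
    metrics = seg.pooled_metrics(pairs)
    return metrics, state, log


def run_detection_benchmark(
    model_state: seg.ModelState,
    seed: int = 0,
    n_scenes: int = 3,
    config: seg.SegmentationConfig | None = None,
):
    """Detection range over constructed scenes spanning diameters 3-220 px.

    Each scene holds parallel straight vessels at fixed diameters on a
    512x512 canvas; detection follows the 50%-pixel-overlap rule.  Returns
    ``(min_detected, max_detected, per_scene_results)`` with diameters
    pooled over scenes.
    """
    config = config or seg.SegmentationConfig()
    results = []
    detected = []
    for k in range(n_scenes):
        tree = syn.detection_tree(seed=seed + k)
        sample = syn.render_cam_image(tree, seed=seed + 77 + k)
        score = seg.predict_scoremap(model_state, sample.image, config)
        pred = seg.binarize(score, config.threshold)
        res = seg.per_vessel_detection(pred, tree)
        results.append(res)
        detected.extend(
            row["diameter"] for row in res.segments if row["detected"]
        )
    mn = min(detected) if detected else None
    mx = max(detected) if detected else None
    return mn, mx, results


def run_perfusion_benchmark(seed: int = 0):
    """Synthetic frames with an injected motion spike, end to end.

    Returns a dict with the selected window, recovered summary and the
    analytic (noise-free) oracle summary.
    """
    params = syn.PerfusionParams(
        n_frames=20, motion_frames=(5,), motion_amplitude=900.0, noise_sd=12.0
    )
    ss = np.random.SeedSequence(seed)
    tree_seed, frame_seed = (int(s) for s in ss.generate_state(2))
    tree = syn.generate_vessel_tree(
        (128, 128),
        syn.TreeParams(n_roots=3, diameter_range=(4.0, 20.0), deep_fraction=0.0),
        seed=tree_seed,
    )
    frames = syn.generate_perfusion_frames(tree, params, seed=frame_seed)
    truth_map = syn.perfusion_ground_truth(tree, params, seed=frame_seed)
    cfg = perf.PerfusionConfig(k_frames=10)
    start, avg = perf.stable_window(frames, cfg)
    recovered = perf.summarize_perfusion(avg, cfg)
    analytic = perf.summarize_perfusion(truth_map, cfg)
    return {
        "window_start": start,
        "motion_frames": params.motion_frames,
        "recovered": recovered,
        "analytic": analytic,
    }


def run_morphometry_oracle(n_trees: int = 50, seed: int = 0):
    """Compare quantify(truth_mask) to analytic morphometrics over many trees.

    Trees use well-separated branches, no deep distractors and diameters
    >= 8 px so the analytic references are exact; near-empty trees (truth
    length < 300 px, where single-pixel quantization dominates any relative
    tolerance) are skipped and replaced by the next seed.  Returns a list of
    per-tree dicts with measured and true values.
    """
    params = syn.TreeParams(
        n_roots=2,
        branch_probability=0.06,
        diameter_range=(8.0, 18.0),
        deep_fraction=0.0,
        min_branch_separation_px=64.0,
        jitter=0.10,
        max_segments=12,
        max_steps=200,
        min_elongation=10.0,
    )
    rows = []
    k = 0
    while len(rows) < n_trees and k < 20 * n_trees:
        tree = syn.generate_vessel_tree((448, 448), params, seed=seed + k)
        k += 1
        mask, truth = syn.rasterize_tree(tree)
        if truth.total_vessel_length < 300.0:
            continue
        m = morph.quantify(mask)
        rows.append({"measured": m, "truth": truth, "seed": seed + k - 1})
    return rows
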