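"""Trainable encoder–decoder vessel segmentation.

The segmenter is a compact U-shaped convolutional network (see
:mod:`camquant._nn`) producing a per-pixel vessel score in [0, 1].  Training
uses binary cross-entropy with flip/rotation/shift/color augmentation and
early stopping on validation Dice; inference runs tiled with feathered
blending so large images fit in memory.  Thresholding the score map at 0.5
yields the binary mask consumed by :mod:`camquant.morphometry`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np

from ._nn import UNet, Adam, bce_with_logits, sigmoid

__all__ = [
    "SegmentationConfig",
    "ModelState",
    "TrainingLog",
    "SegMetrics",
    "DetectionResult",
    "augment_pair",
    "train_segmenter",
    "predict_scoremap",
    "binarize",
    "evaluate_segmentation",
    "pooled_metrics",
    "per_vessel_detection",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Hyperparameters for training and inference."""

    threshold: float = 0.5
    depth: int = 4
    base_channels: int = 8
    tile_size: int = 256
    tile_overlap: int = 32
    learning_rate: float = 3e-3
    batch_size: int = 4
    max_epochs: int = 25
    patience: int = 6
    crop_size: int = 128
    crops_per_image: int = 2
    pos_weight: float = 2.0
    flip_lr_prob: float = 0.5
    flip_ud_prob: float = 0.5
    rotations: tuple[int, ...] = (0, 90, 180, 270)
    color_shift: float = 12.0     # max per-channel additive shift (8-bit units)
    spatial_shift: float = 16.0   # max |shift| in px, applied as a wrap-around roll
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")
        if self.tile_overlap >= self.tile_size:
            raise ValueError("tile_overlap must be smaller than tile_size")
        for r in self.rotations:
            if r % 90 != 0:
                raise ValueError("rotations must be multiples of 90 degrees")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ModelState:
    """Serializable snapshot of a trained segmenter."""

    depth: int
    base_channels: int
    in_channels: int
    weights: list[np.ndarray]
    config_hash: str = ""
    epochs_run: int = 0
    best_val_dice: float = float("nan")

    def build(self) -> UNet:
        net = UNet(in_ch=self.in_channels, depth=self.depth,
                   base=self.base_channels, seed=0)
        net.set_weights(self.weights)
        return net

    def save(self, path) -> None:
        meta = {
            "depth": self.depth,
            "base_channels": self.base_channels,
            "in_channels": self.in_channels,
            "config_hash": self.config_hash,
            "epochs_run": self.epochs_run,
            "best_val_dice": self.best_val_dice,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            n = sum(1 for k in z.files if k.startswith("w"))
            weights = [z[f"w{i}"] for i in range(n)]
        return cls(weights=weights, **meta)


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)  # epoch, train_loss, val_dice
    best_epoch: int = -1
    best_val_dice: float = float("-inf")
    stopped_early: bool = False


@dataclass(frozen=True)
class SegMetrics:
    dice: float
    precision: float
    recall: float


@dataclass(frozen=True)
class DetectionResult:
    """Per-segment detection flags plus the detected diameter range."""

    segments: tuple[dict, ...]   # index, diameter, n_pixels, n_hit, detected
    min_detected_diameter: float | None
    max_detected_diameter: float | None


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    config: SegmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random flip / 90-degree rotation / shift on both, color shift on image.

    Geometric transforms are exact (no interpolation), so the mask stays
    binary.  With zero amplitudes, zero flip probabilities and ``(0,)``
    rotations the pair passes through unchanged.
    """
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask must share spatial shape")
    img, m = image.copy(), mask.copy()
    if rng.random() < config.flip_lr_prob:
        img, m = img[:, ::-1], m[:, ::-1]
    if rng.random() < config.flip_ud_prob:
        img, m = img[::-1], m[::-1]
    rot = config.rotations[rng.integers(len(config.rotations))]
    k = (rot // 90) % 4
    if k:
        img, m = np.rot90(img, k), np.rot90(m, k)
    if config.spatial_shift > 0:
        s = int(config.spatial_shift)
        dr, dc = int(rng.integers(-s, s + 1)), int(rng.integers(-s, s + 1))
        img = np.roll(np.roll(img, dr, axis=0), dc, axis=1)
        m = np.roll(np.roll(m, dr, axis=0), dc, axis=1)
    if config.color_shift > 0:
        shift = rng.uniform(-config.color_shift, config.color_shift, size=(3,))
        img = np.clip(img.astype(np.float64) + shift, 0, 255).astype(image.dtype)
    return np.ascontiguousarray(img), np.ascontiguousarray(m)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _unpack(sample):
    """Accept (image, mask) tuples or objects with .image / .truth_mask."""
    if hasattr(sample, "image") and hasattr(sample, "truth_mask"):
        return sample.image, sample.truth_mask
    img, mask = sample
    return img, mask


def _to_net_input(image: np.ndarray) -> np.ndarray:
    """(H, W, 3) uint8 -> (3, H, W) float32 in roughly [-0.5, 0.5]."""
    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 2:
        x = np.stack([x] * 3, axis=-1)
    return (x / 255.0 - 0.5).transpose(2, 0, 1)


def _random_crop(img, mask, size, rng):
    H, W = mask.shape
    if H < size or W < size:
        pr, pc = max(size - H, 0), max(size - W, 0)
        img = np.pad(img, ((0, pr), (0, pc), (0, 0)), mode="reflect")
        mask = np.pad(mask, ((0, pr), (0, pc)), mode="reflect")
        H, W = mask.shape
    r = int(rng.integers(0, H - size + 1))
    c = int(rng.integers(0, W - size + 1))
    return img[r:r + size, c:c + size], mask[r:r + size, c:c + size]


def _val_dice(net: UNet, val_pairs, config) -> float:
    tp = fp = fn = 0
    for img, mask in val_pairs:
        score = _predict_net(net, img, config)
        pred = score >= config.threshold
        truth = mask.astype(bool)
        tp += int((pred & truth).sum())
        fp += int((pred & ~truth).sum())
        fn += int((~pred & truth).sum())
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def train_segmenter(
    train_samples: Sequence,
    val_samples: Sequence,
    config: SegmentationConfig | None = None,
    init: ModelState | None = None,
) -> tuple[ModelState, TrainingLog]:
    """Train (or fine-tune) the segmenter with early stopping.

    Each epoch draws ``crops_per_image`` augmented random crops from every
    training sample, optimizes weighted binary cross-entropy with Adam, and
    evaluates pooled Dice on the validation set; the best-Dice checkpoint is
    returned.  When ``init`` is given its weights are the starting point and
    the learning rate is reduced tenfold (fine-tuning mode).  Fully
    reproducible for a fixed config seed.
    """
    config = config or SegmentationConfig()
    if len(train_samples) == 0:
        raise ValueError("training set is empty")
    if len(val_samples) == 0:
        raise ValueError("validation set is empty")
    train_pairs = [_unpack(s) for s in train_samples]
    val_pairs = [_unpack(s) for s in val_samples]
    for img, mask in train_pairs + val_pairs:
        if img.shape[:2] != mask.shape[:2]:
            raise ValueError("sample image/mask shape mismatch")

    rng = np.random.default_rng(config.seed)
    if init is not None:
        net = init.build()
        lr = config.learning_rate * 0.1
    else:
        net = UNet(in_ch=3, depth=config.depth, base=config.base_channels,
                   seed=int(rng.integers(2 ** 31)))
        lr = config.learning_rate
    opt = Adam(net.params(), lr=lr)

    log = TrainingLog()
    best_weights = net.get_weights()
    since_best = 0
    for epoch in range(config.max_epochs):
        crops = []
        for img, mask in train_pairs:
            for _ in range(config.crops_per_image):
                ai, am = augment_pair(img, mask, config, rng)
                ci, cm = _random_crop(ai, am, config.crop_size, rng)
                crops.append((ci, cm))
        order = rng.permutation(len(crops))
        losses = []
        for b0 in range(0, len(order), config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            x = np.stack([_to_net_input(crops[i][0]) for i in idx])
            y = np.stack([crops[i][1].astype(np.float32)[None] for i in idx])
            logits = net.forward(x, train=True)
            loss, dlogits = bce_with_logits(logits, y, config.pos_weight)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss!r}; "
                    "reduce the learning rate"
                )
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        vd = _val_dice(net, val_pairs, config)
        log.epochs.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_dice": vd}
        )
        if vd > log.best_val_dice:
            log.best_val_dice = vd
            log.best_epoch = epoch
            best_weights = net.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                log.stopped_early = True
                break

    state = ModelState(
        depth=config.depth,
        base_channels=config.base_channels,
        in_channels=3,
        weights=best_weights,
        config_hash=config.hash(),
        epochs_run=len(log.epochs),
        best_val_dice=log.best_val_dice,
    )
    return state, log


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _forward_scores(net: UNet, image: np.ndarray) -> np.ndarray:
    """Single forward pass; pads to the network stride and crops back."""
    H, W = image.shape[:2]
    s = net.stride
    ph, pw = (-H) % s, (-W) % s
    img = image
    if ph or pw:
        img = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    x = _to_net_input(img)[None]
    logits = net.forward(x, train=False)
    return sigmoid(logits[0, 0])[:H, :W]


def _feather_weights(size: int, overlap: int) -> np.ndarray:
    ramp = np.minimum(np.arange(1, size + 1), overlap) / overlap
    w = np.minimum(ramp, ramp[::-1]).astype(np.float64)
    return np.outer(w, w)


def _predict_net(
    net: UNet, image: np.ndarray, config: SegmentationConfig
) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    H, W = image.shape[:2]
    ts, ov = config.tile_size, config.tile_overlap
    if H <= ts and W <= ts:
        return _forward_scores(net, image)
    # pad up to at least one tile, then slide with overlap
    ph, pw = max(ts - H, 0), max(ts - W, 0)
    img = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect") if ph or pw \
        else image
    Hp, Wp = img.shape[:2]
    step = ts - ov

    def _starts(total):
        ss = list(range(0, max(total - ts, 0) + 1, step))
        if ss[-1] != total - ts:
            ss.append(total - ts)
        return ss

    wtile = _feather_weights(ts, max(ov, 1))
    num = np.zeros((Hp, Wp), dtype=np.float64)
    den = np.zeros((Hp, Wp), dtype=np.float64)
    for r in _starts(Hp):
        for c in _starts(Wp):
            tile = img[r:r + ts, c:c + ts]
            sc = _forward_scores(net, tile)
            num[r:r + ts, c:c + ts] += sc * wtile
            den[r:r + ts, c:c + ts] += wtile
    return (num / den)[:H, :W]


def predict_scoremap(
    model: ModelState | UNet,
    image: np.ndarray,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Per-pixel vessel scores in [0, 1], same shape as the input image."""
    config = config or SegmentationConfig()
    net = model.build() if isinstance(model, ModelState) else model
    score = _predict_net(net, image, config)
    return np.clip(score, 0.0, 1.0).astype(np.float32)


def binarize(score_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Vessel mask: score >= threshold (inclusive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    score_map = np.asarray(score_map)
    if score_map.min() < 0 or score_map.max() > 1:
        raise ValueError("score map values must lie in [0, 1]")
    return score_map >= threshold


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _counts(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int]:
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    return tp, fp, fn


def _metrics_from_counts(tp: int, fp: int, fn: int) -> SegMetrics:
    if tp == 0 and fp == 0 and fn == 0:
        return SegMetrics(1.0, 1.0, 1.0)  # both masks empty
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    dice = 2 * tp / (2 * tp + fp + fn)
    return SegMetrics(float(dice), float(precision), float(recall))


def evaluate_segmentation(pred_mask: np.ndarray, truth_mask: np.ndarray) -> SegMetrics:
    """Pixel-wise Dice / precision / recall of one prediction."""
    return _metrics_from_counts(*_counts(pred_mask, truth_mask))


def pooled_metrics(pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> SegMetrics:
    """Metrics with TP/FP/FN pooled over many (pred, truth) pairs."""
    tp = fp = fn = 0
    for pred, truth in pairs:
        a, b, c = _counts(pred, truth)
        tp, fp, fn = tp + a, fp + b, fn + c
    return _metrics_from_counts(tp, fp, fn)


def per_vessel_detection(pred_mask: np.ndarray, tree) -> DetectionResult:
    """Flag each superficial segment as detected and report the diameter range.

    A segment counts as detected when at least half of its own rasterized
    pixels are predicted vessel.  Diameters are arc-length-weighted means
    per segment.
    """
    from .synthetic import segment_pixel_counts

    pred = np.asarray(pred_mask).astype(bool)
    if pred.shape != tuple(tree.canvas_size):
        raise ValueError(
            f"mask shape {pred.shape} does not match tree canvas {tree.canvas_size}"
        )
    rows = []
    detected_d = []
    for idx, diam, n_px, n_hit in segment_pixel_counts(tree, pred):
        det = n_px > 0 and n_hit >= 0.5 * n_px
        rows.append(
            {"index": idx, "diameter": diam, "n_pixels": n_px,
             "n_hit": n_hit, "detected": det}
        )
        if det:
            detected_d.append(diam)
    return DetectionResult(
        segments=tuple(rows),
        min_detected_diameter=min(detected_d) if detected_d else None,
        max_detected_diameter=max(detected_d) if detected_d else None,
    )
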