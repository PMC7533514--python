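"""Stage-I multi-head network and training procedure, plus the small
abnormality classifier.

Architecture
------------
A shared **Encoder** turns the input photo into a feature pyramid
f1..f5 at downsample factors 1/2/4/8/16 and channel widths W..16W:
Conv-1 (stride-1 Conv-BN-ReLU), Conv-2 (stride-2 Conv-BN-ReLU), then
three residual "Res conv" blocks, each with a stride-2 and a stride-1
3x3 convolution (1x1 projection shortcut), halving resolution and
doubling width.  Three heads consume the pyramid:

* **SegDecoder** — four expanding blocks; each upsamples 2x with a
  transposed convolution, concatenates the matching encoder map, and
  convolves; a 1x1 score layer and channel softmax yield 4-class
  per-pixel probabilities at input resolution.  Trained with the
  multi-class dice loss.
* **Classification Subnet** — one Res conv block on f5, then two fully
  connected layers and a softmax over {fetal, maternal}.  Operates on
  the disc crop.  Trained with 2-class cross-entropy.
* **IPDecoder** — two expanding blocks over {f5, f4, f3} with a 1x1
  score layer after each block, producing one-channel insertion-point
  heatmaps at 1/8 and 1/4 of the crop (intermediate supervision);
  summed MSE against Gaussian ground truth regenerated per resolution.

Training runs in three phases: (1) Encoder+SegDecoder from scratch;
(2) Classification Subnet with the encoder frozen; (3) IPDecoder with
the encoder frozen.  SGD uses lr 0.1, momentum 0.9, weight decay
5e-4; batch 2 for segmentation and 10 for the other heads.  "From
scratch" means no pretraining: weights are He-initialized from the run
seed (an all-zero start cannot break symmetry in a conv net) and
biases start at zero.

The base width ``W`` (channel multiplier) and input resolution are
configurable; the clinical-scale setting is W=64 at 768x1024 photos
with 512x512 crops, while tests run W=8 at 128x128.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize, rotate

from . import nn
from .heatmaps import gaussian_heatmap
from .metrics import KeypointEval, confusion, mean_iou, pck
from .nn import core
from .scene import DISC, Scene

__all__ = [
    "Stage1Model", "CroppedDisc", "build_stage1", "crop_disc", "augment",
    "train_stage1", "TrainConfig", "build_small_classifier", "mask_nondisc",
    "save_checkpoint", "load_checkpoint",
]

SIDES = ("fetal", "maternal")


# ---------------------------------------------------------------------------
# blocks


class ResConvBlock(nn.Module):
    """Residual block: stride-2 then stride-1 3x3 conv, halving the
    resolution and (by default) doubling the channels."""

    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, stride=2)
        self.bn1 = nn.BatchNorm2d(cout)
        self.relu = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, stride=1)
        self.bn2 = nn.BatchNorm2d(cout)
        self.proj = nn.Conv2d(cin, cout, 1, rng, stride=2, pad=0)
        self.bn_proj = nn.BatchNorm2d(cout)

    def forward(self, x):
        y = self.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        s = self.bn_proj(self.proj(x))
        return self.relu(core.add(y, s))


class Encoder(nn.Module):
    def __init__(self, width: int, rng, in_channels: int = 3):
        super().__init__()
        W = width
        self.conv1 = nn.Sequential(nn.Conv2d(in_channels, W, 3, rng, stride=1),
                                   nn.BatchNorm2d(W), nn.ReLU())
        self.conv2 = nn.Sequential(nn.Conv2d(W, 2 * W, 3, rng, stride=2),
                                   nn.BatchNorm2d(2 * W), nn.ReLU())
        self.res3 = ResConvBlock(2 * W, 4 * W, rng)
        self.res4 = ResConvBlock(4 * W, 8 * W, rng)
        self.res5 = ResConvBlock(8 * W, 16 * W, rng)

    def forward(self, x):
        f1 = self.conv1(x)
        f2 = self.conv2(f1)
        f3 = self.res3(f2)
        f4 = self.res4(f3)
        f5 = self.res5(f4)
        return [f1, f2, f3, f4, f5]


class ExpandBlock(nn.Module):
    """Upsample 2x, concatenate the skip feature map, convolve."""

    def __init__(self, cin: int, cskip: int, cout: int, rng):
        super().__init__()
        self.up = nn.ConvTranspose2x(cin, cout, rng)
        self.conv = nn.Conv2d(cout + cskip, cout, 3, rng)
        self.bn = nn.BatchNorm2d(cout)
        self.relu = nn.ReLU()

    def forward(self, x, skip):
        y = core.concat([self.up(x), skip], axis=1)
        return self.relu(self.bn(self.conv(y)))


class SegDecoder(nn.Module):
    def __init__(self, width: int, rng, num_classes: int = 4):
        super().__init__()
        W = width
        self.b4 = ExpandBlock(16 * W, 8 * W, 8 * W, rng)
        self.b3 = ExpandBlock(8 * W, 4 * W, 4 * W, rng)
        self.b2 = ExpandBlock(4 * W, 2 * W, 2 * W, rng)
        self.b1 = ExpandBlock(2 * W, W, W, rng)
        self.score = nn.Conv2d(W, num_classes, 1, rng, pad=0)

    def forward(self, fs):
        f1, f2, f3, f4, f5 = fs
        y = self.b4(f5, f4)
        y = self.b3(y, f3)
        y = self.b2(y, f2)
        y = self.b1(y, f1)
        return core.softmax_channels(self.score(y))


class ClassificationSubnet(nn.Module):
    def __init__(self, width: int, crop_size: int, rng, fc_width: int = 256):
        super().__init__()
        W = width
        self.res = ResConvBlock(16 * W, 32 * W, rng)
        spatial = crop_size // 32
        self.flat = nn.Flatten()
        self.fc1 = nn.Linear(32 * W * spatial * spatial, fc_width, rng)
        self.relu = nn.ReLU()
        self.fc2 = nn.Linear(fc_width, 2, rng)

    def forward(self, f5):
        y = self.flat(self.res(f5))
        return self.fc2(self.relu(self.fc1(y)))      # logits over SIDES


class IPDecoder(nn.Module):
    def __init__(self, width: int, rng):
        super().__init__()
        W = width
        self.b1 = ExpandBlock(16 * W, 8 * W, 8 * W, rng)
        self.score1 = nn.Conv2d(8 * W, 1, 1, rng, pad=0)
        self.b2 = ExpandBlock(8 * W, 4 * W, 4 * W, rng)
        self.score2 = nn.Conv2d(4 * W, 1, 1, rng, pad=0)

    def forward(self, fs):
        f1, f2, f3, f4, f5 = fs
        y1 = self.b1(f5, f4)
        h1 = self.score1(y1)                         # 1/8 resolution
        y2 = self.b2(y1, f3)
        h2 = self.score2(y2)                         # 1/4 resolution
        return h1, h2


class Stage1Model(nn.Module):
    def __init__(self, width: int = 64, crop_size: int = 512, rng=None,
                 num_classes: int = 4):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.width = width
        self.crop_size = crop_size
        self.num_classes = num_classes
        self.encoder = Encoder(width, rng)
        self.seg = SegDecoder(width, rng, num_classes)
        self.side = ClassificationSubnet(width, crop_size, rng)
        self.ip = IPDecoder(width, rng)

    # -- heads --------------------------------------------------------------

    def forward_seg(self, x: core.Tensor) -> core.Tensor:
        self._check_divisible(x)
        return self.seg(self.encoder(x))

    def forward_side(self, xc: core.Tensor) -> core.Tensor:
        self._check_divisible(xc)
        return self.side(self.encoder(xc)[4])

    def forward_ip(self, xc: core.Tensor):
        self._check_divisible(xc)
        return self.ip(self.encoder(xc))

    @staticmethod
    def _check_divisible(x) -> None:
        H, W = x.data.shape[2], x.data.shape[3]
        if H % 16 or W % 16:
            raise ValueError(f"input {H}x{W} must be divisible by 16")

    # -- inference helpers --------------------------------------------------

    def predict_labels(self, image: np.ndarray) -> np.ndarray:
        """Argmax 4-class label map for one H x W x 3 uint8 image."""
        self.eval()
        x = core.Tensor(_to_input(image))
        p = self.forward_seg(x)
        return np.argmax(p.data[0], axis=0).astype(np.uint8)

    def predict_side(self, crop_image: np.ndarray) -> str:
        self.eval()
        logits = self.forward_side(core.Tensor(_to_input(crop_image)))
        return SIDES[int(np.argmax(logits.data[0]))]

    def predict_insertion(self, crop: "CroppedDisc") -> tuple[float, float]:
        """Insertion point in source-image coordinates."""
        self.eval()
        _, h2 = self.forward_ip(core.Tensor(_to_input(crop.image)))
        hm = h2.data[0, 0]
        r, c = np.unravel_index(int(np.argmax(hm)), hm.shape)
        scale = crop.image.shape[0] / hm.shape[0]
        return crop.point_from_crop(((r + 0.5) * scale, (c + 0.5) * scale))


def _to_input(image: np.ndarray) -> np.ndarray:
    """HWC uint8 -> 1CHW float32 in [-0.5, 0.5]."""
    x = image.astype(np.float32) / 255.0 - 0.5
    return np.moveaxis(x, -1, 0)[None]


def build_stage1(base_width: int = 64, crop_size: int = 512,
                 num_classes: int = 4, seed: int = 0) -> Stage1Model:
    """Construct the multi-head Stage-I model with seeded He init."""
    if base_width < 4:
        raise ValueError("base width must be at least 4")
    return Stage1Model(width=base_width, crop_size=crop_size,
                       rng=np.random.default_rng(seed), num_classes=num_classes)


# ---------------------------------------------------------------------------
# disc crop


@dataclass
class CroppedDisc:
    """A square resized crop around the disc with its source box."""

    image: np.ndarray                       # out x out x C
    crop_box: tuple[int, int, int, int]     # (row0, col0, row1, col1), half-open

    def point_to_crop(self, point: tuple[float, float]) -> tuple[float, float]:
        r0, c0, r1, c1 = self.crop_box
        out = self.image.shape[0]
        return ((point[0] - r0) * out / (r1 - r0),
                (point[1] - c0) * out / (c1 - c0))

    def point_from_crop(self, point: tuple[float, float]) -> tuple[float, float]:
        r0, c0, r1, c1 = self.crop_box
        out = self.image.shape[0]
        return (point[0] * (r1 - r0) / out + r0,
                point[1] * (c1 - c0) / out + c0)


def crop_disc(image: np.ndarray, label_map: np.ndarray, out_size: int = 512,
              margin_frac: float = 0.05) -> CroppedDisc:
    """Square crop of the disc bounding box (plus margin), resized.

    The box is the tight bounding rectangle of the disc class expanded
    by ``margin_frac`` of its size, made square, and clipped to the
    image; during training the ground-truth map supplies it, at
    inference the predicted map does.
    """
    disc = np.asarray(label_map) == DISC
    if not disc.any():
        raise ValueError("no disc pixels: segmentation unusable for cropping")
    rows, cols = np.nonzero(disc)
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    mr = int(round((r1 - r0) * margin_frac))
    mc = int(round((c1 - c0) * margin_frac))
    r0, r1 = r0 - mr, r1 + mr
    c0, c1 = c0 - mc, c1 + mc
    # square the box around its center
    side = max(r1 - r0, c1 - c0)
    rc, cc = (r0 + r1) / 2.0, (c0 + c1) / 2.0
    r0, r1 = int(round(rc - side / 2.0)), int(round(rc + side / 2.0))
    c0, c1 = int(round(cc - side / 2.0)), int(round(cc + side / 2.0))
    H, W = disc.shape
    r0, r1 = max(r0, 0), min(r1, H)
    c0, c1 = max(c0, 0), min(c1, W)
    patch = image[r0:r1, c0:c1]
    out = resize(patch, (out_size, out_size), order=1, preserve_range=True,
                 anti_aliasing=False)
    return CroppedDisc(image=out.astype(image.dtype), crop_box=(r0, c0, r1, c1))


# ---------------------------------------------------------------------------
# augmentation


def augment(sample: dict, seed: int, max_rotation_deg: float = 30.0) -> dict:
    """Random rotation (+-30 deg) and horizontal/vertical flips.

    ``sample`` maps names to aligned targets: ``image`` (HWC float or
    uint8), optional ``label_map`` (HW int, nearest-neighbor), optional
    ``keypoints`` (list of (row, col)).  The identical geometric
    transform is applied to every entry.
    """
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    flip_h = rng.random() < 0.5
    flip_v = rng.random() < 0.5
    out = {}
    img = sample["image"]
    H, W = img.shape[:2]

    def tf_array(a, order):
        b = rotate(a.astype(float), angle, order=order, preserve_range=True,
                   mode="constant", cval=0.0)
        if flip_h:
            b = b[:, ::-1]
        if flip_v:
            b = b[::-1, :]
        return b

    out["image"] = tf_array(img, 1).astype(img.dtype)
    if "label_map" in sample:
        out["label_map"] = np.round(
            tf_array(sample["label_map"], 0)).astype(sample["label_map"].dtype)
    if "keypoints" in sample:
        # skimage rotates counterclockwise about the center in (x, y);
        # in (row, col) that is a clockwise rotation of coordinates
        th = np.deg2rad(angle)
        cr, cc = (H - 1) / 2.0, (W - 1) / 2.0
        pts = []
        for (r, c) in sample["keypoints"]:
            dr, dc = r - cr, c - cc
            r2 = cr + dr * np.cos(th) - dc * np.sin(th)
            c2 = cc + dr * np.sin(th) + dc * np.cos(th)
            if flip_h:
                c2 = W - 1 - c2
            if flip_v:
                r2 = H - 1 - r2
            pts.append((r2, c2))
        out["keypoints"] = pts
    return out


def mask_nondisc(image: np.ndarray, label_map: np.ndarray) -> np.ndarray:
    """Zero every pixel not classified as disc (all channels)."""
    if image.shape[:2] != label_map.shape:
        raise ValueError("image and label map sizes differ")
    out = image.copy()
    out[label_map != DISC] = 0
    return out


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the published schedule."""

    lr: float = 0.1
    side_lr: float = 0.01
    ip_lr: float = 0.03
    momentum: float = 0.9
    weight_decay: float = 5e-4
    seg_batch: int = 2
    head_batch: int = 10
    seg_epochs: int = 30
    side_epochs: int = 10
    ip_epochs: int = 10
    heatmap_sigma_at_512: float = 7.0
    heatmap_sigma_floor: float = 2.0
    use_augmentation: bool = True
    val_fraction: float = 0.2


def _heatmap_sigma(cfg: TrainConfig, res: int) -> float:
    return max(cfg.heatmap_sigma_at_512 * res / 512.0, cfg.heatmap_sigma_floor)


def _scene_tensors(scene: Scene, size: int, aug_seed: int | None):
    img = scene.image
    lm = scene.label_map
    if aug_seed is not None:
        s = augment({"image": img, "label_map": lm}, aug_seed)
        img, lm = s["image"], s["label_map"]
    if img.shape[0] != size or img.shape[1] != size:
        img = resize(img.astype(float), (size, size), order=1,
                     preserve_range=True, anti_aliasing=False)
        lm = resize(lm.astype(float), (size, size), order=0,
                    preserve_range=True, anti_aliasing=False)
    x = _to_input(np.asarray(img))
    onehot = np.moveaxis(np.eye(4, dtype=np.float32)[np.asarray(lm).astype(int)], -1, 0)[None]
    return x, onehot, np.asarray(lm).astype(np.uint8)


def _crop_and_heatmaps(scene: Scene, crop_size: int, cfg: TrainConfig,
                       aug_seed: int | None):
    img, lm = scene.image, scene.label_map
    kp = list(scene.truth.insertion_point) if scene.truth.insertion_point else None
    if aug_seed is not None:
        s = {"image": img, "label_map": lm}
        if kp is not None:
            s["keypoints"] = [tuple(kp)]
        s = augment(s, aug_seed)
        img, lm = s["image"], s["label_map"]
        if kp is not None:
            kp = list(s["keypoints"][0])
    if not (lm == DISC).any():
        return None
    crop = crop_disc(img, lm, out_size=crop_size)
    x = _to_input(crop.image)
    heatmaps = None
    if kp is not None:
        rc = crop.point_to_crop((kp[0], kp[1]))
        heatmaps = []
        for factor in (8, 4):
            res = crop_size // factor
            center = (rc[0] / factor, rc[1] / factor)
            if not (0 <= center[0] < res and 0 <= center[1] < res):
                return None
            hm = gaussian_heatmap(center, _heatmap_sigma(cfg, res), (res, res))
            heatmaps.append(hm.values.astype(np.float32)[None, None])
    return x, crop, heatmaps


def train_stage1(model: Stage1Model, scenes: list[Scene],
                 cfg: TrainConfig | None = None, seed: int = 0,
                 phases: tuple[int, ...] = (1, 2, 3),
                 size: int | None = None) -> dict:
    """Three-phase staged training; returns the history dict.

    Phase 1 trains Encoder+SegDecoder with the dice loss; phases 2/3
    train the Classification Subnet and IPDecoder with the encoder
    frozen (its weights are bit-identical before and after).  History
    entries carry per-epoch training loss and validation metrics; the
    best validation checkpoint per phase is restored at the end of the
    phase.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(seed)
    size = size or scenes[0].image.shape[0]
    n_val = max(int(len(scenes) * cfg.val_fraction), 1) if len(scenes) > 1 else 0
    order = rng.permutation(len(scenes))
    val_idx = [int(i) for i in order[:n_val]]
    train_idx = [int(i) for i in order[n_val:]] or val_idx
    history: dict = {"phase1": [], "phase2": [], "phase3": []}

    if 1 in phases:
        _train_seg_phase(model, scenes, train_idx, val_idx, cfg, rng, size,
                         history["phase1"])
        model._phase1_done = True
    if 2 in phases or 3 in phases:
        if not getattr(model, "_phase1_done", False):
            raise RuntimeError("phases 2/3 require phase-1 weights: run "
                               "phase 1 first")
        enc_params = set(id(p) for p in model.encoder.parameters())
        for p in model.encoder.parameters():
            p.requires_grad = False
        try:
            if 2 in phases:
                _train_side_phase(model, scenes, train_idx, val_idx, cfg, rng,
                                  history["phase2"])
            if 3 in phases:
                _train_ip_phase(model, scenes, train_idx, val_idx, cfg, rng,
                                history["phase3"])
        finally:
            for p in model.encoder.parameters():
                if id(p) in enc_params:
                    p.requires_grad = True
    return history


def _train_seg_phase(model, scenes, train_idx, val_idx, cfg, rng, size, log):
    params = model.encoder.parameters() + model.seg.parameters()
    opt = nn.SGD(params, lr=cfg.lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    best = (-1.0, None)
    for epoch in range(cfg.seg_epochs):
        model.train()
        idx = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(idx), cfg.seg_batch):
            batch = idx[start:start + cfg.seg_batch]
            xs, gs = [], []
            for i in batch:
                aug_seed = int(rng.integers(2 ** 31)) if cfg.use_augmentation else None
                x, onehot, _ = _scene_tensors(scenes[i], size, aug_seed)
                xs.append(x)
                gs.append(onehot)
            x = core.Tensor(np.concatenate(xs, axis=0))
            g = np.concatenate(gs, axis=0)
            p = model.forward_seg(x)
            loss = core.dice_loss(p, g)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        miou = _validate_seg(model, scenes, val_idx, size) if val_idx else None
        log.append({"epoch": epoch, "loss": float(np.mean(losses)),
                    "val_mean_iou": miou})
        if miou is not None and miou > best[0]:
            best = (miou, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])


def _validate_seg(model, scenes, val_idx, size):
    model.eval()
    cms = None
    for i in val_idx:
        x, _, lm = _scene_tensors(scenes[i], size, None)
        p = model.forward_seg(core.Tensor(x))
        pred = np.argmax(p.data[0], axis=0)
        cm = confusion(pred, lm, 4)
        cms = cm.counts if cms is None else cms + cm.counts
    from .metrics import ConfusionMatrix
    return mean_iou(ConfusionMatrix(cms))


def _train_side_phase(model, scenes, train_idx, val_idx, cfg, rng, log):
    opt = nn.SGD(model.side.parameters(), lr=cfg.side_lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    best = (-1.0, None)
    for epoch in range(cfg.side_epochs):
        model.train()
        model.encoder.eval()     # frozen: a fixed feature extractor
        idx = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(idx), cfg.head_batch):
            batch = idx[start:start + cfg.head_batch]
            xs, ys = [], []
            for i in batch:
                aug_seed = int(rng.integers(2 ** 31)) if cfg.use_augmentation else None
                got = _crop_and_heatmaps(scenes[i], model.crop_size, cfg, aug_seed)
                if got is None:
                    continue
                xs.append(got[0])
                ys.append(SIDES.index(scenes[i].truth.side))
            if not xs:
                continue
            logits = model.forward_side(core.Tensor(np.concatenate(xs, axis=0)))
            loss = core.cross_entropy(logits, np.asarray(ys))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        acc = _validate_side(model, scenes, val_idx, cfg) if val_idx else None
        log.append({"epoch": epoch, "loss": float(np.mean(losses)),
                    "val_accuracy": acc})
        if acc is not None and acc > best[0]:
            best = (acc, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])


def _validate_side(model, scenes, val_idx, cfg):
    model.eval()
    hits = []
    for i in val_idx:
        got = _crop_and_heatmaps(scenes[i], model.crop_size, cfg, None)
        if got is None:
            continue
        pred = model.predict_side(got[1].image)
        hits.append(pred == scenes[i].truth.side)
    return float(np.mean(hits)) if hits else None


def _train_ip_phase(model, scenes, train_idx, val_idx, cfg, rng, log):
    fetal = [i for i in train_idx
             if scenes[i].truth.insertion_point is not None]
    opt = nn.SGD(model.ip.parameters(), lr=cfg.ip_lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    best = (-1.0, None)
    for epoch in range(cfg.ip_epochs):
        model.train()
        model.encoder.eval()     # frozen: a fixed feature extractor
        idx = rng.permutation(fetal)
        losses = []
        for start in range(0, len(idx), cfg.head_batch):
            batch = idx[start:start + cfg.head_batch]
            xs, h1s, h2s = [], [], []
            for i in batch:
                aug_seed = int(rng.integers(2 ** 31)) if cfg.use_augmentation else None
                got = _crop_and_heatmaps(scenes[i], model.crop_size, cfg, aug_seed)
                if got is None or got[2] is None:
                    continue
                xs.append(got[0])
                h1s.append(got[2][0])
                h2s.append(got[2][1])
            if not xs:
                continue
            # pixel-averaged MSE: the summed two-head objective rescaled by
            # a constant so the step size is resolution-independent
            h1, h2 = model.forward_ip(core.Tensor(np.concatenate(xs, axis=0)))
            loss = core.add(core.mse_mean(h1, np.concatenate(h1s, axis=0)),
                            core.mse_mean(h2, np.concatenate(h2s, axis=0)))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        p = _validate_ip(model, scenes, val_idx, cfg) if val_idx else None
        log.append({"epoch": epoch, "loss": float(np.mean(losses)) if losses else None,
                    "val_pck01": p})
        if p is not None and p > best[0]:
            best = (p, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])


def _validate_ip(model, scenes, val_idx, cfg):
    model.eval()
    truths, preds, norms = [], [], []
    for i in val_idx:
        scene = scenes[i]
        if scene.truth.insertion_point is None:
            continue
        got = _crop_and_heatmaps(scene, model.crop_size, cfg, None)
        if got is None:
            continue
        pred = model.predict_insertion(got[1])
        truths.append(tuple(scene.truth.insertion_point))
        preds.append(pred)
        norms.append(2.0 * max(scene.truth.disc_semi_axes))
    if not truths:
        return None
    curve = pck(KeypointEval(truths, preds, norms, grid=[0.1]))
    return curve[0][1]


# ---------------------------------------------------------------------------
# small abnormality classifier


def build_small_classifier(input_size: int = 200, seed: int = 0,
                           in_channels: int = 3) -> nn.Sequential:
    """6-layer CNN: four conv/pool stages (3x3 valid, stride 1, 2x2 max
    pool) with 32/64/128/256 channels, then FC-1024 and FC-1 with a
    sigmoid output.  With a 200x200 input the stage outputs are 99, 48,
    23 and 10 px square — the only ladder the architecture prints."""
    sizes = []
    s = input_size
    for _ in range(4):
        s = (s - 2) // 2
        sizes.append(s)
    if sizes != [99, 48, 23, 10]:
        raise ValueError(
            f"input size {input_size} gives conv/pool ladder {sizes}; "
            "use 200 to reproduce 99/48/23/10")
    rng = np.random.default_rng(seed)
    chans = [in_channels, 32, 64, 128, 256]
    layers: list[nn.Module] = []
    for cin, cout in zip(chans[:-1], chans[1:]):
        layers += [nn.Conv2d(cin, cout, 3, rng, stride=1, pad=0), nn.ReLU(),
                   nn.MaxPool2x()]
    layers += [nn.Flatten(), nn.Linear(10 * 10 * 256, 1024, rng), nn.ReLU(),
               nn.Linear(1024, 1, rng)]
    return nn.Sequential(*layers)


def small_classifier_prob(model: nn.Sequential, image: np.ndarray) -> float:
    """Sigmoid probability for one HWC image."""
    model.eval()
    logit = model(core.Tensor(_to_input(image)))
    return float(1.0 / (1.0 + np.exp(-logit.data[0, 0])))


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: Stage1Model, path) -> None:
    """Native .npz weights plus a JSON architecture sidecar inside."""
    meta = {"width": model.width, "crop_size": model.crop_size,
            "num_classes": model.num_classes,
            "phase1_done": bool(getattr(model, "_phase1_done", False))}
    state = model.state_dict()
    np.savez_compressed(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> Stage1Model:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    model = build_stage1(base_width=meta["width"], crop_size=meta["crop_size"],
                         num_classes=meta["num_classes"], seed=0)
    state = {k: data[k] for k in data.files if k != "__meta__"}
    model.load_state_dict(state)
    model._phase1_done = meta["phase1_done"]
    return model
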