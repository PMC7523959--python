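"""Two-stage detection/segmentation network with feature pyramid fusion.

Three architecture variants share the same two-stage skeleton (region
proposal network → RoI-aligned box/class/mask heads on a feature pyramid):

* ``cell_only`` — one 1-channel backbone over the cytoplasm image;
* ``early_fusion`` — one 2-channel backbone over the stacked nucleus +
  cytoplasm images;
* ``fpf`` — feature pyramid fusion: a nucleus detector is trained first,
  its feature pyramid is frozen, and every cell pyramid level is merged
  with the corresponding nucleus level by addition (channel counts
  unchanged) or concatenation (doubled, then projected back by a 1×1
  convolution so head shapes are merge-invariant).

The multi-task loss is ``L = L_cls + 2·L_box + 2·L_mask`` plus the RPN
terms (objectness cross-entropy and box regression, the latter also
weighted by 2); the mask loss is per-pixel sigmoid binary cross-entropy
on 28×28 crops, optionally multiplied by a border weight-map crop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.special import expit

from . import nn
from .backbone import BackboneConfig, ReducedResNet
from .core import ImagePair, InstanceSet
from .evaluation import box_iou
from .nn import (Conv2d, Linear, Module, Tensor, add, concat,
                 relu, reshape, roi_align, subsample2, take_rows,
                 transpose, upsample_nearest2, weighted_sum)

__all__ = [
    "ModelConfig", "LossBundle", "Detector", "FPN",
    "build_pyramid", "fuse_pyramids", "assign_pyramid_level",
    "rpn_propose", "compute_loss", "predict", "micro_config",
]

LEVELS = ("P2", "P3", "P4", "P5", "P6")
STRIDES = {"P2": 4, "P3": 8, "P4": 16, "P5": 32, "P6": 64}
ANCHOR_SCALES = {"P2": 32, "P3": 64, "P4": 128, "P5": 256, "P6": 512}
MASK_SIZE = 28


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "cell_only"              # {cell_only, early_fusion, fpf}
    input_channel: str = "cell"             # channel a 1-input model consumes
    merge_mode: str = "add"                 # {add, concat}; fpf only
    weighted_loss: bool = False
    pyramid_width: int = 256
    fc_dim: int = 512
    mask_channels: int = 256
    n_mask_convs: int = 4
    concat_projection: bool = True
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    rpn_nms_thresh: float = 0.7
    head_nms_thresh: float = 0.5
    score_floor: float = 0.05
    max_detections: int = 100
    rpn_pre_nms: int = 1000
    rpn_post_nms_train: int = 256
    rpn_post_nms_test: int = 300
    rpn_batch: int = 256
    rpn_pos_fraction: float = 0.5
    roi_batch: int = 512
    roi_pos_fraction: float = 0.25
    roi_pos_iou: float = 0.5
    mask_rois: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("cell_only", "early_fusion", "fpf"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.merge_mode not in ("add", "concat"):
            raise ValueError(f"merge_mode must be 'add' or 'concat'")


def micro_config(**overrides) -> ModelConfig:
    """Desk-scale configuration for small synthetic scenes (128–256 px)."""
    base = dict(
        pyramid_width=128, fc_dim=128, mask_channels=64, n_mask_convs=2,
        rpn_pre_nms=400, rpn_post_nms_train=96, rpn_post_nms_test=150,
        rpn_batch=96, roi_batch=48, mask_rois=24,
    )
    base.update(overrides)
    return ModelConfig(**base)


# ---------------------------------------------------------------------------
# boxes, anchors, NMS

def encode_boxes(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Regression deltas (dx, dy, dw, dh) taking ``anchors`` onto ``boxes``."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2
    ay = anchors[:, 1] + ah / 2
    gw = boxes[:, 2] - boxes[:, 0]
    gh = boxes[:, 3] - boxes[:, 1]
    gx = boxes[:, 0] + gw / 2
    gy = boxes[:, 1] + gh / 2
    return np.stack([(gx - ax) / aw, (gy - ay) / ah,
                     np.log(gw / aw), np.log(gh / ah)], axis=1)


def decode_boxes(deltas: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + aw / 2
    ay = anchors[:, 1] + ah / 2
    dx, dy, dw, dh = deltas.T
    dw = np.clip(dw, None, 4.0)
    dh = np.clip(dh, None, 4.0)
    cx = ax + dx * aw
    cy = ay + dy * ah
    w = aw * np.exp(dw)
    h = ah * np.exp(dh)
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def clip_boxes(boxes: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    out = boxes.copy()
    out[:, 0::2] = np.clip(out[:, 0::2], 0, w)
    out[:, 1::2] = np.clip(out[:, 1::2], 0, h)
    return out


def nms(boxes: np.ndarray, scores: np.ndarray, thresh: float) -> np.ndarray:
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        iou = box_iou(boxes[i : i + 1], boxes[rest])[0]
        order = rest[iou <= thresh]
    return np.array(keep, dtype=np.int64)


_anchor_cache: dict[tuple, np.ndarray] = {}


def level_anchors(level: str, fh: int, fw: int, ratios: tuple[float, ...]) -> np.ndarray:
    key = (level, fh, fw, ratios)
    if key not in _anchor_cache:
        stride = STRIDES[level]
        scale = ANCHOR_SCALES[level]
        ys = (np.arange(fh) + 0.5) * stride
        xs = (np.arange(fw) + 0.5) * stride
        shapes = np.array([[scale / np.sqrt(r), scale * np.sqrt(r)] for r in ratios])
        cy, cx = np.meshgrid(ys, xs, indexing="ij")
        cy = cy[:, :, None]
        cx = cx[:, :, None]
        w = shapes[None, None, :, 0]
        h = shapes[None, None, :, 1]
        anchors = np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)
        _anchor_cache[key] = anchors.reshape(-1, 4)
    return _anchor_cache[key]


def assign_pyramid_level(box: np.ndarray, image_size: tuple[int, int] | None = None) -> int:
    """FPN level for one box: ``clamp(⌊4 + log2(√(wh)/224)⌋, 2, 5)``."""
    x0, y0, x1, y1 = [float(v) for v in box]
    area = max(x1 - x0, 0.0) * max(y1 - y0, 0.0)
    if area <= 0:
        return 2
    k = int(np.floor(4 + np.log2(np.sqrt(area) / 224.0)))
    return int(np.clip(k, 2, 5))


# ---------------------------------------------------------------------------
# modules

class FPN(Module):
    """Lateral 1×1 projections + top-down nearest-neighbor pathway + 3×3 smoothing."""

    def __init__(self, rng, in_channels: tuple[int, int, int, int], width: int, name: str):
        self.width = width
        self.laterals = [
            Conv2d(rng, c, width, 1, bias=True, name=f"{name}.lateral{i + 2}")
            for i, c in enumerate(in_channels)
        ]
        self.smooth = [
            Conv2d(rng, width, width, 3, bias=True, name=f"{name}.smooth{i + 2}")
            for i in range(4)
        ]

    def __call__(self, stages: dict[str, Tensor]) -> dict[str, Tensor]:
        cs = [stages[f"C{i}"] for i in range(2, 6)]
        for lat, c in zip(self.laterals, cs):
            if lat.w.data.shape[1] != c.data.shape[1]:
                raise ValueError("stage channel count does not match lateral conv")
        tops = [self.laterals[3](cs[3])]
        for i in (2, 1, 0):
            up = upsample_nearest2(tops[-1], cs[i].data.shape[2:])
            tops.append(add(self.laterals[i](cs[i]), up))
        tops = tops[::-1]                      # index 0 ↔ P2
        pyr = {f"P{i + 2}": self.smooth[i](tops[i]) for i in range(4)}
        pyr["P6"] = subsample2(pyr["P5"])
        return pyr


def build_pyramid(stages: dict[str, Tensor], fpn: FPN) -> dict[str, Tensor]:
    """Functional wrapper: run an FPN over C2…C5 stage features."""
    return fpn(stages)


def fuse_pyramids(
    cell_pyr: dict[str, Tensor],
    nucleus_pyr: dict[str, Tensor],
    mode: str,
    projections: list[Conv2d] | None = None,
) -> dict[str, Tensor]:
    """Merge a (frozen) nucleus pyramid into the cell pyramid level-by-level."""
    fused: dict[str, Tensor] = {}
    for i, lev in enumerate(LEVELS):
        c, n = cell_pyr[lev], nucleus_pyr[lev]
        if c.data.shape[2:] != n.data.shape[2:]:
            raise ValueError(f"spatial mismatch at {lev}: {c.data.shape} vs {n.data.shape}")
        if mode == "add":
            if c.data.shape[1] != n.data.shape[1]:
                raise ValueError(f"channel mismatch at {lev} for add merge")
            fused[lev] = add(c, n)
        elif mode == "concat":
            merged = concat([c, n], axis=1)
            fused[lev] = projections[i](merged) if projections else merged
        else:
            raise ValueError(f"unknown merge mode {mode!r}")
    return fused


class RPNHead(Module):
    def __init__(self, rng, width: int, n_anchors: int, name: str):
        self.conv = Conv2d(rng, width, width, 3, bias=True, name=f"{name}.conv")
        self.obj = Conv2d(rng, width, n_anchors, 1, bias=True, name=f"{name}.obj")
        self.reg = Conv2d(rng, width, n_anchors * 4, 1, bias=True, name=f"{name}.reg")

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = relu(self.conv(x))
        return self.obj(h), self.reg(h)


class BoxHead(Module):
    def __init__(self, rng, width: int, fc_dim: int, name: str):
        self.fc1 = Linear(rng, width * 7 * 7, fc_dim, name=f"{name}.fc1")
        self.fc2 = Linear(rng, fc_dim, fc_dim, name=f"{name}.fc2")
        self.cls = Linear(rng, fc_dim, 2, name=f"{name}.cls")
        self.reg = Linear(rng, fc_dim, 4, name=f"{name}.reg")

    def __call__(self, feats: Tensor) -> tuple[Tensor, Tensor]:
        h = relu(self.fc1(nn.flatten(feats)))
        h = relu(self.fc2(h))
        return self.cls(h), self.reg(h)


class MaskHead(Module):
    def __init__(self, rng, width: int, channels: int, n_convs: int, name: str):
        self.convs = [
            Conv2d(rng, width if i == 0 else channels, channels, 3, bias=True,
                   name=f"{name}.conv{i}")
            for i in range(n_convs)
        ]
        self.up_conv = Conv2d(rng, channels, channels, 3, bias=True, name=f"{name}.upconv")
        self.logit = Conv2d(rng, channels, 1, 1, bias=True, name=f"{name}.logit")

    def __call__(self, feats: Tensor) -> Tensor:
        h = feats
        for c in self.convs:
            h = relu(c(h))
        h = relu(self.up_conv(upsample_nearest2(h)))
        return self.logit(h)                    # (R, 1, 28, 28)


@dataclass
class LossBundle:
    """Multi-task loss terms with their weights; ``total`` backpropagates."""

    rpn_cls: Tensor
    rpn_box: Tensor
    cls: Tensor
    box: Tensor
    mask: Tensor
    weights: dict[str, float] = field(
        default_factory=lambda: {"rpn_cls": 1.0, "rpn_box": 2.0, "cls": 1.0, "box": 2.0, "mask": 2.0}
    )

    @property
    def total(self) -> Tensor:
        return weighted_sum([
            (self.rpn_cls, self.weights["rpn_cls"]),
            (self.rpn_box, self.weights["rpn_box"]),
            (self.cls, self.weights["cls"]),
            (self.box, self.weights["box"]),
            (self.mask, self.weights["mask"]),
        ])

    def as_floats(self) -> dict[str, float]:
        out = {k: float(getattr(self, k).data) for k in ("rpn_cls", "rpn_box", "cls", "box", "mask")}
        out["total"] = float(sum(out[k] * self.weights[k] for k in self.weights))
        return out


def _standardize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float32)
    return (img - img.mean()) / (img.std() + 1e-6)


def _crop_mask(mask: np.ndarray, box: np.ndarray, out: int = MASK_SIZE) -> np.ndarray:
    """Binary 28×28 crop of a full-image mask over a half-open box."""
    x0, y0, x1, y1 = [float(v) for v in box]
    bh = (y1 - y0) / out
    bw = (x1 - x0) / out
    ys = y0 + (np.arange(out) + 0.5) * bh - 0.5
    xs = x0 + (np.arange(out) + 0.5) * bw - 0.5
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    vals = map_coordinates(mask.astype(np.float64), [yy.ravel(), xx.ravel()],
                           order=1, mode="constant").reshape(out, out)
    return (vals >= 0.5).astype(np.float32)


def paste_mask(prob: np.ndarray, box: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Resize a mask-space probability map into image coordinates, threshold 0.5."""
    H, W = shape
    x0, y0, x1, y1 = [float(v) for v in box]
    ix0 = max(int(np.floor(x0)), 0)
    iy0 = max(int(np.floor(y0)), 0)
    ix1 = min(int(np.ceil(x1)), W)
    iy1 = min(int(np.ceil(y1)), H)
    out = np.zeros(shape, dtype=bool)
    if ix1 <= ix0 or iy1 <= iy0:
        return out
    ms = prob.shape[0]
    py = np.arange(iy0, iy1) + 0.5
    px = np.arange(ix0, ix1) + 0.5
    my = (py - y0) / (y1 - y0) * ms - 0.5
    mx = (px - x0) / (x1 - x0) * ms - 0.5
    yy, xx = np.meshgrid(np.clip(my, 0, ms - 1), np.clip(mx, 0, ms - 1), indexing="ij")
    vals = map_coordinates(prob.astype(np.float64), [yy.ravel(), xx.ravel()],
                           order=1, mode="nearest").reshape(iy1 - iy0, ix1 - ix0)
    out[iy0:iy1, ix0:ix1] = vals >= 0.5
    return out


class Detector(Module):
    """Single-class Mask R-CNN-style detector, optionally with a fused frozen
    nucleus branch (``variant='fpf'``)."""

    def __init__(self, config: ModelConfig, nucleus_model: "Detector | None" = None,
                 prefix: str = "cell"):
        self.config = config
        self.prefix = prefix
        if config.variant == "fpf":
            if nucleus_model is None:
                raise ValueError("fpf variant requires a stage-1 nucleus model")
            if nucleus_model.config.pyramid_width != config.pyramid_width:
                raise ValueError("pyramid widths of the two branches must match")
        self.nucleus_model = nucleus_model
        if self.nucleus_model is not None:
            self.nucleus_model.freeze()
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF9F]))
        in_ch = 2 if config.variant == "early_fusion" else 1
        self.backbone = ReducedResNet(BackboneConfig(
            input_channels=in_ch, seed=config.seed, name=f"{prefix}.backbone"))
        width = config.pyramid_width
        self.fpn = FPN(rng, self.backbone.out_channels, width, name=f"{prefix}.fpn")
        self.fuse_projections: list[Conv2d] | None = None
        if config.variant == "fpf" and config.merge_mode == "concat" and config.concat_projection:
            self.fuse_projections = [
                Conv2d(rng, 2 * width, width, 1, bias=True, name=f"{prefix}.fuse_proj{i + 2}")
                for i in range(5)
            ]
        n_anchors = len(config.anchor_ratios)
        self.rpn = RPNHead(rng, width, n_anchors, name=f"{prefix}.rpn")
        head_width = width if not (
            config.variant == "fpf" and config.merge_mode == "concat"
            and not config.concat_projection
        ) else 2 * width
        self.box_head = BoxHead(rng, head_width, config.fc_dim, name=f"{prefix}.box_head")
        self.mask_head = MaskHead(rng, head_width, config.mask_channels,
                                  config.n_mask_convs, name=f"{prefix}.mask_head")
        self._train_mode = True

    # -- parameter bookkeeping -------------------------------------------------

    def freeze(self) -> None:
        for p in self.parameters():
            p.trainable = False
            p.requires_grad = False

    def set_trainable(self, prefixes: tuple[str, ...] | None) -> None:
        """Restrict trainable parameters to the given dotted-name prefixes.

        ``None`` marks everything of this model trainable.  The frozen
        nucleus branch is never touched.
        """
        nucleus_names = set()
        if self.nucleus_model is not None:
            nucleus_names = {p.name for p in self.nucleus_model.parameters()}
        for p in self.parameters():
            if p.name in nucleus_names:
                continue
            p.trainable = (
                True if prefixes is None else any(p.name.startswith(pre) for pre in prefixes)
            )

    # -- forward ---------------------------------------------------------------

    def _input_tensor(self, image_pair: ImagePair) -> Tensor:
        if self.config.variant == "early_fusion":
            stacked = np.stack([_standardize(image_pair.cell),
                                _standardize(image_pair.nucleus)])[None]
            return Tensor(stacked)
        chan = image_pair.nucleus if self.config.input_channel == "nucleus" else image_pair.cell
        return Tensor(_standardize(chan)[None, None])

    def pyramid(self, image_pair: ImagePair) -> dict[str, Tensor]:
        x = self._input_tensor(image_pair)
        pyr = self.fpn(self.backbone(x))
        if self.config.variant == "fpf":
            nuc_in = Tensor(_standardize(image_pair.nucleus)[None, None])
            nuc_pyr = self.nucleus_model.fpn(self.nucleus_model.backbone(nuc_in))
            nuc_pyr = {k: v.detach() for k, v in nuc_pyr.items()}   # frozen branch
            pyr = fuse_pyramids(pyr, nuc_pyr, self.config.merge_mode, self.fuse_projections)
        return pyr

    def rpn_forward(self, pyr: dict[str, Tensor]):
        cfg = self.config
        obj_parts, reg_parts, anchor_parts = [], [], []
        for lev in LEVELS:
            o, r = self.rpn(pyr[lev])
            _, A, fh, fw = o.data.shape
            obj_parts.append(reshape(transpose(o, (0, 2, 3, 1)), (-1,)))
            reg_parts.append(reshape(transpose(r, (0, 2, 3, 1)), (-1, 4)))
            anchor_parts.append(level_anchors(lev, fh, fw, cfg.anchor_ratios))
        return (concat(obj_parts, axis=0), concat(reg_parts, axis=0),
                np.concatenate(anchor_parts, axis=0),
                [a.shape[0] for a in anchor_parts])

    def propose(self, obj_flat: Tensor, reg_flat: Tensor, anchors: np.ndarray,
                level_sizes: list[int], image_shape: tuple[int, int],
                training: bool) -> np.ndarray:
        cfg = self.config
        post = cfg.rpn_post_nms_train if training else cfg.rpn_post_nms_test
        scores = obj_flat.data
        deltas = reg_flat.data
        offset = 0
        all_boxes, all_scores = [], []
        for n in level_sizes:
            sl = slice(offset, offset + n)
            offset += n
            s = scores[sl]
            k = min(cfg.rpn_pre_nms, n)
            top = np.argpartition(-s, k - 1)[:k] if k < n else np.arange(n)
            boxes = decode_boxes(deltas[sl][top], anchors[sl][top])
            boxes = clip_boxes(boxes, image_shape)
            wh = np.minimum(boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1])
            valid = wh >= 2
            boxes, sv = boxes[valid], s[top][valid]
            if len(boxes):
                keep = nms(boxes, sv, cfg.rpn_nms_thresh)
                all_boxes.append(boxes[keep])
                all_scores.append(sv[keep])
        if not all_boxes:
            return np.zeros((0, 4))
        boxes = np.concatenate(all_boxes)
        s = np.concatenate(all_scores)
        order = np.argsort(-s, kind="stable")[:post]
        return boxes[order]

    def _roi_features(self, pyr: dict[str, Tensor], boxes: np.ndarray, out_size: int) -> Tensor:
        """RoI-align boxes from their assigned pyramid levels, original order."""
        levels = np.array([assign_pyramid_level(b) for b in boxes])
        parts, orders = [], []
        for k in range(2, 6):
            idx = np.nonzero(levels == k)[0]
            if idx.size == 0:
                continue
            parts.append(roi_align(pyr[f"P{k}"], boxes[idx], out_size, stride=STRIDES[f"P{k}"]))
            orders.append(idx)
        feats = concat(parts, axis=0) if len(parts) > 1 else parts[0]
        order = np.concatenate(orders)
        inv = np.argsort(order)
        return take_rows(feats, inv)

    # -- training --------------------------------------------------------------

    def loss_step(self, image_pair: ImagePair, gt: InstanceSet,
                  weight_map: np.ndarray | None = None,
                  rng: np.random.Generator | None = None) -> LossBundle:
        """Forward pass and multi-task loss for one image."""
        cfg = self.config
        rng = rng or np.random.default_rng(0)
        shape = image_pair.shape
        pyr = self.pyramid(image_pair)
        obj_flat, reg_flat, anchors, level_sizes = self.rpn_forward(pyr)
        zero = Tensor(np.float32(0.0))

        gt_boxes = gt.boxes
        # ---- RPN targets
        if len(gt):
            iou = box_iou(anchors, gt_boxes)
            best_gt = iou.argmax(axis=1)
            best_iou = iou[np.arange(len(anchors)), best_gt]
            pos = best_iou >= 0.7
            for j in range(len(gt)):                 # every gt keeps its best anchor
                pos[int(iou[:, j].argmax())] = True
            neg = (best_iou < 0.3) & ~pos
        else:
            pos = np.zeros(len(anchors), dtype=bool)
            neg = np.ones(len(anchors), dtype=bool)
        pos_idx = np.nonzero(pos)[0]
        neg_idx = np.nonzero(neg)[0]
        n_pos = min(len(pos_idx), int(cfg.rpn_batch * cfg.rpn_pos_fraction))
        n_neg = min(len(neg_idx), cfg.rpn_batch - n_pos)
        pos_idx = rng.choice(pos_idx, n_pos, replace=False) if n_pos else pos_idx[:0]
        neg_idx = rng.choice(neg_idx, n_neg, replace=False) if n_neg else neg_idx[:0]
        sampled = np.concatenate([pos_idx, neg_idx])
        if sampled.size:
            labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)]).astype(np.float32)
            rpn_cls = nn.bce_with_logits(take_rows(obj_flat, sampled), labels)
        else:
            rpn_cls = zero
        if n_pos:
            targets = encode_boxes(gt_boxes[best_gt[pos_idx]], anchors[pos_idx])
            rpn_box = nn.smooth_l1(take_rows(reg_flat, pos_idx), targets, beta=1.0 / 9)
        else:
            rpn_box = zero

        # ---- proposals (+ gt boxes, standard training aid)
        proposals = self.propose(obj_flat, reg_flat, anchors, level_sizes, shape, training=True)
        if len(gt):
            proposals = np.concatenate([proposals, gt_boxes]) if len(proposals) else gt_boxes.copy()
        if len(proposals) == 0:
            return LossBundle(rpn_cls, rpn_box, zero, zero, zero)

        # ---- RoI sampling
        if len(gt):
            iou_p = box_iou(proposals, gt_boxes)
            p_best = iou_p.argmax(axis=1)
            p_iou = iou_p[np.arange(len(proposals)), p_best]
        else:
            p_best = np.zeros(len(proposals), dtype=np.int64)
            p_iou = np.zeros(len(proposals))
        fg = p_iou >= cfg.roi_pos_iou
        fg_idx = np.nonzero(fg)[0]
        bg_idx = np.nonzero(~fg)[0]
        n_fg = min(len(fg_idx), int(cfg.roi_batch * cfg.roi_pos_fraction))
        n_bg = min(len(bg_idx), cfg.roi_batch - n_fg)
        fg_idx = rng.choice(fg_idx, n_fg, replace=False) if n_fg else fg_idx[:0]
        bg_idx = rng.choice(bg_idx, n_bg, replace=False) if n_bg else bg_idx[:0]
        roi_idx = np.concatenate([fg_idx, bg_idx])
        rois = proposals[roi_idx]
        roi_labels = np.concatenate([np.ones(n_fg, np.int64), np.zeros(n_bg, np.int64)])

        feats = self._roi_features(pyr, rois, 7)
        cls_logits, reg_out = self.box_head(feats)
        cls_loss = nn.softmax_cross_entropy(cls_logits, roi_labels)
        if n_fg:
            box_targets = encode_boxes(gt_boxes[p_best[fg_idx]], rois[:n_fg])
            box_loss = nn.smooth_l1(take_rows(reg_out, np.arange(n_fg)), box_targets)
        else:
            box_loss = zero

        # ---- mask loss on (a subset of) the positive RoIs
        if n_fg:
            m_sel = np.arange(n_fg)[: cfg.mask_rois]
            m_rois = rois[m_sel]
            m_feats = self._roi_features(pyr, m_rois, 14)
            logits = self.mask_head(m_feats)
            targets = np.stack([
                _crop_mask(gt.masks[p_best[fg_idx[i]]], m_rois[j])
                for j, i in enumerate(m_sel)
            ])[:, None]
            weights = None
            if cfg.weighted_loss and weight_map is not None:
                from .weighting import crop_weights
                weights = np.stack([crop_weights(weight_map, b) for b in m_rois])[:, None]
            mask_loss = nn.bce_with_logits(logits, targets, weights)
        else:
            mask_loss = zero
        return LossBundle(rpn_cls, rpn_box, cls_loss, box_loss, mask_loss)

    # -- inference -------------------------------------------------------------

    def predict(self, image_pair: ImagePair) -> InstanceSet:
        """Detect instances; at most ``max_detections`` top-scoring kept."""
        cfg = self.config
        shape = image_pair.shape
        pyr = self.pyramid(image_pair)
        obj_flat, reg_flat, anchors, level_sizes = self.rpn_forward(pyr)
        proposals = self.propose(obj_flat, reg_flat, anchors, level_sizes, shape, training=False)
        if len(proposals) == 0:
            return InstanceSet.empty(shape)
        feats = self._roi_features(pyr, proposals, 7)
        cls_logits, reg_out = self.box_head(feats)
        z = cls_logits.data - cls_logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        fg_scores = (e / e.sum(axis=1, keepdims=True))[:, 1]
        boxes = clip_boxes(decode_boxes(reg_out.data, proposals), shape)
        wh = np.minimum(boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1])
        keep = (fg_scores >= cfg.score_floor) & (wh >= 1)
        boxes, fg_scores = boxes[keep], fg_scores[keep]
        if len(boxes) == 0:
            return InstanceSet.empty(shape)
        keep = nms(boxes, fg_scores, cfg.head_nms_thresh)
        order = keep[np.argsort(-fg_scores[keep], kind="stable")][: cfg.max_detections]
        boxes, fg_scores = boxes[order], fg_scores[order]
        m_feats = self._roi_features(pyr, boxes, 14)
        logits = self.mask_head(m_feats).data[:, 0]
        probs = expit(logits)
        masks = [paste_mask(p, b, shape) for p, b in zip(probs, boxes)]
        nonempty = np.array([m.any() for m in masks], dtype=bool)
        if not nonempty.all():
            boxes, fg_scores = boxes[nonempty], fg_scores[nonempty]
            masks = [m for m, ok in zip(masks, nonempty) if ok]
        return InstanceSet(shape=shape, masks=masks, boxes=boxes, scores=fg_scores)

    def predict_pair(self, image_pair: ImagePair) -> tuple[InstanceSet, InstanceSet | None]:
        """Cell detections plus, for fpf models, nucleus detections from the
        embedded stage-1 model in the same call."""
        cells = self.predict(image_pair)
        nuclei = None
        if self.nucleus_model is not None:
            nuclei = self.nucleus_model.predict(image_pair)
        return cells, nuclei


# ---------------------------------------------------------------------------
# functional wrappers mirroring the operation-level interface

def rpn_propose(model: Detector, image_pair: ImagePair, training: bool = False) -> np.ndarray:
    pyr = model.pyramid(image_pair)
    obj, reg, anchors, sizes = model.rpn_forward(pyr)
    return model.propose(obj, reg, anchors, sizes, image_pair.shape, training)


def compute_loss(model: Detector, image_pair: ImagePair, gt: InstanceSet,
                 weight_map: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> LossBundle:
    return model.loss_step(image_pair, gt, weight_map=weight_map, rng=rng)


def predict(model: Detector, image_pair: ImagePair) -> InstanceSet:
    return model.predict(image_pair)
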