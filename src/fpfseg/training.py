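"""Two-stage training driver with the three-phase fine-tuning schedule.

Stage 1 trains a nucleus detector; stage 2 trains the cell detector (for
the fusion variant, with the stage-1 pyramid frozen inside it).  Each
stage follows the same schedule:

1. heads + pyramid for ``phase_iters[0]`` iterations at ``learning_rate``;
2. additionally backbone stages conv4 and deeper for ``phase_iters[1]``;
3. the whole network for ``phase_iters[2]`` at ``final_lr``.

Optimization is SGD with momentum 0.9 and weight decay 1e-4, batch size 1.
All phase budgets scale by a single ``scale`` factor so the schedule can
be shrunk proportionally for desk-scale runs.  Augmentation applies random
crops, horizontal/vertical flips and 90° rotations to image and masks
consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ImagePair, InstanceSet
from .data import SyntheticSample
from .network import Detector, LossBundle, ModelConfig
from .nn import SGD
from .weighting import WeightConfig, contour_weight_map

__all__ = [
    "TrainConfig", "Phase", "TrainState", "make_schedule", "augment", "train",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0001
    phase_iters: tuple[int, int, int] = (100_000, 250_000, 500_000)
    final_lr: float = 0.0001
    scale: float = 1.0
    crop_size: int | None = None      # None: train on full frames
    flips: bool = True
    rotations: bool = True
    log_interval: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if any(it <= 0 for it in self.phase_iters):
            raise ValueError("phase budgets must be positive")
        if self.learning_rate <= 0 or self.final_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.crop_size is not None and self.crop_size % 64:
            raise ValueError("crop_size must be divisible by 64")


@dataclass(frozen=True)
class Phase:
    name: str
    iterations: int
    learning_rate: float
    trainable_prefixes: tuple[str, ...] | None   # None = everything (sans frozen branch)


@dataclass
class TrainState:
    iteration: int = 0
    phase: str = ""
    loss_history: list[dict] = field(default_factory=list)


def make_schedule(config: TrainConfig, prefix: str = "cell") -> list[Phase]:
    """Three phases with scaled budgets and their trainable parameter sets."""
    iters = [max(1, int(round(it * config.scale))) for it in config.phase_iters]
    head_prefixes = (
        f"{prefix}.rpn", f"{prefix}.box_head", f"{prefix}.mask_head",
        f"{prefix}.fpn", f"{prefix}.fuse_proj",
    )
    deep_prefixes = head_prefixes + (f"{prefix}.backbone.conv4", f"{prefix}.backbone.conv5")
    return [
        Phase("heads", iters[0], config.learning_rate, head_prefixes),
        Phase("conv4_up", iters[1], config.learning_rate, deep_prefixes),
        Phase("all", iters[2], config.final_lr, None),
    ]


def _transform_arrays(arrs: list[np.ndarray], flip_h: bool, flip_v: bool, k_rot: int) -> list[np.ndarray]:
    out = []
    for a in arrs:
        if flip_h:
            a = a[:, ::-1]
        if flip_v:
            a = a[::-1, :]
        if k_rot:
            a = np.rot90(a, k_rot)
        out.append(np.ascontiguousarray(a))
    return out


def augment(sample: SyntheticSample, config: TrainConfig, rng: np.random.Generator) -> SyntheticSample:
    """Random crop / flip / rotate one sample; masks move with the image.

    Instances emptied by the crop are dropped.  With all augmentation flags
    off and no crop this is the identity.
    """
    pair = sample.image_pair
    nuc, cell = pair.nucleus, pair.cell
    cell_masks = list(sample.cell_truth.masks)
    nuc_masks = list(sample.nucleus_truth.masks)

    if config.crop_size is not None:
        cs = config.crop_size
        h, w = cell.shape
        if h < cs or w < cs:
            py, px = max(0, cs - h), max(0, cs - w)
            pad = ((0, py), (0, px))
            nuc = np.pad(nuc, pad, mode="reflect")
            cell = np.pad(cell, pad, mode="reflect")
            cell_masks = [np.pad(m, pad, mode="constant") for m in cell_masks]
            nuc_masks = [np.pad(m, pad, mode="constant") for m in nuc_masks]
            h, w = cell.shape
        y0 = int(rng.integers(0, h - cs + 1))
        x0 = int(rng.integers(0, w - cs + 1))
        sl = (slice(y0, y0 + cs), slice(x0, x0 + cs))
        nuc, cell = nuc[sl], cell[sl]
        cell_masks = [m[sl] for m in cell_masks]
        nuc_masks = [m[sl] for m in nuc_masks]

    flip_h = config.flips and bool(rng.integers(2))
    flip_v = config.flips and bool(rng.integers(2))
    k_rot = int(rng.integers(4)) if config.rotations else 0
    nuc, cell = _transform_arrays([nuc, cell], flip_h, flip_v, k_rot)
    cell_masks = _transform_arrays(cell_masks, flip_h, flip_v, k_rot)
    nuc_masks = _transform_arrays(nuc_masks, flip_h, flip_v, k_rot)

    keep_c = [i for i, m in enumerate(cell_masks) if m.any()]
    keep_n = [i for i, m in enumerate(nuc_masks) if m.any()]
    old_c_labels = sample.cell_truth.labels
    old_n_labels = sample.nucleus_truth.labels
    kept_cell_labels = {int(old_c_labels[i]) for i in keep_c}
    n2c = {}
    new_nuc_masks = []
    for j, i in enumerate(keep_n):
        lab = int(old_n_labels[i])
        cell_lab = sample.nucleus_to_cell.get(lab)
        if cell_lab in kept_cell_labels:
            n2c[j + 1] = cell_lab
        new_nuc_masks.append(nuc_masks[i])
    shape = cell.shape
    return SyntheticSample(
        image_pair=ImagePair(nucleus=nuc, cell=cell),
        cell_truth=InstanceSet(shape=shape, masks=[cell_masks[i] for i in keep_c]),
        nucleus_truth=InstanceSet(shape=shape, masks=new_nuc_masks),
        nucleus_to_cell=n2c,
        config=sample.config,
    )


def train(
    model_config: ModelConfig,
    samples: list[SyntheticSample],
    config: TrainConfig = TrainConfig(),
    nucleus_model: Detector | None = None,
    target: str = "cell",
) -> tuple[Detector, TrainState]:
    """Train one detector on in-memory samples; returns (model, state).

    ``target`` selects the supervision ("cell" or "nucleus" truth).  The
    fusion variant requires a trained ``nucleus_model``; its parameters are
    verified frozen by construction.  Deterministic given ``config.seed``.
    """
    if model_config.variant == "fpf" and nucleus_model is None:
        raise ValueError("fpf training requires a stage-1 nucleus model/checkpoint")
    if not samples:
        raise ValueError("no training samples")
    prefix = "nucleus" if target == "nucleus" and model_config.variant != "fpf" else "cell"
    model = Detector(model_config, nucleus_model=nucleus_model, prefix=prefix)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A]))
    state = TrainState()
    weight_maps: dict[int, np.ndarray] = {}
    needs_weights = model_config.weighted_loss

    def get_truth(s: SyntheticSample) -> InstanceSet:
        return s.nucleus_truth if target == "nucleus" else s.cell_truth

    for phase in make_schedule(config, prefix=prefix):
        model.set_trainable(phase.trainable_prefixes)
        opt = SGD(model.parameters(), lr=phase.learning_rate,
                  momentum=config.momentum, weight_decay=config.weight_decay)
        state.phase = phase.name
        order = np.arange(len(samples))
        for it in range(phase.iterations):
            if it % len(samples) == 0:
                rng.shuffle(order)
            si = int(order[it % len(samples)])
            s = samples[si]
            augmented = (config.crop_size is not None) or config.flips or config.rotations
            if augmented:
                s = augment(s, config, rng)
            wmap = None
            if needs_weights:
                if augmented:
                    wmap = contour_weight_map(get_truth(s).label_map(), WeightConfig())
                else:
                    if si not in weight_maps:
                        weight_maps[si] = contour_weight_map(get_truth(s).label_map(), WeightConfig())
                    wmap = weight_maps[si]
            model.zero_grad()
            bundle = model.loss_step(s.image_pair, get_truth(s), weight_map=wmap, rng=rng)
            bundle.total.backward()
            opt.step()
            state.iteration += 1
            if state.iteration % config.log_interval == 0 or it == phase.iterations - 1:
                rec = bundle.as_floats()
                rec.update(iteration=state.iteration, phase=phase.name)
                state.loss_history.append(rec)
    model.set_trainable(None)
    return model, state
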