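"""Reduced ResNet-50 feature extractor.

Compared to the standard ResNet-50, both the filter counts and the number
of bottleneck blocks per stage are halved, shrinking the parameter budget
by roughly a factor of ten — appropriate for single-class fluorescence
imagery with little background clutter.  Default stage layout:

====== ============ =========================== ======
stage  output/224   bottleneck (widths) × blocks stride
====== ============ =========================== ======
conv1  112×112      7×7, 64                      2
conv2  56×56        3×3 max pool; (32,32,128)×2  2 (pool)
conv3  28×28        (64,64,256)×2                2
conv4  14×14        (128,128,512)×3              2
conv5  7×7          (256,256,1024)×2             2
====== ============ =========================== ======

Convolutions carry no bias (batch normalization follows every one);
downsampling lives on the 3×3 convolution of the first block per stage.
The extractor accepts 1- or 2-channel inputs; a 1-channel first layer can
be adapted to 2 channels by duplicating and halving its kernel so that
feeding the same image to both channels reproduces the original responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import BatchNorm2d, Conv2d, Module, Tensor, add, maxpool2d, relu

__all__ = [
    "BackboneConfig",
    "ReducedResNet",
    "build_backbone",
    "count_parameters",
    "adapt_first_layer_two_channels",
]

# (inner width of 1x1/3x3, output width of final 1x1, block count) per stage
REDUCED_STAGES = ((32, 128, 2), (64, 256, 2), (128, 512, 3), (256, 1024, 2))
ORIGINAL_STAGES = ((64, 256, 3), (128, 512, 4), (256, 1024, 6), (512, 2048, 3))


@dataclass(frozen=True)
class BackboneConfig:
    input_channels: int = 1
    conv1_filters: int = 64
    stage_specs: tuple[tuple[int, int, int], ...] = REDUCED_STAGES
    num_classes: int | None = None      # attach avg-pool + fc head when set
    seed: int = 0
    name: str = "backbone"

    def __post_init__(self) -> None:
        if self.input_channels not in (1, 2, 3):
            raise ValueError("input_channels must be 1, 2 or 3")
        if len(self.stage_specs) != 4:
            raise ValueError("exactly four stages (conv2_x … conv5_x) expected")


class Bottleneck(Module):
    """1×1 reduce → 3×3 (stride here) → 1×1 expand, with identity/projection."""

    def __init__(self, rng, cin: int, width: int, cout: int, stride: int, name: str):
        self.conv1 = Conv2d(rng, cin, width, 1, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(width, f"{name}.bn1")
        self.conv2 = Conv2d(rng, width, width, 3, stride=stride, name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(width, f"{name}.bn2")
        self.conv3 = Conv2d(rng, width, cout, 1, name=f"{name}.conv3")
        self.bn3 = BatchNorm2d(cout, f"{name}.bn3")
        self.proj = None
        self.proj_bn = None
        if stride != 1 or cin != cout:
            self.proj = Conv2d(rng, cin, cout, 1, stride=stride, name=f"{name}.proj")
            self.proj_bn = BatchNorm2d(cout, f"{name}.proj_bn")

    def __call__(self, x: Tensor) -> Tensor:
        out = relu(self.bn1(self.conv1(x)))
        out = relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return relu(add(out, shortcut))


class ReducedResNet(Module):
    def __init__(self, config: BackboneConfig):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB0]))
        self.config = config
        n = config.name
        self.conv1 = Conv2d(rng, config.input_channels, config.conv1_filters, 7,
                            stride=2, pad=3, name=f"{n}.conv1")
        self.bn1 = BatchNorm2d(config.conv1_filters, f"{n}.bn1")
        self.stages: list[list[Bottleneck]] = []
        cin = config.conv1_filters
        for si, (width, cout, blocks) in enumerate(config.stage_specs):
            stage = []
            for bi in range(blocks):
                # conv2_x is downsampled by the max pool; later stages stride
                # in their first block
                stride = 2 if (si > 0 and bi == 0) else 1
                stage.append(Bottleneck(rng, cin, width, cout, stride,
                                        name=f"{n}.conv{si + 2}_{bi}"))
                cin = cout
            self.stages.append(stage)
        self.head_fc = None
        if config.num_classes is not None:
            self.head_fc = nn.Linear(rng, cin, config.num_classes, name=f"{n}.fc")
        self.out_channels = tuple(spec[1] for spec in config.stage_specs)

    def set_batch_stats(self, use_batch: bool) -> None:
        for m, _ in self._bn_modules():
            m.use_batch_stats = use_batch

    def __call__(self, x: Tensor) -> dict[str, Tensor]:
        """Return the C2…C5 stage outputs (strides 4, 8, 16, 32)."""
        h, w = x.data.shape[2], x.data.shape[3]
        if h < 32 or w < 32:
            raise ValueError(f"input {h}x{w} too small for the stride-32 budget")
        out = relu(self.bn1(self.conv1(x)))
        out = maxpool2d(out, 3, 2, 1)
        feats: dict[str, Tensor] = {}
        for si, stage in enumerate(self.stages):
            for block in stage:
                out = block(out)
            feats[f"C{si + 2}"] = out
        return feats

    def classify(self, x: Tensor) -> Tensor:
        """Global-average-pool + fc logits (classification warm-up hook)."""
        if self.head_fc is None:
            raise ValueError("backbone built without a classification head")
        feats = self(x)
        c5 = feats["C5"]
        pooled = Tensor(c5.data.mean(axis=(2, 3)), requires_grad=c5.requires_grad,
                        parents=(c5,) if c5.requires_grad else (),
                        backward=(lambda g, c5=c5: c5._accum(
                            np.broadcast_to(g[:, :, None, None] / (c5.data.shape[2] * c5.data.shape[3]),
                                            c5.data.shape).astype(np.float32)))
                        if c5.requires_grad else None)
        return self.head_fc(pooled)


def build_backbone(config: BackboneConfig = BackboneConfig()) -> ReducedResNet:
    return ReducedResNet(config)


def count_parameters(module: Module) -> int:
    """Exact count of trainable scalars (conv/fc weights, BN affine terms)."""
    return int(sum(p.data.size for p in module.parameters()))


def adapt_first_layer_two_channels(weights_1ch: np.ndarray) -> np.ndarray:
    """Duplicate-and-halve a 1-channel first-layer kernel for 2-channel input.

    The two channel slices each equal half the original kernel, so the sum
    over input channels reproduces the original kernel and identical inputs
    on both channels leave downstream activations undisturbed.
    """
    w = np.asarray(weights_1ch)
    if w.ndim != 4 or w.shape[1] != 1:
        raise ValueError(f"expected (filters, 1, kh, kw) kernel, got {w.shape}")
    return np.concatenate([w / 2.0, w / 2.0], axis=1)
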