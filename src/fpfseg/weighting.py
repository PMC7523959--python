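"""Border-weighted mask-loss support.

Pixels near cell contours are the hardest to segment, especially inside
clusters where the cytoplasm signal barely changes across the contact line.
The mask loss can therefore be re-weighted with a per-pixel multiplier map:
instance contours are extracted from the full-image label mask, blurred with
an isotropic Gaussian ``G(x, y) = 1/(2πσ²)·exp(−(x²+y²)/(2σ²))`` (default
25×25 kernel, σ = 5), peak-normalized, and mapped affinely to
``[1, max_weight]`` (default max 2).  Contour pixels thus carry exactly twice
the weight of interior pixels, decaying smoothly with distance.

For each box proposal the map is cropped and bilinearly resized to the 28×28
mask-loss grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, map_coordinates

__all__ = ["WeightConfig", "gaussian_kernel", "contour_weight_map", "crop_weights"]

MASK_CROP = 28


@dataclass(frozen=True)
class WeightConfig:
    kernel_size: int = 25
    sigma: float = 5.0
    max_weight: float = 2.0

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.max_weight < 1:
            raise ValueError("max_weight must be >= 1")


def gaussian_kernel(config: WeightConfig = WeightConfig()) -> np.ndarray:
    """Gaussian kernel sampled at integer offsets from the center."""
    half = config.kernel_size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    s2 = config.sigma**2
    return 1.0 / (2.0 * np.pi * s2) * np.exp(-(x**2 + y**2) / (2.0 * s2))


def instance_contours(label_mask: np.ndarray) -> np.ndarray:
    """1-px contours: pixels of an instance 4-adjacent to a different label.

    Background (label 0) never contributes contour pixels, but a foreground
    pixel bordering background is a contour pixel.
    """
    lab = np.asarray(label_mask)
    if lab.ndim != 2:
        raise ValueError("label mask must be 2-D")
    fg = lab > 0
    contour = np.zeros(lab.shape, dtype=bool)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        neighbor = np.roll(lab, shift, axis=axis)
        # roll wraps around; mask out the wrapped edge row/column
        edge = np.zeros_like(contour)
        if axis == 0:
            idx = 0 if shift == 1 else -1
            edge[idx, :] = True
        else:
            idx = 0 if shift == 1 else -1
            edge[:, idx] = True
        differs = (neighbor != lab) & ~edge
        contour |= fg & differs
    # image-frame edge pixels of an instance also border "outside"
    frame = np.zeros_like(contour)
    frame[0, :] = frame[-1, :] = True
    frame[:, 0] = frame[:, -1] = True
    contour |= fg & frame
    return contour


def contour_weight_map(
    full_label_mask: np.ndarray, config: WeightConfig = WeightConfig()
) -> np.ndarray:
    """Per-pixel loss multipliers in ``[1, max_weight]`` from instance contours."""
    contour = instance_contours(full_label_mask)
    if not contour.any():
        return np.ones(contour.shape, dtype=np.float64)
    kernel = gaussian_kernel(config)
    blurred = convolve(contour.astype(np.float64), kernel, mode="constant", cval=0.0)
    peak = blurred.max()
    normalized = blurred / peak
    return 1.0 + (config.max_weight - 1.0) * normalized


def crop_weights(
    weight_map: np.ndarray, box: np.ndarray, output_size: int = MASK_CROP
) -> np.ndarray:
    """Bilinear resize of the boxed region of a weight map to ``output_size``².

    Sample points are the centers of an ``output_size`` × ``output_size``
    grid laid over the half-open box, matching the RoI-Align convention of
    the mask head so weights align with mask logits.
    """
    x0, y0, x1, y1 = [float(v) for v in box]
    if not (x1 > x0 and y1 > y0):
        raise ValueError(f"degenerate box {box!r}")
    h = (y1 - y0) / output_size
    w = (x1 - x0) / output_size
    ys = y0 + (np.arange(output_size) + 0.5) * h - 0.5
    xs = x0 + (np.arange(output_size) + 0.5) * w - 0.5
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    out = map_coordinates(
        np.asarray(weight_map, dtype=np.float64),
        [yy.ravel(), xx.ravel()],
        order=1,
        mode="nearest",
    ).reshape(output_size, output_size)
    return out
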