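"""Classical ground-truth bootstrapping.

Label masks for a new dataset are seeded by classical segmentation before
any manual curation: each channel is thresholded (Otsu by default, or a
fixed value), the foreground is morphologically closed, small components
are dropped, and every remaining connected component becomes one instance.
Cells containing several nuclei are then split like a Voronoi partition —
every cell pixel is assigned to the nearest intersecting nucleus, with
distance measured to the nucleus *mask* (robust for elongated nuclei) and
ties broken toward the lower nucleus label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from scipy.ndimage import binary_closing
from skimage.morphology import disk

from .core import ImagePair, InstanceSet

__all__ = [
    "BootstrapConfig",
    "threshold_segment",
    "split_multinucleate",
    "bootstrap_ground_truth",
]


@dataclass(frozen=True)
class BootstrapConfig:
    threshold_method: str = "otsu"          # {"otsu", "fixed"}
    fixed_threshold: float | None = None
    min_instance_area: int = 30
    morphology_radius: int = 2

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required for method='fixed'")
        if self.min_instance_area < 1:
            raise ValueError("min_instance_area must be >= 1")


def threshold_segment(channel: np.ndarray, config: BootstrapConfig) -> InstanceSet:
    """Initial instance segmentation of one channel by global threshold.

    Connected components of the closed, thresholded foreground become
    instances; components smaller than ``min_instance_area`` are removed.
    An all-background image yields an empty set.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.ndim != 2:
        raise ValueError("channel must be a 2-D raster")
    if not np.isfinite(channel).all():
        raise ValueError("channel contains non-finite values")
    if config.threshold_method == "fixed":
        thr = float(config.fixed_threshold)
    else:
        if np.ptp(channel) == 0:
            return InstanceSet.empty(channel.shape)
        thr = float(threshold_otsu(channel))
    fg = channel > thr
    if config.morphology_radius > 0:
        fg = binary_closing(fg, structure=disk(config.morphology_radius))
    lab, n = cc_label(fg, connectivity=1, return_num=True)
    masks = []
    for i in range(1, n + 1):
        m = lab == i
        if m.sum() >= config.min_instance_area:
            masks.append(m)
    return InstanceSet(shape=channel.shape, masks=masks)


def split_multinucleate(cell_mask: np.ndarray, nuclei: InstanceSet) -> list[np.ndarray]:
    """Partition one cell mask among its intersecting nuclei.

    Every cell pixel joins the nucleus whose mask is nearest in Euclidean
    distance; equidistant pixels join the lowest nucleus label.  The output
    masks are pairwise disjoint and union exactly to the input.  A cell with
    no intersecting nucleus is returned unchanged with a warning.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    hits = [i for i, nm in enumerate(nuclei.masks) if (nm & cell_mask).any()]
    if not hits:
        warnings.warn("cell without intersecting nucleus left unsplit", stacklevel=2)
        return [cell_mask]
    if len(hits) == 1:
        return [cell_mask]
    # distance to each nucleus mask via EDT of its complement; iterate in
    # ascending label order and keep strict inequality so ties stay with
    # the earlier (lower) label
    order = sorted(hits, key=lambda i: nuclei.labels[i])
    best = np.full(cell_mask.shape, np.inf)
    assign = np.full(cell_mask.shape, -1, dtype=np.int64)
    for i in order:
        d = distance_transform_edt(~nuclei.masks[i])
        closer = cell_mask & (d < best)
        best[closer] = d[closer]
        assign[closer] = i
    return [(assign == i) & cell_mask for i in order]


def bootstrap_ground_truth(
    image_pair: ImagePair,
    config: BootstrapConfig = BootstrapConfig(),
    nucleus_config: BootstrapConfig | None = None,
) -> tuple[InstanceSet, InstanceSet]:
    """Two-step bootstrap: threshold both channels, then split multinucleates.

    Returns ``(cells, nuclei)``.  Nuclei are segmented from the nucleus
    channel and cells from the cytoplasm channel; any cell overlapping more
    than one nucleus is split into one instance per nucleus.
    """
    nuclei = threshold_segment(image_pair.nucleus, nucleus_config or config)
    cells_raw = threshold_segment(image_pair.cell, config)
    out_masks: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # nucleus-free cells are expected pre-curation
        for cm in cells_raw.masks:
            out_masks.extend(split_multinucleate(cm, nuclei))
    out_masks = [m for m in out_masks if m.any()]
    return InstanceSet(shape=image_pair.shape, masks=out_masks), nuclei
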