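"""Rule-based refinement of predicted cell instances using nucleus predictions.

Three steps run in order:

1. cells overlapping the same nucleus are merged (transitively);
2. threshold-foreground not covered by any predicted cell is recovered:
   each residual region is (a) appended to the unique adjacent cell,
   (b) dropped when adjacent to several cells, or (c) promoted to a new
   instance when adjacent to none — regions below a minimum area are
   discarded outright;
3. nucleus pixels left outside every cell either extend the unique
   overlapping cell or found a new cell with the nucleus's shape.

The composite is idempotent and leaves every nucleus pixel covered by
exactly one cell instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from scipy.ndimage import binary_closing, binary_dilation
from skimage.morphology import disk

from .core import InstanceSet

__all__ = [
    "PostprocessConfig",
    "merge_cells_sharing_nucleus",
    "recover_uncovered_regions",
    "expand_cells_to_nuclei",
    "postprocess",
]


@dataclass(frozen=True)
class PostprocessConfig:
    min_region_area: int = 40
    foreground_threshold: float | str = "otsu"
    connectivity: int = 8
    morphology_radius: int = 3

    def __post_init__(self) -> None:
        if self.min_region_area < 1:
            raise ValueError("min_region_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _adjacent_or_overlapping(a: np.ndarray, b: np.ndarray) -> bool:
    """8-adjacency (or overlap) between two masks."""
    return bool((binary_dilation(a, structure=np.ones((3, 3), bool)) & b).any())


def merge_cells_sharing_nucleus(cells: InstanceSet, nuclei: InstanceSet) -> InstanceSet:
    """Union every group of cells that overlap a common nucleus (transitively)."""
    n = len(cells)
    if n == 0 or len(nuclei) == 0:
        return cells
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for nm in nuclei.masks:
        owners = [i for i, cm in enumerate(cells.masks) if (cm & nm).any()]
        for i in owners[1:]:
            union(owners[0], i)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    masks, scores = [], []
    for members in groups.values():
        m = np.zeros(cells.shape, dtype=bool)
        for i in members:
            m |= cells.masks[i]
        masks.append(m)
        scores.append(max(cells.scores[i] for i in members))
    return InstanceSet(shape=cells.shape, masks=masks, scores=np.array(scores))


def recover_uncovered_regions(
    cell_channel: np.ndarray,
    cells: InstanceSet,
    config: PostprocessConfig = PostprocessConfig(),
) -> InstanceSet:
    """Recover thresholded foreground missed by the predictions."""
    cell_channel = np.asarray(cell_channel, dtype=np.float64)
    if cell_channel.shape != tuple(cells.shape):
        raise ValueError("raster and instance shapes differ")
    if config.foreground_threshold == "otsu":
        if np.ptp(cell_channel) == 0:
            return cells
        thr = float(threshold_otsu(cell_channel))
    else:
        thr = float(config.foreground_threshold)
    fg = cell_channel > thr
    covered = np.zeros(cells.shape, dtype=bool)
    for m in cells.masks:
        covered |= m
    residual = fg & ~covered
    if config.morphology_radius > 0:
        residual = binary_closing(residual, structure=disk(config.morphology_radius)) & ~covered
    lab, nreg = cc_label(residual, connectivity=1 if config.connectivity == 4 else 2,
                         return_num=True)
    masks = [m.copy() for m in cells.masks]
    scores = list(cells.scores)
    for r in range(1, nreg + 1):
        region = lab == r
        if region.sum() < config.min_region_area:
            continue
        touching = [i for i, m in enumerate(masks) if _adjacent_or_overlapping(region, m)]
        if len(touching) == 1:
            masks[touching[0]] |= region          # rule (a): append
        elif len(touching) > 1:
            continue                              # rule (b): ambiguous, drop
        else:
            masks.append(region)                  # rule (c): new instance
            scores.append(1.0)
    return InstanceSet(shape=cells.shape, masks=masks, scores=np.array(scores))


def expand_cells_to_nuclei(cells: InstanceSet, nuclei: InstanceSet) -> InstanceSet:
    """Cover every nucleus: grow the unique overlapping cell or add a new one."""
    masks = [m.copy() for m in cells.masks]
    scores = list(cells.scores)
    for nm in nuclei.masks:
        covered = np.zeros(cells.shape, dtype=bool)
        for m in masks:
            covered |= m
        outside = nm & ~covered
        if not outside.any():
            continue
        owners = [i for i, m in enumerate(masks) if (m & nm).any()]
        if len(owners) == 1:
            masks[owners[0]] |= nm
        elif len(owners) == 0:
            masks.append(nm.copy())
            scores.append(1.0)
        # several owners: step 1 should have merged them; leave untouched
    return InstanceSet(shape=cells.shape, masks=masks, scores=np.array(scores))


def postprocess(
    cells: InstanceSet,
    nuclei: InstanceSet,
    cell_channel: np.ndarray,
    config: PostprocessConfig = PostprocessConfig(),
) -> InstanceSet:
    """Merge → recover → expand, in that order."""
    out = merge_cells_sharing_nucleus(cells, nuclei)
    out = recover_uncovered_regions(cell_channel, out, config)
    out = merge_cells_sharing_nucleus(out, nuclei)  # recovery may bridge cells onto a shared nucleus
    out = expand_cells_to_nuclei(out, nuclei)
    return out
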