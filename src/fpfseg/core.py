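"""Shared containers: image pairs and per-image instance sets.

An :class:`InstanceSet` stores one binary mask per instance on the full image
raster, together with bounding boxes (half-open pixel coordinates
``[x0, x1) x [y0, y1)``), scores and integer instance labels.  Label 0 is
reserved for background in label-map form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImagePair", "InstanceSet", "box_from_mask"]


def box_from_mask(mask: np.ndarray) -> np.ndarray:
    """Tight half-open bounding box ``(x0, y0, x1, y1)`` of a binary mask."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return np.zeros(4, dtype=np.float64)
    return np.array([xs.min(), ys.min(), xs.max() + 1, ys.max() + 1], dtype=np.float64)


@dataclass
class ImagePair:
    """Registered nucleus-channel and cell-channel rasters of equal shape."""

    nucleus: np.ndarray
    cell: np.ndarray

    def __post_init__(self) -> None:
        self.nucleus = np.asarray(self.nucleus)
        self.cell = np.asarray(self.cell)
        if self.nucleus.shape != self.cell.shape:
            raise ValueError(
                f"channel shapes differ: {self.nucleus.shape} vs {self.cell.shape}"
            )
        if self.nucleus.ndim != 2:
            raise ValueError("channels must be 2-D single-channel rasters")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nucleus.shape


@dataclass
class InstanceSet:
    """Per-image collection of instance masks, boxes, scores and labels."""

    shape: tuple[int, int]
    masks: list[np.ndarray] = field(default_factory=list)
    boxes: np.ndarray | None = None
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.masks)
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        for m in self.masks:
            if m.shape != tuple(self.shape):
                raise ValueError("mask shape does not match image shape")
        if self.boxes is None:
            self.boxes = np.array([box_from_mask(m) for m in self.masks], dtype=np.float64).reshape(n, 4)
        else:
            self.boxes = np.asarray(self.boxes, dtype=np.float64).reshape(n, 4)
        if self.scores is None:
            self.scores = np.ones(n, dtype=np.float64)
        else:
            self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.labels is None:
            self.labels = np.arange(1, n + 1, dtype=np.int64)
        else:
            self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.masks) == len(self.boxes) == len(self.scores) == len(self.labels)):
            raise ValueError("masks/boxes/scores/labels length mismatch")
        if n and (self.labels <= 0).any():
            raise ValueError("instance labels must be positive")

    def __len__(self) -> int:
        return len(self.masks)

    @classmethod
    def from_label_map(cls, label_map: np.ndarray, scores: np.ndarray | None = None) -> "InstanceSet":
        label_map = np.asarray(label_map)
        labels = np.unique(label_map)
        labels = labels[labels > 0]
        masks = [label_map == lab for lab in labels]
        return cls(shape=label_map.shape, masks=masks, scores=scores, labels=labels)

    def label_map(self, dtype=np.uint16) -> np.ndarray:
        """Flatten to a single label raster; later instances overwrite earlier."""
        out = np.zeros(self.shape, dtype=dtype)
        for m, lab in zip(self.masks, self.labels):
            out[m] = lab
        return out

    def subset(self, idx) -> "InstanceSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return InstanceSet(
            shape=self.shape,
            masks=[self.masks[i] for i in idx],
            boxes=self.boxes[idx],
            scores=self.scores[idx],
            labels=self.labels[idx],
        )

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "InstanceSet":
        return cls(shape=tuple(shape), masks=[])
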