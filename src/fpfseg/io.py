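"""Dataset I/O, serialization, and pipeline helpers.

Formats: single-channel or 2-channel TIFF intensity images, 16-bit label
TIFF masks (0 = background), COCO-style detection JSON (uncompressed
Fortran-order run-length-encoded masks, xywh boxes, scores), JSON dataset
manifests, npz checkpoints, and CSV report tables with one row per method
and columns for the nine IoU thresholds plus the mean AP.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImagePair, InstanceSet
from .evaluation import IOU_THRESHOLDS, evaluate, relative_improvement

__all__ = [
    "read_image_pair", "write_label_map", "read_label_map",
    "rle_encode", "rle_decode", "detections_to_coco", "detections_from_coco",
    "save_checkpoint", "load_checkpoint", "load_manifest",
    "clustered_patches", "make_clustered_subset", "run_experiment",
]


# ---------------------------------------------------------------------------
# rasters

def read_image_pair(paths: str | Path | tuple[str | Path, str | Path]) -> ImagePair:
    """Load a registered pair from one 2-channel stack or two 1-channel files.

    Channel order for stacks: nucleus first, cytoplasm second.  Intensities
    are converted to float32 with their stored scale preserved.
    """
    if isinstance(paths, (tuple, list)):
        npath, cpath = paths
        try:
            nuc = tifffile.imread(npath)
            cell = tifffile.imread(cpath)
        except (OSError, ValueError) as e:
            raise OSError(f"cannot read image pair {npath}, {cpath}: {e}") from e
    else:
        try:
            stack = tifffile.imread(paths)
        except (OSError, ValueError) as e:
            raise OSError(f"cannot read image stack {paths}: {e}") from e
        if stack.ndim != 3:
            raise ValueError(f"{paths}: expected a 2-channel stack, got shape {stack.shape}")
        if stack.shape[0] == 2:
            nuc, cell = stack[0], stack[1]
        elif stack.shape[-1] == 2:
            nuc, cell = stack[..., 0], stack[..., 1]
        else:
            raise ValueError(f"{paths}: no 2-channel axis in shape {stack.shape}")
    return ImagePair(nucleus=np.asarray(nuc, dtype=np.float32),
                     cell=np.asarray(cell, dtype=np.float32))


def write_label_map(path: str | Path, instances: InstanceSet) -> None:
    tifffile.imwrite(path, instances.label_map(np.uint16))


def read_label_map(path: str | Path) -> InstanceSet:
    try:
        lab = tifffile.imread(path)
    except (OSError, ValueError) as e:
        raise OSError(f"cannot read label mask {path}: {e}") from e
    return InstanceSet.from_label_map(lab)


# ---------------------------------------------------------------------------
# run-length encoding (COCO convention: column-major, counts start with 0s)

def rle_encode(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=bool).flatten(order="F").astype(np.int8)
    change = np.nonzero(np.diff(flat))[0] + 1
    runs = np.diff(np.concatenate([[0], change, [flat.size]]))
    counts = runs.tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": list(mask.shape), "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in rle["counts"]:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    return flat.reshape((h, w), order="F")


def detections_to_coco(instances: InstanceSet, image_id: int = 0) -> list[dict]:
    out = []
    for mask, box, score in zip(instances.masks, instances.boxes, instances.scores):
        x0, y0, x1, y1 = box
        out.append({
            "image_id": image_id,
            "category_id": 1,
            "bbox": [float(x0), float(y0), float(x1 - x0), float(y1 - y0)],
            "score": float(score),
            "segmentation": rle_encode(mask),
        })
    return out


def detections_from_coco(records: list[dict], shape: tuple[int, int]) -> InstanceSet:
    masks, boxes, scores = [], [], []
    for r in records:
        masks.append(rle_decode(r["segmentation"]))
        x, y, w, h = r["bbox"]
        boxes.append([x, y, x + w, y + h])
        scores.append(r["score"])
    if not masks:
        return InstanceSet.empty(shape)
    return InstanceSet(shape=shape, masks=masks, boxes=np.array(boxes), scores=np.array(scores))


# ---------------------------------------------------------------------------
# checkpoints and manifests

def save_checkpoint(path: str | Path, model) -> None:
    """Save a model state dict as npz (keys are dotted parameter names)."""
    np.savez_compressed(path, **model.state_dict())


def load_checkpoint(path: str | Path, model) -> None:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    with open(path) as f:
        manifest = json.load(f)
    root = Path(manifest.get("root", path.parent))
    if not root.is_absolute():
        root = path.parent
    for entry in manifest["samples"]:
        for key, rel in entry["paths"].items():
            p = root / rel
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file {p}")
    manifest["root"] = str(root)
    return manifest


# ---------------------------------------------------------------------------
# clustered-cells subset

def _adjacency(masks: list[np.ndarray]) -> list[set[int]]:
    from .data import _four_adjacent

    n = len(masks)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _four_adjacent(masks[i], masks[j]):
                adj[i].add(j)
                adj[j].add(i)
    return adj


def clustered_patches(cells: InstanceSet, patch_size: int = 256) -> list[tuple[int, int]]:
    """Top-left corners of patches centered on clusters of ≥2 touching cells."""
    adj = _adjacency(list(cells.masks))
    seen: set[int] = set()
    corners = []
    h, w = cells.shape
    for i in range(len(cells)):
        if i in seen or not adj[i]:
            continue
        group = {i}
        stack = [i]
        while stack:
            k = stack.pop()
            for j in adj[k]:
                if j not in group:
                    group.add(j)
                    stack.append(j)
        seen |= group
        union = np.zeros(cells.shape, dtype=bool)
        for k in group:
            union |= cells.masks[k]
        ys, xs = np.nonzero(union)
        cy, cx = ys.mean(), xs.mean()
        y0 = int(np.clip(round(cy - patch_size / 2), 0, max(h - patch_size, 0)))
        x0 = int(np.clip(round(cx - patch_size / 2), 0, max(w - patch_size, 0)))
        corners.append((y0, x0))
    return corners


def _crop_instances(instances: InstanceSet, y0: int, x0: int, size: int) -> InstanceSet:
    sl = (slice(y0, y0 + size), slice(x0, x0 + size))
    masks = [m[sl] for m in instances.masks]
    keep = [m for m in masks if m.any()]
    shape = (min(size, instances.shape[0] - y0), min(size, instances.shape[1] - x0))
    return InstanceSet(shape=shape, masks=keep)


def make_clustered_subset(
    pairs: list[ImagePair], truths: list[InstanceSet], patch_size: int = 256
) -> list[tuple[ImagePair, InstanceSet]]:
    """Cluster-centered crops containing ≥2 touching cells each."""
    subset = []
    for pair, gt in zip(pairs, truths):
        for y0, x0 in clustered_patches(gt, patch_size):
            sl = (slice(y0, y0 + patch_size), slice(x0, x0 + patch_size))
            cropped_pair = ImagePair(nucleus=pair.nucleus[sl], cell=pair.cell[sl])
            cropped_gt = _crop_instances(gt, y0, x0, patch_size)
            if len(cropped_gt) >= 2:
                subset.append((cropped_pair, cropped_gt))
    return subset


# ---------------------------------------------------------------------------
# report table

def run_experiment(
    predictions: dict[str, list[InstanceSet]],
    ground_truths: list[InstanceSet],
    mode: str = "mask",
    baseline: str | None = None,
) -> pd.DataFrame:
    """Evaluate several methods on one test set into a table: one row per
    method, AP per threshold, mean AP, and relative improvement over a
    designated baseline row."""
    rows = {}
    for name, preds in predictions.items():
        if len(preds) != len(ground_truths):
            raise ValueError(f"{name}: prediction count does not match test set")
        rep = evaluate(preds, ground_truths, mode=mode)
        row = {f"AP@{t:.2f}": rep.ap_by_threshold[round(float(t), 2)] for t in IOU_THRESHOLDS}
        row["mean AP"] = rep.mean_ap
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    if baseline is not None:
        base = df.loc[baseline, "mean AP"]
        df["improvement %"] = [
            relative_improvement(v, base) if name != baseline else 0.0
            for name, v in df["mean AP"].items()
        ]
    return df
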