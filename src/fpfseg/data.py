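"""Synthetic two-channel fluorescence scenes with pixel-perfect ground truth.

The generator emulates the statistical challenges of macrophage screening
data: round, well-separated nuclei on a DNA-stain channel; irregular
star-convex cytoplasm outlines on a cytoplasm-stain channel; clusters of
two or more touching cells whose shared boundary shows only a faint
intensity change; occasional multinucleate (mitotic) cells; and instances
truncated by the image frame.

Geometry and rendering are split: :func:`sample_geometry` draws instance
masks (cells, nuclei, and the nucleus→cell map), :func:`render_channels`
turns a truth layout into the two intensity rasters.  Both are pure
functions of the configuration seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon

from .core import ImagePair, InstanceSet

__all__ = [
    "SceneConfig",
    "SyntheticSample",
    "PackingError",
    "sample_geometry",
    "render_channels",
    "simulate_scene",
    "generate_dataset",
    "write_dataset",
]


class PackingError(RuntimeError):
    """Raised when the requested cells cannot be placed in the frame."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Radii are in pixels at the emulated 20x magnification: cells span
    roughly 18–35 px in radius, nuclei 6–11 px, so nuclei always fit well
    inside their cells.  ``contact_attenuation`` dims the cytoplasm signal
    along cell–cell contact lines (0 = boundary invisible in intensity,
    1 = boundary drops to zero signal); the faint-contact regime of real
    clusters corresponds to small values.
    """

    image_height: int = 256
    image_width: int = 256
    n_cells: int = 6
    cluster_fraction: float = 0.5
    multinucleate_rate: float = 0.05
    nucleus_radius_range: tuple[float, float] = (6.0, 11.0)
    cell_radius_range: tuple[float, float] = (18.0, 35.0)
    contact_attenuation: float = 0.25
    noise_sd: float = 8.0
    background_level: float = 60.0
    nucleus_level: float = 600.0
    cell_level: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 8 or self.image_width < 8:
            raise ValueError("frame too small")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for lo, hi in (self.nucleus_radius_range, self.cell_radius_range):
            if not (0 < lo <= hi):
                raise ValueError("radius ranges must be positive and ordered")
        if self.nucleus_radius_range[1] >= self.cell_radius_range[0]:
            raise ValueError("max nucleus radius must be below min cell radius")
        for r in (self.cluster_fraction, self.multinucleate_rate, self.contact_attenuation):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise and background must be nonnegative")


@dataclass
class SyntheticSample:
    """One scene: rendered channels plus the exact instance ground truth."""

    image_pair: ImagePair | None
    cell_truth: InstanceSet
    nucleus_truth: InstanceSet
    nucleus_to_cell: dict[int, int]
    config: SceneConfig


def _star_polygon(rng: np.random.Generator, cy: float, cx: float, radius: float,
                  shape: tuple[int, int], n_vertices: int = 32) -> np.ndarray:
    """Rasterize a star-convex radial perturbation of an ellipse."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    # low-order periodic perturbation keeps the outline irregular but smooth
    r = np.full(n_vertices, 1.0)
    for k in range(1, 5):
        amp = rng.uniform(0.0, 0.12 / k)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(k * theta + phase)
    ecc = rng.uniform(0.75, 1.0)
    ang = rng.uniform(0, np.pi)
    xs = radius * r * np.cos(theta)
    ys = radius * r * np.sin(theta)
    xr = xs * np.cos(ang) - ys * np.sin(ang)
    yr = xs * np.sin(ang) + ys * np.cos(ang)
    rr, cc = draw_polygon(cy + yr * ecc, cx + xr, shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _four_adjacent(a: np.ndarray, b: np.ndarray) -> bool:
    for axis in (0, 1):
        for shift in (1, -1):
            if (a & np.roll(b, shift, axis=axis)).any():
                return True
    return False


def _partition_clusters(rng: np.random.Generator, n_clustered: int) -> list[int]:
    """Split clustered cells into groups of >= 2 (a leftover of 1 joins the last)."""
    sizes: list[int] = []
    remaining = n_clustered
    while remaining >= 2:
        s = int(min(remaining, rng.integers(2, 5)))
        if remaining - s == 1:
            s += 1 if s < remaining else 0
        sizes.append(min(s, remaining))
        remaining -= sizes[-1]
    if remaining == 1:
        if sizes:
            sizes[-1] += 1
        else:
            sizes = [1]  # a singleton "cluster" can't touch anything; caller guards
    return sizes


def sample_geometry(config: SceneConfig) -> SyntheticSample:
    """Draw cell and nucleus instance masks for one scene.

    Deterministic given ``config.seed``.  Raises :class:`PackingError` when
    the requested number of cells cannot be placed after a bounded number
    of attempts.
    """
    h, w = config.image_height, config.image_width
    if config.n_cells == 0:
        return SyntheticSample(
            image_pair=None,
            cell_truth=InstanceSet.empty((h, w)),
            nucleus_truth=InstanceSet.empty((h, w)),
            nucleus_to_cell={},
            config=config,
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9E0]))
    for _ in range(25):
        sample = _try_sample_geometry(rng, config)
        if sample is not None:
            return sample
    raise PackingError(
        f"could not place {config.n_cells} cells of radius "
        f"{config.cell_radius_range} in a {h}x{w} frame"
    )


def _try_sample_geometry(rng: np.random.Generator, config: SceneConfig) -> SyntheticSample | None:
    h, w = config.image_height, config.image_width
    n = config.n_cells
    r_lo, r_hi = config.cell_radius_range

    n_clustered = int(round(config.cluster_fraction * n))
    if n_clustered == 1:
        n_clustered = 2 if n >= 2 else 0
    cluster_sizes = _partition_clusters(rng, n_clustered) if n_clustered >= 2 else []

    radii = rng.uniform(r_lo, r_hi, size=n)
    centers = np.zeros((n, 2))  # (y, x)
    cluster_id = np.full(n, -1)

    def far_enough(idx: int, cy: float, cx: float, same_cluster: int) -> bool:
        for j in range(idx):
            if cluster_id[j] == same_cluster and same_cluster >= 0:
                continue
            d = np.hypot(cy - centers[j, 0], cx - centers[j, 1])
            if d < radii[idx] + radii[j] + 6:
                return False
        return True

    idx = 0
    margin = 0.55
    for cid, size in enumerate(cluster_sizes):
        # anchor of the cluster, then mates overlapping a previous member
        for k in range(size):
            placed = False
            for _ in range(200):
                if k == 0:
                    cy = rng.uniform(margin * radii[idx], h - margin * radii[idx])
                    cx = rng.uniform(margin * radii[idx], w - margin * radii[idx])
                else:
                    ref = idx - rng.integers(1, k + 1)
                    d = rng.uniform(0.65, 0.9) * (radii[idx] + radii[ref])
                    ang = rng.uniform(0, 2 * np.pi)
                    cy = centers[ref, 0] + d * np.sin(ang)
                    cx = centers[ref, 1] + d * np.cos(ang)
                    if not (0 <= cy < h and 0 <= cx < w):
                        continue
                if far_enough(idx, cy, cx, cid):
                    centers[idx] = (cy, cx)
                    cluster_id[idx] = cid
                    placed = True
                    break
            if not placed:
                return None
            idx += 1
    while idx < n:
        placed = False
        for _ in range(200):
            cy = rng.uniform(margin * radii[idx], h - margin * radii[idx])
            cx = rng.uniform(margin * radii[idx], w - margin * radii[idx])
            if far_enough(idx, cy, cx, -1):
                centers[idx] = (cy, cx)
                placed = True
                break
        if not placed:
            return None
        idx += 1

    raw_masks = [
        _star_polygon(rng, centers[i, 0], centers[i, 1], radii[i], (h, w))
        for i in range(n)
    ]
    # resolve overlaps: contested pixels go to the cell of smallest
    # radius-normalized center distance (a weighted Voronoi partition)
    claim = np.zeros((h, w), dtype=np.int16)
    for m in raw_masks:
        claim += m
    label_map = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for i, m in enumerate(raw_masks):
        label_map[m & (claim == 1)] = i + 1
    contested = claim > 1
    if contested.any():
        best = np.full((h, w), np.inf)
        for i, m in enumerate(raw_masks):
            d = np.hypot(yy - centers[i, 0], xx - centers[i, 1]) / radii[i]
            take = contested & m & (d < best)
            best[take & m] = d[take & m]
            label_map[take] = i + 1

    cell_masks = [label_map == i + 1 for i in range(n)]
    if any(m.sum() < 30 for m in cell_masks):
        return None
    # every clustered cell must actually touch a cluster mate
    for cid in range(len(cluster_sizes)):
        members = [i for i in range(n) if cluster_id[i] == cid]
        for i in members:
            if not any(_four_adjacent(cell_masks[i], cell_masks[j]) for j in members if j != i):
                return None

    # nuclei: one per cell, a second with probability multinucleate_rate
    n_lo, n_hi = config.nucleus_radius_range
    nucleus_masks: list[np.ndarray] = []
    nucleus_to_cell: dict[int, int] = {}
    taken = np.zeros((h, w), dtype=bool)
    for i in range(n):
        k_nuclei = 2 if rng.random() < config.multinucleate_rate else 1
        offsets = [0.0] if k_nuclei == 1 else [-0.35, 0.35]
        ang = rng.uniform(0, 2 * np.pi)
        for off in offsets:
            nr = rng.uniform(n_lo, n_hi)
            placed_mask = None
            for _ in range(30):
                jy = centers[i, 0] + off * radii[i] * np.sin(ang) + rng.normal(0, 0.08 * radii[i])
                jx = centers[i, 1] + off * radii[i] * np.cos(ang) + rng.normal(0, 0.08 * radii[i])
                disk = (yy - jy) ** 2 + (xx - jx) ** 2 <= nr**2
                cand = disk & cell_masks[i] & ~taken
                if cand.sum() >= 0.5 * np.pi * nr**2:
                    placed_mask = cand
                    break
            if placed_mask is None:
                if off == 0.0:
                    return None
                continue  # second nucleus simply not placed
            taken |= placed_mask
            nucleus_masks.append(placed_mask)
            nucleus_to_cell[len(nucleus_masks)] = i + 1

    cell_truth = InstanceSet(shape=(h, w), masks=cell_masks,
                             labels=np.arange(1, n + 1))
    nucleus_truth = InstanceSet(shape=(h, w), masks=nucleus_masks,
                                labels=np.arange(1, len(nucleus_masks) + 1))
    return SyntheticSample(
        image_pair=None,
        cell_truth=cell_truth,
        nucleus_truth=nucleus_truth,
        nucleus_to_cell=nucleus_to_cell,
        config=config,
    )


def _contact_band(cell_label_map: np.ndarray) -> np.ndarray:
    """Pixels on either side of a boundary between two different cells."""
    lab = cell_label_map
    band = np.zeros(lab.shape, dtype=bool)
    for axis in (0, 1):
        for shift in (1, -1):
            neighbor = np.roll(lab, shift, axis=axis)
            edge = np.zeros_like(band)
            if axis == 0:
                edge[0 if shift == 1 else -1, :] = True
            else:
                edge[:, 0 if shift == 1 else -1] = True
            band |= (lab > 0) & (neighbor > 0) & (neighbor != lab) & ~edge
    return band


def render_channels(truth: SyntheticSample, config: SceneConfig | None = None) -> ImagePair:
    """Render the nucleus and cytoplasm intensity channels for a truth layout.

    Inside-cell pixels sit at ``cell_level``; pixels on the two-pixel band
    around a cell–cell contact are dimmed by ``contact_attenuation``; the
    rest of the frame sits at ``background_level``.  Gaussian read noise of
    standard deviation ``noise_sd`` is added to both channels from a render
    stream derived from the scene seed, so rendering is a pure function of
    (truth, config).
    """
    config = config or truth.config
    h, w = config.image_height, config.image_width
    cell_lab = truth.cell_truth.label_map(dtype=np.int32)
    nuc_lab = truth.nucleus_truth.label_map(dtype=np.int32)

    cell_img = np.full((h, w), config.background_level, dtype=np.float32)
    cell_img[cell_lab > 0] = config.cell_level
    band = _contact_band(cell_lab)
    cell_img[band] = config.cell_level * (1.0 - config.contact_attenuation)

    nuc_img = np.full((h, w), config.background_level, dtype=np.float32)
    nuc_img[nuc_lab > 0] = config.nucleus_level

    if config.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9E1]))
        nuc_img = nuc_img + rng.normal(0, config.noise_sd, size=(h, w)).astype(np.float32)
        cell_img = cell_img + rng.normal(0, config.noise_sd, size=(h, w)).astype(np.float32)
    return ImagePair(nucleus=np.clip(nuc_img, 0, None).astype(np.float32),
                     cell=np.clip(cell_img, 0, None).astype(np.float32))


def simulate_scene(config: SceneConfig) -> SyntheticSample:
    """Geometry plus rendering in one call."""
    sample = sample_geometry(config)
    sample.image_pair = render_channels(sample, config)
    return sample


def generate_dataset(base_config: SceneConfig, n_samples: int, seed: int | None = None) -> list[SyntheticSample]:
    """Generate ``n_samples`` scenes with independent per-scene seed streams."""
    root = base_config.seed if seed is None else seed
    ss = np.random.SeedSequence(root)
    scene_seeds = ss.generate_state(n_samples) % (2**31 - 1)
    return [simulate_scene(replace(base_config, seed=int(s))) for s in scene_seeds]


def write_dataset(samples: list[SyntheticSample], directory: str | Path,
                  n_train: int | None = None, n_test: int | None = None) -> dict:
    """Write TIFF channels, 16-bit label masks, and a JSON manifest.

    The split defaults to the 64:18 train:test proportion of the emulated
    benchmark, scaled to the number of samples.
    """
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = len(samples)
    if n_train is None:
        n_train = int(round(n * 64 / 82))
    if n_test is None:
        n_test = n - n_train
    if n_train + n_test > n:
        raise ValueError("split exceeds number of samples")

    entries = []
    for i, s in enumerate(samples):
        if s.image_pair is None:
            s.image_pair = render_channels(s)
        stem = f"sample_{i:04d}"
        paths = {
            "nucleus": f"{stem}_nucleus.tif",
            "cell": f"{stem}_cell.tif",
            "nucleus_masks": f"{stem}_nucleus_masks.tif",
            "cell_masks": f"{stem}_cell_masks.tif",
        }
        try:
            tifffile.imwrite(directory / paths["nucleus"],
                             np.clip(np.round(s.image_pair.nucleus), 0, 65535).astype(np.uint16))
            tifffile.imwrite(directory / paths["cell"],
                             np.clip(np.round(s.image_pair.cell), 0, 65535).astype(np.uint16))
            tifffile.imwrite(directory / paths["nucleus_masks"],
                             s.nucleus_truth.label_map(np.uint16))
            tifffile.imwrite(directory / paths["cell_masks"],
                             s.cell_truth.label_map(np.uint16))
        except OSError as e:
            raise OSError(f"failed writing sample files under {directory}: {e}") from e
        entries.append({
            "id": stem,
            "split": "train" if i < n_train else ("test" if i < n_train + n_test else "extra"),
            "paths": paths,
            "nucleus_to_cell": {str(k): int(v) for k, v in s.nucleus_to_cell.items()},
            "seed": s.config.seed,
        })
    manifest = {
        "root": str(directory),
        "n_train": n_train,
        "n_test": n_test,
        "samples": entries,
    }
    with open(directory / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest


def micro_scene_config(seed: int = 0, **overrides) -> SceneConfig:
    """Desk-scale scene: 128x128 frame, 4 cells with proportionally smaller
    radii than the 256x256 default, same clustering and contact regime."""
    base = dict(
        image_height=128, image_width=128, n_cells=4, cluster_fraction=0.5,
        cell_radius_range=(14.0, 22.0), nucleus_radius_range=(5.0, 8.0),
        seed=seed,
    )
    base.update(overrides)
    return SceneConfig(**base)
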