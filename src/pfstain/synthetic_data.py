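"""Synthetic two-domain stained patches with known ground truth.

Real H&E/EBER slide pairs cannot ship with the package, so every other
module is exercised on rendered scenes that reproduce the stain statistics
the rule cascade relies on:

* EBER-positive nuclei are dark blue: R channel strictly below 100;
* EBER-negative tissue is pink: R channel strictly above 200 but not
  glass-white (min(R,G,B) stays under the background cutoff);
* glass background is near-saturated in all channels;
* tumor nuclei have a minimum footprint (~125 px at full resolution, the
  measured average of the smallest tumor cell per patch);
* in the source (H&E-like) domain, tumor nuclei and small lymphocyte-like
  cells are rendered with clearly separable palettes — a deliberate
  simplification, since the morphological differences in real H&E are not
  reducible to colour intervals.

Cells are noisy discs on a tissue (or glass) canvas; per-pixel noise is
drawn uniformly *within* each palette interval, so palette compliance holds
exactly and ground-truth masks coincide with rendered positive pixels by
construction. All rendering is a pure function of the scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ChannelRange",
    "StainPalette",
    "CellSpec",
    "SyntheticScene",
    "InvalidSceneError",
    "UnpairedSet",
    "disc_mask",
    "render_pair",
    "render_pseudo_wsi",
    "make_unpaired_training_set",
    "random_scene",
    "write_patch_set",
    "MIN_TUMOR_AREA",
]

#: Minimum tumor-cell footprint in pixels (average measured smallest cell).
MIN_TUMOR_AREA = 125

ChannelRange = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class StainPalette:
    """Inclusive per-channel 8-bit intensity intervals for each material."""

    positive_rgb_range: ChannelRange = ((40, 90), (40, 100), (110, 170))
    negative_rgb_range: ChannelRange = ((210, 250), (140, 180), (150, 190))
    background_rgb_range: ChannelRange = ((235, 255), (235, 255), (235, 255))
    he_tumor_rgb_range: ChannelRange = ((80, 130), (50, 90), (140, 190))
    he_stroma_rgb_range: ChannelRange = ((200, 240), (140, 180), (170, 210))
    he_lymphocyte_rgb_range: ChannelRange = ((25, 60), (30, 70), (120, 170))
    background_cutoff: int = 230

    def __post_init__(self):
        for name, rng_ in vars(self).items():
            if name == "background_cutoff":
                continue
            for lo, hi in rng_:
                if not 0 <= lo <= hi <= 255:
                    raise ValueError(f"invalid interval {lo}..{hi} in {name}")
        if self.positive_rgb_range[0][1] >= 100:
            raise ValueError("positive range must have R upper bound < 100")
        if self.negative_rgb_range[0][0] <= 200:
            raise ValueError("negative range must have R lower bound > 200")
        if any(lo < self.background_cutoff for lo, _ in self.background_rgb_range):
            raise ValueError("background range must start at the background cutoff")


@dataclass(frozen=True)
class CellSpec:
    center: tuple[int, int]  # (row, col)
    radius: int
    cls: str  # "tumor" | "non_tumor"

    def __post_init__(self):
        if self.cls not in ("tumor", "non_tumor"):
            raise ValueError(f"unknown cell class {self.cls!r}")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")


class InvalidSceneError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticScene:
    canvas_size: tuple[int, int]  # (H, W)
    cells: tuple[CellSpec, ...]
    seed: int
    has_tissue: bool = True


def disc_mask(shape: tuple[int, int], center: tuple[int, int], radius: int) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _disc_area(radius: int) -> int:
    rr, cc = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return int((rr**2 + cc**2 <= radius**2).sum())


def validate_scene(scene: SyntheticScene, min_tumor_area: int = MIN_TUMOR_AREA) -> None:
    h, w = scene.canvas_size
    if h < 1 or w < 1:
        raise InvalidSceneError("canvas must be at least 1x1")
    for cell in scene.cells:
        r, c = cell.center
        if not (cell.radius <= r < h - cell.radius and cell.radius <= c < w - cell.radius):
            raise InvalidSceneError(
                f"cell at {cell.center} radius {cell.radius} does not fit the "
                f"{h}x{w} canvas"
            )
        if cell.cls == "tumor" and _disc_area(cell.radius) < min_tumor_area:
            raise InvalidSceneError(
                f"tumor cell radius {cell.radius} has footprint "
                f"{_disc_area(cell.radius)} < minimum {min_tumor_area}"
            )


def _fill(img: np.ndarray, where: np.ndarray, ranges: ChannelRange, rng) -> None:
    n = int(where.sum())
    for ch, (lo, hi) in enumerate(ranges):
        img[..., ch][where] = rng.integers(lo, hi + 1, size=n)


def render_pair(
    scene: SyntheticScene,
    palette: StainPalette | None = None,
    min_tumor_area: int = MIN_TUMOR_AREA,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one scene in both stain styles.

    Returns ``(source, target, mask)``: the H&E-like patch, the EBER-like
    patch of the same scene, and the ground-truth positivity mask marking
    exactly the tumor-cell pixels.
    """
    palette = palette or StainPalette()
    validate_scene(scene, min_tumor_area)
    rng = np.random.default_rng(scene.seed)
    h, w = scene.canvas_size
    source = np.zeros((h, w, 3), dtype=np.uint8)
    target = np.zeros((h, w, 3), dtype=np.uint8)

    everywhere = np.ones((h, w), dtype=bool)
    if scene.has_tissue:
        _fill(source, everywhere, palette.he_stroma_rgb_range, rng)
        _fill(target, everywhere, palette.negative_rgb_range, rng)
    else:
        _fill(source, everywhere, palette.background_rgb_range, rng)
        _fill(target, everywhere, palette.background_rgb_range, rng)

    # paint non-tumor cells first so tumor pixels are never overwritten and
    # the ground-truth mask equals the rendered positive pixels exactly
    ordered = [c for c in scene.cells if c.cls == "non_tumor"] + [
        c for c in scene.cells if c.cls == "tumor"
    ]
    mask = np.zeros((h, w), dtype=np.uint8)
    for cell in ordered:
        disc = disc_mask((h, w), cell.center, cell.radius)
        if cell.cls == "tumor":
            _fill(source, disc, palette.he_tumor_rgb_range, rng)
            _fill(target, disc, palette.positive_rgb_range, rng)
            mask[disc] = 1
        else:
            _fill(source, disc, palette.he_lymphocyte_rgb_range, rng)
            _fill(target, disc, palette.negative_rgb_range, rng)
    return source, target, mask


def random_scene(
    seed: int,
    canvas_size: tuple[int, int] = (256, 256),
    tumor: bool = False,
    has_tissue: bool = True,
    min_tumor_area: int = MIN_TUMOR_AREA,
) -> SyntheticScene:
    """Draw a plausible random scene: a few small lymphocyte-like cells,
    plus 1-3 well-separated tumor nuclei if `tumor`."""
    rng = np.random.default_rng(seed)
    h, w = canvas_size
    cells: list[CellSpec] = []

    min_radius = 1
    while _disc_area(min_radius) < min_tumor_area:
        min_radius += 1
    max_radius = min(min_radius + 4, (min(h, w) - 2) // 2)
    if tumor and max_radius < min_radius:
        raise InvalidSceneError(
            f"canvas {h}x{w} too small for a tumor cell of footprint {min_tumor_area}"
        )

    def place(radius: int, cls: str) -> None:
        r = int(rng.integers(radius, h - radius))
        c = int(rng.integers(radius, w - radius))
        cells.append(CellSpec((r, c), radius, cls))

    if has_tissue:
        for _ in range(int(rng.integers(3, 9))):
            place(int(rng.integers(3, 6)), "non_tumor")
        if tumor:
            for _ in range(int(rng.integers(1, 4))):
                place(int(rng.integers(min_radius, max_radius + 1)), "tumor")
    return SyntheticScene((h, w), tuple(cells), seed=int(seed), has_tissue=has_tissue)


def render_pseudo_wsi(
    n_tiles_x: int,
    n_tiles_y: int,
    tumor_tiles: set[tuple[int, int]],
    palette: StainPalette | None = None,
    seed: int = 0,
    tile_size: int = 256,
    tissue_tiles: set[tuple[int, int]] | None = None,
    min_tumor_area: int = MIN_TUMOR_AREA,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a tiled pseudo-whole-slide image in both stain styles.

    `tumor_tiles` are ``(row, col)`` grid positions that receive at least one
    tumor cell above the minimum footprint; all other tiles receive none.
    `tissue_tiles` restricts which tiles carry tissue at all (default: all);
    non-tissue tiles are glass. Returns ``(source_wsi, target_wsi, labels)``
    with `labels` an (n_tiles_y, n_tiles_x) {0,1} grid.
    """
    if n_tiles_x < 1 or n_tiles_y < 1:
        raise ValueError("grid dimensions must be >= 1")
    palette = palette or StainPalette()
    for pos in tumor_tiles:
        if not (0 <= pos[0] < n_tiles_y and 0 <= pos[1] < n_tiles_x):
            raise ValueError(f"tumor tile {pos} outside {n_tiles_y}x{n_tiles_x} grid")
    if tissue_tiles is None:
        tissue_tiles = {(r, c) for r in range(n_tiles_y) for c in range(n_tiles_x)}
    missing = set(tumor_tiles) - tissue_tiles
    if missing:
        raise ValueError(f"tumor tiles {sorted(missing)} are not tissue tiles")

    source = np.zeros((n_tiles_y * tile_size, n_tiles_x * tile_size, 3), dtype=np.uint8)
    target = np.zeros_like(source)
    labels = np.zeros((n_tiles_y, n_tiles_x), dtype=np.uint8)
    for r in range(n_tiles_y):
        for c in range(n_tiles_x):
            tile_seed = int(
                np.random.SeedSequence([seed, r, c]).generate_state(1)[0] % (2**31)
            )
            scene = random_scene(
                tile_seed,
                (tile_size, tile_size),
                tumor=(r, c) in tumor_tiles,
                has_tissue=(r, c) in tissue_tiles,
                min_tumor_area=min_tumor_area,
            )
            src, tgt, _ = render_pair(scene, palette, min_tumor_area)
            sl = (slice(r * tile_size, (r + 1) * tile_size), slice(c * tile_size, (c + 1) * tile_size))
            source[sl] = src
            target[sl] = tgt
            labels[r, c] = 1 if (r, c) in tumor_tiles else 0
    return source, target, labels


@dataclass
class UnpairedSet:
    """Unpaired training material with ground truth retained for validation."""

    source_patches: np.ndarray  # (n, H, W, 3) uint8
    source_labels: np.ndarray  # (n,) {0,1}, 1 iff the patch contains tumor
    target_patches: np.ndarray
    target_labels: np.ndarray
    seed: int
    palette: StainPalette = field(default_factory=StainPalette)


def make_unpaired_training_set(
    n_source: int,
    n_target: int,
    tumor_fraction: float,
    seed: int = 0,
    patch_size: int = 256,
    palette: StainPalette | None = None,
    min_tumor_area: int = MIN_TUMOR_AREA,
) -> UnpairedSet:
    """Generate independent source- and target-domain patch sets.

    Each patch contains tumor with probability `tumor_fraction`; the two
    domains are sampled independently (unpaired, as in real H&E/EBER slides
    from different sections).
    """
    if n_source < 1 or n_target < 1:
        raise ValueError("patch counts must be >= 1")
    if not 0 <= tumor_fraction <= 1:
        raise ValueError("tumor_fraction must be in [0, 1]")
    palette = palette or StainPalette()
    root = np.random.default_rng(np.random.SeedSequence([seed]))

    def draw(n: int, keep: str):
        patches = np.zeros((n, patch_size, patch_size, 3), dtype=np.uint8)
        labels = np.zeros(n, dtype=np.uint8)
        for i in range(n):
            tumor = bool(root.random() < tumor_fraction)
            scene_seed = int(root.integers(0, 2**31))
            scene = random_scene(
                scene_seed, (patch_size, patch_size), tumor=tumor,
                min_tumor_area=min_tumor_area,
            )
            src, tgt, _ = render_pair(scene, palette, min_tumor_area)
            patches[i] = src if keep == "source" else tgt
            labels[i] = int(tumor)
        return patches, labels

    src, src_labels = draw(n_source, "source")
    tgt, tgt_labels = draw(n_target, "target")
    return UnpairedSet(src, src_labels, tgt, tgt_labels, seed=seed, palette=palette)


def write_patch_set(
    patches: np.ndarray,
    labels: np.ndarray,
    domain: str,
    outdir: str | Path,
    seed: int,
) -> pd.DataFrame:
    """Write patches as PNGs plus a CSV manifest (path,label,domain,seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (patch, label) in enumerate(zip(patches, labels)):
        name = f"{domain}_{i:05d}.png"
        Image.fromarray(patch).save(outdir / name)
        rows.append({"path": name, "label": int(label), "domain": domain, "seed": seed})
    manifest = pd.DataFrame(rows, columns=["path", "label", "domain", "seed"])
    manifest.to_csv(outdir / f"{domain}_manifest.csv", index=False)
    return manifest
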