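"""Slide-level plumbing: foreground detection, overlapping tile extraction,
and reconstruction of translated slides and tumor masks from per-tile output.

Coordinates are 0-based (row, col) with the origin at the top-left; tiles
are half-open ``[r, r+tile) x [c, c+tile)`` crops. The last row/column of
origins is clamped so tiles never leave the slide (edge tiles may overlap
more); no pixels are invented by padding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SlideLayout",
    "grid_origins",
    "detect_foreground",
    "extract_tiles",
    "reconstruct",
]


@dataclass(frozen=True)
class SlideLayout:
    """Tile grid geometry for one slide."""

    slide_shape: tuple[int, int]  # (H, W)
    tile_size: int
    stride: int
    origins: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        h, w = self.slide_shape
        if self.tile_size < 1 or self.tile_size > min(h, w):
            raise ValueError(f"tile size {self.tile_size} does not fit slide {h}x{w}")
        if not 1 <= self.stride <= self.tile_size:
            raise ValueError("stride must be in [1, tile_size] (overlapping tiles)")
        if len(set(self.origins)) != len(self.origins):
            raise ValueError("duplicate tile origins")
        for r, c in self.origins:
            if not (0 <= r <= h - self.tile_size and 0 <= c <= w - self.tile_size):
                raise ValueError(f"origin {(r, c)} out of bounds for slide {h}x{w}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "slide_shape": list(self.slide_shape),
                "tile_size": self.tile_size,
                "stride": self.stride,
                "origins": [list(o) for o in self.origins],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SlideLayout":
        d = json.loads(text)
        return cls(
            tuple(d["slide_shape"]),
            d["tile_size"],
            d["stride"],
            tuple(tuple(o) for o in d["origins"]),
        )


def _axis_origins(extent: int, tile: int, stride: int) -> list[int]:
    """Origins along one axis; the final origin is clamped to extent - tile."""
    last = extent - tile
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


def grid_origins(slide_shape: tuple[int, int], tile_size: int, stride: int) -> list[tuple[int, int]]:
    rows = _axis_origins(slide_shape[0], tile_size, stride)
    cols = _axis_origins(slide_shape[1], tile_size, stride)
    return [(r, c) for r in rows for c in cols]


def detect_foreground(
    slide: np.ndarray,
    background_min_intensity: int = 230,
    min_foreground_fraction: float = 0.05,
    tile_size: int = 256,
    stride: int | None = None,
) -> tuple[dict[tuple[int, int], bool], SlideLayout]:
    """Flag tissue-bearing tiles and build the layout of foreground tiles.

    A pixel is background iff min(R, G, B) >= `background_min_intensity`;
    a tile is foreground iff its fraction of non-background pixels is at
    least `min_foreground_fraction` (a threshold of 0 keeps every tile).
    Returns ``(flags over the full grid, layout listing foreground tiles)``.
    """
    slide = np.asarray(slide)
    if slide.ndim != 3 or slide.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) slide, got shape {slide.shape}")
    stride = tile_size if stride is None else stride
    flags: dict[tuple[int, int], bool] = {}
    kept: list[tuple[int, int]] = []
    not_bg = slide.min(axis=2) < background_min_intensity
    for r, c in grid_origins(slide.shape[:2], tile_size, stride):
        frac = not_bg[r : r + tile_size, c : c + tile_size].mean()
        is_fg = bool(
            frac >= min_foreground_fraction
            if min_foreground_fraction > 0
            else True
        )
        flags[(r, c)] = is_fg
        if is_fg:
            kept.append((r, c))
    layout = SlideLayout(slide.shape[:2], tile_size, stride, tuple(kept))
    return flags, layout


def extract_tiles(slide: np.ndarray, layout: SlideLayout) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Crop every layout origin; returns ``[(origin, tile), ...]`` in order."""
    slide = np.asarray(slide)
    if slide.shape[:2] != layout.slide_shape:
        raise ValueError(
            f"slide shape {slide.shape[:2]} does not match layout {layout.slide_shape}"
        )
    t = layout.tile_size
    return [((r, c), slide[r : r + t, c : c + t].copy()) for r, c in layout.origins]


def reconstruct(
    tile_outputs: dict[tuple[int, int], np.ndarray],
    layout: SlideLayout,
    mode: str = "mean",
    background_value: int = 255,
) -> np.ndarray:
    """Assemble per-tile outputs back into a slide-sized array.

    ``mode="mean"`` averages overlapping image tiles (uncovered pixels take
    `background_value`); ``mode="or"`` combines binary masks by logical OR
    (uncovered pixels are 0).
    """
    missing = [o for o in layout.origins if o not in tile_outputs]
    if missing:
        raise ValueError(f"missing tile outputs at origins: {missing}")
    t = layout.tile_size
    h, w = layout.slide_shape
    sample = np.asarray(next(iter(tile_outputs.values()))) if tile_outputs else None

    if mode == "or":
        out = np.zeros((h, w), dtype=np.uint8)
        for (r, c) in layout.origins:
            tile = np.asarray(tile_outputs[(r, c)])
            out[r : r + t, c : c + t] |= (tile > 0).astype(np.uint8)
        return out
    if mode == "mean":
        channels = sample.shape[2] if sample is not None and sample.ndim == 3 else 1
        acc = np.zeros((h, w, channels), dtype=np.float64)
        count = np.zeros((h, w, 1), dtype=np.float64)
        for (r, c) in layout.origins:
            tile = np.asarray(tile_outputs[(r, c)], dtype=np.float64)
            if tile.ndim == 2:
                tile = tile[:, :, None]
            acc[r : r + t, c : c + t] += tile
            count[r : r + t, c : c + t] += 1
        covered = count[:, :, 0] > 0
        out = np.full((h, w, channels), float(background_value))
        out[covered] = acc[covered] / count[covered]
        out = np.rint(out).astype(np.uint8)
        return out[:, :, 0] if (sample is not None and sample.ndim == 2) else out
    raise ValueError(f"unknown reconstruction mode {mode!r}")
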