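"""Whole-slide tiling: crop slides and masks into fixed-size labeled tiles.

Whole-slide images are far too large for direct network input, so each slide
(and its paired binary mask) is cropped on a non-overlapping grid of
``tile_size`` x ``tile_size`` windows anchored at the top-left corner. A tile
is labeled ``glomerulus`` when its mask contains at least one positive pixel,
``non-glomerulus`` otherwise. Tiles can then be split (reproducibly) into
train/test sets, either per tile or per slide.

Coordinates are 0-based ``(row, col)`` with a top-left origin; the tile at
origin ``(r, c)`` covers the half-open window ``[r, r+T) x [c, c+T)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .rle_codec import validate_binary, write_mask_png

GLOMERULUS = "glomerulus"
NON_GLOMERULUS = "non-glomerulus"

EdgePolicy = Literal["pad-zero", "drop"]

DEFAULT_TILE_SIZE = 512


@dataclass
class WholeSlide:
    """An RGB whole-slide image with an optional paired binary mask."""

    image: np.ndarray  # H x W x 3, uint8
    id: str
    mask: np.ndarray | None = None  # H x W, {0,1}

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(
                f"slide image must be HxWx3 RGB, got shape {self.image.shape}"
            )
        if self.mask is not None:
            self.mask = validate_binary(self.mask)
            if self.mask.shape != self.image.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match slide "
                    f"shape {self.image.shape[:2]}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


def label_tile(mask: np.ndarray) -> str:
    """Label a tile mask: ``glomerulus`` iff it has >= 1 positive pixel."""
    return GLOMERULUS if validate_binary(mask).any() else NON_GLOMERULUS


@dataclass
class Tile:
    """A fixed-size crop of a slide with its mask crop and presence label."""

    image: np.ndarray  # T x T x 3
    mask: np.ndarray  # T x T, {0,1}
    origin: tuple[int, int]  # (row, col) in parent pixels, 0-based
    parent_id: str
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.mask = validate_binary(self.mask)
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"tile image {self.image.shape[:2]} / mask {self.mask.shape} mismatch"
            )
        self.label = label_tile(self.mask)

    @property
    def size(self) -> int:
        return self.image.shape[0]


class TileSet:
    """An ordered collection of tiles with presence-label bookkeeping."""

    def __init__(self, tiles: Iterable[Tile] = ()) -> None:
        self.tiles: list[Tile] = list(tiles)

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)

    def __getitem__(self, i: int) -> Tile:
        return self.tiles[i]

    def append(self, tile: Tile) -> None:
        self.tiles.append(tile)

    def extend(self, tiles: Iterable[Tile]) -> None:
        self.tiles.extend(tiles)

    @property
    def n_glomerulus(self) -> int:
        return sum(t.label == GLOMERULUS for t in self.tiles)

    @property
    def n_non_glomerulus(self) -> int:
        return len(self.tiles) - self.n_glomerulus

    @property
    def counts(self) -> dict[str, int]:
        g = self.n_glomerulus
        return {"total": len(self.tiles), GLOMERULUS: g,
                NON_GLOMERULUS: len(self.tiles) - g}

    def manifest(self) -> pd.DataFrame:
        """Tile manifest table: parent_id, row, col, label."""
        return pd.DataFrame(
            [{"parent_id": t.parent_id, "row": t.origin[0],
              "col": t.origin[1], "label": t.label} for t in self.tiles]
        )


def tile_slide(
    slide: WholeSlide,
    tile_size: int = DEFAULT_TILE_SIZE,
    edge_policy: EdgePolicy = "pad-zero",
) -> TileSet:
    """Crop a slide into a non-overlapping grid of labeled tiles.

    The grid is anchored at (0, 0) with stride ``tile_size``. With
    ``edge_policy="pad-zero"`` partial border tiles are zero-padded on the
    bottom/right, giving ``ceil(H/T) * ceil(W/T)`` tiles; with ``"drop"``
    partial tiles are discarded, giving ``floor(H/T) * floor(W/T)``. A slide
    without a mask is tiled against an all-zero mask (every tile
    non-glomerulus).
    """
    if tile_size < 1:
        raise ValueError(f"tile_size must be >= 1, got {tile_size}")
    if edge_policy not in ("pad-zero", "drop"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    H, W = slide.shape
    mask = slide.mask if slide.mask is not None else np.zeros((H, W), np.uint8)
    T = tile_size
    if edge_policy == "drop":
        n_rows, n_cols = H // T, W // T
    else:
        n_rows, n_cols = math.ceil(H / T), math.ceil(W / T)
    tiles = TileSet()
    for i in range(n_rows):
        for j in range(n_cols):
            r, c = i * T, j * T
            img = slide.image[r : r + T, c : c + T]
            msk = mask[r : r + T, c : c + T]
            if img.shape[:2] != (T, T):
                pad_img = np.zeros((T, T, 3), dtype=slide.image.dtype)
                pad_img[: img.shape[0], : img.shape[1]] = img
                pad_msk = np.zeros((T, T), dtype=np.uint8)
                pad_msk[: msk.shape[0], : msk.shape[1]] = msk
                img, msk = pad_img, pad_msk
            tiles.append(Tile(img, msk, (r, c), slide.id))
    return tiles


def split_tiles(
    tiles: TileSet,
    train_fraction: float,
    seed: int,
    group_by_slide: bool = False,
) -> tuple[TileSet, TileSet]:
    """Partition a tile set into disjoint, exhaustive train/test sets.

    With ``group_by_slide=True`` the seeded shuffle acts on slide ids and the
    fraction is applied to slides, so no slide straddles the split — the
    recommended setting, since tiles from one slide are not independent and a
    per-tile split leaks slide-level appearance into the test set.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(
            f"train_fraction must be in (0, 1), got {train_fraction}"
        )
    rng = np.random.default_rng(seed)
    if group_by_slide:
        slide_ids = sorted({t.parent_id for t in tiles})
        order = rng.permutation(len(slide_ids))
        n_train = round(train_fraction * len(slide_ids))
        train_ids = {slide_ids[k] for k in order[:n_train]}
        train = TileSet(t for t in tiles if t.parent_id in train_ids)
        test = TileSet(t for t in tiles if t.parent_id not in train_ids)
    else:
        order = rng.permutation(len(tiles))
        n_train = round(train_fraction * len(tiles))
        train = TileSet(tiles[int(k)] for k in sorted(order[:n_train]))
        test = TileSet(tiles[int(k)] for k in sorted(order[n_train:]))
    return train, test


def stitch_tiles(tiles: Sequence[Tile], height: int, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Reassemble tiles by origin into an (image, mask) pair.

    Inverse of :func:`tile_slide` under the drop policy on grid-aligned
    slides; padded border content is cropped away by the target shape.
    """
    image = np.zeros((height, width, 3), dtype=tiles[0].image.dtype)
    mask = np.zeros((height, width), dtype=np.uint8)
    for t in tiles:
        r, c = t.origin
        h = min(t.size, height - r)
        w = min(t.size, width - c)
        if h <= 0 or w <= 0:
            continue
        image[r : r + h, c : c + w] = t.image[:h, :w]
        mask[r : r + h, c : c + w] = t.mask[:h, :w]
    return image, mask


def write_tiles(tiles: TileSet, out_dir: str | Path) -> Path:
    """Write tiles as PNG pairs plus a ``tiles.csv`` manifest.

    Files follow ``{parent_id}_{row}_{col}.png`` and
    ``{parent_id}_{row}_{col}_mask.png``; the manifest has columns
    parent_id, row, col, label.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for t in tiles:
        stem = f"{t.parent_id}_{t.origin[0]}_{t.origin[1]}"
        Image.fromarray(t.image, mode="RGB").save(out / f"{stem}.png")
        write_mask_png(t.mask, out / f"{stem}_mask.png")
    manifest_path = out / "tiles.csv"
    tiles.manifest().to_csv(manifest_path, index=False)
    return manifest_path
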