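"""Class-balancing augmentation of glomerulus tiles.

Tiled whole-slide datasets are heavily imbalanced: most tiles contain no
glomerulus. To rebalance, each glomerulus tile is augmented with geometric
transforms — horizontal flip, horizontal shift, vertical shift — that apply
identically to the image and its mask so the pixel-level ground truth stays
aligned. With the default two augmented copies per original the glomerulus
class triples in size (13,441 tiles become 40,323 images at full scale).

Shifts translate the content and fill the vacated band with a constant (black
by default) in the image and 0 in the mask; a shift can evict every positive
pixel, in which case the tile's presence label is recomputed and may flip.
Augmentation is for training tiles only — never augment evaluation tiles.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .tiling import GLOMERULUS, Tile, TileSet

HORIZONTAL_FLIP = "horizontal_flip"
HORIZONTAL_SHIFT = "horizontal_shift"
VERTICAL_SHIFT = "vertical_shift"
TECHNIQUES = (HORIZONTAL_FLIP, HORIZONTAL_SHIFT, VERTICAL_SHIFT)

#: manifest `source` tags per technique
SOURCE_TAGS = {
    None: "original",
    HORIZONTAL_FLIP: "flip",
    HORIZONTAL_SHIFT: "hshift",
    VERTICAL_SHIFT: "vshift",
}


@dataclass
class AugmentConfig:
    """Configuration of the balancing augmentation.

    ``shift_fraction`` bounds the random shift magnitude as a fraction of the
    tile size (offsets are drawn uniformly from ``[1, shift_fraction * T]``
    pixels, with a random sign); ``fill`` is the constant written into the
    vacated image band. ``copies_per_tile`` augmented copies are added to
    each original, so the output is ``(1 + copies_per_tile)`` times the input.
    """

    techniques: Sequence[str] = TECHNIQUES
    shift_fraction: float = 0.1
    fill: int = 0
    copies_per_tile: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.techniques) - set(TECHNIQUES)
        if unknown:
            raise ValueError(f"unknown augmentation technique(s) {sorted(unknown)}")
        if not self.techniques:
            raise ValueError("techniques must be non-empty")
        if not 0.0 < self.shift_fraction < 1.0:
            raise ValueError(f"shift_fraction must be in (0, 1), got {self.shift_fraction}")
        if self.copies_per_tile < 1:
            raise ValueError(f"copies_per_tile must be >= 1, got {self.copies_per_tile}")


def horizontal_flip(tile: Tile) -> Tile:
    """Mirror a tile (image and mask) about the vertical axis."""
    return Tile(
        image=tile.image[:, ::-1].copy(),
        mask=tile.mask[:, ::-1].copy(),
        origin=tile.origin,
        parent_id=tile.parent_id,
    )


def shift(
    tile: Tile,
    axis: Literal["horizontal", "vertical"],
    offset: int,
    fill: int = 0,
) -> Tile:
    """Translate a tile by ``offset`` pixels along ``axis``.

    Positive offsets move content right (horizontal) or down (vertical). The
    vacated band gets ``fill`` in the image and 0 in the mask; the label is
    recomputed, since a shift can push every glomerulus pixel off the tile.
    """
    T = tile.size
    if abs(offset) >= T:
        raise ValueError(f"|offset| {abs(offset)} must be < tile size {T}")
    ax = {"vertical": 0, "horizontal": 1}.get(axis)
    if ax is None:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    image = np.full_like(tile.image, fill)
    mask = np.zeros_like(tile.mask)
    if offset == 0:
        image[...] = tile.image
        mask[...] = tile.mask
    elif ax == 0:
        if offset > 0:
            image[offset:], mask[offset:] = tile.image[:-offset], tile.mask[:-offset]
        else:
            image[:offset], mask[:offset] = tile.image[-offset:], tile.mask[-offset:]
    else:
        if offset > 0:
            image[:, offset:], mask[:, offset:] = tile.image[:, :-offset], tile.mask[:, :-offset]
        else:
            image[:, :offset], mask[:, :offset] = tile.image[:, -offset:], tile.mask[:, -offset:]
    return Tile(image=image, mask=mask, origin=tile.origin, parent_id=tile.parent_id)


def _apply_technique(tile: Tile, technique: str, config: AugmentConfig,
                     rng: np.random.Generator) -> Tile:
    if technique == HORIZONTAL_FLIP:
        return horizontal_flip(tile)
    max_off = max(1, int(config.shift_fraction * tile.size))
    offset = int(rng.integers(1, max_off + 1)) * (1 if rng.random() < 0.5 else -1)
    axis = "horizontal" if technique == HORIZONTAL_SHIFT else "vertical"
    return shift(tile, axis, offset, fill=config.fill)


def balance_dataset(
    glom_tiles: TileSet, config: AugmentConfig | None = None
) -> tuple[TileSet, list[str]]:
    """Augment glomerulus tiles into a class-balanced set.

    Every input tile must be labeled glomerulus. Originals are retained
    verbatim, followed by ``copies_per_tile`` augmented copies each, produced
    by a seeded draw from ``config.techniques`` (shifts use seeded offsets).
    The output size is ``len(glom_tiles) * (1 + copies_per_tile)``; the
    companion list gives each output tile's source tag
    (original | flip | hshift | vshift).
    """
    config = config or AugmentConfig()
    for t in glom_tiles:
        if t.label != GLOMERULUS:
            raise ValueError(
                f"balance_dataset expects glomerulus tiles only; tile at "
                f"origin {t.origin} of slide {t.parent_id!r} is {t.label}"
            )
    rng = np.random.default_rng(config.seed)
    out = TileSet()
    sources: list[str] = []
    techniques = list(config.techniques)
    for tile in glom_tiles:
        out.append(copy.deepcopy(tile))
        sources.append(SOURCE_TAGS[None])
        for _ in range(config.copies_per_tile):
            technique = techniques[int(rng.integers(len(techniques)))]
            out.append(_apply_technique(tile, technique, config, rng))
            sources.append(SOURCE_TAGS[technique])
    return out, sources
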