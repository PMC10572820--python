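"""Synthetic whole-slide imagery with glomerulus-like structures.

Generates RGB "slides" that coarsely mimic PAS-stained kidney tissue — a
pink-ish textured background — containing non-overlapping elliptical
glomerulus-like structures: a darker ring at the boundary and a mottled,
more saturated interior, echoing the capillary-tuft morphology seen in real
sections. Each slide comes with its exact binary ground-truth mask (the
union of ellipse interiors) and the mask's run-length encoding, so the
codec, tiling, augmentation and training modules are all exercisable
end-to-end without any external download.

This is an appearance model sufficient for segmentation learnability, not a
histological simulation: no nuclei, tubules, stain variation or scanner
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

from .rle_codec import RunLengthMask, encode_rle, write_mask_png, write_mask_table
from .tiling import Tile, TileSet, WholeSlide

# PAS-like palette (RGB, 0-255): light pink background, magenta interior,
# darker ring
BACKGROUND_COLOR = (233, 205, 220)
INTERIOR_COLOR = (186, 126, 168)
RING_COLOR = (128, 66, 116)


class PlacementError(RuntimeError):
    """Could not place the requested structures without overlap."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic slide.

    ``glomerulus_axis_range`` bounds the ellipse semi-axes in pixels;
    ``background_texture`` is the amplitude (in 0-255 intensity units) of
    the low-frequency background noise; ``ring_contrast`` scales how far
    ring and interior colors depart from the background.
    """

    slide_height: int = 1024
    slide_width: int = 1024
    n_glomeruli: int = 8
    glomerulus_axis_range: tuple[int, int] = (20, 60)
    background_texture: float = 10.0
    ring_contrast: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.glomerulus_axis_range
        if not 1 <= lo <= hi:
            raise ValueError(f"bad axis range {self.glomerulus_axis_range}")
        if 2 * hi >= min(self.slide_height, self.slide_width):
            raise ValueError(
                f"axes up to {hi} px cannot fit a "
                f"{self.slide_height}x{self.slide_width} slide"
            )
        if self.n_glomeruli < 0:
            raise ValueError("n_glomeruli must be >= 0")


MAX_PLACEMENT_RETRIES = 100  # rejection-sampling cap per structure


def _textured_background(h: int, w: int, amplitude: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Pink-ish base with smoothed low-frequency noise plus fine speckle."""
    img = np.empty((h, w, 3), dtype=np.float32)
    img[...] = BACKGROUND_COLOR
    low = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, (h, w)).astype(np.float32), sigma=max(h, w) / 40
    )
    low *= amplitude / max(low.std(), 1e-6)
    speckle = rng.normal(0.0, amplitude / 3, (h, w)).astype(np.float32)
    img += (low + speckle)[..., None]
    return img


def _ellipse_fields(h: int, w: int, center: tuple[float, float],
                    axes: tuple[float, float], angle: float) -> np.ndarray:
    """Normalized squared radius field of a rotated ellipse (<=1 inside)."""
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float32)
    dr, dc = rows - center[0], cols - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2


def _paint_glomerulus(img: np.ndarray, r2: np.ndarray, contrast: float,
                      rng: np.random.Generator) -> None:
    """Draw ring + mottled interior onto ``img`` where ``r2 <= 1``."""
    inside = r2 <= 1.0
    ring = inside & (r2 >= 0.7)
    core = inside & ~ring
    bg = np.array(BACKGROUND_COLOR, np.float32)
    interior = bg + contrast * (np.array(INTERIOR_COLOR, np.float32) - bg)
    ring_col = bg + contrast * (np.array(RING_COLOR, np.float32) - bg)
    img[core] = interior
    img[ring] = ring_col
    # capillary-tuft speckle inside the core
    mottle = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, r2.shape).astype(np.float32), sigma=2.0
    )
    mottle = 25.0 * contrast * mottle / max(mottle.std(), 1e-6)
    img[core] += mottle[core, None]


def generate_slide(
    config: SynthConfig | None = None,
) -> tuple[WholeSlide, np.ndarray, RunLengthMask]:
    """Generate one synthetic slide with its mask and RLE encoding.

    Structures are placed by rejection sampling so their bounding ellipses
    (with a small margin) never overlap; after 100 failed draws for one
    structure a :class:`PlacementError` is raised. Fully reproducible under
    ``config.seed``.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    h, w = config.slide_height, config.slide_width
    img = _textured_background(h, w, config.background_texture, rng)
    mask = np.zeros((h, w), dtype=np.uint8)
    placed: list[tuple[float, float, float]] = []  # (row, col, radius)
    for _ in range(config.n_glomeruli):
        for attempt in range(MAX_PLACEMENT_RETRIES):
            lo, hi = config.glomerulus_axis_range
            axes = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
            radius = max(axes)
            center = (
                float(rng.uniform(radius, h - radius)),
                float(rng.uniform(radius, w - radius)),
            )
            margin = 4.0
            if all(
                np.hypot(center[0] - r0, center[1] - c0) > radius + rad0 + margin
                for r0, c0, rad0 in placed
            ):
                break
        else:
            raise PlacementError(
                f"could not place structure {len(placed) + 1} of "
                f"{config.n_glomeruli} within {MAX_PLACEMENT_RETRIES} retries"
            )
        angle = float(rng.uniform(0.0, np.pi))
        r2 = _ellipse_fields(h, w, center, axes, angle)
        _paint_glomerulus(img, r2, config.ring_contrast, rng)
        mask[r2 <= 1.0] = 1
        placed.append((center[0], center[1], radius))
    slide = WholeSlide(
        image=np.clip(img, 0, 255).astype(np.uint8),
        id=f"synth-{config.seed:06d}",
        mask=mask,
    )
    return slide, mask, encode_rle(mask)


def _tile_background(T: int, rng: np.random.Generator,
                     amplitude: float = 10.0) -> np.ndarray:
    img = np.empty((T, T, 3), dtype=np.float32)
    img[...] = BACKGROUND_COLOR
    low = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, (T, T)).astype(np.float32), sigma=T / 8
    )
    low *= amplitude / max(low.std(), 1e-6)
    img += (low + rng.normal(0.0, amplitude / 3, (T, T)).astype(np.float32))[..., None]
    return img


def generate_tileset(
    n_glom_tiles: int,
    n_background_tiles: int,
    tile_size: int = 64,
    seed: int = 0,
) -> TileSet:
    """Generate labeled tiles directly, at any requested class composition.

    Glomerulus tiles contain one ellipse (ring + mottled interior) whose
    center lies inside the tile, guaranteeing at least one positive mask
    pixel; background tiles are pure textured tissue. Reproducible under
    ``seed``. Tile ids encode the class and index.
    """
    if n_glom_tiles < 0 or n_background_tiles < 0:
        raise ValueError("tile counts must be >= 0")
    rng = np.random.default_rng(seed)
    T = tile_size
    tiles = TileSet()
    for i in range(n_glom_tiles):
        img = _tile_background(T, rng)
        lo, hi = max(3, int(0.15 * T)), max(4, int(0.3 * T))
        axes = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
        center = (
            float(rng.uniform(0.25 * T, 0.75 * T)),
            float(rng.uniform(0.25 * T, 0.75 * T)),
        )
        angle = float(rng.uniform(0.0, np.pi))
        r2 = _ellipse_fields(T, T, center, axes, angle)
        _paint_glomerulus(img, r2, 1.0, rng)
        mask = (r2 <= 1.0).astype(np.uint8)
        tiles.append(Tile(np.clip(img, 0, 255).astype(np.uint8), mask,
                          (0, 0), f"synth-glom-{i:05d}"))
    for i in range(n_background_tiles):
        img = _tile_background(T, rng)
        tiles.append(Tile(np.clip(img, 0, 255).astype(np.uint8),
                          np.zeros((T, T), np.uint8),
                          (0, 0), f"synth-bg-{i:05d}"))
    return tiles


def write_slide(
    slide: WholeSlide,
    rle: RunLengthMask,
    out_dir: str | Path,
    image_format: str = "png",
) -> dict[str, Path]:
    """Write a generated slide: image (PNG or TIFF), mask PNG, masks.csv.

    The CSV follows the codec dialect (header ``id,encoding``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if image_format not in ("png", "tiff"):
        raise ValueError(f"image_format must be png or tiff, got {image_format!r}")
    if image_format == "tiff":
        image_path = out / f"{slide.id}.tiff"
        tifffile.imwrite(image_path, slide.image)
    else:
        image_path = out / f"{slide.id}.png"
        Image.fromarray(slide.image, mode="RGB").save(image_path)
    mask_path = out / f"{slide.id}_mask.png"
    write_mask_png(slide.mask, mask_path)
    csv_path = out / "masks.csv"
    write_mask_table({slide.id: rle}, csv_path)
    return {"image": image_path, "mask": mask_path, "table": csv_path}
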