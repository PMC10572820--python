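import numpy as np
import pytest

from glomseg.tiling import Tile, TileSet, WholeSlide


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tile(mask: np.ndarray, image: np.ndarray | None = None,
              parent_id: str = "t") -> Tile:
    """A tile from a given mask, with a deterministic image if none given."""
    mask = np.asarray(mask, dtype=np.uint8)
    if image is None:
        image = np.zeros(mask.shape + (3,), dtype=np.uint8)
        image[..., 0] = 200
        image[mask == 1] = (90, 40, 80)
    return Tile(image=image, mask=mask, origin=(0, 0), parent_id=parent_id)


@pytest.fixture
def random_slide(rng):
    """A 96x128 RGB slide with a random (non-trivial) mask."""
    image = rng.integers(0, 256, (96, 128, 3), dtype=np.uint8)
    mask = (rng.random((96, 128)) < 0.1).astype(np.uint8)
    return WholeSlide(image=image, id="slide-0", mask=mask)


@pytest.fixture
def coordinate_tile():
    """A 16x16 tile whose image channels encode (row, col) coordinates.

    Lets a test verify that any geometric transform moved image pixels and
    mask pixels identically.
    """
    T = 16
    rows, cols = np.mgrid[0:T, 0:T].astype(np.uint8)
    image = np.stack([rows, cols, np.ones_like(rows)], axis=-1)
    mask = np.zeros((T, T), np.uint8)
    mask[3:7, 5:9] = 1
    return Tile(image=image, mask=mask, origin=(0, 0), parent_id="coord")
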