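"""Run-length-encoded (RLE) glomerulus mask codec.

Ground-truth glomerulus annotations for whole-slide kidney images ship as a
CSV table mapping each slide id to a single RLE string: space-delimited
alternating ``start length`` integer pairs over the linearized pixel grid.
This module decodes those strings to binary masks, encodes masks back to
canonical strings, and reads/writes the CSV table.

The linearization follows the Kaggle segmentation dialect: pixel indices are
1-based and **column-major** — index 1 is the top-left pixel, indices increase
down the first column, then continue at the top of the second column. The
ordering is held in a single constant (`RLE_ORDER`) so a row-major dialect is
a one-line change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from PIL import Image

#: numpy order character used to linearize masks: "F" = column-major
#: (down the first column, then right), the Kaggle convention.
RLE_ORDER = "F"


class RLEError(ValueError):
    """Malformed or out-of-bounds run-length encoding."""


@dataclass(frozen=True)
class RunLengthMask:
    """A sparse binary mask as ordered (start, length) runs.

    ``start`` is a 1-based linear pixel index; ``length`` a positive pixel
    count. The canonical form has strictly increasing starts and no
    overlapping or adjacent runs (adjacent runs are merged).
    """

    runs: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for start, length in self.runs:
            if start < 1:
                raise RLEError(f"run start {start} is not a 1-based index")
            if length < 1:
                raise RLEError(f"run ({start}, {length}) has non-positive length")

    @classmethod
    def from_string(cls, s: str) -> "RunLengthMask":
        """Parse a space-delimited ``start length start length ...`` string.

        An empty (or all-whitespace) string is the empty mask. An odd number
        of tokens raises :class:`RLEError`.
        """
        tokens = s.split()
        if not tokens:
            return cls()
        if len(tokens) % 2:
            raise RLEError(
                f"malformed RLE: odd token count {len(tokens)} in {s[:40]!r}"
            )
        try:
            values = [int(t) for t in tokens]
        except ValueError as exc:
            raise RLEError(f"malformed RLE: non-integer token in {s[:40]!r}") from exc
        return cls(tuple(zip(values[::2], values[1::2])))

    def to_string(self) -> str:
        return " ".join(f"{s} {l}" for s, l in self.runs)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def n_pixels(self) -> int:
        """Total number of positive pixels (sum of run lengths)."""
        return sum(length for _, length in self.runs)

    def is_empty(self) -> bool:
        return not self.runs

    def canonicalize(self) -> "RunLengthMask":
        """Sort runs by start and merge overlapping/adjacent runs."""
        if not self.runs:
            return self
        merged: list[list[int]] = []
        for start, length in sorted(self.runs):
            if merged and start <= merged[-1][0] + merged[-1][1]:
                end = max(merged[-1][0] + merged[-1][1], start + length)
                merged[-1][1] = end - merged[-1][0]
            else:
                merged.append([start, length])
        return RunLengthMask(tuple((s, l) for s, l in merged))


def validate_binary(mask: np.ndarray) -> np.ndarray:
    """Check that ``mask`` is a 2-D strictly {0,1} array; return it as uint8."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        bad = np.unique(arr[~np.isin(arr, (0, 1))])[:5]
        raise ValueError(f"mask is not binary; offending values include {bad}")
    return arr.astype(np.uint8, copy=False)


def decode_rle(
    rle: RunLengthMask | str, height: int, width: int
) -> np.ndarray:
    """Decode an RLE mask to an ``(height, width)`` uint8 {0,1} array.

    Pixel at 1-based linear index ``i`` (column-major) is 1 iff ``i`` lies in
    some run. Non-canonical but valid input (unsorted, overlapping runs) is
    accepted. A run reaching past ``height * width`` raises :class:`RLEError`.
    """
    if isinstance(rle, str):
        rle = RunLengthMask.from_string(rle)
    n = height * width
    flat = np.zeros(n, dtype=np.uint8)
    for start, length in rle.runs:
        if start + length - 1 > n:
            raise RLEError(
                f"run ({start}, {length}) exceeds the {height}x{width} "
                f"mask ({n} pixels)"
            )
        flat[start - 1 : start - 1 + length] = 1
    return flat.reshape((height, width), order=RLE_ORDER)


def encode_rle(mask: np.ndarray) -> RunLengthMask:
    """Encode a binary mask as a canonical :class:`RunLengthMask`.

    The result has the minimal number of runs with strictly increasing
    starts; ``decode_rle(encode_rle(m), *m.shape) == m`` always holds.
    """
    arr = validate_binary(mask)
    flat = arr.ravel(order=RLE_ORDER)
    if not flat.any():
        return RunLengthMask()
    # transitions: prepend/append 0 so every run has a rise and a fall
    padded = np.concatenate(([0], flat, [0]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1  # 1-based
    ends = np.flatnonzero(diff == -1) + 1
    lengths = ends - starts
    return RunLengthMask(tuple(zip(starts.tolist(), lengths.tolist())))


# ---------------------------------------------------------------------------
# CSV table I/O (header: id,encoding)
# ---------------------------------------------------------------------------

def read_mask_table(path: str | Path) -> dict[str, RunLengthMask]:
    """Read a mask table CSV into a mapping ``image id -> RunLengthMask``.

    The CSV must have ``id`` and ``encoding`` columns; a missing/empty
    encoding cell yields an empty mask. Duplicate ids raise ``ValueError``.
    """
    df = pd.read_csv(path, dtype={"id": str, "encoding": str})
    missing = {"id", "encoding"} - set(df.columns)
    if missing:
        raise ValueError(
            f"mask table {path} lacks required column(s) {sorted(missing)}"
        )
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate image id(s) in mask table: {dupes}")
    table: dict[str, RunLengthMask] = {}
    for row in df.itertuples(index=False):
        enc = row.encoding if isinstance(row.encoding, str) else ""
        table[row.id] = RunLengthMask.from_string(enc)
    return table


def write_mask_table(
    table: Mapping[str, RunLengthMask], path: str | Path
) -> None:
    """Write a mapping ``image id -> RunLengthMask`` as an id,encoding CSV."""
    df = pd.DataFrame(
        {"id": list(table.keys()),
         "encoding": [rle.to_string() for rle in table.values()]}
    )
    df.to_csv(path, index=False)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Materialize a binary mask as a single-channel 0/255 PNG."""
    arr = validate_binary(mask)
    Image.fromarray(arr * np.uint8(255), mode="L").save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a 0/255 single-channel PNG back to a {0,1} uint8 mask."""
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def iter_runs(mask: np.ndarray) -> Iterator[tuple[int, int]]:
    """Yield canonical (start, length) runs of a binary mask."""
    yield from encode_rle(mask).runs
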