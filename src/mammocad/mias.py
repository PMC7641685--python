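"""PGM mammogram I/O, MIAS-style metadata, and binary label assignment.

Pixel convention used throughout the package: row-major grids, origin at the
top-left corner, 0-based indices, half-open ranges for every rectangular
region.  Stating it once here prevents off-by-one drift in ROI cropping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MammogramRecord",
    "PGMFormatError",
    "UnsupportedDepthError",
    "read_pgm",
    "write_pgm",
    "read_metadata",
    "write_metadata",
    "assign_labels",
    "label_for",
]

#: three-way pathology class -> binary label (normal and benign are the
#: negative class; only malignant mammograms are positive)
LABEL_MAP = {"normal": 0, "benign": 0, "malignant": 1}


class PGMFormatError(ValueError):
    """Raised when a PGM file does not parse."""


class UnsupportedDepthError(ValueError):
    """Raised for PGM files with maxval > 255 (16-bit grids are out of scope)."""


@dataclass
class MammogramRecord:
    """One mammogram: id, 8-bit pixel grid, pathology class and laterality."""

    id: str
    pixels: np.ndarray
    class_raw: Optional[str] = None  # normal | benign | malignant
    label: Optional[int] = None      # 0 | 1, absent until assigned
    side: str = "unknown"            # left | right | unknown

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixel grid must be 2-D")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 255):
            raise ValueError("pixel values must lie in [0, 255]")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def _tokens(data: bytes):
    """Yield whitespace-separated header tokens, skipping '#' comments."""
    i = 0
    n = len(data)
    while i < n:
        c = data[i:i + 1]
        if c.isspace():
            i += 1
        elif c == b"#":
            while i < n and data[i:i + 1] not in (b"\n", b"\r"):
                i += 1
        else:
            j = i
            while j < n and not data[j:j + 1].isspace() and data[j:j + 1] != b"#":
                j += 1
            yield data[i:j].decode("ascii", errors="replace"), j
            i = j


def read_pgm(path) -> np.ndarray:
    """Read a P2 (ASCII) or P5 (binary) PGM file into a uint8 grid.

    No rescaling is performed; the grid keeps its stored dimensions.
    """
    data = Path(path).read_bytes()
    toks = _tokens(data)
    try:
        magic, _ = next(toks)
    except StopIteration:
        raise PGMFormatError(f"{path}: empty file")
    if magic not in ("P2", "P5"):
        raise PGMFormatError(f"{path}: not a PGM file (magic {magic!r})")
    try:
        (w, _), (h, _), (maxval, end) = next(toks), next(toks), next(toks)
        width, height, maxval = int(w), int(h), int(maxval)
    except (StopIteration, ValueError):
        raise PGMFormatError(f"{path}: malformed header")
    if width <= 0 or height <= 0:
        raise PGMFormatError(f"{path}: non-positive dimensions")
    if maxval > 255:
        raise UnsupportedDepthError(f"{path}: maxval {maxval} > 255 unsupported")
    if maxval <= 0:
        raise PGMFormatError(f"{path}: non-positive maxval")

    if magic == "P5":
        raster = data[end + 1:]  # exactly one whitespace byte after maxval
        if len(raster) < width * height:
            raise PGMFormatError(f"{path}: truncated raster")
        grid = np.frombuffer(raster[: width * height], dtype=np.uint8)
    else:
        try:
            vals = [int(t) for t, _ in _tokens(data[end:])]
        except ValueError:
            raise PGMFormatError(f"{path}: non-numeric sample in P2 raster")
        if len(vals) < width * height:
            raise PGMFormatError(f"{path}: truncated raster")
        grid = np.asarray(vals[: width * height])
        if grid.min() < 0 or grid.max() > maxval:
            raise PGMFormatError(f"{path}: sample outside [0, maxval]")
        grid = grid.astype(np.uint8)
    return grid.reshape(height, width)


def write_pgm(path, pixels: np.ndarray, binary: bool = True) -> None:
    """Write an 8-bit grid as P5 (binary, default) or P2 (ASCII) PGM."""
    grid = np.asarray(pixels)
    if grid.ndim != 2:
        raise ValueError("pixel grid must be 2-D")
    if grid.size and (grid.min() < 0 or grid.max() > 255):
        raise ValueError("pixel values must lie in [0, 255]")
    grid = grid.astype(np.uint8)
    h, w = grid.shape
    with open(path, "wb") as fh:
        if binary:
            fh.write(f"P5\n{w} {h}\n255\n".encode("ascii"))
            fh.write(grid.tobytes())
        else:
            buf = io.StringIO()
            buf.write(f"P2\n{w} {h}\n255\n")
            for row in grid:
                buf.write(" ".join(str(int(v)) for v in row) + "\n")
            fh.write(buf.getvalue().encode("ascii"))


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path) -> pd.DataFrame:
    """Parse a whitespace-delimited metadata table, one record per line.

    Columns: id, class, and optionally ground-truth lesion x, y, radius
    (absent on normal records).  Lines starting with '#' are skipped.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"metadata line too short: {line!r}")
        row = {"id": parts[0], "class": parts[1]}
        if len(parts) >= 5:
            row["x"], row["y"], row["radius"] = (float(parts[2]), float(parts[3]),
                                                 float(parts[4]))
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", "class", "x", "y", "radius"])


def write_metadata(path, meta: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for _, row in meta.iterrows():
            parts = [str(row["id"]), str(row["class"])]
            if "x" in meta.columns and pd.notna(row.get("x")):
                parts += [f"{row['x']:.0f}", f"{row['y']:.0f}", f"{row['radius']:.0f}"]
            fh.write(" ".join(parts) + "\n")


def label_for(class_raw: str) -> int:
    """Map one pathology class to the binary label (malignant -> 1)."""
    try:
        return LABEL_MAP[class_raw.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown class {class_raw!r}; "
                         f"expected one of {sorted(LABEL_MAP)}")


def assign_labels(meta: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the metadata with a binary ``label`` column.

    Normal and benign records are labelled 0, malignant records 1.  The
    mapping is total (an unknown class raises) and idempotent.
    """
    out = meta.copy()
    out["label"] = [label_for(c) for c in out["class"]] if len(out) else \
        pd.Series(dtype=int)
    return out
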