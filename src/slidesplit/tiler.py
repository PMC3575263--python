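"""Grid splitting of a slide into fixed-size TIFF tiles.

A slide is cut at a chosen output magnification into a row-major grid of
``tile_width x tile_height`` tiles.  Tiles are named spreadsheet-style by
grid position — rows map to bijective base-26 letters (A..Z, AA, AB, ...),
columns to 1-based numbers — so the first row reads A1, A2, A3, ...  Last
row/column tiles are truncated rather than padded, which keeps the tiles an
exact partition of the level raster: stitching them back by their boxes
reproduces it pixel-for-pixel.

``split_slide`` writes each tile as a baseline TIFF under a directory named
after the slide.  With an emptiness filter enabled, tiles classified empty
go to an ``empty_tiles`` subdirectory (retained for review, never deleted),
and ``log.txt`` records one tab-separated line per tile with the scores and
thresholds behind every verdict, so thresholds can be tuned from the log.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .emptiness import (
    CompressionThresholds,
    EmptinessReport,
    IntensityThresholds,
    classify_tiles,
)
from .exceptions import ValidationError
from .slide_io import SlideImage, round_half_up

LOG_FILENAME = "log.txt"
EMPTY_SUBDIR = "empty_tiles"


def tile_name(row: int, col: int) -> str:
    """Spreadsheet-style name for a 0-based (row, col): rows->letters, cols->numbers."""
    if row < 0 or col < 0:
        raise ValidationError("row and col must be >= 0")
    letters = ""
    n = row + 1  # bijective base-26: no zero digit
    while n > 0:
        n, rem = divmod(n - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return f"{letters}{col + 1}"


def parse_tile_name(name: str) -> tuple[int, int]:
    """Inverse of :func:`tile_name`; returns 0-based (row, col)."""
    i = 0
    while i < len(name) and name[i].isalpha():
        i += 1
    letters, digits = name[:i], name[i:]
    if not letters or not digits or not digits.isdigit():
        raise ValidationError(f"not a grid tile name: {name!r}")
    row = 0
    for ch in letters.upper():
        row = row * 26 + (ord(ch) - ord("A") + 1)
    return row - 1, int(digits) - 1


@dataclass(frozen=True)
class TileSpec:
    """One grid cell: indices, half-open pixel box at level resolution, name."""

    row: int
    col: int
    box: tuple[int, int, int, int]  # (x0, y0, x1, y1)
    name: str
    is_edge: bool

    @property
    def width(self) -> int:
        return self.box[2] - self.box[0]

    @property
    def height(self) -> int:
        return self.box[3] - self.box[1]


@dataclass(frozen=True)
class TileGrid:
    """An exact row-major partition of the level raster into tiles."""

    tile_width: int
    tile_height: int
    magnification: float
    level_width: int
    level_height: int
    n_rows: int
    n_cols: int
    tiles: tuple[TileSpec, ...]


def compute_grid(
    slide: SlideImage,
    tile_width: int,
    tile_height: int,
    magnification: float | None = None,
) -> TileGrid:
    """Plan the tile grid for ``slide`` at ``magnification``.

    Tile dimensions are interpreted at the output magnification.  The level
    raster is the slide downsampled by ``scan_magnification / magnification``
    (dimensions rounded); the grid has ``ceil(level / tile)`` columns and
    rows, with truncated (never padded) edge tiles.
    """
    if tile_width < 1 or tile_height < 1:
        raise ValidationError("tile dimensions must be >= 1")
    mag = magnification if magnification is not None else slide.scan_magnification
    if mag <= 0:
        raise ValidationError("magnification must be positive")
    if mag > slide.scan_magnification + 1e-9:
        raise ValidationError("magnification cannot exceed the scan magnification")
    d = slide.scan_magnification / mag
    level_w = max(1, round_half_up(slide.width_px / d))
    level_h = max(1, round_half_up(slide.height_px / d))
    n_cols = math.ceil(level_w / tile_width)
    n_rows = math.ceil(level_h / tile_height)

    tiles = []
    for row in range(n_rows):
        y0 = row * tile_height
        y1 = min(y0 + tile_height, level_h)
        for col in range(n_cols):
            x0 = col * tile_width
            x1 = min(x0 + tile_width, level_w)
            tiles.append(
                TileSpec(
                    row=row,
                    col=col,
                    box=(x0, y0, x1, y1),
                    name=tile_name(row, col),
                    is_edge=(x1 - x0 < tile_width) or (y1 - y0 < tile_height),
                )
            )
    return TileGrid(
        tile_width=tile_width,
        tile_height=tile_height,
        magnification=mag,
        level_width=level_w,
        level_height=level_h,
        n_rows=n_rows,
        n_cols=n_cols,
        tiles=tuple(tiles),
    )


def extract_tiles(level_raster: np.ndarray, grid: TileGrid):
    """Yield ``(TileSpec, raster)`` pairs by slicing the level raster."""
    for tile in grid.tiles:
        x0, y0, x1, y1 = tile.box
        yield tile, level_raster[y0:y1, x0:x1]


@dataclass(frozen=True)
class SplitResult:
    """Outcome of one split: counts, output locations, per-tile reports."""

    slide_dir: Path
    written_count: int
    empty_count: int
    log_path: Path | None
    reports: tuple[EmptinessReport, ...] = ()

    @property
    def total(self) -> int:
        return self.written_count + self.empty_count


def split_slide(
    slide: SlideImage,
    grid: TileGrid,
    out_dir: str | os.PathLike,
    empty_filter: str | None = None,
    thresholds: IntensityThresholds | CompressionThresholds | None = None,
) -> SplitResult:
    """Split ``slide`` by ``grid`` and write TIFF tiles under ``out_dir``.

    A directory named after the slide file's stem is created in ``out_dir``.
    With ``empty_filter`` in {"intensity", "compression"}, tiles judged empty
    are written to the ``empty_tiles`` subdirectory and ``log.txt`` records
    every tile's scores, thresholds and verdict; with the filter off all
    tiles go to the slide directory and no log is written.
    """
    import tifffile

    if empty_filter is not None and empty_filter not in ("intensity", "compression"):
        raise ValidationError(f"unknown emptiness algorithm {empty_filter!r}")

    slide_dir = Path(out_dir) / slide.source_path.stem
    slide_dir.mkdir(parents=True, exist_ok=True)
    level = slide.read_full(grid.magnification)
    if level.shape[0] != grid.level_height or level.shape[1] != grid.level_width:
        raise ValidationError("grid was computed for a different slide or magnification")

    pairs = [(spec, raster) for spec, raster in extract_tiles(level, grid)]
    reports: list[EmptinessReport] = []
    if empty_filter is not None:
        reports = classify_tiles(
            [(spec.name, raster) for spec, raster in pairs], empty_filter, thresholds
        )
        verdicts = [r.is_empty for r in reports]
    else:
        verdicts = [False] * len(pairs)

    empty_dir = slide_dir / EMPTY_SUBDIR
    written = empty = 0
    for (spec, raster), is_empty in zip(pairs, verdicts):
        if is_empty:
            empty_dir.mkdir(exist_ok=True)
            target = empty_dir / f"{spec.name}.tif"
            empty += 1
        else:
            target = slide_dir / f"{spec.name}.tif"
            written += 1
        tifffile.imwrite(target, raster)

    log_path = None
    if empty_filter is not None:
        log_path = slide_dir / LOG_FILENAME
        log_path.write_text("".join(r.log_line() + "\n" for r in reports))

    return SplitResult(
        slide_dir=slide_dir,
        written_count=written,
        empty_count=empty,
        log_path=log_path,
        reports=tuple(reports),
    )
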