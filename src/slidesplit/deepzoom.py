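"""Deep Zoom (DZI) pyramid generation.

Deep Zoom serves an image as a tree of fixed-size tiles at power-of-two
resolution levels, so a web viewer can progressively load only the tiles in
view.  Level ``max_level = ceil(log2(max(width, height)))`` holds the source
at full resolution; each lower level halves both dimensions with ceiling
rounding, down to 1x1 at level 0.  Within a level, tiles are ``tile_size``
pixels on a side with ``overlap`` extra pixels shared along interior edges
(so interior tiles measure ``tile_size + 2*overlap``), addressed
``{col}_{row}`` left-to-right, top-to-bottom.

On disk the pyramid is an XML descriptor ``<name>.dzi`` plus a tile tree
``<name>_files/<level>/<col>_<row>.<format>``, following the Microsoft Deep
Zoom schema (namespace ``http://schemas.microsoft.com/deepzoom/2008``); any
standard JavaScript DZI viewer can consume the output directly.

Defaults (254-pixel tiles, 1-pixel overlap, JPEG tiles) are the conventional
Deep Zoom parameters.  Level rasters are produced by successive ceil-halving
from the next larger level — matching the dimension recurrence exactly and
keeping peak memory at one extra level, rather than resizing from the source
each time.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from lxml import etree
from PIL import Image

from .exceptions import BoundsError, ValidationError

DZI_NAMESPACE = "http://schemas.microsoft.com/deepzoom/2008"
DEFAULT_TILE_SIZE = 254
DEFAULT_OVERLAP = 1
DEFAULT_FORMAT = "jpg"
DEFAULT_TILE_QUALITY = 85


@dataclass(frozen=True)
class PyramidDescriptor:
    """Geometry of a Deep Zoom pyramid for a source of given dimensions."""

    width: int
    height: int
    tile_size: int = DEFAULT_TILE_SIZE
    overlap: int = DEFAULT_OVERLAP
    fmt: str = DEFAULT_FORMAT

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValidationError("source dimensions must be >= 1")
        if self.tile_size < 1:
            raise ValidationError("tile_size must be >= 1")
        if self.overlap < 0 or self.overlap >= self.tile_size:
            raise ValidationError("overlap must be in [0, tile_size)")

    @property
    def max_level(self) -> int:
        return max(0, math.ceil(math.log2(max(self.width, self.height))))

    @property
    def level_dims(self) -> tuple[tuple[int, int], ...]:
        """Per-level (width, height), index 0 = 1x1, index max_level = source."""
        dims = [(self.width, self.height)]
        while dims[-1] != (1, 1):
            w, h = dims[-1]
            dims.append((max(1, math.ceil(w / 2)), max(1, math.ceil(h / 2))))
        # levels below log2 collapse to 1x1; pad so len == max_level + 1
        while len(dims) < self.max_level + 1:
            dims.append((1, 1))
        return tuple(reversed(dims))

    def tiles_across(self, level: int) -> tuple[int, int]:
        """(n_cols, n_rows) of tiles at ``level``."""
        w, h = self.level_dims[level]
        return math.ceil(w / self.tile_size), math.ceil(h / self.tile_size)

    def total_tiles(self) -> int:
        return sum(
            c * r for c, r in (self.tiles_across(l) for l in range(self.max_level + 1))
        )


@dataclass(frozen=True)
class TileAddress:
    """(level, col, row) address of one tile within a pyramid."""

    level: int
    col: int
    row: int


def compute_pyramid(
    width: int,
    height: int,
    tile_size: int = DEFAULT_TILE_SIZE,
    overlap: int = DEFAULT_OVERLAP,
    fmt: str = DEFAULT_FORMAT,
) -> PyramidDescriptor:
    """Plan a Deep Zoom pyramid for a ``width x height`` source."""
    return PyramidDescriptor(width, height, tile_size, overlap, fmt)


def tile_box(
    desc: PyramidDescriptor, addr: TileAddress
) -> tuple[int, int, int, int]:
    """Half-open pixel box of a tile within its level, overlap included."""
    if not (0 <= addr.level <= desc.max_level):
        raise BoundsError(f"level {addr.level} outside [0, {desc.max_level}]")
    level_w, level_h = desc.level_dims[addr.level]
    n_cols, n_rows = desc.tiles_across(addr.level)
    if not (0 <= addr.col < n_cols and 0 <= addr.row < n_rows):
        raise BoundsError(f"tile {addr} outside the {n_cols}x{n_rows} level grid")
    x0 = max(0, addr.col * desc.tile_size - desc.overlap)
    y0 = max(0, addr.row * desc.tile_size - desc.overlap)
    x1 = min(level_w, (addr.col + 1) * desc.tile_size + desc.overlap)
    y1 = min(level_h, (addr.row + 1) * desc.tile_size + desc.overlap)
    return (x0, y0, x1, y1)


class LevelCache:
    """Level rasters built by successive ceil-halving from the source."""

    def __init__(self, image: np.ndarray, desc: PyramidDescriptor):
        image = np.asarray(image)
        if image.shape[0] != desc.height or image.shape[1] != desc.width:
            raise ValidationError("image dimensions do not match the descriptor")
        self._desc = desc
        self._levels: dict[int, np.ndarray] = {desc.max_level: image}

    def level(self, level: int) -> np.ndarray:
        if not (0 <= level <= self._desc.max_level):
            raise BoundsError(f"level {level} outside pyramid")
        if level not in self._levels:
            larger = self.level(level + 1)
            w, h = self._desc.level_dims[level]
            self._levels[level] = np.asarray(
                Image.fromarray(larger).resize((w, h), Image.BOX)
            )
        return self._levels[level]


def render_tile(
    image: np.ndarray,
    desc: PyramidDescriptor,
    addr: TileAddress,
    cache: LevelCache | None = None,
) -> np.ndarray:
    """Render one tile: the level raster cropped to the tile's (overlapping) box."""
    cache = cache or LevelCache(image, desc)
    x0, y0, x1, y1 = tile_box(desc, addr)
    return cache.level(addr.level)[y0:y1, x0:x1]


def write_pyramid(
    image: np.ndarray,
    name: str,
    out_dir: str | os.PathLike,
    desc: PyramidDescriptor | None = None,
    jpeg_quality: int = DEFAULT_TILE_QUALITY,
) -> tuple[Path, Path]:
    """Write ``<name>.dzi`` and the ``<name>_files`` tile tree under ``out_dir``.

    Returns ``(descriptor_path, tiles_root)``.  Re-publishing the same name
    overwrites in place, so publication is idempotent.
    """
    image = np.asarray(image)
    desc = desc or compute_pyramid(image.shape[1], image.shape[0])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files_root = out_dir / f"{name}_files"
    cache = LevelCache(image, desc)

    pil_format = {"jpg": "JPEG", "jpeg": "JPEG", "png": "PNG"}.get(
        desc.fmt.lower()
    )
    if pil_format is None:
        raise ValidationError(f"unsupported tile format {desc.fmt!r}")

    for level in range(desc.max_level + 1):
        level_dir = files_root / str(level)
        level_dir.mkdir(parents=True, exist_ok=True)
        n_cols, n_rows = desc.tiles_across(level)
        for row in range(n_rows):
            for col in range(n_cols):
                tile = render_tile(image, desc, TileAddress(level, col, row), cache)
                out = level_dir / f"{col}_{row}.{desc.fmt}"
                kwargs = {"quality": jpeg_quality} if pil_format == "JPEG" else {}
                Image.fromarray(tile).save(out, format=pil_format, **kwargs)

    dzi_path = out_dir / f"{name}.dzi"
    dzi_path.write_bytes(descriptor_xml(desc))
    return dzi_path, files_root


def descriptor_xml(desc: PyramidDescriptor) -> bytes:
    """Serialise the descriptor as Deep Zoom schema XML."""
    image = etree.Element(
        f"{{{DZI_NAMESPACE}}}Image",
        nsmap={None: DZI_NAMESPACE},
        TileSize=str(desc.tile_size),
        Overlap=str(desc.overlap),
        Format=desc.fmt,
    )
    etree.SubElement(
        image,
        f"{{{DZI_NAMESPACE}}}Size",
        Width=str(desc.width),
        Height=str(desc.height),
    )
    return etree.tostring(
        image, xml_declaration=True, encoding="utf-8", pretty_print=True
    )


def read_descriptor(dzi_path: str | os.PathLike) -> PyramidDescriptor:
    """Parse a ``.dzi`` file back into a :class:`PyramidDescriptor`."""
    root = etree.parse(str(dzi_path)).getroot()
    if etree.QName(root).localname != "Image":
        raise ValidationError(f"not a DZI descriptor: {dzi_path}")
    size = root.find(f"{{{DZI_NAMESPACE}}}Size")
    if size is None:
        raise ValidationError(f"DZI descriptor missing Size element: {dzi_path}")
    return PyramidDescriptor(
        width=int(size.get("Width")),
        height=int(size.get("Height")),
        tile_size=int(root.get("TileSize")),
        overlap=int(root.get("Overlap")),
        fmt=root.get("Format"),
    )
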