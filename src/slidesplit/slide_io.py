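"""Uniform access to large slide images.

A whole-slide scan is, from the caller's point of view, just three things: a
pixel size, a scan magnification (the objective-equivalent resolution of the
full raster, e.g. 40 for a "400x" scan), and a way to pull out rectangular
regions at that or any lower magnification.  This module provides exactly
that contract and hides the container format behind a reader registry.

Shipped readers cover plain and tiled/pyramidal TIFF (via :mod:`tifffile`)
and PNG (via Pillow).  Proprietary containers such as Hamamatsu NDPI are a
plugin point: register a reader implementing :class:`SlideReader` under the
``.ndpi`` extension and the rest of the toolkit works unchanged.

Conventions
-----------
* Coordinates are 0-based with the origin at the top-left; boxes are
  half-open ``[x0, x1) x [y0, y1)``.
* Requesting magnification ``m`` on a slide scanned at ``M`` yields a
  downsample factor ``d = M / m >= 1``; the output raster has dimensions
  ``round(w / d) x round(h / d)``.  Upsampling (``d < 1``) is refused.
* Downsampling uses area (box) resampling for ``d >= 2`` and bilinear for
  ``1 < d < 2`` by default; pass ``resampling=`` to override.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
from PIL import Image

from .exceptions import (
    BoundsError,
    SlideOpenError,
    UnsupportedMagnificationError,
    ValidationError,
)

#: Fallback scan magnification when the container carries no tag.
DEFAULT_MAGNIFICATION = 40.0

#: Resampling filters accepted by :func:`read_region`.
RESAMPLING_FILTERS = {"area": Image.BOX, "bilinear": Image.BILINEAR}


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return int(math.floor(x + 0.5))


class SlideReader(Protocol):
    """Backend contract a format reader must satisfy."""

    #: Short identifier recorded on the SlideImage (e.g. ``"tiff"``).
    reader_id: str

    @property
    def width(self) -> int: ...

    @property
    def height(self) -> int: ...

    @property
    def magnification(self) -> float | None:
        """Scan magnification from container metadata, or None if untagged."""
        ...

    def read(self, x0: int, y0: int, width: int, height: int) -> np.ndarray:
        """Return the full-resolution RGB crop ``[x0, x0+width) x [y0, y0+height)``."""
        ...


def _to_rgb(arr: np.ndarray) -> np.ndarray:
    """Coerce grayscale/RGBA uint8 arrays to H x W x 3 RGB."""
    if arr.dtype != np.uint8:
        if arr.dtype == np.uint16:
            arr = (arr // 257).astype(np.uint8)
        else:
            arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.shape[2] != 3:
        raise SlideOpenError(f"unsupported channel count: {arr.shape[2]}")
    return np.ascontiguousarray(arr)


def _parse_magnification_tag(text: str | None) -> float | None:
    """Extract ``magnification=<x>`` from a free-text metadata string."""
    if not text:
        return None
    for token in text.replace(";", "\n").splitlines():
        key, _, value = token.strip().partition("=")
        if key.strip().lower() == "magnification":
            try:
                mag = float(value)
            except ValueError:
                return None
            return mag if mag > 0 else None
    return None


class TiffSlideReader:
    """Plain and tiled/pyramidal TIFF, decoded through tifffile.

    The base (highest-resolution) page is authoritative for dimensions; the
    array is materialised lazily on first region read and cached, which is
    appropriate at the slide sizes this toolkit targets.
    """

    reader_id = "tiff"

    def __init__(self, path: Path):
        import tifffile

        try:
            self._tif = tifffile.TiffFile(path)
            page = self._tif.pages[0]
            self._shape = (int(page.imagelength), int(page.imagewidth))
            self._magnification = _parse_magnification_tag(page.description)
        except Exception as exc:  # tifffile raises a zoo of types on corrupt input
            raise SlideOpenError(f"cannot open TIFF slide {path}: {exc}") from exc
        self._array: np.ndarray | None = None

    @property
    def width(self) -> int:
        return self._shape[1]

    @property
    def height(self) -> int:
        return self._shape[0]

    @property
    def magnification(self) -> float | None:
        return self._magnification

    def _load(self) -> np.ndarray:
        if self._array is None:
            try:
                self._array = _to_rgb(self._tif.pages[0].asarray())
            except Exception as exc:
                raise SlideOpenError(f"cannot decode TIFF pixels: {exc}") from exc
        return self._array

    def read(self, x0: int, y0: int, width: int, height: int) -> np.ndarray:
        return self._load()[y0 : y0 + height, x0 : x0 + width]


class PngSlideReader:
    """PNG reader; magnification may come from a ``magnification`` text chunk."""

    reader_id = "png"

    def __init__(self, path: Path):
        try:
            with Image.open(path) as im:
                im.load()
                self._magnification = _parse_magnification_tag(
                    im.info.get("magnification")
                    and f"magnification={im.info['magnification']}"
                )
                self._array = _to_rgb(np.asarray(im.convert("RGB")))
        except SlideOpenError:
            raise
        except Exception as exc:
            raise SlideOpenError(f"cannot open PNG slide {path}: {exc}") from exc

    @property
    def width(self) -> int:
        return self._array.shape[1]

    @property
    def height(self) -> int:
        return self._array.shape[0]

    @property
    def magnification(self) -> float | None:
        return self._magnification

    def read(self, x0: int, y0: int, width: int, height: int) -> np.ndarray:
        return self._array[y0 : y0 + height, x0 : x0 + width]


class ArraySlideReader:
    """In-memory raster exposed through the slide contract.

    Used for synthetic fixtures and for re-publishing already-decoded images
    (e.g. a JPEG snapshot being fed to the Deep Zoom converter).
    """

    reader_id = "array"

    def __init__(self, array: np.ndarray, magnification: float | None = None):
        self._array = _to_rgb(np.asarray(array))
        self._magnification = magnification

    @property
    def width(self) -> int:
        return self._array.shape[1]

    @property
    def height(self) -> int:
        return self._array.shape[0]

    @property
    def magnification(self) -> float | None:
        return self._magnification

    def read(self, x0: int, y0: int, width: int, height: int) -> np.ndarray:
        return self._array[y0 : y0 + height, x0 : x0 + width]


@dataclass(frozen=True)
class _ReaderSpec:
    reader_id: str
    extensions: tuple[str, ...]
    magics: tuple[bytes, ...]
    factory: Callable[[Path], SlideReader]


_REGISTRY: dict[str, _ReaderSpec] = {}


def register_reader(
    reader_id: str,
    extensions: tuple[str, ...],
    magics: tuple[bytes, ...],
    factory: Callable[[Path], SlideReader],
) -> None:
    """Register a format reader keyed by extension and magic bytes.

    This is the NDPI plugin hook: a reader wrapping a vendor SDK registers
    itself here and every tool in the package can then open its files.
    """
    _REGISTRY[reader_id] = _ReaderSpec(
        reader_id, tuple(e.lower() for e in extensions), tuple(magics), factory
    )


register_reader(
    "tiff", (".tif", ".tiff"), (b"II*\x00", b"MM\x00*"), TiffSlideReader
)
register_reader("png", (".png",), (b"\x89PNG\r\n\x1a\n",), PngSlideReader)


def _match_reader(path: Path) -> _ReaderSpec:
    ext = path.suffix.lower()
    by_ext = next((s for s in _REGISTRY.values() if ext in s.extensions), None)
    try:
        head = path.open("rb").read(16)
    except OSError as exc:
        raise SlideOpenError(f"cannot read {path}: {exc}") from exc
    by_magic = next(
        (s for s in _REGISTRY.values() if any(head.startswith(m) for m in s.magics)),
        None,
    )
    spec = by_magic or by_ext
    if spec is None:
        raise SlideOpenError(f"no registered reader for {path}")
    return spec


@dataclass(frozen=True)
class RegionRequest:
    """A rectangular read at full-resolution coordinates.

    ``magnification=None`` means "at scan magnification" (downsample 1).
    """

    x0: int
    y0: int
    width: int
    height: int
    magnification: float | None = None

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValidationError("region width/height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise BoundsError("region origin must be non-negative")
        if self.magnification is not None and self.magnification <= 0:
            raise ValidationError("magnification must be positive")


@dataclass(frozen=True)
class SlideImage:
    """Open handle to a slide: dimensions, scan magnification, region reads."""

    width_px: int
    height_px: int
    scan_magnification: float
    source_path: Path
    reader_id: str
    _reader: SlideReader = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValidationError("slide dimensions must be >= 1")
        if self.scan_magnification <= 0:
            raise ValidationError("scan magnification must be positive")

    def read_region(self, req: RegionRequest, resampling: str = "auto") -> np.ndarray:
        return read_region(self, req, resampling=resampling)

    def read_full(self, magnification: float | None = None) -> np.ndarray:
        """The whole slide at ``magnification`` (default: scan resolution)."""
        return self.read_region(
            RegionRequest(0, 0, self.width_px, self.height_px, magnification)
        )


def open_slide(
    path: str | os.PathLike,
    default_magnification: float = DEFAULT_MAGNIFICATION,
) -> SlideImage:
    """Open a slide file through the registered reader for its format.

    Magnification is taken from container metadata when present, otherwise
    ``default_magnification`` applies.  Unreadable or corrupt files raise
    :class:`~slidesplit.exceptions.SlideOpenError`, the signal the archiving
    workflow uses to route a file to its failure folder.
    """
    path = Path(path)
    if not path.is_file():
        raise SlideOpenError(f"no such slide file: {path}")
    spec = _match_reader(path)
    reader = spec.factory(path)
    if reader.width < 1 or reader.height < 1:
        raise SlideOpenError(f"degenerate slide dimensions in {path}")
    return SlideImage(
        width_px=reader.width,
        height_px=reader.height,
        scan_magnification=reader.magnification or default_magnification,
        source_path=path,
        reader_id=spec.reader_id,
        _reader=reader,
    )


def slide_from_array(
    array: np.ndarray,
    magnification: float = DEFAULT_MAGNIFICATION,
    source: str = "<memory>",
) -> SlideImage:
    """Wrap an in-memory RGB raster as a :class:`SlideImage`."""
    reader = ArraySlideReader(array, magnification)
    return SlideImage(
        width_px=reader.width,
        height_px=reader.height,
        scan_magnification=magnification,
        source_path=Path(source),
        reader_id=reader.reader_id,
        _reader=reader,
    )


def read_region(
    slide: SlideImage, req: RegionRequest, resampling: str = "auto"
) -> np.ndarray:
    """Extract a region, downsampling to the requested magnification.

    The crop is taken at full resolution, then resized by the downsample
    factor ``d = scan_magnification / req.magnification``.  ``resampling``
    is ``"area"``, ``"bilinear"``, or ``"auto"`` (area when ``d >= 2``,
    bilinear below).
    """
    if req.x0 + req.width > slide.width_px or req.y0 + req.height > slide.height_px:
        raise BoundsError(
            f"region {req} exceeds slide bounds "
            f"{slide.width_px}x{slide.height_px}"
        )
    mag = req.magnification if req.magnification is not None else slide.scan_magnification
    d = slide.scan_magnification / mag
    if d < 1.0 - 1e-9:
        raise UnsupportedMagnificationError(
            f"requested magnification {mag} exceeds scan magnification "
            f"{slide.scan_magnification}"
        )
    crop = slide._reader.read(req.x0, req.y0, req.width, req.height)
    if abs(d - 1.0) < 1e-9:
        return np.ascontiguousarray(crop)
    out_w = max(1, round_half_up(req.width / d))
    out_h = max(1, round_half_up(req.height / d))
    if resampling == "auto":
        resampling = "area" if d >= 2 else "bilinear"
    try:
        filt = RESAMPLING_FILTERS[resampling]
    except KeyError:
        raise ValidationError(f"unknown resampling mode {resampling!r}") from None
    resized = Image.fromarray(crop).resize((out_w, out_h), filt)
    return np.asarray(resized)
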