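"""Publishable JPEG snapshots of the centre of a slide.

The snapshot is the centred quarter of the slide — a half-width by
half-height box, so its pixel area is one quarter of the full raster —
extracted at a configured magnification, watermarked with a logo at the
bottom, and encoded as JPEG at a configured quality.  Taking the snapshot
from the middle of the slide maximises the chance that the diagnostically
relevant (e.g. malignant) region is included without any content analysis.

Configuration lives in a ``snapshot-creator.properties`` file (key=value):
folder paths, record-store location, magnification and JPEG quality.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import ValidationError
from .slide_io import RegionRequest, SlideImage

logger = logging.getLogger(__name__)

#: Bottom margin under the watermark, as a fraction of image height.
WATERMARK_MARGIN_FRACTION = 0.02


@dataclass(frozen=True)
class SnapshotSpec:
    """How to render a snapshot: magnification, JPEG quality, optional logo."""

    magnification: float
    jpeg_quality: int = 90
    watermark_path: Path | None = None

    def __post_init__(self) -> None:
        if self.magnification <= 0:
            raise ValidationError("magnification must be positive")
        if not (1 <= self.jpeg_quality <= 100):
            raise ValidationError("jpeg_quality must be in [1, 100]")


def snapshot_box(slide: SlideImage) -> tuple[int, int, int, int]:
    """Centred half-open box covering one quarter of the slide's area.

    Width and height are ``floor(dim / 2)``; offsets are
    ``floor((dim - box_dim) / 2)``, so odd dimensions centre to within one
    pixel and the area ratio is exactly 0.25 for even dimensions.
    """
    if slide.width_px < 2 or slide.height_px < 2:
        raise ValidationError("slide too small to snapshot (needs >= 2x2)")
    bw = slide.width_px // 2
    bh = slide.height_px // 2
    x0 = (slide.width_px - bw) // 2
    y0 = (slide.height_px - bh) // 2
    return (x0, y0, x0 + bw, y0 + bh)


def add_watermark(image: np.ndarray, logo: np.ndarray) -> np.ndarray:
    """Alpha-composite ``logo`` (RGBA) bottom-centred onto ``image`` (RGB).

    The output has the input's dimensions; pixels outside the logo's box are
    untouched.  A logo wider than the image is downscaled to fit its width;
    a degenerate logo is skipped with a logged warning.
    """
    image = np.asarray(image)
    logo = np.asarray(logo)
    if logo.ndim != 3 or logo.shape[2] != 4:
        raise ValidationError("logo must be an RGBA raster")
    out = image.copy()
    ih, iw = image.shape[:2]
    lh, lw = logo.shape[:2]
    if lh == 0 or lw == 0:
        logger.warning("degenerate watermark logo skipped")
        return out
    if lw > iw or lh > ih:
        scale = min(iw / lw, ih / lh)
        new_w, new_h = max(1, int(lw * scale)), max(1, int(lh * scale))
        logo = np.asarray(
            Image.fromarray(logo).resize((new_w, new_h), Image.BILINEAR)
        )
        lh, lw = logo.shape[:2]

    margin = max(1, round(ih * WATERMARK_MARGIN_FRACTION))
    y0 = max(0, ih - margin - lh)
    x0 = (iw - lw) // 2
    y1, x1 = y0 + lh, x0 + lw

    alpha = logo[:, :, 3:4].astype(np.float64) / 255.0
    region = out[y0:y1, x0:x1].astype(np.float64)
    blended = alpha * logo[:, :, :3].astype(np.float64) + (1 - alpha) * region
    out[y0:y1, x0:x1] = np.clip(np.rint(blended), 0, 255).astype(np.uint8)
    return out


def load_logo(path: str | os.PathLike) -> np.ndarray:
    """Load a watermark logo as RGBA."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGBA"))


def render_snapshot(slide: SlideImage, spec: SnapshotSpec) -> bytes:
    """Render the centred-quarter snapshot as JPEG bytes."""
    x0, y0, x1, y1 = snapshot_box(slide)
    raster = slide.read_region(
        RegionRequest(x0, y0, x1 - x0, y1 - y0, spec.magnification)
    )
    if spec.watermark_path is not None:
        raster = add_watermark(raster, load_logo(spec.watermark_path))
    buf = io.BytesIO()
    Image.fromarray(raster).save(buf, format="JPEG", quality=spec.jpeg_quality)
    return buf.getvalue()


def write_snapshot(
    slide: SlideImage, spec: SnapshotSpec, out_path: str | os.PathLike
) -> Path:
    """Render and write the snapshot; the filename should be the slide identifier."""
    out_path = Path(out_path)
    out_path.write_bytes(render_snapshot(slide, spec))
    return out_path


def spec_from_properties(props: dict[str, str]) -> SnapshotSpec:
    """Build a :class:`SnapshotSpec` from ``snapshot-creator.properties`` keys.

    Recognised keys: ``snapshot.magnification``, ``snapshot.quality``,
    ``snapshot.watermark`` (path, optional).
    """
    watermark = props.get("snapshot.watermark")
    return SnapshotSpec(
        magnification=float(props.get("snapshot.magnification", 10.0)),
        jpeg_quality=int(props.get("snapshot.quality", 90)),
        watermark_path=Path(watermark) if watermark else None,
    )
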