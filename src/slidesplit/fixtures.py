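"""Deterministic synthetic slides with ground-truth occupancy masks.

Real inputs to this toolkit are multi-gigapixel brightfield (H&E-like tissue
on a white field) or fluorescent (bright signal on a black field) scans.
The generator here emulates just the features the rest of the package
exercises: a near-uniform background, a handful of smooth elliptical "tissue"
blobs with enough interior texture that a JPEG encoder cannot compress them
away, and a boolean mask recording exactly which pixels were painted.  The
mask is the ground truth the emptiness classifiers are scored against.

Everything is driven by a single integer seed through
``numpy.random.default_rng``; identical seed and parameters give bit-identical
raster and mask.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .slide_io import DEFAULT_MAGNIFICATION

#: Default fixture slide size: large enough for multi-level pyramids and
#: multi-tile grids, small enough to regenerate in every test run.
DEFAULT_WIDTH = 2048
DEFAULT_HEIGHT = 1536
DEFAULT_BLOBS = 8
DEFAULT_SEED = 7
#: Bounded amplitude of the additive background noise (grey levels).
DEFAULT_NOISE = 1
#: Semi-axis range of the painted blobs, pixels.
DEFAULT_RADIUS_RANGE = (90, 240)

#: A tile counts as containing content when at least this fraction of its
#: pixels are on the occupancy mask.
TRUTH_OVERLAP_FRACTION = 0.005


@dataclass(frozen=True)
class SyntheticSlide:
    """A generated slide raster plus its pixel-level ground truth."""

    raster: np.ndarray  # H x W x 3 uint8
    mode: str  # "brightfield" | "fluorescent"
    occupancy_mask: np.ndarray  # H x W bool, True where signal was painted
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.raster.shape[1]

    @property
    def height(self) -> int:
        return self.raster.shape[0]


def _paint_blob(
    raster: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    mode: str,
    radius_range: tuple[int, int],
) -> None:
    h, w = mask.shape
    r_lo, r_hi = radius_range
    rx = float(rng.uniform(r_lo, r_hi))
    ry = float(rng.uniform(r_lo, r_hi))
    theta = float(rng.uniform(0, np.pi))
    # keep centers inside the slide so every blob contributes visible area
    cx = float(rng.uniform(min(rx, w / 2), max(w - rx, w / 2)))
    cy = float(rng.uniform(min(ry, h / 2), max(h - ry, h / 2)))

    x0 = max(0, int(cx - max(rx, ry)) - 1)
    x1 = min(w, int(cx + max(rx, ry)) + 2)
    y0 = max(0, int(cy - max(rx, ry)) - 1)
    y1 = min(h, int(cy + max(rx, ry)) + 2)
    if x0 >= x1 or y0 >= y1:
        return

    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    rho = (u / rx) ** 2 + (v / ry) ** 2
    inside = rho <= 1.0

    # Texture has three layers so a JPEG encoder sees high-frequency content
    # everywhere inside the blob, including thin boundary slivers:
    #   * low-frequency sinusoidal shading (stain density variation),
    #   * gray per-pixel speckle (incompressible fine structure),
    #   * high-contrast puncta concentrated in the outer margin band,
    #     emulating the nucleus-dense rim of a lesion.
    wavelength = float(rng.uniform(12, 30))
    phase = float(rng.uniform(0, 2 * np.pi))
    shading = 35.0 * np.sin(2 * np.pi * xx / wavelength + phase) * np.sin(
        2 * np.pi * yy / (wavelength * 1.3)
    )
    speckle = rng.integers(-90, 91, size=inside.shape).astype(np.float64)
    puncta = (rho > 0.8) & inside & (rng.random(inside.shape) < 0.5)

    patch = raster[y0:y1, x0:x1].astype(np.float64)
    if mode == "brightfield":
        base = np.array([160.0, 95.0, 150.0])  # hematoxylin/eosin-like purple
        puncta_value = 15.0  # dark nuclei
    else:
        base = np.array([25.0, 190.0, 45.0])  # fluorophore-like green
        puncta_value = 240.0  # bright puncta
    blob = base[None, None, :] + (shading + speckle)[:, :, None]
    blob[puncta] = puncta_value
    if mode == "fluorescent":
        # fluorophore signal is additive light above background: keep the
        # signal channel at a floor so painted pixels stay clearly lit
        blob[:, :, 1] = np.maximum(blob[:, :, 1], 100.0)
    patch[inside] = blob[inside]
    raster[y0:y1, x0:x1] = np.clip(patch, 0, 255).astype(np.uint8)
    mask[y0:y1, x0:x1] |= inside


def generate_slide(
    width: int = DEFAULT_WIDTH,
    height: int = DEFAULT_HEIGHT,
    mode: str = "brightfield",
    n_blobs: int = DEFAULT_BLOBS,
    seed: int = DEFAULT_SEED,
    noise_amplitude: int = DEFAULT_NOISE,
    radius_range: tuple[int, int] = DEFAULT_RADIUS_RANGE,
) -> SyntheticSlide:
    """Generate a synthetic slide.

    Parameters
    ----------
    mode:
        ``"brightfield"`` paints dark textured blobs on a near-white field;
        ``"fluorescent"`` paints bright textured blobs on a near-black field.
    n_blobs:
        Number of elliptical blobs; blobs may overlap and merge.
    noise_amplitude:
        Uniform additive noise bounded by this amplitude is applied to the
        whole raster (background included), emulating sensor noise.
    """
    if width < 16 or height < 16:
        raise ValidationError("fixture slides must be at least 16x16")
    if n_blobs < 0:
        raise ValidationError("n_blobs must be >= 0")
    if mode not in ("brightfield", "fluorescent"):
        raise ValidationError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    background = 252 if mode == "brightfield" else 3
    raster = np.full((height, width, 3), background, dtype=np.uint8)
    mask = np.zeros((height, width), dtype=bool)

    for _ in range(n_blobs):
        _paint_blob(raster, mask, rng, mode, radius_range)

    if noise_amplitude > 0:
        noise = rng.integers(
            -noise_amplitude, noise_amplitude + 1, size=raster.shape
        )
        raster = np.clip(raster.astype(np.int16) + noise, 0, 255).astype(np.uint8)

    params = {
        "n_blobs": n_blobs,
        "radius_range": radius_range,
        "noise_amplitude": noise_amplitude,
    }
    return SyntheticSlide(raster, mode, mask, seed, params)


def grid_truth(slide: SyntheticSlide, grid) -> list[bool]:
    """Per-tile "contains content" flags, row-major, matching ``grid.tiles``.

    A tile is true when the occupancy-mask overlap covers at least
    ``TRUTH_OVERLAP_FRACTION`` of its pixels.  The grid must have been
    computed on this slide at the scan magnification (downsample 1), so that
    tile boxes index the mask directly.
    """
    h, w = slide.occupancy_mask.shape
    truths: list[bool] = []
    for tile in grid.tiles:
        x0, y0, x1, y1 = tile.box
        if x1 > w or y1 > h:
            raise ValidationError("grid does not match the slide's dimensions")
        sub = slide.occupancy_mask[y0:y1, x0:x1]
        truths.append(bool(sub.mean() >= TRUTH_OVERLAP_FRACTION))
    return truths


def write_slide(
    slide: SyntheticSlide,
    path: str | os.PathLike,
    magnification: float = DEFAULT_MAGNIFICATION,
    mask_path: str | os.PathLike | None = None,
) -> Path:
    """Write the raster as a TIFF with a magnification tag; optionally the mask as PNG."""
    import tifffile
    from PIL import Image

    path = Path(path)
    tifffile.imwrite(path, slide.raster, description=f"magnification={magnification}")
    if mask_path is not None:
        Image.fromarray(slide.occupancy_mask.astype(np.uint8) * 255).save(mask_path)
    return path
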