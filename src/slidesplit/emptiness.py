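"""Empty-tile detection.

When a slide is split into a grid, many cells hold nothing but scanner
background.  Two cheap classifiers decide whether a tile carries any
pathology content, each suited to one imaging modality:

intensity (fluorescent / black background)
    Per-pixel intensity is the unweighted channel mean on [0, 255].  A tile
    is *empty* when its mean intensity falls below ``avg_threshold`` AND the
    fraction of pixels at or above ``whiteness_threshold`` falls below
    ``min_lit_fraction`` — i.e. a tile is interesting if it has either
    enough overall signal or enough sufficiently-bright pixels.

compression (brightfield / white background)
    The tile is JPEG-encoded in memory at ``probe_quality``; the ratio of
    encoded bytes to raw bytes (``width * height * channels``) measures how
    much structure the tile holds.  A near-uniform white tile compresses to
    a tiny fraction of its raw size, so a ratio below ``ratio_threshold``
    marks it empty.  Every JPEG stream carries a fixed header overhead
    (~0.6 kB with standard tables), which would dominate the ratio for small
    tiles — truncated edge tiles of a grid would score *higher* than full
    blank tiles.  The ratio therefore subtracts the encoder's fixed stream
    overhead (measured once per quality setting by encoding a 1x1 image)
    before normalising by raw byte count, which is what actually makes the
    threshold independent of tile size.

Every verdict is returned as an :class:`EmptinessReport` carrying the scores
and the thresholds applied, so a log of reports is enough to re-derive (and
fine-tune) every decision.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .exceptions import ValidationError

ALGORITHMS = ("intensity", "compression")


@dataclass(frozen=True)
class IntensityThresholds:
    """Cutoffs for the intensity classifier (fluorescent slides)."""

    avg_threshold: float = 10.0  # mean-intensity cutoff, grey levels
    whiteness_threshold: float = 30.0  # per-pixel "lit" cutoff, grey levels
    min_lit_fraction: float = 0.01  # fraction of lit pixels needed

    def __post_init__(self) -> None:
        if not (0 <= self.avg_threshold <= 255):
            raise ValidationError("avg_threshold must be in [0, 255]")
        if not (0 <= self.whiteness_threshold <= 255):
            raise ValidationError("whiteness_threshold must be in [0, 255]")
        if not (0 <= self.min_lit_fraction <= 1):
            raise ValidationError("min_lit_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CompressionThresholds:
    """Cutoffs for the compression classifier (brightfield slides)."""

    probe_quality: int = 75  # JPEG encoder quality for the probe
    ratio_threshold: float = 0.008  # overhead-corrected compressed/raw cutoff

    def __post_init__(self) -> None:
        if not (1 <= self.probe_quality <= 100):
            raise ValidationError("probe_quality must be in [1, 100]")
        if not (0 < self.ratio_threshold < 1):
            raise ValidationError("ratio_threshold must be in (0, 1)")


@dataclass(frozen=True)
class EmptinessReport:
    """One tile's verdict, with the evidence that produced it."""

    tile_name: str
    algorithm: str
    scores: dict[str, float]
    thresholds: dict[str, float]
    is_empty: bool

    def log_line(self) -> str:
        """Tab-separated line: name, algorithm, scores, thresholds, verdict."""
        scores = ";".join(f"{k}={v:.6g}" for k, v in self.scores.items())
        thresholds = ";".join(f"{k}={v:g}" for k, v in self.thresholds.items())
        verdict = "empty" if self.is_empty else "kept"
        return "\t".join([self.tile_name, self.algorithm, scores, thresholds, verdict])


def _check_tile(tile: np.ndarray) -> np.ndarray:
    tile = np.asarray(tile)
    if tile.size == 0:
        raise ValidationError("tile raster is empty")
    if tile.ndim not in (2, 3):
        raise ValidationError("tile must be a 2-D grayscale or 3-D RGB raster")
    return tile


def intensity_emptiness(
    tile: np.ndarray,
    thresholds: IntensityThresholds | None = None,
    tile_name: str = "",
) -> EmptinessReport:
    """Classify a tile by pixel intensity (black-background modality)."""
    t = thresholds or IntensityThresholds()
    tile = _check_tile(tile)
    intensity = tile.astype(np.float64)
    if intensity.ndim == 3:
        intensity = intensity.mean(axis=2)
    mean_intensity = float(intensity.mean())
    lit_fraction = float((intensity >= t.whiteness_threshold).mean())
    is_empty = mean_intensity < t.avg_threshold and lit_fraction < t.min_lit_fraction
    return EmptinessReport(
        tile_name=tile_name,
        algorithm="intensity",
        scores={"mean_intensity": mean_intensity, "lit_fraction": lit_fraction},
        thresholds={
            "avg_threshold": t.avg_threshold,
            "whiteness_threshold": t.whiteness_threshold,
            "min_lit_fraction": t.min_lit_fraction,
        },
        is_empty=is_empty,
    )


def _encoded_size(tile: np.ndarray, quality: int) -> int:
    buf = io.BytesIO()
    Image.fromarray(tile).save(buf, format="JPEG", quality=quality)
    return buf.tell()


# fixed JPEG stream overhead (headers, quantisation/Huffman tables) per quality
_OVERHEAD_CACHE: dict[int, int] = {}


def _stream_overhead(quality: int) -> int:
    if quality not in _OVERHEAD_CACHE:
        probe = np.zeros((1, 1, 3), dtype=np.uint8)
        _OVERHEAD_CACHE[quality] = _encoded_size(probe, quality)
    return _OVERHEAD_CACHE[quality]


def compression_emptiness(
    tile: np.ndarray,
    thresholds: CompressionThresholds | None = None,
    tile_name: str = "",
) -> EmptinessReport:
    """Classify a tile by JPEG compressibility (white-background modality)."""
    t = thresholds or CompressionThresholds()
    tile = _check_tile(tile)
    channels = 1 if tile.ndim == 2 else tile.shape[2]
    raw_bytes = tile.shape[0] * tile.shape[1] * channels
    encoded = _encoded_size(tile, t.probe_quality)
    ratio = max(0, encoded - _stream_overhead(t.probe_quality)) / raw_bytes
    return EmptinessReport(
        tile_name=tile_name,
        algorithm="compression",
        scores={"compression_ratio": float(ratio)},
        thresholds={
            "probe_quality": float(t.probe_quality),
            "ratio_threshold": t.ratio_threshold,
        },
        is_empty=ratio < t.ratio_threshold,
    )


def classify_tiles(
    tiles,  # iterable of (name, raster) pairs
    algorithm: str,
    thresholds: IntensityThresholds | CompressionThresholds | None = None,
) -> list[EmptinessReport]:
    """Run one classifier over a sequence of ``(name, raster)`` pairs.

    Verdicts are independent across tiles and order is preserved.
    """
    if algorithm == "intensity":
        if thresholds is not None and not isinstance(thresholds, IntensityThresholds):
            raise ValidationError("intensity algorithm needs IntensityThresholds")
        return [intensity_emptiness(r, thresholds, name) for name, r in tiles]
    if algorithm == "compression":
        if thresholds is not None and not isinstance(thresholds, CompressionThresholds):
            raise ValidationError("compression algorithm needs CompressionThresholds")
        return [compression_emptiness(r, thresholds, name) for name, r in tiles]
    raise ValidationError(
        f"unknown emptiness algorithm {algorithm!r}; expected one of {ALGORITHMS}"
    )


def thresholds_from_properties(props: dict[str, str], algorithm: str):
    """Build a thresholds object from ``NDPIsplitter.properties`` keys.

    Recognised keys: ``empty.intensity.avg``, ``empty.intensity.whiteness``,
    ``empty.intensity.minfraction``, ``empty.compression.quality``,
    ``empty.compression.ratio``.  Missing keys fall back to defaults.
    """
    if algorithm == "intensity":
        d = IntensityThresholds()
        return IntensityThresholds(
            avg_threshold=float(
                props.get("empty.intensity.avg", d.avg_threshold)
            ),
            whiteness_threshold=float(
                props.get("empty.intensity.whiteness", d.whiteness_threshold)
            ),
            min_lit_fraction=float(
                props.get("empty.intensity.minfraction", d.min_lit_fraction)
            ),
        )
    if algorithm == "compression":
        d = CompressionThresholds()
        return CompressionThresholds(
            probe_quality=int(props.get("empty.compression.quality", d.probe_quality)),
            ratio_threshold=float(
                props.get("empty.compression.ratio", d.ratio_threshold)
            ),
        )
    raise ValidationError(f"unknown emptiness algorithm {algorithm!r}")
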