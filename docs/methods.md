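# Methods

This note documents the models and procedures behind `slidesplit`, the
parameters that matter, the numerical choices at the edges, and what the
synthetic fixtures do and do not demonstrate about real slides.

## Slide access model

A slide is abstracted as `(width_px, height_px, scan_magnification)` plus a
region-read operation. `scan_magnification` is the objective-equivalent
resolution of the full raster (40 for a typical "400x" scan at
~0.25 µm/px); requesting a region at magnification `m` implies a downsample
factor `d = scan_magnification / m ≥ 1`. Upsampling is refused — the data
does not exist.

Conventions, fixed once and used everywhere: 0-based pixel coordinates,
top-left origin, half-open boxes `[x0, x1) × [y0, y1)`. Output dimensions of
a downsampled read are `round(w/d) × round(h/d)` with round-half-up, so that
grid planning and pixel extraction always agree on level sizes.

Resampling: area (box) averaging for `d ≥ 2`, bilinear for `1 < d < 2`,
selectable per call. Area averaging is the default because it is the
correct anti-aliasing choice for integer decimation and is exactly
checkable against a block-mean oracle. At `d = 1` reads are verbatim memory
copies — no filter is applied, so pixels outside a requested box can never
influence it.

Container formats are behind a registry keyed by extension and magic bytes
(magic wins on conflict). Shipped readers: TIFF (plain and tiled/pyramidal,
via tifffile; the base page is authoritative) and PNG (Pillow). Scan
magnification comes from a `magnification=<x>` token in the container's
free-text description/text chunk when present, else a configurable default
(40). Proprietary formats such as NDPI are plugin points: any object
satisfying the reader protocol can be registered; nothing else in the
toolkit changes.

## Grid splitting

Tile dimensions are interpreted at the output magnification: a request for
300x300 tiles at 20x of a 40x scan grids the 2x-downsampled level raster.
The grid has `ceil(level_w / tile_w)` columns and `ceil(level_h / tile_h)`
rows; last-row/column tiles are **truncated, not padded**. Truncation keeps
the tiles an exact partition of the level raster — areas sum to the level
area, stitching tiles back by their boxes is bit-exact — and avoids
fabricating pixels that would bias downstream image analysis.

Names are spreadsheet-style: rows map to bijective base-26 letters (A…Z,
AA, AB, …; no zero digit), columns to 1-based numbers, so row 0 reads
A1, A2, A3, … The mapping is injective and round-trips through a parser.

A filtered split writes classified-empty tiles to an `empty_tiles/`
subdirectory (never deletes them — the classifiers are heuristics and the
tiles must remain reviewable) and a `log.txt` with one tab-separated line
per grid cell: name, algorithm, scores, thresholds, verdict. The log is the
tuning surface: every verdict can be re-derived and re-thresholded from it.

## Empty-tile classification

Two cheap, training-free classifiers, each matched to one background type.

**Intensity (fluorescent, black background).** Per-pixel intensity is the
unweighted channel mean on [0, 255] (luma weighting was rejected: the
target is near-black backgrounds where channel balance is irrelevant). A
tile is *empty* iff `mean_intensity < avg_threshold` **and**
`lit_fraction < min_lit_fraction`, where `lit_fraction` is the fraction of
pixels at or above `whiteness_threshold`. The conjunction means a tile
stays interesting if it has *either* enough aggregate signal *or* enough
individually bright pixels — a dim but punctate signal pattern passes via
the second criterion. Defaults: `avg_threshold = 10`,
`whiteness_threshold = 30`, `min_lit_fraction = 0.01`. The rule is monotone:
brightening pixels can only move a tile away from "empty".

**Compression (brightfield, white background).** The tile is JPEG-encoded
in memory at `probe_quality` (default 75); near-uniform white encodes to a
tiny fraction of its raw size while tissue texture does not. The score is

```
compression_ratio = max(0, encoded_bytes − overhead) / (w · h · channels)
```

where `overhead` is the encoder's fixed stream cost (headers plus
quantisation/Huffman tables, ~0.6 kB with standard tables), measured once
per quality setting by encoding a 1x1 image. Subtracting it is essential
for size independence: without the correction a featureless 300x36 edge
tile scores ~0.027 while a featureless 300x300 tile scores ~0.008 — the
header, not the content, would dominate small tiles and any single
threshold would misroute either edge tiles or full tiles. After the
correction, featureless tiles of all sizes score ~0.005–0.007 per raw byte.

The default `ratio_threshold = 0.008` sits just above the residual cost of
encoding featureless background (uniform field plus bounded sensor noise,
~0.005–0.007) and below the cost observed for any tile with ≳1% textured
tissue coverage (≥ 0.0085 on the default fixture; fully covered tiles reach
~0.17, a >20x separation from blank). The probe is in-memory only; written
tiles remain TIFF.

Both classifiers are deterministic functions of the tile and thresholds,
and both are monotone in their thresholds (raising `ratio_threshold` or
`min_lit_fraction` can only grow the empty set). All five cutoffs are
configurable via `NDPIsplitter.properties`
(`empty.intensity.avg`, `empty.intensity.whiteness`,
`empty.intensity.minfraction`, `empty.compression.quality`,
`empty.compression.ratio`).

## Snapshots

The snapshot box is the centred half-width × half-height region:
`box_w = floor(W/2)`, `x0 = floor((W − box_w)/2)` (same for height), giving
a pixel-area ratio of exactly 1/4 for even dimensions and marginally below
for odd ones. "Half of each dimension" rather than "quarter of each
dimension" is the reading consistent with a quarter of the *area*. The box
is rendered at the configured magnification, watermarked, and JPEG-encoded
at the configured quality (default 90).

Watermarking alpha-composites an RGBA logo bottom-centred with a margin of
2% of image height; output dimensions equal input dimensions and pixels
outside the logo box are untouched. Logos larger than the image are
downscaled to fit; degenerate logos are skipped with a warning.

## Deep Zoom pyramids

Level geometry follows the DZI convention: `max_level =
ceil(log2(max(w, h)))`; level `max_level` holds the source; each lower
level ceil-halves both dimensions; level 0 is 1x1. Tiles are
`tile_size = 254` with `overlap = 1` (the conventional Deep Zoom
parameters: interior tiles measure 256, aligning JPEG block boundaries),
JPEG-encoded at quality 85 by default; PNG tiles are supported where
lossless output matters. The descriptor XML uses the
`http://schemas.microsoft.com/deepzoom/2008` namespace and the tile tree is
`{name}_files/{level}/{col}_{row}.{format}`, so any standard viewer can
consume the output.

Each level raster is produced by box-downsampling the next larger level
(successive ceil-halving) rather than resizing from the source every time:
this matches the dimension recurrence exactly and bounds peak memory to one
extra level. Publication overwrites in place, making re-publication
idempotent.

## Archiving workflow

The nightly pipeline is a folder state machine — the filesystem is the
job queue and the audit trail. Stage 1 moves each inbox slide through
open → snapshot; failures of either step route the slide to the failure
folder and never abort the batch. Stage 2 treats the snapshot filename stem
as the slide identifier: a successful record-store lookup links the record
(last-write-wins, idempotent) and publishes the pyramid; an unknown
identifier routes the JPEG to `JPEG-Failed` and fires the notification hook
(a callback; wiring it to email is deployment detail). Every ingested file
ends in exactly one terminal folder, and re-running a batch after an
interruption cannot double-link or double-publish.

The specimen store is an adapter interface (`lookup`/`link`); the reference
backend is a single-file SQLite database with a `specimens(identifier,
image_path)` table, standing in for a clinical system where a stored
procedure updates the matched specimen record. Manually corrected
snapshots re-enter through `reprocess_corrected`, which validates that the
file decodes as JPEG and deduplicates by name. Scheduling is left to the
host (cron or `slidesplit watch`, a polling loop); published JPEGs are
retained by default, with an optional retention flag to delete them once
the pyramid exists.

## Synthetic fixtures

The generator emulates the two imaging modalities at desk scale: a
near-uniform background (brightfield 252, fluorescent 3, plus uniform
additive noise of amplitude 1 by default) and `n_blobs` rotated elliptical
"tissue" regions with three texture layers — low-frequency sinusoidal
shading (stain-density variation, amplitude 35, wavelength 12–30 px), gray
per-pixel speckle (±90, incompressible fine structure), and high-contrast
puncta in the outer margin band, emulating the nucleus-dense rim of a
lesion. Fluorescent blobs keep their signal channel at a floor of 100,
reflecting that fluorophore signal is additive light above background, so
every painted pixel clears the whiteness threshold. The boolean occupancy
mask records exactly the painted pixels, and mask geometry is identical
across modes for the same seed. Everything is driven by one integer seed
through `numpy.random.default_rng`; outputs are bit-reproducible.

Per-tile ground truth (`grid_truth`) marks a tile as containing content
when mask overlap covers at least 0.5% of its pixels. The default test
slide is 2048x1536 with 8 blobs of semi-axis 90–240 px — large enough for
multi-level pyramids and 42-cell grids, small enough to regenerate in every
test run.

Texture amplitudes were calibrated once, by measuring encoder cost curves
for candidate textures across several seeds, so that the JPEG ratio
separates blank from blob-bearing tiles decisively (featureless ~0.005–0.007
vs fully covered ~0.17). What passing fixture tests shows is that the
classifiers agree perfectly with ground truth *when blank and occupied
tiles are well separated*. What they do not show: real slides contain faint
tissue, stain gradients, scanner vignetting and dust, where both
classifiers will misclassify near-threshold tiles — which is precisely why
empty tiles are retained for review and every decision is logged. Tiles
whose true occupancy sits in the ambiguous band around both the truth
cutoff (0.5%) and the classifier detection floor (~1%) are genuinely
undecidable by these statistics; the default fixture's blob geometry keeps
its tiles out of that band, real data will not always oblige.

## Problem sizes and numerical edges

Tests and the acceptance script run at desk scale: 2048x1536 fixtures,
300x300 tiles, fuzzed rasters up to ~320 px for bit-exactness checks,
pyramid geometry fuzzed to 4096 px with pixel-level stitching verified at
~600 px, and an 8-file workflow batch. These sizes exercise every code path
(multi-level pyramids, truncated edge tiles, failure routing) while keeping
a full run under a minute.

Edge cases pinned down by tests: 1x1 pyramids (`max_level = 0`); tiles
larger than the level raster (legal: a single tile); slides smaller than
2x2 cannot be snapshotted; non-integer downsample factors round half-up;
empty tile rasters are rejected rather than scored; corrupt container
files raise a distinct open-failure signal that the workflow maps to its
failure folder.
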