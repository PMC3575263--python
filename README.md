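# slidesplit

Tools for getting whole-slide microscopy images out of the scanner and into
the hands of image-analysis software and web viewers.

Digitised histology slides are multi-gigapixel images. That size blocks the
two things a tissue bank most wants to do with them: feed them to image
analysis packages (which run out of memory on whole slides) and publish them
online (where a browser needs progressive, tiled delivery). `slidesplit`
covers both paths with one shared slide-access layer:

* **Splitting** — cut a slide into a grid of fixed-size TIFF tiles at a
  chosen magnification, named spreadsheet-style (`A1, A2, …, B1, …`) by grid
  position. Tiles that contain no tissue can be filtered out automatically:
  an **intensity** test (for fluorescent slides — is there enough signal
  above black?) or a **compression** test (for brightfield slides — does the
  tile JPEG-compress so well that it must be blank white?). Filtered tiles
  are retained in an `empty_tiles/` subdirectory for review, and `log.txt`
  records every score and threshold so cutoffs can be tuned.
* **Snapshots** — render the centred quarter of a slide (half width x half
  height, so exactly 1/4 of the pixel area) as a watermarked JPEG at a
  configured magnification. Centre cropping maximises the chance of
  capturing the diagnostically relevant region without any content analysis.
* **Deep Zoom publishing** — convert a snapshot (or any raster) into a DZI
  pyramid: an XML descriptor plus `{name}_files/{level}/{col}_{row}.jpg`
  tiles with power-of-two levels (`max_level = ceil(log2(max(w, h)))`,
  ceil-halving dimensions down to 1x1), consumable by any standard
  JavaScript Deep Zoom viewer.
* **Archiving workflow** — a folder state machine for nightly batches:
  scanner inbox → snapshot → specimen-record linking (SQLite reference
  backend, adapter interface for real systems) → Deep Zoom publication,
  with per-file failure routing (`NDPI-Failed`, `JPEG-Failed`) and a
  notification hook for unmatched slide identifiers.

Slides are read through a format registry (plain/tiled TIFF via `tifffile`,
PNG via Pillow); proprietary containers such as Hamamatsu NDPI plug in via
`slidesplit.register_reader` without touching the rest of the toolkit. A
deterministic synthetic-slide generator (`slidesplit.fixtures`) produces
brightfield and fluorescent slides with ground-truth occupancy masks, so the
whole pipeline is testable without any scanner data.

## Worked example

Generate a synthetic brightfield slide, split it with empty-tile filtering,
snapshot it, and publish the snapshot as a Deep Zoom pyramid:

```sh
$ slidesplit fixtures --width 2048 --height 1536 --mode brightfield \
      --blobs 8 --seed 7 --out scan042.tif
scan042.tif (2048x1536 brightfield, 8 blobs, seed 7)

$ slidesplit split scan042.tif --tile-width 300 --tile-height 300 \
      --empty-filter compression --out tiles
scan042.tif: 6x7 grid, 18 tiles kept, 24 empty -> tiles/scan042

$ slidesplit snapshot scan042.tif --magnification 20 --quality 90 --out snaps
scan042.tif -> snaps/scan042.jpg

$ slidesplit deepzoom snaps/scan042.jpg --out publish
scan042.jpg: 10 levels, 16 tiles -> publish/scan042.dzi
```

The split produced a 6x7 grid (42 tiles of 300x300 px, edge tiles
truncated); 24 tiles were classified empty and moved to
`tiles/scan042/empty_tiles/`. Each decision is logged:

```
$ head -2 tiles/scan042/log.txt
A1	compression	compression_ratio=0.00534444	probe_quality=75;ratio_threshold=0.008	empty
A2	compression	compression_ratio=0.00533704	probe_quality=75;ratio_threshold=0.008	empty
```

Tile `A1` compressed to 0.53% of its raw byte size (after subtracting the
encoder's fixed stream overhead) — far below the 0.8% cutoff, so it is
blank background. The snapshot is the centred 1024x768 quarter of the slide
rendered at 20x (half the 40x scan magnification), i.e. 512x384 px; its
pyramid has 10 levels (512 → 1x1 by repeated halving) and 16 tile files.

The nightly pipeline over a watch-folder tree is one command:

```sh
slidesplit watch --config snapshot-creator.properties --once
```

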