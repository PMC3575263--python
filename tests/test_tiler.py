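import math

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

from slidesplit.emptiness import CompressionThresholds
from slidesplit.exceptions import ValidationError
from slidesplit.fixtures import generate_slide, grid_truth, write_slide
from slidesplit.slide_io import open_slide, slide_from_array
from slidesplit.tiler import compute_grid, parse_tile_name, split_slide, tile_name


class TestTileName:
    @pytest.mark.parametrize(
        "row, col, expected",
        [
            (0, 0, "A1"),
            (0, 1, "A2"),
            (0, 2, "A3"),
            (1, 0, "B1"),
            (25, 0, "Z1"),
            (26, 0, "AA1"),
            (27, 1, "AB2"),
            (701, 9, "ZZ10"),
            (702, 0, "AAA1"),
        ],
    )
    def test_spreadsheet_naming(self, row, col, expected):
        assert tile_name(row, col) == expected

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_round_trips_through_parser(self, row, col):
        assert parse_tile_name(tile_name(row, col)) == (row, col)

    def test_injective_over_a_grid(self):
        names = {tile_name(r, c) for r in range(60) for c in range(40)}
        assert len(names) == 60 * 40

    def test_negative_indices_rejected(self):
        with pytest.raises(ValidationError):
            tile_name(-1, 0)


def _slide(w, h, mag=40):
    return slide_from_array(np.zeros((h, w, 3), np.uint8), magnification=mag)


class TestComputeGrid:
    def test_exact_division_2x2(self):
        grid = compute_grid(_slide(600, 600), 300, 300)
        assert (grid.n_rows, grid.n_cols) == (2, 2)
        assert [t.name for t in grid.tiles] == ["A1", "A2", "B1", "B2"]
        assert not any(t.is_edge for t in grid.tiles)

    def test_truncated_edges_700x500(self):
        grid = compute_grid(_slide(700, 500), 300, 300)
        assert (grid.n_cols, grid.n_rows) == (3, 2)
        assert len(grid.tiles) == 6
        last = grid.tiles[-1]  # B3: bottom-right
        assert last.width == 100 and last.height == 200
        assert last.is_edge

    def test_single_tile_identity(self):
        grid = compute_grid(_slide(300, 300), 300, 300)
        assert len(grid.tiles) == 1
        assert grid.tiles[0].name == "A1"
        assert grid.tiles[0].box == (0, 0, 300, 300)

    def test_tile_larger_than_level_is_single_tile(self):
        grid = compute_grid(_slide(100, 80), 300, 300)
        assert (grid.n_rows, grid.n_cols) == (1, 1)
        assert grid.tiles[0].box == (0, 0, 100, 80)

    def test_grid_at_lower_magnification_uses_level_dims(self):
        grid = compute_grid(_slide(700, 500, mag=40), 300, 300, magnification=20)
        assert (grid.level_width, grid.level_height) == (350, 250)
        assert (grid.n_cols, grid.n_rows) == (2, 1)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValidationError):
            compute_grid(_slide(100, 100), 0, 300)
        with pytest.raises(ValidationError):
            compute_grid(_slide(100, 100), 300, 300, magnification=80)

    @given(
        st.integers(1, 400),
        st.integers(1, 400),
        st.integers(1, 150),
        st.integers(1, 150),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_and_partition(self, w, h, tw, th):
        grid = compute_grid(_slide(w, h), tw, th)
        # ceiling arithmetic
        assert grid.n_cols == math.ceil(w / tw)
        assert grid.n_rows == math.ceil(h / th)
        # pixel-area conservation
        assert sum(t.width * t.height for t in grid.tiles) == w * h
        # exact partition: every pixel covered exactly once
        cover = np.zeros((h, w), dtype=np.int32)
        for t in grid.tiles:
            x0, y0, x1, y1 = t.box
            cover[y0:y1, x0:x1] += 1
        assert np.all(cover == 1)


class TestSplitSlide:
    def test_filter_off_writes_all_tiles_and_reassembles(self, tmp_path, rng):
        arr = rng.integers(0, 256, (500, 700, 3), dtype=np.uint8)
        slide = slide_from_array(arr, source="synthetic_slide.tif")
        grid = compute_grid(slide, 300, 300)
        result = split_slide(slide, grid, tmp_path)
        assert result.written_count == 6 and result.empty_count == 0
        assert result.log_path is None
        assert not (result.slide_dir / "empty_tiles").exists()
        stitched = np.zeros_like(arr)
        for t in grid.tiles:
            x0, y0, x1, y1 = t.box
            stitched[y0:y1, x0:x1] = tifffile.imread(result.slide_dir / f"{t.name}.tif")
        assert np.array_equal(stitched, arr)

    def test_all_white_slide_goes_entirely_to_empty_tiles(self, tmp_path):
        arr = np.full((600, 600, 3), 255, np.uint8)
        slide = slide_from_array(arr, source="blank.tif")
        grid = compute_grid(slide, 300, 300)
        result = split_slide(slide, grid, tmp_path, empty_filter="compression")
        assert result.written_count == 0 and result.empty_count == 4
        assert len(list((result.slide_dir / "empty_tiles").glob("*.tif"))) == 4
        assert not list(result.slide_dir.glob("*.tif"))

    def test_filtered_split_routes_tiles_by_ground_truth(self, tmp_path):
        # 12 grid cells; truth from the generator's occupancy mask
        fixture = generate_slide(1200, 900, "brightfield", n_blobs=3, seed=5)
        slide = slide_from_array(fixture.raster, source="fx.tif")
        grid = compute_grid(slide, 300, 300)
        truth = grid_truth(fixture, grid)
        result = split_slide(slide, grid, tmp_path, empty_filter="compression")
        assert len(grid.tiles) == 12
        assert result.written_count + result.empty_count == 12
        assert result.written_count == sum(truth)
        kept = {p.stem for p in result.slide_dir.glob("*.tif")}
        assert kept == {t.name for t, tr in zip(grid.tiles, truth) if tr}

    def test_log_records_every_grid_cell(self, tmp_path, brightfield_slide):
        slide = slide_from_array(brightfield_slide.raster, source="bf.tif")
        grid = compute_grid(slide, 300, 300)
        result = split_slide(slide, grid, tmp_path, empty_filter="compression")
        lines = result.log_path.read_text().splitlines()
        assert len(lines) == grid.n_rows * grid.n_cols
        for line in lines:
            name, algorithm, scores, thresholds, verdict = line.split("\t")
            assert algorithm == "compression"
            assert verdict in ("empty", "kept")
            assert "compression_ratio=" in scores
            assert "ratio_threshold=" in thresholds

    def test_unknown_algorithm_rejected(self, tmp_path):
        slide = slide_from_array(np.zeros((100, 100, 3), np.uint8))
        grid = compute_grid(slide, 50, 50)
        with pytest.raises(ValidationError):
            split_slide(slide, grid, tmp_path, empty_filter="texture")

    def test_split_from_tiff_file_round_trip(self, tmp_path):
        fixture = generate_slide(640, 480, "brightfield", n_blobs=1, seed=3)
        path = write_slide(fixture, tmp_path / "scan01.tif")
        slide = open_slide(path)
        grid = compute_grid(slide, 256, 256)
        result = split_slide(
            slide, grid, tmp_path / "out",
            empty_filter="compression",
            thresholds=CompressionThresholds(probe_quality=75),
        )
        assert result.slide_dir.name == "scan01"
        assert result.total == len(grid.tiles)
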