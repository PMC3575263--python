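import numpy as np
import pytest
from PIL import Image

from slidesplit.exceptions import StoreError, ValidationError
from slidesplit.fixtures import generate_slide, write_slide
from slidesplit.snapshot import SnapshotSpec
from slidesplit.workflow import (
    FileStatus,
    FolderLayout,
    LinkOutcome,
    SqliteSpecimenStore,
    link_specimen,
    reprocess_corrected,
    run_batch,
)


def make_slide_file(path, seed=1, size=(256, 192)):
    fixture = generate_slide(size[0], size[1], "brightfield", n_blobs=2, seed=seed)
    return write_slide(fixture, path)


@pytest.fixture
def layout(tmp_path):
    layout = FolderLayout.under(tmp_path)
    layout.ensure()
    return layout


@pytest.fixture
def spec():
    return SnapshotSpec(magnification=20.0, jpeg_quality=85)


def terminal_files(layout):
    folders = [
        layout.ndpi_processed,
        layout.ndpi_failed,
        layout.jpeg_processed,
        layout.jpeg_failed,
    ]
    return {p.name: folder.name for folder in folders for p in folder.iterdir()}


class TestRunBatch:
    def test_happy_path_publishes_and_links(self, layout, spec, tmp_path):
        ids = ["TB0001", "TB0002", "TB0003"]
        for i, sid in enumerate(ids):
            make_slide_file(layout.ndpi_new / f"{sid}.tif", seed=i)
        store = SqliteSpecimenStore.create(tmp_path / "specimens.db", ids)
        report = run_batch(layout, spec, store)
        assert report.count(FileStatus.PROCESSED) == 6  # 3 slides + 3 snapshots
        assert not list(layout.ndpi_new.iterdir())
        for sid in ids:
            assert (layout.ndpi_processed / f"{sid}.tif").is_file()
            assert (layout.publish_root / f"{sid}.dzi").is_file()
            assert (layout.publish_root / f"{sid}_files").is_dir()
            assert store.image_path(sid) is not None

    def test_unmatched_identifier_fails_link_and_notifies(self, layout, spec, tmp_path):
        make_slide_file(layout.ndpi_new / "NOSUCHID.tif")
        store = SqliteSpecimenStore.create(tmp_path / "s.db", ["OTHER"])
        notifications = []
        report = run_batch(
            layout, spec, store, notify=lambda i, p, m: notifications.append(i)
        )
        assert (layout.jpeg_failed / "NOSUCHID.jpg").is_file()
        assert notifications == ["NOSUCHID"]
        assert report.notifications == 1
        assert report.count(FileStatus.LINK_FAILED) == 1

    def test_corrupt_slide_contained_and_rest_processed(self, layout, spec, tmp_path):
        (layout.ndpi_new / "BROKEN.tif").write_bytes(b"II*\x00junk")
        make_slide_file(layout.ndpi_new / "GOOD.tif")
        store = SqliteSpecimenStore.create(tmp_path / "s.db", ["GOOD"])
        report = run_batch(layout, spec, store)
        assert (layout.ndpi_failed / "BROKEN.tif").is_file()
        assert (layout.publish_root / "GOOD.dzi").is_file()
        assert report.count(FileStatus.OPEN_FAILED) == 1

    def test_file_conservation_and_rerun_idempotence(self, layout, spec, tmp_path):
        ids = [f"SPEC{i}" for i in range(3)]
        for i, sid in enumerate(ids):
            make_slide_file(layout.ndpi_new / f"{sid}.tif", seed=i)
        (layout.ndpi_new / "BAD1.tif").write_bytes(b"II*\x00x")
        make_slide_file(layout.ndpi_new / "UNMATCHED.tif", seed=9)
        store = SqliteSpecimenStore.create(tmp_path / "s.db", ids)
        run_batch(layout, spec, store)
        placed = terminal_files(layout)
        # every ingested file in exactly one terminal folder
        assert sorted(placed) == sorted(
            [f"{s}.tif" for s in ids]
            + [f"{s}.jpg" for s in ids]
            + ["BAD1.tif", "UNMATCHED.tif", "UNMATCHED.jpg"]
        )
        links = {sid: store.image_path(sid) for sid in ids}
        # re-run: nothing to do, nothing changes
        report2 = run_batch(layout, spec, store)
        assert report2.outcomes == []
        assert terminal_files(layout) == placed
        assert {sid: store.image_path(sid) for sid in ids} == links

    def test_retention_flag_deletes_published_jpegs(self, layout, spec, tmp_path):
        make_slide_file(layout.ndpi_new / "KEEP0.tif")
        store = SqliteSpecimenStore.create(tmp_path / "s.db", ["KEEP0"])
        run_batch(layout, spec, store, keep_processed_jpegs=False)
        assert not list(layout.jpeg_processed.iterdir())
        assert (layout.publish_root / "KEEP0.dzi").is_file()


class TestSpecimenStore:
    def test_link_is_idempotent(self, tmp_path):
        store = SqliteSpecimenStore.create(tmp_path / "s.db", ["S1"])
        p = tmp_path / "S1.jpg"
        assert link_specimen(store, "S1", p) is LinkOutcome.LINKED
        assert link_specimen(store, "S1", p) is LinkOutcome.LINKED
        assert store.image_path("S1") == str(p)

    def test_missing_identifier_leaves_store_unchanged(self, tmp_path):
        db = tmp_path / "s.db"
        store = SqliteSpecimenStore.create(db, ["S1"])
        before = db.read_bytes()
        assert link_specimen(store, "S2", tmp_path / "x.jpg") is LinkOutcome.NOT_FOUND
        assert db.read_bytes() == before

    def test_second_link_overwrites_first(self, tmp_path):
        store = SqliteSpecimenStore.create(tmp_path / "s.db", ["S1"])
        link_specimen(store, "S1", tmp_path / "a.jpg")
        link_specimen(store, "S1", tmp_path / "b.jpg")
        assert store.image_path("S1") == str(tmp_path / "b.jpg")

    def test_unreachable_store_is_retryable_error(self, tmp_path):
        with pytest.raises(StoreError):
            SqliteSpecimenStore(tmp_path / "missing.db")

    def test_empty_identifier_rejected(self, tmp_path):
        store = SqliteSpecimenStore.create(tmp_path / "s.db")
        with pytest.raises(ValidationError):
            store.link("", tmp_path / "x.jpg")


class TestReprocessCorrected:
    def _jpeg(self, path):
        Image.fromarray(np.full((40, 60, 3), 90, np.uint8)).save(path, format="JPEG")
        return path

    def test_corrected_file_queued_and_linked_next_run(self, layout, spec, tmp_path):
        src = self._jpeg(tmp_path / "FIXEDID.jpg")
        queued = reprocess_corrected(layout, src)
        assert queued.parent == layout.jpeg_processing
        store = SqliteSpecimenStore.create(tmp_path / "s.db", ["FIXEDID"])
        run_batch(layout, spec, store)
        assert store.image_path("FIXEDID") is not None
        assert (layout.publish_root / "FIXEDID.dzi").is_file()

    def test_non_image_rejected(self, layout, tmp_path):
        bad = tmp_path / "junk.jpg"
        bad.write_bytes(b"not an image")
        with pytest.raises(ValidationError):
            reprocess_corrected(layout, bad)

    def test_png_masquerading_as_jpeg_rejected(self, layout, tmp_path):
        path = tmp_path / "sneaky.jpg"
        Image.fromarray(np.zeros((10, 10, 3), np.uint8)).save(path, format="PNG")
        with pytest.raises(ValidationError):
            reprocess_corrected(layout, path)

    def test_duplicate_queue_is_noop(self, layout, tmp_path):
        src = self._jpeg(tmp_path / "DUP.jpg")
        first = reprocess_corrected(layout, src)
        mtime = first.stat().st_mtime_ns
        again = reprocess_corrected(layout, src)
        assert again == first
        assert first.stat().st_mtime_ns == mtime


def test_layout_folders_must_be_distinct(tmp_path):
    with pytest.raises(ValidationError):
        FolderLayout(
            ndpi_new=tmp_path / "a",
            ndpi_processed=tmp_path / "a",
            ndpi_failed=tmp_path / "c",
            jpeg_processing=tmp_path / "d",
            jpeg_processed=tmp_path / "e",
            jpeg_failed=tmp_path / "f",
            publish_root=tmp_path / "g",
        )
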