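"""The nightly archiving pipeline as a folder state machine.

A scanner drops slides into an inbox; a batch run then moves every file
through a fixed set of folders so that the filesystem itself records the
pipeline state:

* ``ndpi_new`` — scanner inbox.  Each slide is opened, its centred-quarter
  snapshot rendered into ``jpeg_processing``, and the slide moved to
  ``ndpi_processed``; a slide that fails to open or render moves to
  ``ndpi_failed`` instead.
* ``jpeg_processing`` — snapshots awaiting publication (also the drop point
  for manually produced snapshots).  The filename stem is the slide
  identifier.  If the specimen record store knows the identifier, the record
  is linked to the snapshot, a Deep Zoom pyramid is published under
  ``publish_root``, and the JPEG moves to ``jpeg_processed``.  An unknown
  identifier moves the JPEG to ``jpeg_failed`` and fires the notification
  hook (the deployment's stand-in for an administrator email).

Errors are contained per file: one corrupt slide never aborts the batch, and
every ingested file ends in exactly one terminal folder.  Re-running a batch
is safe — linking is idempotent and publication overwrites in place.

The specimen store is an adapter interface; the reference backend is a
single-file SQLite database mimicking a clinical system's Specimens table,
where linking updates the matched record's image field.
"""

from __future__ import annotations

import enum
import logging
import os
import shutil
import sqlite3
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from PIL import Image

from . import deepzoom
from .exceptions import StoreError, ValidationError
from .slide_io import open_slide
from .snapshot import SnapshotSpec, write_snapshot

logger = logging.getLogger(__name__)

#: Extensions scanned in the slide inbox; `.ndpi` files are picked up when a
#: reader plugin for them is registered.
SLIDE_EXTENSIONS = (".tif", ".tiff", ".png", ".ndpi")


@dataclass(frozen=True)
class FolderLayout:
    """The seven pipeline folders; all must be distinct."""

    ndpi_new: Path
    ndpi_processed: Path
    ndpi_failed: Path
    jpeg_processing: Path
    jpeg_processed: Path
    jpeg_failed: Path
    publish_root: Path

    def __post_init__(self) -> None:
        paths = [Path(p).resolve() for p in self._all()]
        if len(set(paths)) != 7:
            raise ValidationError("the seven workflow folders must be distinct")

    def _all(self) -> tuple[Path, ...]:
        return (
            self.ndpi_new,
            self.ndpi_processed,
            self.ndpi_failed,
            self.jpeg_processing,
            self.jpeg_processed,
            self.jpeg_failed,
            self.publish_root,
        )

    def ensure(self) -> None:
        """Create any missing folders."""
        for p in self._all():
            Path(p).mkdir(parents=True, exist_ok=True)

    @classmethod
    def under(cls, root: str | os.PathLike) -> "FolderLayout":
        """Conventional layout rooted at ``root``."""
        root = Path(root)
        return cls(
            ndpi_new=root / "NDPI-New",
            ndpi_processed=root / "NDPI-Processed",
            ndpi_failed=root / "NDPI-Failed",
            jpeg_processing=root / "JPEG-Snapshot-Processing",
            jpeg_processed=root / "JPEG-Processed",
            jpeg_failed=root / "JPEG-Failed",
            publish_root=root / "publish",
        )

    @classmethod
    def from_properties(cls, props: dict[str, str]) -> "FolderLayout":
        """Read folder paths from ``snapshot-creator.properties`` keys.

        Keys: ``folders.ndpi.new``, ``folders.ndpi.processed``,
        ``folders.ndpi.failed``, ``folders.jpeg.processing``,
        ``folders.jpeg.processed``, ``folders.jpeg.failed``,
        ``folders.publish``.
        """
        return cls(
            ndpi_new=Path(props["folders.ndpi.new"]),
            ndpi_processed=Path(props["folders.ndpi.processed"]),
            ndpi_failed=Path(props["folders.ndpi.failed"]),
            jpeg_processing=Path(props["folders.jpeg.processing"]),
            jpeg_processed=Path(props["folders.jpeg.processed"]),
            jpeg_failed=Path(props["folders.jpeg.failed"]),
            publish_root=Path(props["folders.publish"]),
        )


class LinkOutcome(enum.Enum):
    LINKED = "linked"
    NOT_FOUND = "not_found"


class SpecimenStore:
    """Adapter contract to the specimen record system.

    ``lookup`` answers whether a slide identifier exists; ``link`` attaches a
    snapshot path to the matching record, atomically, and is idempotent —
    re-linking the same identifier overwrites (last write wins), and a failed
    lookup leaves the store unchanged.
    """

    def lookup(self, identifier: str) -> bool:
        raise NotImplementedError

    def link(self, identifier: str, snapshot_path: Path) -> LinkOutcome:
        raise NotImplementedError


class SqliteSpecimenStore(SpecimenStore):
    """Reference store: a single-file relational database of specimens."""

    def __init__(self, path: str | os.PathLike):
        self.path = Path(path)
        if not self.path.is_file():
            raise StoreError(f"specimen store not found: {self.path}")

    @classmethod
    def create(
        cls, path: str | os.PathLike, identifiers: Iterable[str] = ()
    ) -> "SqliteSpecimenStore":
        """Create a new store seeded with specimen identifiers."""
        path = Path(path)
        with sqlite3.connect(path) as conn:
            conn.execute(
                "CREATE TABLE IF NOT EXISTS specimens ("
                "identifier TEXT PRIMARY KEY, image_path TEXT)"
            )
            conn.executemany(
                "INSERT OR IGNORE INTO specimens (identifier) VALUES (?)",
                [(i,) for i in identifiers],
            )
        return cls(path)

    def _connect(self) -> sqlite3.Connection:
        try:
            return sqlite3.connect(self.path)
        except sqlite3.Error as exc:
            raise StoreError(f"cannot reach specimen store {self.path}: {exc}") from exc

    def lookup(self, identifier: str) -> bool:
        with self._connect() as conn:
            row = conn.execute(
                "SELECT 1 FROM specimens WHERE identifier = ?", (identifier,)
            ).fetchone()
        return row is not None

    def link(self, identifier: str, snapshot_path: Path) -> LinkOutcome:
        if not identifier:
            raise ValidationError("identifier must be non-empty")
        try:
            with self._connect() as conn:
                cur = conn.execute(
                    "UPDATE specimens SET image_path = ? WHERE identifier = ?",
                    (str(snapshot_path), identifier),
                )
        except sqlite3.Error as exc:
            raise StoreError(f"link failed for {identifier}: {exc}") from exc
        return LinkOutcome.LINKED if cur.rowcount else LinkOutcome.NOT_FOUND

    def image_path(self, identifier: str) -> str | None:
        """The snapshot currently linked to ``identifier`` (inspection helper)."""
        with self._connect() as conn:
            row = conn.execute(
                "SELECT image_path FROM specimens WHERE identifier = ?",
                (identifier,),
            ).fetchone()
        return row[0] if row else None


class FileStatus(enum.Enum):
    PROCESSED = "processed"
    OPEN_FAILED = "open_failed"
    LINK_FAILED = "link_failed"


@dataclass(frozen=True)
class FileOutcome:
    """Where one ingested file ended up and why."""

    source: Path
    status: FileStatus
    destination: Path
    notified: bool = False


@dataclass
class ProcessingReport:
    """Per-file outcomes of one batch run."""

    outcomes: list[FileOutcome] = field(default_factory=list)

    @property
    def notifications(self) -> int:
        return sum(o.notified for o in self.outcomes)

    def count(self, status: FileStatus) -> int:
        return sum(o.status is status for o in self.outcomes)


NotifyHook = Callable[[str, Path, str], None]


def _default_notify(identifier: str, path: Path, message: str) -> None:
    logger.warning("notification for %s (%s): %s", identifier, path, message)


def _move(src: Path, dst_dir: Path) -> Path:
    dst = dst_dir / src.name
    shutil.move(str(src), str(dst))
    return dst


def run_batch(
    layout: FolderLayout,
    spec: SnapshotSpec,
    store: SpecimenStore,
    notify: NotifyHook | None = None,
    keep_processed_jpegs: bool = True,
    tile_size: int = deepzoom.DEFAULT_TILE_SIZE,
    overlap: int = deepzoom.DEFAULT_OVERLAP,
) -> ProcessingReport:
    """Run one pipeline pass over the inbox and snapshot queue.

    Set ``keep_processed_jpegs=False`` to delete published snapshots instead
    of retaining them in ``jpeg_processed`` (a disk-space retention policy;
    the published pyramid always remains).
    """
    layout.ensure()
    notify = notify or _default_notify
    report = ProcessingReport()

    # stage 1: slides in the inbox -> snapshots
    for slide_path in sorted(Path(layout.ndpi_new).iterdir()):
        if not slide_path.is_file() or slide_path.suffix.lower() not in SLIDE_EXTENSIONS:
            continue
        try:
            slide = open_slide(slide_path)
            jpeg_path = Path(layout.jpeg_processing) / f"{slide_path.stem}.jpg"
            write_snapshot(slide, spec, jpeg_path)
        except Exception as exc:
            logger.warning("slide %s failed: %s", slide_path.name, exc)
            dest = _move(slide_path, Path(layout.ndpi_failed))
            report.outcomes.append(
                FileOutcome(slide_path, FileStatus.OPEN_FAILED, dest)
            )
            continue
        dest = _move(slide_path, Path(layout.ndpi_processed))
        report.outcomes.append(FileOutcome(slide_path, FileStatus.PROCESSED, dest))

    # stage 2: snapshots -> link + publish
    for jpeg_path in sorted(Path(layout.jpeg_processing).glob("*.jpg")):
        identifier = jpeg_path.stem
        if store.lookup(identifier):
            store.link(identifier, jpeg_path)
            with Image.open(jpeg_path) as im:
                raster = np.asarray(im.convert("RGB"))
            deepzoom.write_pyramid(
                raster,
                identifier,
                Path(layout.publish_root),
                deepzoom.compute_pyramid(
                    raster.shape[1], raster.shape[0], tile_size, overlap
                ),
            )
            if keep_processed_jpegs:
                dest = _move(jpeg_path, Path(layout.jpeg_processed))
            else:
                jpeg_path.unlink()
                dest = Path(layout.publish_root) / f"{identifier}.dzi"
            report.outcomes.append(FileOutcome(jpeg_path, FileStatus.PROCESSED, dest))
        else:
            dest = _move(jpeg_path, Path(layout.jpeg_failed))
            notify(identifier, dest, "no specimen record matches this identifier")
            report.outcomes.append(
                FileOutcome(jpeg_path, FileStatus.LINK_FAILED, dest, notified=True)
            )

    return report


def link_specimen(
    store: SpecimenStore, identifier: str, snapshot_path: Path
) -> LinkOutcome:
    """Link a snapshot to its specimen record (thin adapter passthrough)."""
    return store.link(identifier, snapshot_path)


def reprocess_corrected(layout: FolderLayout, renamed_jpeg: str | os.PathLike) -> Path:
    """Queue a manually corrected/produced JPEG for the next batch.

    The file must decode as a JPEG; queueing is deduplicated by name, so
    re-queueing the same file is a no-op.
    """
    src = Path(renamed_jpeg)
    try:
        with Image.open(src) as im:
            if im.format != "JPEG":
                raise ValidationError(f"{src.name} is not a JPEG (got {im.format})")
            im.verify()
    except ValidationError:
        raise
    except Exception as exc:
        raise ValidationError(f"{src.name} is not a decodable image: {exc}") from exc
    layout.ensure()
    target = Path(layout.jpeg_processing) / (src.stem + ".jpg")
    if target.exists() and target.resolve() != src.resolve():
        logger.info("already queued, skipping: %s", target.name)
        return target
    if target.resolve() != src.resolve():
        shutil.copy2(src, target)
    return target


def watch(
    layout: FolderLayout,
    spec: SnapshotSpec,
    store: SpecimenStore,
    interval_seconds: float = 60.0,
    once: bool = False,
    notify: NotifyHook | None = None,
) -> ProcessingReport:
    """Poll the inbox, running batches until interrupted (or once).

    Scheduling ("overnight") belongs to the host — cron, a service unit, or
    this simple polling loop.
    """
    report = run_batch(layout, spec, store, notify=notify)
    while not once:
        time.sleep(interval_seconds)
        report = run_batch(layout, spec, store, notify=notify)
    return report
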