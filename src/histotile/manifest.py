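"""Discovery, splitting and loading of class-per-folder image tile datasets.

Histology tile collections such as Kather texture 2016 (8 classes of
150x150 px tiles) and NCT-CRC-HE-100K (9 classes of 224x224 px tiles) are
distributed as one directory per tissue class, each holding the image tiles
of that class.  This module scans such a tree into a :class:`DatasetManifest`,
assigns a stratified train/validation/test split, and loads individual tiles
as RGB arrays.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

#: image extensions accepted by :func:`scan_dataset` (case-insensitive)
IMAGE_EXTENSIONS = (".tif", ".tiff", ".png", ".jpg", ".jpeg")

SPLITS = ("train", "val", "test")
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TileRecord:
    """One image tile: its path, tissue class and hold-out split."""

    path: Path
    class_label: str
    split: str = UNASSIGNED


@dataclass(frozen=True)
class SplitRatios:
    """Train/validation/test fractions; default is the 60-20-20 hold-out."""

    train: float = 0.6
    val: float = 0.2
    test: float = 0.2

    def __post_init__(self) -> None:
        total = self.train + self.val + self.test
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split ratios must sum to 1, got {total!r}")
        if not (0.0 < self.train < 1.0):
            raise ValueError("train fraction must lie in (0, 1)")
        if self.val < 0.0 or self.test < 0.0:
            raise ValueError("val/test fractions must be nonnegative")


@dataclass
class DatasetManifest:
    """Catalog of tile records with an ordered class list.

    ``tile_size`` is ``(height, width)`` when known, else ``None``.
    """

    class_names: list[str]
    records: list[TileRecord]
    tile_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        known = set(self.class_names)
        for rec in self.records:
            if rec.class_label not in known:
                raise ValueError(
                    f"record {rec.path} has unknown class {rec.class_label!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, split: str) -> list[TileRecord]:
        if split not in SPLITS and split != UNASSIGNED:
            raise ValueError(f"unknown split {split!r}")
        return [r for r in self.records if r.split == split]

    def counts(self) -> dict[str, dict[str, int]]:
        """Per-class counts by split, plus per-class totals under ``"all"``."""
        table: dict[str, dict[str, int]] = {
            c: {s: 0 for s in SPLITS + (UNASSIGNED, "all")} for c in self.class_names
        }
        for rec in self.records:
            table[rec.class_label][rec.split] += 1
            table[rec.class_label]["all"] += 1
        return table

    def split_totals(self) -> dict[str, int]:
        totals = {s: 0 for s in SPLITS + (UNASSIGNED,)}
        for rec in self.records:
            totals[rec.split] += 1
        return totals

    # -- persistence --------------------------------------------------------

    def save_tsv(self, path: str | Path) -> None:
        """Write the manifest as a ``path<TAB>class<TAB>split`` table."""
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("path\tclass\tsplit\n")
            for rec in self.records:
                fh.write(f"{rec.path}\t{rec.class_label}\t{rec.split}\n")

    @classmethod
    def load_tsv(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        records: list[TileRecord] = []
        with path.open("r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["path", "class", "split"]:
                raise ValueError(f"unexpected manifest header {header!r} in {path}")
            for line in fh:
                p, cls_name, split = line.rstrip("\n").split("\t")
                records.append(TileRecord(Path(p), cls_name, split))
        class_names = sorted({r.class_label for r in records})
        return cls(class_names=class_names, records=records)


def scan_dataset(root_dir: str | Path) -> DatasetManifest:
    """Scan a class-per-folder tree into a manifest with unassigned splits.

    Class names are the subdirectory names in lexicographic order.  Files
    whose extension is not an accepted image type, or that fail to decode,
    are skipped with a logged warning.  A class folder containing no usable
    image raises ``ValueError`` naming the folder.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {root}")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(
            f"{root} must contain at least 2 class folders, found {len(class_dirs)}"
        )
    records: list[TileRecord] = []
    tile_size: tuple[int, int] | None = None
    for class_dir in class_dirs:
        n_before = len(records)
        for f in sorted(class_dir.iterdir()):
            if not f.is_file():
                continue
            if f.suffix.lower() not in IMAGE_EXTENSIONS:
                logger.warning("skipping non-image file %s", f)
                continue
            try:
                with Image.open(f) as im:
                    size = (im.height, im.width)
            except Exception:
                logger.warning("skipping undecodable image %s", f)
                continue
            if tile_size is None:
                tile_size = size
            elif tile_size != size:
                tile_size = None  # heterogeneous tiles: size unknown
            records.append(TileRecord(f, class_dir.name))
        if len(records) == n_before:
            raise ValueError(f"class folder {class_dir} holds no decodable image")
    return DatasetManifest(
        class_names=[d.name for d in class_dirs], records=records, tile_size=tile_size
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def split_counts(n: int, ratios: SplitRatios) -> tuple[int, int, int]:
    """Per-class (train, val, test) counts for a class of size ``n``.

    Validation and test take ``round(ratio * n)`` (half away from zero);
    train absorbs the remainder, so no tile is dropped or duplicated.
    """
    n_val = _round_half_away(ratios.val * n)
    n_test = _round_half_away(ratios.test * n)
    n_train = n - n_val - n_test
    if n_train <= 0:
        raise ValueError(f"class of size {n} leaves no training tiles at {ratios}")
    return n_train, n_val, n_test


def stratified_split(
    manifest: DatasetManifest,
    ratios: SplitRatios = SplitRatios(),
    seed: int = 0,
) -> DatasetManifest:
    """Assign train/val/test splits class by class with a seeded shuffle.

    The assignment is deterministic given ``(manifest, ratios, seed)``;
    different seeds permute membership but the per-class counts are fixed
    by :func:`split_counts`.
    """
    by_class: dict[str, list[int]] = {c: [] for c in manifest.class_names}
    for i, rec in enumerate(manifest.records):
        by_class[rec.class_label].append(i)
    for cls_name, idx in by_class.items():
        if len(idx) < 3:
            raise ValueError(
                f"class {cls_name!r} has {len(idx)} tiles; at least 3 are required"
            )
    rng = np.random.default_rng(seed)
    new_records = list(manifest.records)
    for cls_name in manifest.class_names:
        idx = np.array(by_class[cls_name])
        n = len(idx)
        n_train, n_val, n_test = split_counts(n, ratios)
        order = rng.permutation(n)
        shuffled = idx[order]
        assignment = (
            ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
        )
        for record_i, split in zip(shuffled, assignment):
            new_records[record_i] = replace(new_records[record_i], split=split)
    return DatasetManifest(
        class_names=list(manifest.class_names),
        records=new_records,
        tile_size=manifest.tile_size,
    )


def load_tile(record: TileRecord) -> np.ndarray:
    """Load one tile as an ``H x W x 3`` uint8 RGB array.

    Grayscale sources are replicated to three channels with a warning;
    undecodable files raise ``OSError`` carrying the path.
    """
    try:
        with Image.open(record.path) as im:
            if im.mode in ("L", "I;16", "I"):
                logger.warning("grayscale tile %s replicated to RGB", record.path)
            if im.mode != "RGB":
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except OSError as exc:
        raise OSError(f"failed to decode tile {record.path}: {exc}") from exc
    return arr
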