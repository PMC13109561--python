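"""Filename-encoded plant image datasets: parsing, manifests, splits, preprocessing.

Datasets are folders of whole-plant RGB images whose filenames encode the
classification label and acquisition context as ``accession_tag_date_viewpoint.ext``
(e.g. ``R0001_p1_20210601_front.png``).  The manifest is the unit that the
augmentation, training and evaluation stages consume.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

RASTER_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
VIEWPOINTS = ("front", "side")

MANIFEST_COLUMNS = [
    "path", "accession", "tag", "date", "viewpoint",
    "stage", "subspecies", "split", "is_mixed",
]


class FilenameParseError(ValueError):
    """A filename does not follow the accession_tag_date_viewpoint grammar."""


@dataclass
class ImageRecord:
    """One image with its parsed label and acquisition context.

    ``date`` tokens are kept verbatim; they order numerically when every token
    in a dataset parses as an integer (days after sowing) and lexicographically
    otherwise (ISO dates).
    """

    path: str
    accession: str
    tag: str
    date: str
    viewpoint: str
    stage: str | None = None
    subspecies: str | None = None
    split: str | None = None
    is_mixed: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if self.viewpoint not in VIEWPOINTS:
            raise ValueError(
                f"viewpoint {self.viewpoint!r} not in {VIEWPOINTS}"
            )

    @property
    def date_key(self):
        return date_sort_key(self.date)

    @property
    def sort_key(self):
        return (self.accession, self.date_key, self.viewpoint, self.tag, self.path)


def date_sort_key(token: str):
    """Orderable key for a date token: numeric when integral, else lexicographic."""
    try:
        return (0, int(token), "")
    except (TypeError, ValueError):
        return (1, 0, str(token))


def parse_image_filename(name: str) -> ImageRecord:
    """Parse ``accession_tag_date_viewpoint.ext`` into an (unverified) record.

    The stem is split on underscores: first field is the accession, last is
    the viewpoint, second-to-last the date, and everything in between is the
    tag (so tags may themselves contain underscores).
    """
    p = Path(name)
    if p.suffix.lower() not in RASTER_EXTENSIONS:
        raise FilenameParseError(
            f"{name!r}: extension {p.suffix!r} is not a supported raster format"
        )
    fields = p.stem.split("_")
    if len(fields) < 4:
        raise FilenameParseError(
            f"{name!r}: expected >=4 underscore-separated fields "
            f"(accession_tag_date_viewpoint), got {len(fields)}"
        )
    accession, viewpoint = fields[0], fields[-1].lower()
    date, tag = fields[-2], "_".join(fields[1:-2])
    if viewpoint not in VIEWPOINTS:
        raise FilenameParseError(
            f"{name!r}: unknown viewpoint token {fields[-1]!r}; "
            f"accepted tokens: {', '.join(VIEWPOINTS)}"
        )
    if not accession:
        raise FilenameParseError(f"{name!r}: empty accession field")
    return ImageRecord(path=str(name), accession=accession, tag=tag,
                       date=date, viewpoint=viewpoint)


@dataclass
class DatasetManifest:
    """Ordered collection of image records with optional train/test splits."""

    records: list[ImageRecord] = field(default_factory=list)

    @property
    def num_accessions(self) -> int:
        return len({r.accession for r in self.records})

    @property
    def accessions(self) -> list[str]:
        return sorted({r.accession for r in self.records})

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([r for r in self.records if r.split == split])

    def clone(self) -> "DatasetManifest":
        """Deep copy: record mutations on the clone never touch the original."""
        return DatasetManifest([replace(r) for r in self.records])

    def groups(self) -> dict[str, list[ImageRecord]]:
        """Records grouped by accession, each group in deterministic order."""
        out: dict[str, list[ImageRecord]] = {}
        for r in sorted(self.records, key=lambda r: r.sort_key):
            out.setdefault(r.accession, []).append(r)
        return out

    def validate_splits(self) -> None:
        missing = [r.path for r in self.records if r.split not in ("train", "test")]
        if missing:
            raise ValueError(f"{len(missing)} records have no split assignment")
        train = {r.accession for r in self.records if r.split == "train"}
        test = {r.accession for r in self.records if r.split == "test"}
        orphans = test - train
        if orphans:
            raise ValueError(
                f"test accessions absent from train: {sorted(orphans)[:5]}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "path": r.path, "accession": r.accession, "tag": r.tag,
                "date": r.date, "viewpoint": r.viewpoint,
                "stage": r.stage if r.stage is not None else "",
                "subspecies": r.subspecies if r.subspecies is not None else "",
                "split": r.split if r.split is not None else "",
                "is_mixed": r.is_mixed,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DatasetManifest":
        records = []
        for row in df.itertuples(index=False):
            records.append(ImageRecord(
                path=str(row.path), accession=str(row.accession),
                tag="" if pd.isna(row.tag) else str(row.tag),
                date=str(row.date), viewpoint=str(row.viewpoint),
                stage=None if (pd.isna(row.stage) or row.stage == "") else str(row.stage),
                subspecies=None if (pd.isna(row.subspecies) or row.subspecies == "")
                else str(row.subspecies),
                split=None if (pd.isna(row.split) or row.split == "") else str(row.split),
                is_mixed=bool(row.is_mixed),
            ))
        return cls(records)

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        return cls.from_frame(pd.read_csv(path, dtype={"date": str, "tag": str}))


def build_manifest(folder) -> DatasetManifest:
    """Scan a folder of images into a manifest, sorted for determinism.

    Unparseable files are skipped with a warning; duplicate
    (accession, date, viewpoint) triples are retained but reported.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise FileNotFoundError(f"{folder} is not a directory")
    records: list[ImageRecord] = []
    n_seen = 0
    for f in sorted(folder.iterdir()):
        if not f.is_file():
            continue
        n_seen += 1
        try:
            rec = parse_image_filename(f.name)
        except FilenameParseError as e:
            logger.warning("skipping %s: %s", f.name, e)
            continue
        records.append(replace(rec, path=str(f)))
    if not records:
        raise ValueError(
            f"{folder}: no parseable images among {n_seen} files"
        )
    dupes = [k for k, n in Counter(
        (r.accession, r.date, r.viewpoint) for r in records).items() if n > 1]
    if dupes:
        logger.warning(
            "%d duplicate (accession, date, viewpoint) triples, e.g. %s",
            len(dupes), dupes[0],
        )
    records.sort(key=lambda r: r.sort_key)
    return DatasetManifest(records)


def split_dataset(manifest: DatasetManifest, test_fraction: float = 0.2,
                  seed: int = 0, stratify: bool = True) -> DatasetManifest:
    """Assign train/test splits, by default stratified per accession.

    Per accession, ``round(test_fraction * n)`` images go to test, floored at
    0 and capped at n-1 so every accession remains trainable.  With
    ``stratify=False`` a single global draw is used instead.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if not manifest.records:
        raise ValueError("manifest is empty")
    rng = np.random.default_rng(seed)
    new_records = [replace(r) for r in sorted(manifest.records,
                                              key=lambda r: r.sort_key)]
    if stratify:
        groups: dict[str, list[ImageRecord]] = {}
        for r in new_records:
            groups.setdefault(r.accession, []).append(r)
        for acc in sorted(groups):
            recs = groups[acc]
            n = len(recs)
            n_test = int(np.clip(round(test_fraction * n), 0, n - 1))
            if n == 1:
                logger.warning("accession %s has a single image; kept in train", acc)
            order = rng.permutation(n)
            test_idx = set(order[:n_test].tolist())
            for i, r in enumerate(recs):
                r.split = "test" if i in test_idx else "train"
    else:
        n = len(new_records)
        n_test = int(np.clip(round(test_fraction * n), 0, n - 1))
        order = rng.permutation(n)
        test_idx = set(order[:n_test].tolist())
        for i, r in enumerate(new_records):
            r.split = "test" if i in test_idx else "train"
    out = DatasetManifest(new_records)
    out.validate_splits()
    return out


def _foreground_bbox(arr: np.ndarray, margin: float):
    """Bounding box of the largest high-saturation connected component."""
    from skimage import color, filters, measure

    hsv = color.rgb2hsv(arr)
    sat = hsv[..., 1]
    try:
        thr = filters.threshold_otsu(sat)
    except ValueError:  # constant image
        return None
    mask = sat > thr
    if not mask.any():
        return None
    labels = measure.label(mask)
    props = measure.regionprops(labels)
    best = max(props, key=lambda p: p.area)
    r0, c0, r1, c1 = best.bbox
    mr = int(round(margin * (r1 - r0)))
    mc = int(round(margin * (c1 - c0)))
    h, w = arr.shape[:2]
    return (max(0, r0 - mr), max(0, c0 - mc),
            min(h, r1 + mr), min(w, c1 + mc))


def preprocess_image(image, target_size: tuple[int, int] = (360, 480),
                     crop: bool = False, margin: float = 0.05) -> np.ndarray:
    """Optionally crop to the plant, then resize to ``target_size`` (width, height).

    Cropping takes an Otsu threshold on the HSV saturation channel, keeps the
    largest connected component's bounding box padded by ``margin``, and falls
    back to the full frame (with a warning) when no foreground is found.
    Resizing is bilinear with antialiasing.  Output is uint8 RGB of exactly
    ``target_size``.
    """
    if isinstance(image, (str, Path)):
        image = np.asarray(Image.open(image).convert("RGB"))
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image with 3 channels")
    w, h = target_size
    if w <= 0 or h <= 0:
        raise ValueError("target_size must be positive")
    if crop:
        bbox = _foreground_bbox(arr, margin)
        if bbox is None:
            logger.warning("no foreground found; skipping crop")
        else:
            r0, c0, r1, c1 = bbox
            arr = arr[r0:r1, c0:c1]
    if arr.shape[0] == h and arr.shape[1] == w:
        return arr.astype(np.uint8, copy=True)
    pil = Image.fromarray(arr.astype(np.uint8))
    return np.asarray(pil.resize((w, h), resample=Image.BILINEAR))


def load_image(path, size: tuple[int, int] | None = None) -> np.ndarray:
    """Read an RGB image as a uint8 array, optionally resized to (width, height)."""
    img = Image.open(path).convert("RGB")
    if size is not None and img.size != tuple(size):
        img = img.resize(tuple(size), resample=Image.BILINEAR)
    return np.asarray(img)
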