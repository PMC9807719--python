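"""Dataset loading and preprocessing.

Two input routes produce the same canonical in-memory record form:

* :func:`load_figshare` reads a directory of per-slice MATLAB v7.3
  (HDF5-layout) ``.mat`` files, each holding a ``cjdata`` record with
  ``image``, ``label`` (1 = meningioma, 2 = glioma, 3 = pituitary),
  ``PID``, ``tumorBorder`` and ``tumorMask`` — the layout of the public
  3,064-slice contrast-enhanced T1-weighted brain-tumor collection
  (708 meningioma / 1,426 glioma / 930 pituitary slices, 233 patients).
* :func:`load_image_dir` reads grayscale image files listed in a CSV
  manifest with columns ``path,label,patient_id``.

Every image is resized to a square single-channel grid (bilinear) and
min-max scaled to [0, 1]; dataset labels 1/2/3 map to class indices 0/1/2.
Files are read in lexicographic path order so fold assignments downstream
are reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
import h5py
import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "ImageRecord",
    "DatasetManifest",
    "LABEL_NAMES",
    "RAW_TO_CLASS",
    "preprocess",
    "load_figshare",
    "load_image_dir",
    "write_manifest",
    "read_manifest",
    "DataFormatError",
]

LABEL_NAMES = ("meningioma", "glioma", "pituitary")
# raw dataset labels 1/2/3 -> class indices 0/1/2
RAW_TO_CLASS = {1: 0, 2: 1, 3: 2}


class DataFormatError(ValueError):
    """An input file does not match the expected layout."""


@dataclass
class ImageRecord:
    """One preprocessed slice: image in [0,1], class index, provenance."""

    image: np.ndarray
    label: int
    patient_id: str = ""
    source: str = ""
    split_tag: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1, 2):
            raise DataFormatError(f"label must be 0..2, got {self.label}")
        img = np.asarray(self.image, dtype=np.float32)
        if img.min() < -1e-6 or img.max() > 1 + 1e-6:
            raise DataFormatError("image intensities must lie in [0,1]")
        self.image = img


@dataclass
class DatasetManifest:
    """Ordered records plus per-class counts and preprocessing provenance."""

    records: list[ImageRecord]
    provenance: dict = field(default_factory=dict)

    @property
    def class_counts(self) -> tuple[int, int, int]:
        counts = [0, 0, 0]
        for r in self.records:
            counts[r.label] += 1
        return tuple(counts)

    def __len__(self) -> int:
        return len(self.records)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (n, h, w, 1) images and (n,) integer labels."""
        images = np.stack([r.image for r in self.records])[..., None]
        labels = np.array([r.label for r in self.records], dtype=np.int64)
        return images, labels

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]


def preprocess(image, target: int = 256) -> np.ndarray:
    """Bilinear-resize to ``target x target`` and min-max scale to [0, 1].

    A constant image maps to all zeros.  The operation is idempotent within
    float tolerance.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise DataFormatError("empty image")
    if img.ndim != 2:
        raise DataFormatError(f"expected a single-channel 2-D image, got shape {img.shape}")
    if img.shape != (target, target):
        img = _sk_resize(img, (target, target), order=1, anti_aliasing=False,
                         preserve_range=True)
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.zeros((target, target), dtype=np.float32)
    return ((img - lo) / (hi - lo)).astype(np.float32)


def _read_matlab_string(arr: np.ndarray) -> str:
    # MATLAB v7.3 stores char arrays as uint16 code units
    return "".join(chr(int(c)) for c in np.asarray(arr).ravel())


def load_figshare(directory: str | Path, target: int = 256,
                  skip_bad: bool = False) -> DatasetManifest:
    """Load per-slice ``cjdata`` .mat files (HDF5 layout) from ``directory``.

    Labels 1/2/3 are mapped to class indices 0/1/2; images are preprocessed
    to ``target x target`` in [0,1].  Malformed files raise
    :class:`DataFormatError` unless ``skip_bad`` is set, in which case they
    are recorded in the manifest provenance and skipped.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.mat"))
    if not paths:
        raise DataFormatError(f"no .mat files in {directory}")
    records: list[ImageRecord] = []
    skipped: list[str] = []
    for path in paths:
        try:
            records.append(_load_cjdata(path, target))
        except DataFormatError as e:
            if not skip_bad:
                raise
            skipped.append(f"{path.name}: {e}")
    manifest = DatasetManifest(records=records, provenance={
        "source": str(directory), "format": "figshare-cjdata-mat",
        "target_size": target, "normalization": "per-image min-max",
        "interpolation": "bilinear", "skipped": skipped,
    })
    return manifest


def _load_cjdata(path: Path, target: int) -> ImageRecord:
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise DataFormatError(f"{path}: not an HDF5 file ({e})") from e
    with f:
        if "cjdata" not in f:
            raise DataFormatError(f"{path}: missing cjdata group")
        cj = f["cjdata"]
        for fld in ("image", "label", "PID"):
            if fld not in cj:
                raise DataFormatError(f"{path}: cjdata missing field '{fld}'")
        raw_label = int(np.asarray(cj["label"]).ravel()[0])
        if raw_label not in RAW_TO_CLASS:
            raise DataFormatError(f"{path}: label must be 1..3, got {raw_label}")
        image = np.asarray(cj["image"], dtype=np.float64)
        pid = _read_matlab_string(cj["PID"])
        # tumorBorder / tumorMask are parsed when present but unused here
    return ImageRecord(image=preprocess(image, target), label=RAW_TO_CLASS[raw_label],
                       patient_id=pid, source=str(path))


def load_image_dir(directory: str | Path, manifest_csv: str | Path,
                   target: int = 256) -> DatasetManifest:
    """Load grayscale images listed in a ``path,label,patient_id`` CSV."""
    directory = Path(directory)
    rows = list(csv.DictReader(open(manifest_csv, newline="")))
    required = {"path", "label", "patient_id"}
    if not rows or not required.issubset(rows[0].keys()):
        raise DataFormatError(f"manifest must have columns {sorted(required)}")
    seen: set[str] = set()
    records = []
    for i, row in enumerate(rows):
        rel = row["path"]
        if rel in seen:
            raise DataFormatError(f"row {i}: duplicate path {rel!r}")
        seen.add(rel)
        label = int(row["label"])
        if label not in (0, 1, 2):
            raise DataFormatError(f"row {i}: label must be 0..2, got {label}")
        path = directory / rel
        if not path.exists():
            raise DataFormatError(f"row {i}: missing file {path}")
        img = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
        records.append(ImageRecord(image=preprocess(img, target), label=label,
                                   patient_id=row["patient_id"], source=str(path)))
    return DatasetManifest(records=records, provenance={
        "source": str(directory), "format": "image-dir+csv",
        "target_size": target, "normalization": "per-image min-max",
        "interpolation": "bilinear",
    })


_MANIFEST_COLUMNS = ("path", "label", "patient_id", "split_tag")


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """CSV of record paths/labels/patient ids (images are not embedded)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_MANIFEST_COLUMNS)
        for r in manifest.records:
            w.writerow([r.source, r.label, r.patient_id, r.split_tag or ""])


def read_manifest(path: str | Path) -> list[dict]:
    """Rows of a manifest CSV; raises on schema mismatch."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(header) != _MANIFEST_COLUMNS:
            raise DataFormatError(
                f"manifest schema mismatch: expected columns {_MANIFEST_COLUMNS}")
        return [dict(zip(_MANIFEST_COLUMNS, row)) for row in reader]
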