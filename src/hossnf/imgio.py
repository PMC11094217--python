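"""Image and dataset-manifest I/O.

Grayscale cell images are plain 2-D uint8 numpy arrays (row-major, origin at
the top-left, 0-based coordinates).  Datasets are described by a CSV manifest
with the exact header ``image_path,class_label,split`` so that synthetic and
real data share one entry point.  The seven cervical cell classes follow the
standard Pap-smear scheme: three normal morphologies and four grades of
abnormality up to carcinoma in situ.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .exceptions import FormatError, InputError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical ordered class vocabulary (normal morphologies first, then
#: abnormal grades in increasing severity is NOT implied by this order; the
#: order mirrors the conventional dataset listing).
CLASS_NAMES: tuple[str, ...] = (
    "intermediate_squamous",
    "normal_columnar",
    "normal_squamous",
    "high_grade_dysplasia",
    "low_grade_dysplasia",
    "moderate_dysplasia",
    "carcinoma_in_situ",
)

#: Binary grouping used for normal-vs-abnormal reporting.
NORMAL_CLASSES: frozenset[str] = frozenset(CLASS_NAMES[:3])
ABNORMAL_CLASSES: frozenset[str] = frozenset(CLASS_NAMES[3:])

SPLITS: tuple[str, ...] = ("train", "test", "validation")
MANIFEST_COLUMNS: tuple[str, ...] = ("image_path", "class_label", "split")

# ITU-R 601 luminance weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

_SUPPORTED_SUFFIXES = {".png", ".bmp"}


def canonical_label(name: str) -> str:
    """Normalize a class-label spelling: lowercase, runs of spaces/underscores
    and hyphens collapse to single underscores."""
    return re.sub(r"[\s_\-]+", "_", name.strip().lower())


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def validate_gray(img: np.ndarray, min_size: int = 1) -> np.ndarray:
    """Check that ``img`` is a 2-D uint8 raster of at least ``min_size`` per side."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValidationError(f"expected uint8 intensities, got dtype {arr.dtype}")
    if min(arr.shape) < min_size:
        raise ValidationError(
            f"image of shape {arr.shape} smaller than required minimum {min_size}"
        )
    return arr


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance, rounded half-up to uint8."""
    lum = rgb[..., :3].astype(np.float64) @ _LUMA
    return np.floor(lum + 0.5).clip(0, 255).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG or BMP image as grayscale uint8.

    RGB(A) inputs are converted with fixed 0.299/0.587/0.114 luminance
    weights (rounded half-up); alpha is ignored.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise FormatError(f"unsupported image format {path.suffix!r} for {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:  # pragma: no cover - corrupt files
        raise FormatError(f"cannot decode image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = rgb_to_gray(arr)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return validate_gray(arr)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a 2-D uint8 array as a (lossless) PNG/BMP."""
    img = validate_gray(img)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img, mode="L").save(path)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """A validated list of (image_path, class_label, split) records.

    ``root`` is the directory relative image paths resolve against (set when
    loading from disk; None for in-memory manifests).
    """

    records: pd.DataFrame
    class_names: tuple[str, ...] = CLASS_NAMES
    root: Path | None = None

    def __post_init__(self) -> None:
        df = self.records
        if tuple(df.columns) != MANIFEST_COLUMNS:
            raise ValidationError(
                f"manifest columns must be {MANIFEST_COLUMNS}, got {tuple(df.columns)}"
            )
        if len(df) == 0:
            raise ValidationError("no records in manifest")
        bad_labels = df.loc[~df["class_label"].isin(self.class_names)]
        if len(bad_labels):
            rows = ", ".join(
                f"row {i}: {lab!r}" for i, lab in bad_labels["class_label"].items()
            )
            raise ValidationError(f"unknown class labels ({rows})")
        bad_splits = df.loc[~df["split"].isin(SPLITS)]
        if len(bad_splits):
            raise ValidationError(
                f"invalid split values: {sorted(bad_splits['split'].unique())}"
            )
        if df["image_path"].duplicated().any():
            dups = df.loc[df["image_path"].duplicated(), "image_path"].tolist()
            raise ValidationError(f"duplicate image paths: {dups}")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DatasetManifest):
            return NotImplemented
        return (
            self.class_names == other.class_names
            and self.records.reset_index(drop=True).equals(
                other.records.reset_index(drop=True)
            )
        )

    def subset(self, split: str) -> pd.DataFrame:
        return self.records.loc[self.records["split"] == split]

    def resolve(self, image_path: str) -> Path:
        p = Path(image_path)
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load and validate a CSV manifest (header ``image_path,class_label,split``)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"no records in manifest {path}") from exc
    if len(df) == 0:
        raise ValidationError(f"no records in manifest {path}")
    return DatasetManifest(records=df, root=path.parent)


def write_manifest(path: str | Path, manifest: DatasetManifest) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.records.to_csv(path, index=False)


def scan_class_directories(root: str | Path) -> DatasetManifest:
    """Adapt a class-per-directory image layout into a manifest.

    Directory names are matched case-insensitively against the canonical
    class vocabulary after whitespace/underscore normalization; unmatched
    directories are skipped with a warning.  All records get split ``train``.
    """
    root = Path(root)
    if not root.is_dir():
        raise InputError(f"dataset root is not a directory: {root}")
    rows: list[tuple[str, str, str]] = []
    for sub in sorted(root.iterdir()):
        if not sub.is_dir():
            continue
        label = canonical_label(sub.name)
        if label not in CLASS_NAMES:
            logger.warning("skipping non-class directory %s", sub)
            continue
        for img in sorted(sub.iterdir()):
            if img.suffix.lower() in _SUPPORTED_SUFFIXES:
                rows.append((str(img.relative_to(root)), label, "train"))
    if not rows:
        raise InputError(f"no recognized class directories under {root}")
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    return DatasetManifest(records=df, root=root)
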