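"""Data model and I/O for annotated 2D slices.

A dataset is a directory with grayscale slice images (PNG or TIFF, 8- or
16-bit, single channel), binary tumor masks (PNG, 0 = background, any
nonzero value = tumor) and a CSV manifest with one row per slice::

    image_path,mask_path,patient_id,label
    images/p000_s00.png,masks/p000_s00.png,p000,meningioma
    ...

Paths are resolved relative to the manifest's directory.  Class labels are
free-form strings; internally they are mapped to the sorted order of the
distinct labels, which keeps the label/index correspondence stable across
cross-validation folds.

Patient ids matter: the evaluation protocol groups slices by patient so
that no patient contributes to both a training and a test fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import (
    DuplicateRecordError,
    EmptyDatasetError,
    EmptyRoiError,
    FormatError,
    ShapeMismatchError,
)

MANIFEST_COLUMNS = ("image_path", "mask_path", "patient_id", "label")


@dataclass(frozen=True)
class SliceRecord:
    """One manifest row; paths are absolute after loading."""

    image_path: Path
    mask_path: Path
    patient_id: str
    label: str

    @property
    def slice_id(self) -> str:
        return self.image_path.stem


@dataclass
class AnnotatedSlice:
    """A grayscale slice with its binary tumor mask and metadata.

    ``image`` keeps the intensities exactly as read from disk (integer
    dtype for 8/16-bit files); ``mask`` is boolean with at least one true
    pixel and the same shape as ``image``.
    """

    image: np.ndarray
    mask: np.ndarray
    label: str
    patient_id: str
    slice_id: str

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ShapeMismatchError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        if not self.mask.any():
            raise EmptyRoiError(f"slice {self.slice_id!r}: mask has no foreground pixel")


@dataclass
class DatasetManifest:
    records: list[SliceRecord]
    classes: list[str]
    root: Path = field(default_factory=Path)

    def __len__(self) -> int:
        return len(self.records)

    def label_index(self, label: str) -> int:
        return self.classes.index(label)


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read a CSV manifest; records keep file order, classes are sorted.

    Raises :class:`FormatError` if a required column is missing,
    :class:`EmptyDatasetError` on an empty file and
    :class:`DuplicateRecordError` if two rows share (patient_id, slice_id).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyDatasetError(f"manifest {path} is empty") from None
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"manifest {path} is missing required column {col!r}")
    if len(df) == 0:
        raise EmptyDatasetError(f"manifest {path} has a header but no records")

    root = path.parent.resolve()
    records = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        rec = SliceRecord(
            image_path=(root / str(row.image_path)).resolve(),
            mask_path=(root / str(row.mask_path)).resolve(),
            patient_id=str(row.patient_id),
            label=str(row.label),
        )
        key = (rec.patient_id, rec.slice_id)
        if key in seen:
            raise DuplicateRecordError(f"duplicate record for patient/slice {key}")
        seen.add(key)
        for p in (rec.image_path, rec.mask_path):
            if not p.exists():
                raise FormatError(f"manifest references missing file {p}")
        records.append(rec)
    classes = sorted(df["label"].astype(str).unique())
    return DatasetManifest(records=records, classes=classes, root=root)


def _read_gray(path: Path) -> np.ndarray:
    """Read a single-channel 8/16-bit PNG or TIFF, preserving values."""
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            arr = np.asarray(im)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel 2D image, got shape {arr.shape}")
    return arr


def load_slice(record: SliceRecord) -> AnnotatedSlice:
    """Load one record; intensities kept lossless, mask binarized at > 0."""
    image = _read_gray(record.image_path)
    mask_raw = _read_gray(record.mask_path)
    if image.shape != mask_raw.shape:
        raise ShapeMismatchError(
            f"{record.image_path.name}: image shape {image.shape} "
            f"!= mask shape {mask_raw.shape}"
        )
    return AnnotatedSlice(
        image=image,
        mask=mask_raw > 0,
        label=record.label,
        patient_id=record.patient_id,
        slice_id=record.slice_id,
    )


def load_all(manifest: DatasetManifest) -> list[AnnotatedSlice]:
    """Load every record in manifest (file) order — deterministic by design."""
    return [load_slice(rec) for rec in manifest.records]


def save_image(path: Path, array: np.ndarray) -> None:
    """Write a 2D uint8/uint16 array as PNG or TIFF depending on suffix."""
    path = Path(path)
    if array.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"expected uint8/uint16 array, got {array.dtype}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, array)
    else:
        mode = "L" if array.dtype == np.uint8 else "I;16"
        Image.fromarray(array, mode=mode).save(path)


def save_feature_matrix(path: str | Path, X: np.ndarray, params: dict) -> None:
    """Serialize a feature matrix as .npz plus a JSON sidecar of parameters."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), X=X)
    path.with_suffix(".json").write_text(json.dumps(params, indent=2, sort_keys=True))


def load_feature_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    X = np.load(path.with_suffix(".npz"))["X"]
    params = json.loads(path.with_suffix(".json").read_text())
    return X, params
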