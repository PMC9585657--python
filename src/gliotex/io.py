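"""Volume, mask, manifest and feature-table I/O.

Conventions
-----------
Volumes are stored as 3D arrays indexed ``(slice, row, col)``: the first axis
is the axial slice axis, and all 2D texture operations act on the last two
axes. ``spacing_mm`` follows the same ``(z, y, x)`` order. NIfTI-1 files
written by this package keep that axis order, with voxel sizes carried in the
header zooms.

Feature tables are plain :class:`pandas.DataFrame` objects with the reserved
metadata columns ``patient_id``, ``label`` and (for slice-level tables)
``slice_index``; every other column is a feature. CSV round-trips preserve
values to at least 12 significant digits.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

SEQUENCE_TAGS = ("T1C", "T2")

#: columns that are metadata, not features, in a feature table
RESERVED_COLUMNS = ("patient_id", "slice_index", "label", "n_slices")


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Image intensities; axial slices along the first axis.
    spacing_mm : tuple of float
        Voxel size in mm, ``(z, y, x)`` order, all strictly positive.
    sequence_tag : str
        MR sequence identifier, ``"T1C"`` or ``"T2"``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    sequence_tag: str = "T1C"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.voxels.ndim}D")
        if min(self.voxels.shape) < 1:
            raise ValueError("degenerate volume grid")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"non-positive spacing {self.spacing_mm}")
        if self.sequence_tag not in SEQUENCE_TAGS:
            raise ValueError(
                f"unknown sequence tag {self.sequence_tag!r}; expected one of {SEQUENCE_TAGS}"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclasses.dataclass
class ROIMask:
    """Binary tumor mask aligned voxel-for-voxel with an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got {arr.ndim}D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask is not binary; values {uniq[:10]}")
        self.voxels = arr.astype(bool)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"non-positive spacing {self.spacing_mm}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def _affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    # diagonal affine carrying (z, y, x) voxel sizes on the array axes
    return np.diag(list(spacing_mm) + [1.0])


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1, spacing in the header zooms."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float64), _affine(volume.spacing_mm))
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, path)
    return path


def write_mask(mask: ROIMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing_mm))
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, path)
    return path


def read_volume(path: str | Path, sequence_tag: str = "T1C") -> ImageVolume:
    """Load a NIfTI-1 file as an :class:`ImageVolume`.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        For non-3D images or non-positive header spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(f"expected 3D volume, got {img.ndim}D: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing in header: {spacing}")
    return ImageVolume(np.asanyarray(img.dataobj, dtype=np.float64), spacing, sequence_tag)


def read_mask(path: str | Path) -> ROIMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(f"expected 3D mask, got {img.ndim}D: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ROIMask(np.asanyarray(img.dataobj), spacing)


def validate_pair(volume: ImageVolume, mask: ROIMask) -> tuple[ImageVolume, ROIMask]:
    """Check that a volume and its ROI mask share geometry and the mask is usable.

    Returns the pair unchanged when valid, otherwise raises ``ValueError``
    (shape or spacing mismatch, empty ROI).  Mask binarity is enforced by
    :class:`ROIMask` itself.
    """
    if volume.voxels.shape != mask.voxels.shape:
        raise ValueError(
            f"shape mismatch: volume {volume.voxels.shape} vs mask {mask.voxels.shape}"
        )
    if not np.allclose(volume.spacing_mm, mask.spacing_mm):
        raise ValueError(
            f"spacing mismatch: volume {volume.spacing_mm} vs mask {mask.spacing_mm}"
        )
    if mask.n_voxels == 0:
        raise ValueError("empty ROI")
    return volume, mask


MANIFEST_COLUMNS = ("patient_id", "path_t1c", "path_t2w", "path_mask", "label")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    manifest.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "label": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    if df["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in manifest")
    bad = set(df["label"]) - {"mutant", "wild"}
    if bad:
        raise ValueError(f"labels must be 'mutant'/'wild'; found {sorted(bad)}")
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature (non-metadata) columns, in table order."""
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a feature table as CSV, preserving ≥12 significant digits."""
    path = Path(path)
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicated feature names: {dupes}")
    if "label" not in table.columns:
        raise ValueError("feature table missing label column")
    table.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    # pandas silently renames duplicate headers, so check the raw header line
    with open(path) as fh:
        names = fh.readline().rstrip("\n").split(",")
    if len(names) != len(set(names)):
        raise ValueError("duplicated feature names in file")
    df = pd.read_csv(path, dtype={"patient_id": str, "label": str})
    if "label" not in df.columns:
        raise ValueError("feature table missing label column")
    return df
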