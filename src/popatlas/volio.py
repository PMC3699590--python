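"""Image containers, NIfTI/TSV I/O and brain masking.

Volumes and label maps are plain 3-D arrays on a regular grid.  All geometry
inside the package is expressed in 0-based voxel coordinates of the fixed
grid; millimetre spacing and origin are carried as metadata only and written
to the NIfTI header on output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

REGION_GROUPS = ("cortical", "white_matter", "deep_gray", "other")
HEMISPHERES = ("left", "right", "midline")

__all__ = [
    "Volume",
    "RegionTable",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "otsu_mask",
    "REGION_GROUPS",
    "HEMISPHERES",
]


@dataclass
class Volume:
    """A 3-D scalar image.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z)
        Voxel values; must be finite.
    spacing : tuple of float
        Voxel size along each axis in mm, strictly positive.
    origin : tuple of float
        Position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError("origin must have 3 components")

    @property
    def shape(self):
        return self.data.shape

    def like(self, data) -> "Volume":
        """A new Volume on this grid holding different voxel data."""
        return Volume(np.asarray(data), self.spacing, self.origin)


@dataclass
class RegionTable:
    """Catalogue of anatomical regions.

    Wraps a DataFrame with columns ``region_id`` (unique positive int; 0 is
    reserved for background and never listed), ``name``, ``group`` (one of
    cortical / white_matter / deep_gray / other) and ``hemisphere`` (left /
    right / midline).
    """

    table: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.table).copy()
        required = ["region_id", "name", "group", "hemisphere"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"region table missing columns: {missing}")
        df["region_id"] = df["region_id"].astype(int)
        if (df["region_id"] <= 0).any():
            raise ValueError("region_ids must be positive (0 is background)")
        if df["region_id"].duplicated().any():
            raise ValueError("region_ids must be unique")
        bad_group = set(df["group"]) - set(REGION_GROUPS)
        if bad_group:
            raise ValueError(f"unknown region groups: {sorted(bad_group)}")
        bad_hemi = set(df["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValueError(f"unknown hemispheres: {sorted(bad_hemi)}")
        self.table = df[required].reset_index(drop=True)

    @property
    def ids(self) -> np.ndarray:
        """Region ids in ascending order."""
        return np.sort(self.table["region_id"].to_numpy())

    def __len__(self):
        return len(self.table)

    def name_of(self, region_id: int) -> str:
        row = self.table[self.table["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"region id {region_id} not in table")
        return str(row["name"].iloc[0])

    @classmethod
    def from_rows(cls, rows) -> "RegionTable":
        """Build from an iterable of (region_id, name, group, hemisphere)."""
        df = pd.DataFrame(rows, columns=["region_id", "name", "group", "hemisphere"])
        return cls(df)

    @classmethod
    def from_tsv(cls, path) -> "RegionTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class LabelMap:
    """An integer parcellation of a 3-D grid plus its region catalogue."""

    labels: np.ndarray
    regions: RegionTable
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label map must be 3-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.array_equal(self.labels, np.round(self.labels)):
                self.labels = self.labels.astype(np.int32)
            else:
                raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        known = set(int(i) for i in self.regions.ids)
        unknown = present - known
        if unknown:
            raise ValueError(f"labels not in region table: {sorted(unknown)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.labels.shape

    def like(self, labels) -> "LabelMap":
        return LabelMap(np.asarray(labels), self.regions, self.spacing, self.origin)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(v: Volume, path) -> None:
    """Write a Volume as NIfTI-1, preserving the array dtype."""
    img = nib.Nifti1Image(np.asarray(v.data), _affine(v.spacing, v.origin))
    img.set_data_dtype(v.data.dtype)
    nib.save(img, str(path))


def read_volume(path) -> Volume:
    """Read a 3-D NIfTI-1 volume.

    Raises on missing files, non-3-D images and non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    aff = img.affine
    spacing = tuple(float(s) for s in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in aff[:3, 3])
    return Volume(data, spacing, origin)


def write_labelmap(lm: LabelMap, nii_path, tsv_path=None) -> None:
    """Write labels as integer NIfTI plus the region table as TSV."""
    labels = lm.labels
    if labels.dtype not in (np.int16, np.int32, np.int64, np.uint8, np.uint16):
        labels = labels.astype(np.int32)
    img = nib.Nifti1Image(labels, _affine(lm.spacing, lm.origin))
    img.set_data_dtype(labels.dtype)
    nib.save(img, str(nii_path))
    if tsv_path is not None:
        lm.regions.to_tsv(tsv_path)


def read_labelmap(nii_path, regions) -> LabelMap:
    """Read a label NIfTI; `regions` is a RegionTable or a TSV path."""
    if not isinstance(regions, RegionTable):
        regions = RegionTable.from_tsv(regions)
    v = read_volume(nii_path)
    if not np.issubdtype(v.data.dtype, np.integer) and not np.array_equal(
        v.data, np.round(v.data)
    ):
        raise ValueError(f"{nii_path}: label image has non-integer values")
    return LabelMap(v.data.astype(np.int32), regions, v.spacing, v.origin)


def otsu_mask(v: Volume, bins: int = 256, foreground: str = "ge"):
    """Otsu threshold and binary brain mask.

    The threshold maximizes the between-class variance of a `bins`-bin
    histogram over [min, max]; ties go to the lowest threshold.  The mask is
    ``data >= threshold`` by default (brain brighter than background);
    ``foreground="lt"`` inverts the polarity.

    Returns
    -------
    threshold : float
    mask : bool ndarray, nonempty
    """
    data = np.asarray(v.data, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise ValueError("constant image: no foreground/background separation")
    hist, edges = np.histogram(data.ravel(), bins=bins, range=(lo, hi))
    c = hist.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = c.sum()
    w0 = np.cumsum(c)[:-1]
    w1 = total - w0
    cm = np.cumsum(c * centers)[:-1]
    s_all = float((c * centers).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        m0 = np.where(w0 > 0, cm / w0, 0.0)
        m1 = np.where(w1 > 0, (s_all - cm) / w1, 0.0)
    sigma_b = np.where((w0 > 0) & (w1 > 0), w0 * w1 * (m0 - m1) ** 2, -np.inf)
    k = int(np.argmax(sigma_b))  # first maximum -> lowest threshold
    threshold = float(edges[k + 1])
    if foreground == "ge":
        mask = data >= threshold
    elif foreground == "lt":
        mask = data < threshold
    else:
        raise ValueError(f"unknown foreground polarity {foreground!r}")
    return threshold, mask
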