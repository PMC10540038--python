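"""Volumetric data model and I/O.

Images and masks are stored as 3D arrays with a NIfTI-style affine mapping
0-based voxel indices (voxel centers) to world coordinates in mm. All
mm-parameterized morphology elsewhere in the package converts mm to voxels
using the per-axis spacing derived from the affine, so anisotropic grids are
supported even though the study data are 1 mm isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import SchemaError, ShapeError

#: Canonical tissue label codes used by phantoms and the ROI builder.
TISSUE_CODES: dict[str, int] = {
    "background": 0,
    "white_matter": 1,
    "gray_matter": 2,
    "basal_ganglia": 3,
    "csf": 4,
    "ventricle": 5,
    "wmh": 6,
}


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


@dataclass
class Volume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data
        3D array of intensities; stored as float32.
    affine
        4x4 voxel-index -> world-mm transform. If None, built from `spacing`.
    spacing
        Per-axis voxel size in mm; ignored when `affine` is given.
    """

    data: np.ndarray
    affine: np.ndarray | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ShapeError(f"expected a 3D image, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ShapeError("each axis needs at least 1 voxel")
        if not np.all(np.isfinite(self.data)):
            raise ShapeError("image contains non-finite values")
        if self.affine is None:
            self.affine = _affine_from_spacing(tuple(self.spacing))
        else:
            self.affine = np.asarray(self.affine, dtype=float)
        self.spacing = _spacing_from_affine(self.affine)
        if min(self.spacing) <= 0:
            raise ShapeError(f"non-positive voxel spacing {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume | RoiMask | LabelVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing
        )


@dataclass
class RoiMask:
    """Binary mask on the same grid as its source volume."""

    data: np.ndarray
    affine: np.ndarray | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ShapeError(f"expected a 3D mask, got {arr.ndim}D")
        self.data = (arr != 0).astype(np.uint8)
        if self.affine is None:
            self.affine = _affine_from_spacing(tuple(self.spacing))
        else:
            self.affine = np.asarray(self.affine, dtype=float)
        self.spacing = _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing
        )


@dataclass
class LabelVolume:
    """Integer tissue codes plus a code -> name dictionary."""

    data: np.ndarray
    labels: Mapping[int, str] = field(
        default_factory=lambda: {v: k for k, v in TISSUE_CODES.items()}
    )
    affine: np.ndarray | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int16)
        if self.data.ndim != 3:
            raise ShapeError(f"expected a 3D label image, got {self.data.ndim}D")
        if self.affine is None:
            self.affine = _affine_from_spacing(tuple(self.spacing))
        else:
            self.affine = np.asarray(self.affine, dtype=float)
        self.spacing = _spacing_from_affine(self.affine)
        present = set(np.unique(self.data)) - {0}
        known = set(int(k) for k in self.labels)
        unknown = present - known
        if unknown:
            raise ShapeError(f"label codes {sorted(unknown)} missing from dictionary")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask_for(self, *names: str) -> RoiMask:
        """Binary mask of the union of the named tissue classes."""
        codes = [c for c, n in self.labels.items() if n in names]
        m = np.isin(self.data, codes)
        return RoiMask(m, affine=self.affine)

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI image as a Volume (spacing taken from the header)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D image, got shape {data.shape}")
    return Volume(data.astype(np.float32), affine=np.asarray(img.affine))


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a Volume as float32 NIfTI; round-trips bit-exactly."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> RoiMask:
    v = read_volume(path)
    return RoiMask(v.data != 0, affine=v.affine)


def write_mask(mask: RoiMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def read_labels(path: str | Path,
                labels: Mapping[int, str] | None = None) -> LabelVolume:
    v = read_volume(path)
    kwargs = {} if labels is None else {"labels": labels}
    return LabelVolume(np.rint(v.data).astype(np.int16), affine=v.affine, **kwargs)


def write_labels(lab: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(lab.data.astype(np.int16), lab.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

#: Columns every long-format cohort table must carry.
REQUIRED_COHORT_COLUMNS = (
    "participant", "site", "arm", "timepoint", "pvs_volume_fraction",
)


@dataclass
class CohortData:
    """A validated long-format cohort table plus its rejection report."""

    table: pd.DataFrame
    rejected: pd.DataFrame

    @property
    def n_records(self) -> int:
        return len(self.table)


def validate_cohort_table(df: pd.DataFrame) -> CohortData:
    """Validate a long-format cohort table.

    Rows with a missing required field or a non-numeric outcome are moved to
    the rejection report; a missing required *column* raises SchemaError.
    """
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing required column(s): {missing}")
    outcome = pd.to_numeric(df["pvs_volume_fraction"], errors="coerce")
    bad = outcome.isna()
    for col in ("participant", "site", "arm", "timepoint"):
        bad |= df[col].isna()
    good = df.loc[~bad].copy()
    good["pvs_volume_fraction"] = outcome[~bad].astype(float)
    return CohortData(table=good.reset_index(drop=True),
                      rejected=df.loc[bad].copy())


def read_cohort_table(path: str | Path) -> CohortData:
    """Read a cohort CSV and validate it (see :func:`validate_cohort_table`)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return validate_cohort_table(pd.read_csv(path))
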