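"""NIfTI and tabular I/O.

Volumes and masks travel as NIfTI-1 (via nibabel); cohort, motion and
regressor tables as delimited text with a header row.  Motion tables follow
the 3-rotations-then-3-translations column convention (degrees, mm).
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import BinaryMask, VolumeGrid, VolumeSeries

__all__ = [
    "read_volume_series",
    "write_volume_series",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_cohort_table",
    "write_cohort_table",
    "read_motion_table",
    "write_motion_table",
    "MOTION_COLUMNS",
]

MOTION_COLUMNS = ["rot_x_deg", "rot_y_deg", "rot_z_deg", "dx_mm", "dy_mm", "dz_mm"]

COHORT_COLUMNS = {"subject", "diagnosis", "sex", "age"}


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VolumeGrid(img.shape[:3], tuple(float(z) for z in zooms), origin)


def read_volume_series(path: str | os.PathLike) -> VolumeSeries:
    """Read a 4D NIfTI image; refuses 3D images."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D image, got {img.ndim}D: {path}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    return VolumeSeries(_grid_from_img(img), data)


def write_volume_series(series: VolumeSeries, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(series.values, np.float64), series.grid.affine())
    img.header.set_zooms(tuple(series.grid.voxel_size_mm) + (1.0,))
    nib.save(img, str(path))


def read_volume(path: str | os.PathLike) -> tuple[VolumeGrid, np.ndarray]:
    """Read a single 3D statistic/value volume."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D image, got {img.ndim}D: {path}")
    return _grid_from_img(img), np.asarray(img.dataobj, dtype=np.float64)


def write_volume(grid: VolumeGrid, values: np.ndarray, path: str | os.PathLike) -> None:
    values = np.asarray(values, np.float64)
    if values.shape != grid.dims:
        raise ValueError("volume shape does not match grid")
    nib.save(nib.Nifti1Image(values, grid.affine()), str(path))


def read_mask(path: str | os.PathLike, label: str = "region") -> BinaryMask:
    grid, values = read_volume(path)
    return BinaryMask(grid, values > 0.5, label=label)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    write_volume(mask.grid, mask.membership.astype(np.float64), path)


def read_cohort_table(path: str | os.PathLike) -> pd.DataFrame:
    """Cohort covariates: subject, diagnosis {ASD, TD}, sex {F, M}, age, ...

    Validates labels and subject-id uniqueness.  Extra columns (iq, motion,
    gcor) pass through untouched.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = COHORT_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if df["subject"].duplicated().any():
        raise ValueError("duplicate subject ids in cohort table")
    bad_dx = set(df["diagnosis"]) - {"ASD", "TD"}
    bad_sex = set(df["sex"]) - {"F", "M"}
    if bad_dx or bad_sex:
        raise ValueError(f"unknown labels: diagnosis={bad_dx}, sex={bad_sex}")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_motion_table(path: str | os.PathLike) -> np.ndarray:
    """Six-column motion table -> (n_volumes, 6) array."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got {df.shape[1]}")
    return df.to_numpy(np.float64)


def write_motion_table(motion: np.ndarray, path: str | os.PathLike) -> None:
    motion = np.asarray(motion, np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion array must be (n_volumes, 6)")
    pd.DataFrame(motion, columns=MOTION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
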