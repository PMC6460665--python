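"""Subject-level connectivity quantities.

Global connectedness maps (per-voxel mean correlation with all other
gray-matter voxels), GCOR, the mm/TR motion summary, Fisher-z, and
seed-to-voxel correlation maps.

The closed forms used here rest on unit-normalised time series: demean each
voxel's series and scale to unit L2 norm, so every pairwise Pearson r is an
inner product.  With ``S`` the sum of the N unit vectors,

* mean correlation of voxel v with the others = (x_v . S - 1) / (N - 1)
* GCOR (self-pairs included)                 = ||S||^2 / N^2

which match the O(N^2) pairwise definitions identically.
"""

from __future__ import annotations

import logging

import numpy as np

from .grids import BinaryMask, VolumeGrid, VolumeSeries

__all__ = [
    "fisher_z",
    "connectedness",
    "connectedness_values",
    "gcor",
    "gcor_value",
    "motion_summary",
    "seed_map",
    "unit_normalise_rows",
    "ConnectednessMap",
]

log = logging.getLogger(__name__)

# correlations are clipped here before arctanh so degenerate inputs
# (identical series) still yield finite z maps
R_CLIP = 1.0 - 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilising arctanh transform, clipped to +/-(1 - 1e-7)."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


class ConnectednessMap:
    """Fisher-z of per-voxel mean correlation, defined inside a gray mask."""

    def __init__(self, grid: VolumeGrid, mask: BinaryMask, values: np.ndarray):
        grid.require_compatible(mask.grid, "connectedness mask")
        self.grid = grid
        self.mask = mask
        self.values = np.asarray(values, np.float64)  # (n_mask_voxels,)

    def volume(self, fill: float = 0.0) -> np.ndarray:
        out = np.full(self.grid.dims, fill, np.float64)
        out[self.mask.membership] = self.values
        return out


def _masked_unit_series(series: VolumeSeries, mask: BinaryMask):
    """(n_vox, T) unit-normalised series; drops zero-variance voxels (logged)."""
    series.grid.require_compatible(mask.grid, "series mask")
    return unit_normalise_rows(series.values[mask.membership])


def unit_normalise_rows(data: np.ndarray):
    """Demean and L2-normalise each row of an (n, T) matrix.

    Returns (unit, keep): unit has the zero-variance rows removed and
    ``keep`` flags the surviving rows.
    """
    data = np.asarray(data, np.float64)
    data = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(data, axis=1)
    keep = norms > 0
    if not keep.all():
        log.warning("dropping %d zero-variance rows", int((~keep).sum()))
    if not keep.any():
        raise ValueError("all series are constant")
    return data[keep] / norms[keep, None], keep


def connectedness_values(data: np.ndarray) -> np.ndarray:
    """Fisher-z mean-correlation per row of an (n, T) matrix (self excluded).

    Zero-variance rows get value 0.
    """
    unit, keep = unit_normalise_rows(data)
    n = unit.shape[0]
    if n < 2:
        raise ValueError("fewer than 2 non-constant series")
    s = unit.sum(axis=0)
    mean_r = (unit @ s - 1.0) / (n - 1)
    values = np.zeros(len(keep))
    values[keep] = fisher_z(mean_r)
    return values


def gcor_value(data: np.ndarray) -> float:
    """GCOR of an (n, T) matrix: squared norm of the mean unit series."""
    unit, _ = unit_normalise_rows(data)
    mean_vec = unit.mean(axis=0)
    return float(mean_vec @ mean_vec)


def connectedness(series: VolumeSeries, gray_mask: BinaryMask) -> ConnectednessMap:
    """Fisher-z of each voxel's mean Pearson r with the rest of the gray mask.

    Self-correlation is excluded; the Fisher transform is applied to the mean
    r (map-level transform).
    """
    if gray_mask.n_voxels < 2:
        raise ValueError("connectedness needs at least 2 mask voxels")
    series.grid.require_compatible(gray_mask.grid, "series mask")
    values = connectedness_values(series.values[gray_mask.membership])
    return ConnectednessMap(series.grid, gray_mask, values)


def connectedness_values_z_first(data: np.ndarray) -> np.ndarray:
    """Alternative reading: Fisher-z each r, then average (config flag).

    O(n^2) — intended for modest masks / validation use.
    """
    unit, keep = unit_normalise_rows(data)
    n = unit.shape[0]
    if n < 2:
        raise ValueError("fewer than 2 non-constant series")
    r = np.clip(unit @ unit.T, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    values = np.zeros(len(keep))
    values[keep] = z.sum(axis=1) / (n - 1)
    return values


def connectedness_z_first(series: VolumeSeries, gray_mask: BinaryMask) -> ConnectednessMap:
    """Alternative reading: Fisher-z each r, then average (config flag)."""
    series.grid.require_compatible(gray_mask.grid, "series mask")
    values = connectedness_values_z_first(series.values[gray_mask.membership])
    return ConnectednessMap(series.grid, gray_mask, values)


def gcor(series: VolumeSeries, gray_mask: BinaryMask) -> float:
    """Global correlation: mean of all N^2 pairwise r, self-pairs included.

    Computed as the squared norm of the mean unit-normalised series, hence
    always >= 0 and identical to the raw pairwise mean.
    """
    series.grid.require_compatible(gray_mask.grid, "series mask")
    return gcor_value(series.values[gray_mask.membership])


def motion_summary(motion_table: np.ndarray, rotation_radius_mm: float = 50.0) -> float:
    """Mean frame-to-frame displacement in mm/TR from a six-parameter table.

    Columns: three rotations (degrees) then three translations (mm).
    Rotations are converted to arc length on a sphere of
    ``rotation_radius_mm`` before taking the Euclidean norm of the
    six-parameter first difference.
    """
    motion = np.asarray(motion_table, np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion table must be (n, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("motion table needs at least 2 rows")
    diffs = np.diff(motion, axis=0)
    diffs[:, :3] *= np.pi / 180.0 * rotation_radius_mm
    return float(np.linalg.norm(diffs, axis=1).mean())


def seed_map(
    residuals: VolumeSeries, seed: BinaryMask, target_mask: BinaryMask
) -> ConnectednessMap:
    """Fisher-z correlation of the seed-mean series with every target voxel."""
    residuals.grid.require_compatible(seed.grid, "seed mask")
    if seed.n_voxels == 0:
        raise ValueError("empty seed mask")
    seed_series = residuals.values[seed.membership].mean(axis=0)
    seed_series = seed_series - seed_series.mean()
    nrm = np.linalg.norm(seed_series)
    if nrm == 0:
        raise ValueError("seed mean series is constant")
    seed_series /= nrm
    unit, keep = _masked_unit_series(residuals, target_mask)
    values = np.zeros(target_mask.n_voxels)
    values[keep] = fisher_z(unit @ seed_series)
    return ConnectednessMap(residuals.grid, target_mask, values)
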