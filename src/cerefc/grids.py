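"""Core volumetric containers: grids, 4D series, and binary masks.

All voxel indices are 0-based.  Distances are always measured between voxel
*centers* in millimetres, using the grid's voxel size; nothing in the package
depends on an atlas space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeGrid", "VolumeSeries", "BinaryMask", "MASK_LABELS"]

MASK_LABELS = ("gray", "white", "ventricle", "coverage", "cerebellum", "region")


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel grid: dimensions, voxel size (mm) and world origin (mm).

    Two grids are *compatible* (images can be combined voxel-wise) iff their
    dims and voxel sizes match; the origin is metadata only.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        vox = tuple(float(v) for v in self.voxel_size_mm)
        org = tuple(float(v) for v in self.origin_mm)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"grid dims must be three integers >= 1, got {dims}")
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise ValueError(f"voxel sizes must be positive, got {vox}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size_mm", vox)
        object.__setattr__(self, "origin_mm", org)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def compatible(self, other: "VolumeGrid") -> bool:
        return self.dims == other.dims and np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        )

    def require_compatible(self, other: "VolumeGrid", what: str = "image") -> None:
        if not self.compatible(other):
            raise ValueError(
                f"grid mismatch for {what}: {self.dims}@{self.voxel_size_mm} vs "
                f"{other.dims}@{other.voxel_size_mm}"
            )

    def affine(self) -> np.ndarray:
        """Diagonal NIfTI affine mapping voxel indices to mm coordinates."""
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def contains_voxel(self, ijk) -> bool:
        i, j, k = (int(x) for x in ijk)
        return all(0 <= x < d for x, d in zip((i, j, k), self.dims))

    def voxel_center_mm(self, ijk) -> np.ndarray:
        return np.asarray(self.origin_mm) + np.asarray(ijk, float) * np.asarray(
            self.voxel_size_mm
        )


@dataclass
class VolumeSeries:
    """One subject's 4D BOLD data: ``values[x, y, z, t]`` on a shared grid."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise ValueError(f"expected 4D array, got ndim={self.values.ndim}")
        if self.values.shape[:3] != self.grid.dims:
            raise ValueError(
                f"data shape {self.values.shape[:3]} does not match grid "
                f"{self.grid.dims}"
            )
        if self.values.shape[3] < 2:
            raise ValueError("a volume series needs at least 2 time points")

    @property
    def n_volumes(self) -> int:
        return int(self.values.shape[3])

    def copy(self) -> "VolumeSeries":
        return VolumeSeries(self.grid, self.values.copy())


@dataclass
class BinaryMask:
    """A boolean voxel-membership volume with a tissue/usage label."""

    grid: VolumeGrid
    membership: np.ndarray
    label: str = "region"

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, bool)
        if self.membership.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.membership.shape} does not match grid "
                f"{self.grid.dims}"
            )
        if self.label not in MASK_LABELS:
            raise ValueError(f"unknown mask label {self.label!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) integer voxel indices of member voxels, in C order."""
        return np.argwhere(self.membership)

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_compatible(other.grid, "mask intersection")
        return BinaryMask(self.grid, self.membership & other.membership, self.label)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_compatible(other.grid, "mask union")
        return BinaryMask(self.grid, self.membership | other.membership, self.label)
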