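"""Mask construction: group-coverage masks, erosion, and sphere ROIs."""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, VolumeGrid

__all__ = ["build_coverage_mask", "erode_mask", "sphere_mask", "sphere_offsets"]

log = logging.getLogger(__name__)

# 6-connectivity (face neighbours only): the most conservative single-voxel
# erosion / cluster-labelling structure.
FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def build_coverage_mask(
    subject_masks: Sequence[BinaryMask], fraction: float = 0.85
) -> BinaryMask:
    """Voxels covered by at least ``fraction`` of subjects (inclusive bound).

    A voxel enters the analysis domain iff the share of subjects whose
    individual coverage mask contains it is >= ``fraction``.
    """
    if not subject_masks:
        raise ValueError("empty subject mask list")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    grid = subject_masks[0].grid
    counts = np.zeros(grid.dims, dtype=np.int64)
    for m in subject_masks:
        grid.require_compatible(m.grid, "coverage mask")
        counts += m.membership
    n = len(subject_masks)
    # small tolerance so 17/20 >= 0.85 holds despite binary floating point
    member = counts >= fraction * n - 1e-9
    return BinaryMask(grid, member, label="coverage")


def erode_mask(mask: BinaryMask, iterations: int = 1) -> BinaryMask:
    """Erode with 6-connectivity; voxels at the volume border erode away."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return BinaryMask(mask.grid, mask.membership.copy(), mask.label)
    out = ndimage.binary_erosion(
        mask.membership, structure=FACE_STRUCTURE, iterations=iterations,
        border_value=0,
    )
    if not out.any():
        log.warning("erosion produced an empty %s mask", mask.label)
    return BinaryMask(mask.grid, out, mask.label)


def sphere_offsets(voxel_size_mm, radius_mm: float) -> np.ndarray:
    """Integer voxel offsets whose center-to-center distance is <= radius_mm."""
    vox = np.asarray(voxel_size_mm, float)
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    reach = np.floor(radius_mm / vox).astype(int)
    ax = [np.arange(-r, r + 1) for r in reach]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    offs = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    d = np.linalg.norm(offs * vox, axis=1)
    return offs[d <= radius_mm + 1e-9]


def sphere_mask(
    grid: VolumeGrid, center_voxel, radius_mm: float, label: str = "region"
) -> BinaryMask:
    """Sphere ROI: voxels whose centers lie within radius_mm of the center voxel.

    Spheres whose extent crosses the grid boundary are clipped (logged).
    """
    center = tuple(int(c) for c in center_voxel)
    if not grid.contains_voxel(center):
        raise ValueError(f"center voxel {center} outside grid {grid.dims}")
    offs = sphere_offsets(grid.voxel_size_mm, radius_mm)
    pts = offs + np.asarray(center)
    inside = np.all((pts >= 0) & (pts < np.asarray(grid.dims)), axis=1)
    if not inside.all():
        log.info(
            "sphere at %s r=%gmm clipped to grid (%d of %d voxels kept)",
            center, radius_mm, int(inside.sum()), len(pts),
        )
    pts = pts[inside]
    member = np.zeros(grid.dims, bool)
    member[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    return BinaryMask(grid, member, label=label)
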