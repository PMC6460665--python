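"""Localized nuisance regression for resting-state BOLD.

The nuisance model removed from each gray-matter voxel follows the
anatomy-informed scheme: one *localized* white-matter average (mean over
eroded-WM voxels within a 15 mm sphere of the target voxel), one average
ventricle series, six motion parameters, any externally supplied
physiological regressor columns, and a 4th-order polynomial baseline.
Nuisance columns are themselves detrended against the polynomial baseline
before fitting; residuals are exactly orthogonal to every retained column.

Percent-signal-change scaling (x / temporal mean * 100) is applied before
regression; voxels with near-zero mean signal are dropped from the mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy import sparse
from scipy.spatial import cKDTree

from .grids import BinaryMask, VolumeSeries

__all__ = [
    "NuisanceDesign",
    "percent_signal_change",
    "detrend_polynomial",
    "local_wm_regressor",
    "LocalWMOperator",
    "regress_nuisance",
    "regress_nuisance_matrix",
]

log = logging.getLogger(__name__)


def legendre_basis(n_volumes: int, order: int) -> np.ndarray:
    """(T, order+1) Legendre polynomial baseline on [-1, 1]."""
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    t = np.linspace(-1.0, 1.0, n_volumes)
    return np.stack(
        [legendre.legval(t, [0] * k + [1]) for k in range(order + 1)], axis=1
    )


def percent_signal_change(
    series: VolumeSeries, mask: BinaryMask, min_mean: float = 1e-6
) -> tuple[VolumeSeries, BinaryMask]:
    """Scale each in-mask voxel to percent of its temporal mean.

    Returns the scaled series (zero outside the mask) and the mask with
    near-zero-mean voxels removed.
    """
    series.grid.require_compatible(mask.grid, "psc mask")
    data = series.values
    means = data.mean(axis=3)
    ok = mask.membership & (np.abs(means) > min_mean)
    dropped = mask.n_voxels - int(ok.sum())
    if dropped:
        log.warning("percent_signal_change: dropped %d near-zero-mean voxels", dropped)
    out = np.zeros_like(data, dtype=np.float64)
    out[ok] = data[ok] / means[ok, None] * 100.0
    return VolumeSeries(series.grid, out), BinaryMask(mask.grid, ok, mask.label)


def detrend_polynomial(series: np.ndarray, order: int) -> np.ndarray:
    """Least-squares removal of a polynomial baseline up to ``order``.

    Works on a single series (T,) or a stack (n, T); the residual is
    orthogonal to every polynomial column and has zero mean.
    """
    arr = np.atleast_2d(np.asarray(series, np.float64))
    n_vol = arr.shape[1]
    if n_vol <= order + 1:
        raise ValueError(
            f"series length {n_vol} too short for polynomial order {order}"
        )
    basis = legendre_basis(n_vol, order)
    q, _ = np.linalg.qr(basis)
    resid = arr - (arr @ q) @ q.T
    return resid[0] if np.asarray(series).ndim == 1 else resid


def local_wm_regressor(
    series: VolumeSeries,
    wm_mask_eroded: BinaryMask,
    voxel,
    radius_mm: float = 15.0,
) -> np.ndarray:
    """Localized WM average for one voxel: mean series over eroded-WM voxels
    whose centers lie within ``radius_mm``; falls back to the global WM mean
    when the sphere contains none (logged)."""
    if wm_mask_eroded.n_voxels == 0:
        raise ValueError("empty white-matter mask")
    series.grid.require_compatible(wm_mask_eroded.grid, "WM mask")
    vox = np.asarray(series.grid.voxel_size_mm)
    wm_idx = wm_mask_eroded.indices()
    d = np.linalg.norm((wm_idx - np.asarray(voxel, float)) * vox, axis=1)
    sel = d <= radius_mm + 1e-9
    if not sel.any():
        log.info("no WM voxels within %g mm of %s; using global WM mean",
                 radius_mm, tuple(voxel))
        sel = slice(None)
    chosen = wm_idx[sel] if not isinstance(sel, slice) else wm_idx
    return series.values[chosen[:, 0], chosen[:, 1], chosen[:, 2]].mean(axis=0)


class LocalWMOperator:
    """Sparse averaging operator mapping WM voxel series to per-gray-voxel
    localized WM regressors; build once per mask geometry, apply per subject."""

    def __init__(
        self,
        gray_mask: BinaryMask,
        wm_mask_eroded: BinaryMask,
        radius_mm: float = 15.0,
    ):
        if wm_mask_eroded.n_voxels == 0:
            raise ValueError("empty white-matter mask")
        gray_mask.grid.require_compatible(wm_mask_eroded.grid, "WM mask")
        vox = np.asarray(gray_mask.grid.voxel_size_mm)
        self.gray_mask = gray_mask
        self.wm_mask = wm_mask_eroded
        gray_idx = gray_mask.indices()
        wm_idx = wm_mask_eroded.indices()
        tree = cKDTree(wm_idx * vox)
        neighbours = tree.query_ball_point(gray_idx * vox, r=radius_mm + 1e-9)
        rows, cols, vals = [], [], []
        n_fallback = 0
        for i, nbrs in enumerate(neighbours):
            if nbrs:
                w = 1.0 / len(nbrs)
                rows.extend([i] * len(nbrs))
                cols.extend(nbrs)
                vals.extend([w] * len(nbrs))
            else:  # global WM mean fallback
                n_fallback += 1
                w = 1.0 / len(wm_idx)
                rows.extend([i] * len(wm_idx))
                cols.extend(range(len(wm_idx)))
                vals.extend([w] * len(wm_idx))
        if n_fallback:
            log.info("LocalWMOperator: %d gray voxels fell back to global WM mean",
                     n_fallback)
        self.weights = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(gray_idx), len(wm_idx))
        )

    def apply(self, series: VolumeSeries) -> np.ndarray:
        """(n_gray, T) localized WM regressors for one subject."""
        return self.apply_matrix(series.values[self.wm_mask.membership])

    def apply_matrix(self, wm_rows: np.ndarray) -> np.ndarray:
        """Same, from the (n_wm, T) matrix of eroded-WM voxel series."""
        return self.weights @ np.asarray(wm_rows, np.float64)


@dataclass
class NuisanceDesign:
    """Per-subject nuisance regressors.

    local_wm : (n_gray_voxels, T) voxel-specific localized WM series, or a
        single (T,) series applied to every voxel.
    """

    ventricle_series: np.ndarray
    motion_series: np.ndarray  # (T, 6)
    local_wm: np.ndarray | None = None
    physio_series: np.ndarray | None = None  # (T, k)
    polynomial_order: int = 4

    def n_volumes(self) -> int:
        return len(np.asarray(self.ventricle_series))


def _shared_design_basis(design: NuisanceDesign) -> np.ndarray:
    """Orthonormal basis (T, p) of the voxel-independent design columns."""
    t_len = design.n_volumes()
    polys = legendre_basis(t_len, design.polynomial_order)
    cols = [polys]
    others = [np.asarray(design.ventricle_series, np.float64).reshape(t_len, 1),
              np.asarray(design.motion_series, np.float64).reshape(t_len, -1)]
    if design.physio_series is not None:
        others.append(np.asarray(design.physio_series, np.float64).reshape(t_len, -1))
    if others[1].shape[1] != 6:
        raise ValueError("motion_series must have 6 columns")
    # nuisance columns are detrended against the polynomial baseline first
    qp, _ = np.linalg.qr(polys)
    for block in others:
        cols.append(block - qp @ (qp.T @ block))
    x = np.concatenate(cols, axis=1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s.max() * max(x.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if rank < x.shape[1]:
        log.warning("nuisance design rank-deficient: dropped %d of %d columns",
                    x.shape[1] - rank, x.shape[1])
    if rank == 0:
        raise ValueError("nuisance design has rank 0")
    return u[:, :rank]


def regress_nuisance_matrix(y: np.ndarray, design: NuisanceDesign) -> np.ndarray:
    """Residualise an (n_voxels, T) matrix against the full nuisance model.

    The shared columns (baseline, motion, ventricle, physio) are projected
    out first; each voxel's localized WM regressor is then removed by exact
    Gram-Schmidt, so residuals are orthogonal to all of its design columns.
    """
    y = np.asarray(y, np.float64)
    t_len = y.shape[1]
    if design.n_volumes() != t_len:
        raise ValueError("design length does not match series")
    q0 = _shared_design_basis(design)
    resid = y - (y @ q0) @ q0.T
    if design.local_wm is not None:
        w = np.asarray(design.local_wm, np.float64)
        if w.ndim == 1:
            w = np.broadcast_to(w, y.shape)
        elif w.shape != y.shape:
            raise ValueError("local_wm shape must match (n_gray_voxels, T)")
        w1 = w - (w @ q0) @ q0.T
        norms = np.einsum("ij,ij->i", w1, w1)
        coef = np.where(norms > 0, np.einsum("ij,ij->i", resid, w1) /
                        np.where(norms > 0, norms, 1.0), 0.0)
        resid = resid - coef[:, None] * w1
    return resid


def regress_nuisance(
    series: VolumeSeries, design: NuisanceDesign, gray_mask: BinaryMask
) -> VolumeSeries:
    """Residualise every gray voxel; see :func:`regress_nuisance_matrix`.

    Returns a 4D series that is zero outside the gray mask.
    """
    series.grid.require_compatible(gray_mask.grid, "gray mask")
    resid = regress_nuisance_matrix(series.values[gray_mask.membership], design)
    out = np.zeros(series.values.shape, dtype=np.float64)
    out[gray_mask.membership] = resid
    return VolumeSeries(series.grid, out)
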