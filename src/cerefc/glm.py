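"""Group-level 2x2 diagnosis-by-sex models with covariates.

With exactly one observation per subject and no within-subject factors the
mixed-effects formulation collapses to ordinary least squares, so the
interaction model is fit by OLS throughout:

    y = b0 + b1*dx + b2*sex + b3*dx*sex + b4*age + b5*motion + b6*gcor + e

with effect coding dx, sex in {-1/2 (TD / F), +1/2 (ASD / M)}.  Under this
coding b3 equals the difference of differences
(ASD_M - TD_M) - (ASD_F - TD_F) directly.  Covariates are mean-centered;
the interaction estimate is invariant to the centering shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import BinaryMask, VolumeGrid

__all__ = [
    "GroupDesign",
    "StatMap",
    "ols_contrast",
    "fit_interaction",
    "within_sex_contrast",
    "match_groups",
]

COVARIATES = ("age", "motion", "gcor")


@dataclass
class GroupDesign:
    """Between-subject design built from a cohort table."""

    subjects: np.ndarray           # subject ids, aligned with rows
    dx: np.ndarray                 # +1/2 ASD, -1/2 TD
    sex: np.ndarray                # +1/2 M, -1/2 F
    covariates: np.ndarray         # (n, k) mean-centered

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame,
                    covariates: tuple[str, ...] = COVARIATES) -> "GroupDesign":
        for cell_dx in ("ASD", "TD"):
            for cell_sex in ("F", "M"):
                n_cell = ((cohort["diagnosis"] == cell_dx)
                          & (cohort["sex"] == cell_sex)).sum()
                if n_cell < 2:
                    raise ValueError(
                        f"cell {cell_dx}/{cell_sex} has {n_cell} subjects (< 2)"
                    )
        dx = np.where(cohort["diagnosis"].to_numpy() == "ASD", 0.5, -0.5)
        sex = np.where(cohort["sex"].to_numpy() == "M", 0.5, -0.5)
        cov = cohort.loc[:, list(covariates)].to_numpy(np.float64)
        cov = cov - cov.mean(axis=0, keepdims=True)
        # constant covariates carry no information and would make the
        # centered design rank-deficient
        cov = cov[:, cov.std(axis=0) > 0]
        return cls(cohort["subject"].to_numpy(), dx, sex, cov)

    def interaction_matrix(self) -> np.ndarray:
        """[1, dx, sex, dx*sex, covariates...]; interaction is column 3."""
        n = len(self.dx)
        return np.column_stack(
            [np.ones(n), self.dx, self.sex, self.dx * self.sex, self.covariates]
        )

    def cells(self) -> dict[str, np.ndarray]:
        """Boolean row masks of the four diagnosis-by-sex cells."""
        return {
            "ASD_F": (self.dx > 0) & (self.sex < 0),
            "ASD_M": (self.dx > 0) & (self.sex > 0),
            "TD_F": (self.dx < 0) & (self.sex < 0),
            "TD_M": (self.dx < 0) & (self.sex > 0),
        }


@dataclass
class StatMap:
    """Per-unit (voxel or region-pair) statistics from a group model."""

    estimate: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    residuals: np.ndarray | None = None        # (n_subjects, n_units)
    grid: VolumeGrid | None = None
    mask: BinaryMask | None = None

    def t_volume(self, fill: float = 0.0) -> np.ndarray:
        if self.grid is None or self.mask is None:
            raise ValueError("StatMap has no grid/mask attached")
        out = np.full(self.grid.dims, fill, np.float64)
        out[self.mask.membership] = self.t
        return out

    def p_volume(self, fill: float = 1.0) -> np.ndarray:
        if self.grid is None or self.mask is None:
            raise ValueError("StatMap has no grid/mask attached")
        out = np.full(self.grid.dims, fill, np.float64)
        out[self.mask.membership] = self.p
        return out


def ols_contrast(y: np.ndarray, x: np.ndarray, contrast: np.ndarray,
                 keep_residuals: bool = False) -> StatMap:
    """Vectorised OLS of many units at once; t and two-sided p for c'beta.

    y : (n, n_units) one column per unit;  x : (n, p);  contrast : (p,).
    """
    y = np.atleast_2d(np.asarray(y, np.float64))
    if y.shape[0] != x.shape[0]:
        y = y.T
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise ValueError(f"design matrix rank-deficient ({rank} < {p})")
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)              # (p, units)
    resid = y - x @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    # residual variance at rounding level relative to the data is zero
    scale = np.einsum("ij,ij->j", y, y) / n
    sigma2 = np.where(sigma2 <= 1e-20 * np.maximum(scale, 1e-300), 0.0, sigma2)
    cvar = float(contrast @ xtx_inv @ contrast)
    est = contrast @ beta
    se = np.sqrt(np.maximum(sigma2 * cvar, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.where(se > 0, pvals, 1.0)  # zero-variance units: no evidence
    return StatMap(est, t, np.clip(pvals, np.finfo(float).tiny, 1.0), df,
                   residuals=resid if keep_residuals else None)


def fit_interaction(values: np.ndarray, design: GroupDesign,
                    grid: VolumeGrid | None = None,
                    mask: BinaryMask | None = None,
                    keep_residuals: bool = False) -> StatMap:
    """Diagnosis-by-sex interaction test per unit.

    ``values`` holds one between-subject observation per subject per unit,
    shape (n_subjects, n_units).
    """
    x = design.interaction_matrix()
    contrast = np.zeros(x.shape[1])
    contrast[3] = 1.0
    sm = ols_contrast(values, x, contrast, keep_residuals=keep_residuals)
    sm.grid, sm.mask = grid, mask
    return sm


def within_sex_contrast(values: np.ndarray, design: GroupDesign,
                        sex: str) -> StatMap:
    """Covariate-adjusted ASD-TD effect within one sex ('F' or 'M')."""
    if sex not in ("F", "M"):
        raise ValueError("sex must be 'F' or 'M'")
    rows = design.sex > 0 if sex == "M" else design.sex < 0
    if not ((design.dx[rows] > 0).sum() >= 2 and (design.dx[rows] < 0).sum() >= 2):
        raise ValueError(f"both diagnosis groups need >= 2 subjects within sex {sex}")
    values = np.atleast_2d(np.asarray(values, np.float64))
    if values.shape[0] != len(design.dx):
        values = values.T
    cov = design.covariates[rows]
    cov = cov - cov.mean(axis=0, keepdims=True)
    x = np.column_stack([np.ones(rows.sum()), design.dx[rows], cov])
    contrast = np.zeros(x.shape[1])
    contrast[1] = 1.0
    return ols_contrast(values[rows], x, contrast)


def match_groups(cohort: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Kruskal-Wallis matching check across the four diagnosis-by-sex cells.

    Variables present in only two cells (e.g. ASD-only instruments) are
    compared with the exact Wilcoxon rank-sum test instead.  All-tied
    variables get H = 0, p = 1 with a warning.
    """
    import logging

    log = logging.getLogger(__name__)
    cells = [
        cohort[(cohort["diagnosis"] == dxv) & (cohort["sex"] == sexv)]
        for dxv in ("ASD", "TD") for sexv in ("F", "M")
    ]
    rows = []
    for var in variables:
        groups = [c[var].dropna().to_numpy(np.float64) for c in cells]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            raise ValueError(f"variable {var!r} present in fewer than 2 groups")
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            log.warning("match_groups: %r is constant; H undefined, p = 1", var)
            rows.append({"variable": var, "statistic": 0.0, "p": 1.0,
                         "test": "kruskal-wallis"})
            continue
        if len(groups) == 2:
            stat, p = stats.mannwhitneyu(groups[0], groups[1],
                                         alternative="two-sided",
                                         method="exact" if
                                         max(map(len, groups)) <= 25 else "auto")
            rows.append({"variable": var, "statistic": float(stat), "p": float(p),
                         "test": "wilcoxon-rank-sum"})
        else:
            h, p = stats.kruskal(*groups)
            rows.append({"variable": var, "statistic": float(h), "p": float(p),
                         "test": "kruskal-wallis"})
    return pd.DataFrame(rows)
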