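"""Region-to-region connectivity matrices and per-pair interaction tests.

Average residual time series are extracted for each analysis region (13
cortical regions plus the 2 cerebellar seeds by default), correlated
pairwise and Fisher-z transformed.  The diagnosis-by-sex interaction model
is fit to every unordered region pair, Benjamini-Hochberg corrected over
all C(K, 2) pairs; ASD-TD contrasts within each sex are then evaluated only
inside the surviving pair set, with a second BH pass restricted to that
set.  Realized p-thresholds are reported alongside q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .connectivity import fisher_z
from .glm import GroupDesign, fit_interaction, within_sex_contrast
from .grids import BinaryMask, VolumeSeries

__all__ = [
    "RegionSet",
    "extract_region_series",
    "fc_matrix",
    "pair_index",
    "pairwise_interaction_fdr",
    "restricted_within_sex",
]


@dataclass
class RegionSet:
    """Ordered analysis regions: (region id, mask) with unique ids."""

    ids: list[str]
    masks: list[BinaryMask]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.masks):
            raise ValueError("ids and masks must align")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("region ids must be unique")
        for rid, m in zip(self.ids, self.masks):
            if m.n_voxels == 0:
                raise ValueError(f"region {rid!r} has an empty mask")

    def __len__(self) -> int:
        return len(self.ids)


def pair_index(ids: list[str]) -> list[tuple[str, str]]:
    """Upper-triangle pair ordering used everywhere pairs are vectorised."""
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def extract_region_series(residuals: VolumeSeries, regions: RegionSet) -> np.ndarray:
    """(K, T) mean residual series per region."""
    out = np.empty((len(regions), residuals.n_volumes))
    for k, (rid, mask) in enumerate(zip(regions.ids, regions.masks)):
        residuals.grid.require_compatible(mask.grid, f"region {rid}")
        out[k] = residuals.values[mask.membership].mean(axis=0)
    return out


def fc_matrix(region_series: np.ndarray) -> np.ndarray:
    """Symmetric Fisher-z correlation matrix; the diagonal is NaN (excluded)."""
    series = np.asarray(region_series, np.float64)
    if series.ndim != 2 or series.shape[0] < 2:
        raise ValueError("need a (K >= 2, T) array of region series")
    if (series.std(axis=1) == 0).any():
        raise ValueError("constant region series")
    r = np.corrcoef(series)
    r = (r + r.T) / 2.0  # corrcoef is symmetric only up to rounding
    z = fisher_z(r)
    np.fill_diagonal(z, np.nan)
    return z


def matrices_to_pairs(matrices: np.ndarray) -> np.ndarray:
    """(n_subjects, K, K) stack -> (n_subjects, n_pairs) upper-triangle values."""
    matrices = np.asarray(matrices, np.float64)
    k = matrices.shape[1]
    iu = np.triu_indices(k, 1)
    return matrices[:, iu[0], iu[1]]


def _bh_table(pvals: np.ndarray, q: float) -> tuple[np.ndarray, float]:
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    realized = float(pvals[reject].max()) if reject.any() else np.nan
    return reject, realized


def pairwise_interaction_fdr(
    matrices: np.ndarray, design: GroupDesign, region_ids: list[str],
    q: float = 0.05,
) -> pd.DataFrame:
    """Diagnosis-by-sex interaction per region pair with BH-FDR over all pairs.

    ``matrices`` is a (n_subjects, K, K) Fisher-z stack.  The returned table
    has one row per unordered pair with estimate, t, p, reject flag; its
    ``attrs['realized_p_threshold']`` echoes the largest rejected p.
    """
    values = matrices_to_pairs(matrices)
    sm = fit_interaction(values, design)
    reject, realized = _bh_table(sm.p, q)
    pairs = pair_index(region_ids)
    table = pd.DataFrame(
        {
            "region_a": [a for a, _ in pairs],
            "region_b": [b for _, b in pairs],
            "estimate": sm.estimate,
            "t": sm.t,
            "p": sm.p,
            "reject": reject,
        }
    )
    table.attrs["q"] = q
    table.attrs["realized_p_threshold"] = realized
    table.attrs["df"] = sm.df
    return table


def restricted_within_sex(
    matrices: np.ndarray, design: GroupDesign, region_ids: list[str],
    surviving: pd.DataFrame | None = None, q: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """ASD-TD contrasts per sex, restricted to interaction-surviving pairs.

    BH runs at level q *within the restricted set only*.  With no surviving
    pairs both tables are empty (not an error).
    """
    if surviving is None:
        surviving = pairwise_interaction_fdr(matrices, design, region_ids, q)
    keep = surviving["reject"].to_numpy()
    values = matrices_to_pairs(matrices)[:, keep]
    pairs = [p for p, k in zip(pair_index(region_ids), keep) if k]
    out = {}
    for sex in ("F", "M"):
        if not pairs:
            table = pd.DataFrame(
                columns=["region_a", "region_b", "estimate", "t", "p", "reject"]
            )
            table.attrs["realized_p_threshold"] = np.nan
        else:
            sm = within_sex_contrast(values, design, sex)
            reject, realized = _bh_table(sm.p, q)
            table = pd.DataFrame(
                {
                    "region_a": [a for a, _ in pairs],
                    "region_b": [b for _, b in pairs],
                    "estimate": sm.estimate,
                    "t": sm.t,
                    "p": sm.p,
                    "reject": reject,
                }
            )
            table.attrs["realized_p_threshold"] = realized
            table.attrs["df"] = sm.df
        table.attrs["q"] = q
        out[sex] = table
    return out
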