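"""FC pattern-similarity tests: gender incoherence vs extreme male brain.

Each subject's FC pattern over the interaction-surviving region pairs is
compared to the mean pattern of TD males and of TD females, by Pearson
correlation (mean-invariant: pattern only) and by Euclidean distance
(pattern plus magnitude).  Per clinical group the two similarity series are
compared by a paired t-test when Shapiro-Wilk does not reject normality of
the paired differences, otherwise by the Wilcoxon signed-rank test.

When a subject is compared against their *own* group's reference mean, the
mean is recomputed without that subject (leave-one-out), avoiding
self-similarity bias.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "reference_mean_pattern",
    "pattern_correlation",
    "pattern_distance",
    "paired_similarity_test",
    "similarity_tables",
    "group_distance_table",
]

log = logging.getLogger(__name__)

CELLS = ("ASD_F", "ASD_M", "TD_F", "TD_M")


def reference_mean_pattern(vectors: np.ndarray, exclude: int | None = None) -> np.ndarray:
    """Element-wise mean pattern of a (n_subjects, n_pairs) group stack.

    ``exclude`` drops one row (leave-one-out for a probe subject belonging
    to the reference group).
    """
    vectors = np.atleast_2d(np.asarray(vectors, np.float64))
    if exclude is not None:
        if not 0 <= exclude < len(vectors):
            raise IndexError(f"exclude={exclude} out of range")
        vectors = np.delete(vectors, exclude, axis=0)
    if len(vectors) == 0:
        raise ValueError("reference group empty after exclusion")
    return vectors.mean(axis=0)


def pattern_correlation(v: np.ndarray, ref: np.ndarray) -> float:
    """Pearson correlation of two patterns (invariant to mean shifts)."""
    v = np.asarray(v, np.float64)
    ref = np.asarray(ref, np.float64)
    if v.shape != ref.shape:
        raise ValueError("pattern length mismatch")
    if v.size < 3:
        raise ValueError("need at least 3 pairs for a pattern correlation")
    if v.std() == 0 or ref.std() == 0:
        raise ValueError("constant pattern vector")
    return float(np.corrcoef(v, ref)[0, 1])


def pattern_distance(v: np.ndarray, ref: np.ndarray) -> float:
    """Euclidean distance between two patterns (sensitive to mean shifts)."""
    v = np.asarray(v, np.float64)
    ref = np.asarray(ref, np.float64)
    if v.shape != ref.shape:
        raise ValueError("pattern length mismatch")
    return float(np.linalg.norm(v - ref))


def paired_similarity_test(values_a, values_b, normality_alpha: float = 0.05):
    """Two-sided paired comparison with a Shapiro-Wilk normality gate.

    Returns (statistic, df, p, test_name); df is n - 1 for the paired t and
    NaN for the signed-rank branch.  Zero-variance differences give p = 1
    with a warning.
    """
    a = np.asarray(values_a, np.float64)
    b = np.asarray(values_b, np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1D samples of n >= 3")
    diffs = a - b
    if np.ptp(diffs) == 0:
        log.warning("paired differences have zero variance; p = 1")
        return 0.0, len(a) - 1, 1.0, "paired-t"
    _, p_norm = stats.shapiro(diffs)
    if p_norm >= normality_alpha:
        t, p = stats.ttest_rel(a, b)
        return float(t), len(a) - 1, float(p), "paired-t"
    log.info("normality rejected (Shapiro p=%.4g); using Wilcoxon signed-rank",
             p_norm)
    w, p = stats.wilcoxon(a, b)
    return float(w), float("nan"), float(p), "wilcoxon-signed-rank"


def _similarity_series(vectors_by_cell: dict[str, np.ndarray], probe_cell: str,
                       ref_cell: str, measure):
    """Per-subject similarity of a probe cell to a reference cell's mean."""
    probe = np.atleast_2d(vectors_by_cell[probe_cell])
    ref_stack = np.atleast_2d(vectors_by_cell[ref_cell])
    vals = []
    for i, v in enumerate(probe):
        ref = reference_mean_pattern(ref_stack,
                                     exclude=i if probe_cell == ref_cell else None)
        vals.append(measure(v, ref))
    return np.array(vals)


def similarity_tables(vectors_by_cell: dict[str, np.ndarray]) -> dict[str, pd.DataFrame]:
    """Per-clinical-group similarity to TD-female and TD-male reference means.

    Returns {'correlation': ..., 'distance': ...} tables with one row per
    ASD group: mean (SD) similarity to each TD reference plus the paired
    test between the two similarity series.
    """
    for cell in CELLS:
        if cell not in vectors_by_cell or len(np.atleast_2d(vectors_by_cell[cell])) == 0:
            raise ValueError(f"cell {cell} missing or empty")
    out = {}
    for name, measure in (("correlation", pattern_correlation),
                          ("distance", pattern_distance)):
        rows = []
        for group in ("ASD_F", "ASD_M"):
            to_f = _similarity_series(vectors_by_cell, group, "TD_F", measure)
            to_m = _similarity_series(vectors_by_cell, group, "TD_M", measure)
            stat, df, p, test = paired_similarity_test(to_f, to_m)
            rows.append({
                "group": group,
                "td_female_mean": to_f.mean(), "td_female_sd": to_f.std(ddof=1),
                "td_male_mean": to_m.mean(), "td_male_sd": to_m.std(ddof=1),
                "statistic": stat, "df": df, "p": p, "test": test,
            })
        out[name] = pd.DataFrame(rows)
    return out


def group_distance_table(vectors_by_cell: dict[str, np.ndarray]) -> pd.DataFrame:
    """4x2 descriptive table: mean (SD) Euclidean distance of every cell's
    members to the TD-female and TD-male reference means (leave-one-out
    within a subject's own cell)."""
    rows = []
    for cell in CELLS:
        if cell not in vectors_by_cell:
            raise ValueError(f"cell {cell} missing")
        row: dict[str, float | str] = {"group": cell}
        for ref_cell, tag in (("TD_F", "td_female"), ("TD_M", "td_male")):
            if len(np.atleast_2d(vectors_by_cell[ref_cell])) < 2 and cell == ref_cell:
                raise ValueError(f"singleton reference cell {ref_cell}")
            d = _similarity_series(vectors_by_cell, cell, ref_cell,
                                   pattern_distance)
            row[f"{tag}_mean"] = float(d.mean())
            row[f"{tag}_sd"] = float(d.std(ddof=1)) if len(d) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
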