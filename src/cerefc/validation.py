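"""Simulation studies validating the pipeline's statistical behaviour.

These routines re-run the pipeline (or its relevant stage) on freshly
generated synthetic data and measure operating characteristics: type-I
error of the voxel-wise interaction test, familywise error of the
Monte-Carlo cluster-size correction, false-discovery behaviour of the
region-pair BH step, recovery of the planted cerebellar crossover, and the
power of the pattern-similarity test under the gender-incoherence
construction.  They are used by the test suite and by the acceptance
script; all randomness derives from explicit seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .clusters import (ACFParams, NullFieldSimulator, cluster_threshold)
from .config import PipelineConfig
from .glm import GroupDesign, fit_interaction
from .grids import BinaryMask, VolumeGrid
from .masks import erode_mask
from .nuisance import LocalWMOperator
from .pipeline import analyze_cohort
from .simulate import CohortSimulation, SimulationDesign, \
    simulate_pattern_cohort
from .similarity import similarity_tables

__all__ = [
    "random_null_design",
    "voxelwise_type1",
    "cluster_fwe",
    "pairwise_fdr_null",
    "cluster_recovery_batch",
    "similarity_detection",
]

STUDY_SIZES = ((23, "ASD", "F"), (56, "ASD", "M"), (24, "TD", "F"),
               (65, "TD", "M"))


def random_null_design(rng: np.random.Generator) -> GroupDesign:
    """Study-sized cohort with covariates but no planted effects."""
    recs = []
    i = 0
    for n, dx, sx in STUDY_SIZES:
        for _ in range(n):
            recs.append({
                "subject": f"s{i:03d}", "diagnosis": dx, "sex": sx,
                "age": rng.normal(21.5, 8.0),
                "motion": rng.lognormal(-2.6, 0.5),
                "gcor": rng.uniform(0.05, 0.3),
            })
            i += 1
    return GroupDesign.from_cohort(pd.DataFrame(recs))


def voxelwise_type1(n_cohorts: int = 200, n_voxels: int = 9600,
                    voxel_p: float = 0.005, seed: int = 0):
    """Rejection rate of the interaction test on null cohorts.

    Subject maps are i.i.d. Gaussian (independent voxel tests, so the
    pooled rate admits an exact binomial interval).  Returns
    (rate, n_tests).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    rejections = 0
    n_subj = sum(n for n, _, _ in STUDY_SIZES)
    for _ in range(n_cohorts):
        design = random_null_design(rng)
        maps = rng.standard_normal((n_subj, n_voxels))
        sm = fit_interaction(maps, design)
        rejections += int((sm.p < voxel_p).sum())
    return rejections / (n_cohorts * n_voxels), n_cohorts * n_voxels


def cluster_fwe(acf: ACFParams | None = None, n_estimate: int = 1000,
                n_evaluate: int = 500, voxel_p: float = 0.005,
                alpha: float = 0.05, seed: int = 0):
    """Familywise error of the cluster-size threshold on fresh null fields.

    Estimates the size threshold from ``n_estimate`` simulated fields and
    measures the fraction of ``n_evaluate`` *fresh* fields with any
    surviving cluster.  Returns (fwe, threshold).
    """
    acf = acf or ACFParams(0.8, 4.0, 3.0)
    grid = VolumeGrid((20, 24, 20), (3.0, 3.0, 3.0))
    mask = BinaryMask(grid, np.ones(grid.dims, bool), "gray")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    thr = cluster_threshold(acf, mask, voxel_p, alpha, n_estimate, rng=rng)
    sim = NullFieldSimulator(grid, mask, acf)
    zthr = stats.norm.isf(voxel_p / 2)
    structure = ndimage.generate_binary_structure(3, 1)
    hits = 0
    for _ in range(n_evaluate):
        field = sim.simulate(rng)
        sup = np.abs(field) >= zthr
        labels, n_lab = ndimage.label(sup, structure=structure)
        if n_lab and np.bincount(labels.ravel())[1:].max() >= thr:
            hits += 1
    return hits / n_evaluate, thr


def pairwise_fdr_null(n_sims: int = 500, n_pairs: int = 105, q: float = 0.05,
                      seed: int = 0):
    """Mean false-discovery proportion of the region-pair BH step under the
    global null (every discovery is false, so FDP is 1 when anything is
    rejected)."""
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    n_subj = sum(n for n, _, _ in STUDY_SIZES)
    fdp = 0.0
    for _ in range(n_sims):
        design = random_null_design(rng)
        values = rng.standard_normal((n_subj, n_pairs))
        pvals = fit_interaction(values, design).p
        reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
        fdp += float(reject.any())
    return fdp / n_sims


def _matches_center(cluster, center, voxel_mm=3.0, tol_mm=9.0) -> bool:
    d = np.linalg.norm((cluster.voxels - np.asarray(center)) * voxel_mm,
                       axis=1)
    return bool(d.min() <= tol_mm)


def cluster_recovery_batch(n_cohorts: int = 20, base_seed: int = 200,
                           design_kwargs: dict | None = None) -> pd.DataFrame:
    """Full-pipeline recovery of the planted cerebellar crossover.

    For each cohort: does a surviving small-volume-corrected cluster cover
    each planted cerebellar region, with ASD > TD connectedness in females
    and ASD < TD in males at those clusters; and do the restricted
    within-sex contrasts carry the planted sign pattern (all rejected
    planted pairs positive in females, negative in males)?
    """
    rows = []
    wm_op = None
    for c in range(n_cohorts):
        seed = base_seed + c
        design = SimulationDesign(rng_seed=seed, **(design_kwargs or {}))
        sim = CohortSimulation(design)
        if wm_op is None:
            wm_op = LocalWMOperator(sim.masks.gray,
                                    erode_mask(sim.masks.white, 1), 15.0)
        res = analyze_cohort(sim, PipelineConfig(rng_seed=seed),
                             run_seed_stage=False, wm_op=wm_op)
        centers = [ctr for rid, ctr, _ in design.region_layout
                   if rid.startswith("cereb")]
        cross = res.crossover.set_index("cluster")
        both = True
        for center in centers:
            hit = [cl for cl in res.report_cerebellum.surviving()
                   if _matches_center(cl, center,
                                      design.grid.voxel_size_mm[0])]
            if not hit:
                both = False
                continue
            row = cross.loc[hit[0].id]
            if not (row.female_asd_minus_td > 0 and row.male_asd_minus_td < 0):
                both = False
        planted = {frozenset(p) for p in sim.truth.interaction_pairs}
        sex_ok = True
        for sex, want in (("F", 1.0), ("M", -1.0)):
            tbl = res.within_sex[sex]
            tbl = tbl[tbl["reject"]]
            tbl = tbl[[frozenset((a, b)) in planted
                       for a, b in zip(tbl["region_a"], tbl["region_b"])]]
            if len(tbl) == 0 or not (np.sign(tbl["estimate"]) == want).all():
                sex_ok = False
        rows.append({"seed": seed, "both_clusters_with_crossover": both,
                     "within_sex_sign_pattern": sex_ok,
                     "n_fdr_pairs": int(res.interaction_pairs["reject"].sum())})
    return pd.DataFrame(rows)


def similarity_detection(n_cohorts: int = 50, base_seed: int = 1000) -> float:
    """Fraction of gender-incoherence cohorts where the distance-based
    paired test detects greater ASD-female similarity to the TD-male
    reference (correct direction, p < 0.05)."""
    detected = 0
    for c in range(n_cohorts):
        cells = simulate_pattern_cohort(
            rng=np.random.default_rng(
                np.random.SeedSequence(base_seed + c, spawn_key=(4,))))
        row = similarity_tables(cells)["distance"].set_index("group").loc[
            "ASD_F"]
        if row["td_male_mean"] < row["td_female_mean"] and row["p"] < 0.05:
            detected += 1
    return detected / n_cohorts
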