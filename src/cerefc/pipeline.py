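"""End-to-end orchestration of the connectivity analysis.

Stages, mirroring the study design:

1. per subject: percent-signal-change scaling, localized nuisance
   regression (ventricle mean + per-voxel 15 mm WM average + 6 motion
   parameters + 4th-order baseline), then the whole-brain connectedness
   map, GCOR and the mm/TR motion summary;
2. voxel-wise 2x2 diagnosis-by-sex OLS on Fisher-z connectedness with
   age/motion/GCOR covariates;
3. spatial-ACF estimation from the model residual maps, Monte-Carlo
   cluster-size thresholds (whole brain and cerebellar small-volume);
4. post hoc 6 mm seed spheres at surviving cerebellar peaks, seed-map
   interaction tests cluster-corrected at alpha / n_seeds (Bonferroni);
5. region-pair Fisher-z matrices, interaction BH-FDR over all pairs,
   within-sex contrasts restricted to surviving pairs;
6. pattern-similarity tests of the surviving-pair FC vectors against the
   TD-male and TD-female reference means.

Nuisance regressors are extracted from the *unsmoothed* scaled data; the
regression itself is applied to the smoothed scaled data, whose residuals
feed all connectivity stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import (ACFParams, ClusterReport, cluster_threshold,
                       estimate_acf, label_clusters, peak_to_seed)
from .config import PipelineConfig
from .connectivity import fisher_z, motion_summary
from .glm import GroupDesign, StatMap, fit_interaction, match_groups, \
    within_sex_contrast
from .grids import BinaryMask
from .masks import erode_mask
from .network import (RegionSet, fc_matrix, pairwise_interaction_fdr,
                      restricted_within_sex)
from .nuisance import LocalWMOperator, NuisanceDesign, regress_nuisance_matrix
from .simulate import CELLS, CohortSimulation, SubjectData, TissueMasks
from .similarity import group_distance_table, similarity_tables

__all__ = [
    "SubjectFeatures",
    "PipelineResult",
    "preprocess_subject",
    "subject_features",
    "analyze_cohort",
    "regions_from_seed_maps",
]

log = logging.getLogger(__name__)


def _psc_rows(values_4d: np.ndarray, member: np.ndarray,
              min_mean: float = 1e-6) -> np.ndarray:
    """Percent-signal-change scaling of the voxel rows selected by a mask."""
    rows = np.asarray(values_4d[member], np.float64)
    means = rows.mean(axis=1, keepdims=True)
    bad = np.abs(means[:, 0]) <= min_mean
    if bad.any():
        log.warning("%d near-zero-mean voxels zeroed during scaling",
                    int(bad.sum()))
        means[bad] = 1.0
        rows[bad] = 0.0
    return rows / means * 100.0


def preprocess_subject(
    subj: SubjectData,
    masks: TissueMasks,
    wm_op: LocalWMOperator,
    config: PipelineConfig,
) -> np.ndarray:
    """Nuisance-regressed residual series for the gray mask, (n_gray, T).

    Ventricle and localized WM regressors come from the unsmoothed scaled
    series; the regression is applied to the smoothed scaled series.
    """
    vent = _psc_rows(subj.series.values,
                     masks.ventricle.membership).mean(axis=0)
    local_wm = wm_op.apply_matrix(
        _psc_rows(subj.series.values, wm_op.wm_mask.membership))
    y = _psc_rows(subj.series_smoothed.values, masks.gray.membership)
    design = NuisanceDesign(
        ventricle_series=vent,
        motion_series=subj.motion,
        local_wm=local_wm,
        polynomial_order=config.polynomial_order,
    )
    return regress_nuisance_matrix(y, design)


@dataclass
class SubjectFeatures:
    subject: str
    cell: str
    conn_values: np.ndarray          # Fisher-z connectedness per gray voxel
    region_series: np.ndarray        # (K, T) mean residual series
    gcor: float
    motion: float
    residuals: np.ndarray | None = None   # (n_gray, T) float32, optional


def subject_features(
    subj: SubjectData,
    masks: TissueMasks,
    wm_op: LocalWMOperator,
    config: PipelineConfig,
    regions: RegionSet,
    keep_residuals: bool = False,
) -> SubjectFeatures:
    from .connectivity import (connectedness_values,
                               connectedness_values_z_first, gcor_value)

    resid = preprocess_subject(subj, masks, wm_op, config)
    conn_fn = (connectedness_values_z_first if config.z_before_average
               else connectedness_values)
    return SubjectFeatures(
        subject=subj.subject,
        cell=subj.cell,
        conn_values=conn_fn(resid),
        region_series=_region_series_from_residuals(resid, regions, masks.gray),
        gcor=gcor_value(resid),
        motion=motion_summary(subj.motion, config.rotation_radius_mm),
        residuals=resid.astype(np.float32) if keep_residuals else None,
    )


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: pd.DataFrame                      # with motion and gcor columns
    masks: TissueMasks
    interaction_map: StatMap
    acf: ACFParams
    threshold_wholebrain: int
    threshold_cerebellum: int
    report_wholebrain: ClusterReport
    report_cerebellum: ClusterReport
    crossover: pd.DataFrame                   # per surviving cerebellar cluster
    seeds: list[BinaryMask] = field(default_factory=list)
    seed_reports: list[ClusterReport] = field(default_factory=list)
    seed_maps: list[StatMap] = field(default_factory=list)
    regions: RegionSet | None = None
    fc_matrices: np.ndarray | None = None     # (n, K, K)
    interaction_pairs: pd.DataFrame | None = None
    within_sex: dict[str, pd.DataFrame] | None = None
    similarity: dict[str, pd.DataFrame] | None = None
    distance_table: pd.DataFrame | None = None
    matching: pd.DataFrame | None = None


def _restrict_map(sm: StatMap, sub_mask: BinaryMask) -> StatMap:
    """View of a gray-mask StatMap limited to a sub-mask of the gray mask."""
    gray = sm.mask.membership
    sel = sub_mask.membership[gray]
    return StatMap(sm.estimate[sel], sm.t[sel], sm.p[sel], sm.df,
                   grid=sm.grid, mask=sub_mask)


def _crossover_table(
    report: ClusterReport, conn_stack: np.ndarray, gray_mask: BinaryMask,
    design: GroupDesign,
) -> pd.DataFrame:
    """Within-sex ASD-TD contrasts of cluster-mean connectedness, per
    surviving cluster: the crossover direction check."""
    gray_lin = np.full(gray_mask.grid.dims, -1, np.int64)
    gray_lin[gray_mask.membership] = np.arange(gray_mask.n_voxels)
    rows = []
    for c in report.surviving():
        cols = gray_lin[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]]
        cols = cols[cols >= 0]
        vals = conn_stack[:, cols].mean(axis=1, keepdims=True)
        f = within_sex_contrast(vals, design, "F")
        m = within_sex_contrast(vals, design, "M")
        rows.append({
            "cluster": c.id, "size_voxels": c.size,
            "peak_i": c.peak_voxel[0], "peak_j": c.peak_voxel[1],
            "peak_k": c.peak_voxel[2],
            "female_asd_minus_td": float(f.estimate[0]),
            "female_p": float(f.p[0]),
            "male_asd_minus_td": float(m.estimate[0]),
            "male_p": float(m.p[0]),
        })
    return pd.DataFrame(rows)


def regions_from_seed_maps(
    seeds: list[BinaryMask],
    seed_reports: list[ClusterReport],
    grid,
    radius_mm: float = 6.0,
    cerebellum: BinaryMask | None = None,
) -> RegionSet:
    """Build the analysis region set the way the study did: the seed
    spheres plus one sphere at the peak of every surviving seed-map cluster
    outside the cerebellum."""
    ids, masks_ = [], []
    for i, seed in enumerate(seeds, start=1):
        ids.append(f"seed_{i:02d}")
        masks_.append(seed)
    n = 0
    for i, rep in enumerate(seed_reports, start=1):
        for sphere in peak_to_seed(rep, grid, radius_mm):
            if cerebellum is not None:
                peak_in_cereb = bool(
                    (sphere.membership & cerebellum.membership).sum()
                    > sphere.n_voxels / 2
                )
                if peak_in_cereb:
                    continue
            n += 1
            ids.append(f"region_{n:02d}")
            masks_.append(sphere)
    return RegionSet(ids, masks_)


def analyze_cohort(
    sim: CohortSimulation,
    config: PipelineConfig | None = None,
    regions: RegionSet | None = None,
    run_seed_stage: bool = True,
    use_planted_regions: bool = True,
    wm_op: LocalWMOperator | None = None,
) -> PipelineResult:
    """Run every analysis stage on a (streamed) synthetic cohort.

    regions: the region set for the matrix stage; defaults to the planted
    layout when ``use_planted_regions`` (the data-driven alternative,
    :func:`regions_from_seed_maps`, requires ``run_seed_stage``).
    Residual series are retained (float32) only when the seed stage runs.
    A prebuilt ``wm_op`` may be passed when many cohorts share one mask
    geometry.
    """
    config = config or PipelineConfig()
    masks = sim.masks
    if wm_op is None:
        wm_eroded = erode_mask(masks.white, 1)
        wm_op = LocalWMOperator(masks.gray, wm_eroded,
                                config.wm_sphere_radius_mm)
    layout_regions = masks.regions

    feats = [
        subject_features(s, masks, wm_op, config, layout_regions,
                         keep_residuals=run_seed_stage)
        for s in sim
    ]
    cohort = sim.cohort.copy()
    cohort["motion"] = [f.motion for f in feats]
    cohort["gcor"] = [f.gcor for f in feats]
    design = GroupDesign.from_cohort(cohort)

    conn_stack = np.stack([f.conn_values for f in feats])     # (n, n_gray)
    sm = fit_interaction(conn_stack, design, grid=sim.design.grid,
                         mask=masks.gray, keep_residuals=True)
    resid_vols = [_embed_map(r, masks.gray) for r in sm.residuals]
    acf = estimate_acf(resid_vols, masks.gray)
    sm.residuals = None

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(101,)))
    thr_wb = cluster_threshold(acf, masks.gray, config.voxel_p_threshold,
                               config.cluster_alpha, config.n_null_fields,
                               df=sm.df, rng=rng)
    thr_cb = cluster_threshold(acf, masks.cerebellum, config.voxel_p_threshold,
                               config.cluster_alpha, config.n_null_fields,
                               df=sm.df, rng=rng)
    report_wb = label_clusters(sm, config.voxel_p_threshold,
                               size_threshold=thr_wb,
                               alpha=config.cluster_alpha)
    sm_cereb = _restrict_map(sm, masks.cerebellum)
    report_cb = label_clusters(sm_cereb, config.voxel_p_threshold,
                               size_threshold=thr_cb,
                               alpha=config.cluster_alpha)
    crossover = _crossover_table(report_cb, conn_stack, masks.gray, design)

    result = PipelineResult(
        config=config, cohort=cohort, masks=masks, interaction_map=sm,
        acf=acf, threshold_wholebrain=thr_wb, threshold_cerebellum=thr_cb,
        report_wholebrain=report_wb, report_cerebellum=report_cb,
        crossover=crossover,
    )

    if run_seed_stage and report_cb.surviving():
        result.seeds = peak_to_seed(report_cb, sim.design.grid,
                                    config.seed_radius_mm)
        n_seeds = len(result.seeds)
        seed_alpha = config.cluster_alpha / n_seeds
        thr_seed = cluster_threshold(acf, masks.gray,
                                     config.voxel_p_threshold, seed_alpha,
                                     config.n_null_fields, df=sm.df, rng=rng)
        for seed in result.seeds:
            zmaps = np.stack([
                _seed_map_values(f.residuals, seed, masks.gray)
                for f in feats
            ])
            seed_sm = fit_interaction(zmaps, design, grid=sim.design.grid,
                                      mask=masks.gray)
            result.seed_maps.append(seed_sm)
            result.seed_reports.append(
                label_clusters(seed_sm, config.voxel_p_threshold,
                               size_threshold=thr_seed, alpha=seed_alpha)
            )
    if regions is None:
        if use_planted_regions:
            regions = layout_regions
        elif result.seed_reports:
            regions = regions_from_seed_maps(
                result.seeds, result.seed_reports, sim.design.grid,
                config.seed_radius_mm, cerebellum=masks.cerebellum,
            )
    if regions is not None and len(regions) >= 2:
        result.regions = regions
        if regions is layout_regions:
            series = [f.region_series for f in feats]
        else:
            # region set differs from the planted layout: re-extract means
            # from the retained residual matrices
            if feats[0].residuals is None:
                raise ValueError(
                    "custom region sets need run_seed_stage=True (residual "
                    "series are only retained on that path)"
                )
            series = [
                _region_series_from_residuals(f.residuals, regions, masks.gray)
                for f in feats
            ]
        result.fc_matrices = np.stack([fc_matrix(rs) for rs in series])
        result.interaction_pairs = pairwise_interaction_fdr(
            result.fc_matrices, design, regions.ids, q=config.fdr_q)
        result.within_sex = restricted_within_sex(
            result.fc_matrices, design, regions.ids,
            surviving=result.interaction_pairs, q=config.fdr_q)

        keep = result.interaction_pairs["reject"].to_numpy()
        if keep.sum() >= 3:
            from .network import matrices_to_pairs

            vec = matrices_to_pairs(result.fc_matrices)[:, keep]
            cells = np.array([f.cell for f in feats])
            vectors_by_cell = {c: vec[cells == c] for c in CELLS}
            result.similarity = similarity_tables(vectors_by_cell)
            result.distance_table = group_distance_table(vectors_by_cell)
        else:
            log.info("fewer than 3 surviving pairs; similarity stage skipped")
    for f in feats:
        f.residuals = None

    match_vars = [v for v in ("age", "motion", "gcor", "iq")
                  if v in cohort.columns]
    result.matching = match_groups(cohort, match_vars)
    return result


def _embed_map(values: np.ndarray, mask: BinaryMask) -> np.ndarray:
    out = np.zeros(mask.grid.dims)
    out[mask.membership] = values
    return out


def _region_series_from_residuals(resid: np.ndarray, regions: RegionSet,
                                  gray_mask: BinaryMask) -> np.ndarray:
    """(K, T) mean residual series per region from a (n_gray, T) matrix."""
    out = np.empty((len(regions), resid.shape[1]))
    for k, (rid, mask) in enumerate(zip(regions.ids, regions.masks)):
        sel = mask.membership[gray_mask.membership]
        if not sel.any():
            raise ValueError(f"region {rid!r} is empty after gray masking")
        out[k] = resid[sel].astype(np.float64).mean(axis=0)
    return out


def _seed_map_values(resid: np.ndarray, seed: BinaryMask,
                     gray_mask: BinaryMask) -> np.ndarray:
    """Fisher-z seed correlation per gray voxel, from a (n_gray, T) matrix."""
    sel = seed.membership[gray_mask.membership]
    if not sel.any():
        raise ValueError("seed lies outside the gray mask")
    seed_series = resid[sel].astype(np.float64).mean(axis=0)
    seed_series -= seed_series.mean()
    nrm = np.linalg.norm(seed_series)
    if nrm == 0:
        raise ValueError("seed mean series is constant")
    seed_series /= nrm
    data = resid.astype(np.float64)
    data = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(data, axis=1)
    norms[norms == 0] = 1.0
    return fisher_z((data / norms[:, None]) @ seed_series)
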